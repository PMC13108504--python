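"""Longitudinal and case-control inference on network measures.

Developmental change is modelled per epoch — development (PND 20-35) and
aging (PND 63-230) — with linear mixed models:

    node level:  normalized strength ~ age + TBV + (1 | subject)
    edge level (system pairs, pooling constituent ROI-edges):
                 normalized weight ~ age + TBV + (1 | subject) + (1 | ROI-edge)

The age t-statistic is the standardized effect (Ds for strength, Dw for
edges); |t| > 2 flags node-level change and |t| > 3.3 edge-level change.

Early-life-stress contrasts at the adult timepoint use fixed-effect models
(group + sex + age + TBV, plus an ROI-edge random intercept at the edge
level); the group coefficient is the case-control effect size, scored by a
z within a subject-level group-permutation distribution (|z| > 1.96
significant). The coupling of stress effects with developmental change is a
Pearson correlation tested by permuting the edge assignment of effects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from ._common import PipelineError, derive_seed

log = logging.getLogger(__name__)

EPOCHS = {"development": (20.0, 35.0), "aging": (63.0, 230.0)}
NODE_T_THRESHOLD = 2.0
EDGE_T_THRESHOLD = 3.3
GROUP_Z_THRESHOLD = 1.96


def normalize_measure(values) -> np.ndarray:
    """z-score a measure across the observations entering one model fit."""
    arr = np.asarray(values, dtype=float)
    if len(np.unique(arr[np.isfinite(arr)])) < 2:
        raise ValueError("cannot normalize a constant (or empty) vector")
    return (arr - np.nanmean(arr)) / np.nanstd(arr, ddof=1)


def select_epoch(cohort: pd.DataFrame, epoch: str) -> pd.DataFrame:
    """Subset scans to one epoch's inclusive age window."""
    if epoch not in EPOCHS:
        raise ValueError(f"unknown epoch {epoch!r}; expected one of {list(EPOCHS)}")
    lo, hi = EPOCHS[epoch]
    out = cohort[(cohort["age_pnd"] >= lo) & (cohort["age_pnd"] <= hi)]
    if out.empty:
        raise PipelineError(f"no scans fall in the {epoch} epoch [{lo}, {hi}]")
    return out.reset_index(drop=True)


@dataclass
class SlopeResult:
    unit: str
    epoch: str
    beta_age: float
    t_stat: float
    p_value: float
    significant: bool
    n_obs: int
    fallback_ols: bool = False
    flagged: bool = False  # singular/failed fit; exclude from downstream maps
    q_value: float = float("nan")


def _fit_mixed(df: pd.DataFrame, formula: str, groups: str | None,
               vc_formula: dict | None = None):
    """REML mixed fit with OLS fallback on non-convergence/singularity.

    Returns (beta_age, t_age, p_age, fallback, flagged).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        # singular RE covariance is expected when network-level measures
        # carry no subject variance (common shifts cancel in similarity)
        warnings.filterwarnings("ignore", message="Random effects covariance is singular")
        try:
            if groups is not None:
                model = smf.mixedlm(formula, df, groups=df[groups],
                                    vc_formula=vc_formula)
            else:
                model = smf.mixedlm(formula, df,
                                    groups=np.ones(len(df), dtype=int),
                                    vc_formula=vc_formula)
            fit = model.fit(reml=True, method=["lbfgs", "bfgs"])
            if fit.converged and np.isfinite(fit.bse.get("age", np.nan)):
                return (float(fit.params["age"]), float(fit.tvalues["age"]),
                        float(fit.pvalues["age"]), False, False)
        except (np.linalg.LinAlgError, ValueError, KeyError) as exc:
            log.debug("mixed fit failed (%s); falling back to OLS", exc)
    try:
        fit = smf.ols(formula, df).fit()
        return (float(fit.params["age"]), float(fit.tvalues["age"]),
                float(fit.pvalues["age"]), True, False)
    except (np.linalg.LinAlgError, ValueError):
        return (float("nan"), float("nan"), float("nan"), True, True)


def fit_node_slope(observations: pd.DataFrame, region: str,
                   epoch: str = "development",
                   t_threshold: float = NODE_T_THRESHOLD) -> SlopeResult:
    """Age slope of one region's normalized strength within an epoch.

    ``observations`` needs columns subject, age_pnd, tbv and ``value``
    (the region's strength per scan). The subject enters as a random
    intercept; on singular or non-converging fits an ordinary regression is
    used and flagged.
    """
    df = observations.dropna(subset=["value", "age_pnd", "tbv"]).copy()
    if df.empty or df["value"].nunique() < 2:
        return SlopeResult(unit=region, epoch=epoch, beta_age=np.nan,
                           t_stat=np.nan, p_value=np.nan, significant=False,
                           n_obs=len(df), fallback_ols=True, flagged=True)
    df["norm_value"] = normalize_measure(df["value"])
    df = df.rename(columns={"age_pnd": "age"})
    multi = (df.groupby("subject")["age"].nunique() >= 2).sum() >= 2
    if multi:
        beta, t, p, fb, flag = _fit_mixed(df, "norm_value ~ age + tbv",
                                          groups="subject")
    else:
        # single timepoint per subject: random intercept unidentifiable
        beta, t, p, fb, flag = _fit_mixed(df, "norm_value ~ age + tbv",
                                          groups=None)
        fb = True
    return SlopeResult(unit=region, epoch=epoch, beta_age=beta, t_stat=t,
                       p_value=p, significant=bool(np.abs(t) > t_threshold),
                       n_obs=len(df), fallback_ols=fb, flagged=flag)


def fit_system_edge_slope(observations: pd.DataFrame,
                          system_pair: tuple[str, str],
                          epoch: str = "development",
                          t_threshold: float = EDGE_T_THRESHOLD) -> SlopeResult:
    """Age slope of normalized weight for one system pair, pooling ROI edges.

    ``observations`` needs columns subject, age_pnd, tbv, roi_edge, value —
    one row per (scan, constituent ROI-level edge). Subject and ROI-edge
    both enter as (crossed) random intercepts, implemented as variance
    components; degenerate designs fall back to ordinary regression.
    """
    unit = "--".join(sorted(system_pair))
    df = observations.dropna(subset=["value", "age_pnd", "tbv"]).copy()
    if df.empty or df["value"].nunique() < 2:
        return SlopeResult(unit=unit, epoch=epoch, beta_age=np.nan,
                           t_stat=np.nan, p_value=np.nan, significant=False,
                           n_obs=len(df), fallback_ols=True, flagged=True)
    df["norm_value"] = normalize_measure(df["value"])
    df = df.rename(columns={"age_pnd": "age"})
    n_edges = df["roi_edge"].nunique()
    n_subj = df["subject"].nunique()
    if n_edges >= 2 and n_subj >= 2:
        vc = {"subject": "0 + C(subject)", "roi_edge": "0 + C(roi_edge)"}
        beta, t, p, fb, flag = _fit_mixed(df, "norm_value ~ age + tbv",
                                          groups=None, vc_formula=vc)
    else:
        beta, t, p, fb, flag = _fit_mixed(df, "norm_value ~ age + tbv",
                                          groups="subject" if n_subj >= 2
                                          else None)
        fb = True
    return SlopeResult(unit=unit, epoch=epoch, beta_age=beta, t_stat=t,
                       p_value=p, significant=bool(np.abs(t) > t_threshold),
                       n_obs=len(df), fallback_ols=fb, flagged=flag)


def adjust_slopes_fdr(results: list[SlopeResult]) -> list[SlopeResult]:
    """Attach Benjamini-Hochberg q-values across a family of slope fits."""
    ok = [r for r in results if np.isfinite(r.p_value)]
    if ok:
        q = multipletests([r.p_value for r in ok], method="fdr_bh")[1]
        for r, qv in zip(ok, q):
            r.q_value = float(qv)
    return results


def epoch_coupling(dev: list[SlopeResult], age: list[SlopeResult]):
    """Pearson correlation between development and aging t-statistics."""
    dmap = {r.unit: r.t_stat for r in dev if not r.flagged}
    amap = {r.unit: r.t_stat for r in age if not r.flagged}
    units = sorted(set(dmap) & set(amap))
    if set(dmap) != set(amap):
        raise ValueError(
            f"unit mismatch between epochs: {sorted(set(dmap) ^ set(amap))}")
    x = np.array([dmap[u] for u in units])
    y = np.array([amap[u] for u in units])
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), len(units)


def fit_group_effect(observations: pd.DataFrame, unit: str,
                     edge_level: bool = False) -> float:
    """Case-control effect size: the group coefficient at the adult timepoint.

    Node level fits value ~ group + sex + age + TBV by ordinary regression;
    edge level adds an ROI-edge random intercept. Rows with missing TBV are
    dropped with a warning. The coefficient is reported for the stressed
    group relative to control.
    """
    df = observations.copy()
    n_missing = df["tbv"].isna().sum()
    if n_missing:
        warnings.warn(f"{unit}: dropping {n_missing} scans with missing TBV",
                      stacklevel=2)
        df = df.dropna(subset=["tbv"])
    if df["group"].nunique() < 2:
        raise ValueError(f"{unit}: both groups must be present")
    df["norm_value"] = normalize_measure(df["value"])
    df = df.rename(columns={"age_pnd": "age"})
    formula = ("norm_value ~ C(group, Treatment(reference='control')) "
               "+ C(sex) + age + tbv")
    key = "C(group, Treatment(reference='control'))[T.stressed]"
    if df["sex"].nunique() < 2:
        formula = formula.replace("+ C(sex) ", "")
    if df["age"].nunique() < 2:
        formula = formula.replace("+ age ", "")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.filterwarnings("ignore", message="Random effects covariance is singular")
        if edge_level and df["roi_edge"].nunique() >= 2:
            try:
                fit = smf.mixedlm(formula, df, groups=df["roi_edge"]).fit(
                    reml=True, method=["lbfgs", "bfgs"])
                return float(fit.params[key])
            except (np.linalg.LinAlgError, ValueError, KeyError):
                log.debug("%s: edge mixed fit failed; OLS fallback", unit)
        fit = smf.ols(formula, df).fit()
    return float(fit.params[key])


@dataclass
class GroupEffectResult:
    unit: str
    effect: float
    z_perm: float
    significant: bool
    n_perm: int
    flagged: bool = False


def permuted_group_null(observations: pd.DataFrame, unit: str,
                        n_perm: int = 1000, seed: int = 0,
                        edge_level: bool = False,
                        z_threshold: float = GROUP_Z_THRESHOLD
                        ) -> GroupEffectResult:
    """Permutation z-score of the case-control effect for one unit.

    Group labels are permuted at the subject level (a subject's scans move
    together), the effect refit under each permutation, and the observed
    effect scored as a z within that null distribution.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    observed = fit_group_effect(observations, unit, edge_level=edge_level)
    subj = observations[["subject", "group"]].drop_duplicates("subject")
    subjects = subj["subject"].to_numpy()
    labels = subj["group"].to_numpy()
    rng = np.random.default_rng(derive_seed(seed, unit))
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = dict(zip(subjects, labels[rng.permutation(len(labels))]))
        shuffled = observations.copy()
        shuffled["group"] = shuffled["subject"].map(perm)
        null[b] = fit_group_effect(shuffled, unit, edge_level=edge_level)
    sd = null.std(ddof=1)
    if sd == 0:
        warnings.warn(f"{unit}: degenerate permutation SD", stacklevel=2)
        return GroupEffectResult(unit=unit, effect=observed, z_perm=np.nan,
                                 significant=False, n_perm=n_perm,
                                 flagged=True)
    z = (observed - null.mean()) / sd
    return GroupEffectResult(unit=unit, effect=observed, z_perm=float(z),
                             significant=bool(abs(z) > z_threshold),
                             n_perm=n_perm)


def stress_development_coupling(group_effects, dev_slopes,
                                n_perm: int = 10_000, seed: int = 0,
                                alternative: str = "greater"):
    """Correlation of edge-level stress effects with developmental change.

    Both arguments are mappings (or Series) keyed by edge unit. The observed
    Pearson r is compared with a null built by randomly reassigning the
    effect values across edges.
    """
    from .topology import permutation_z_p

    ge = pd.Series(dict(group_effects) if not isinstance(group_effects, pd.Series)
                   else group_effects)
    ds = pd.Series(dict(dev_slopes) if not isinstance(dev_slopes, pd.Series)
                   else dev_slopes)
    if set(ge.index) != set(ds.index):
        raise ValueError(
            f"edge sets differ: {sorted(set(ge.index) ^ set(ds.index))}")
    units = sorted(ge.index)
    x = ge[units].to_numpy(dtype=float)
    y = ds[units].to_numpy(dtype=float)
    observed = float(stats.pearsonr(x, y).statistic)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = np.corrcoef(x[rng.permutation(len(x))], y)[0, 1]
    return permutation_z_p(observed, null, alternative=alternative)


def strength_distribution_tests(strengths_by_timepoint: dict
                                ) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis omnibus plus Dunn pairwise tests across timepoints.

    ``strengths_by_timepoint`` maps a timepoint label to that timepoint's
    vector of per-region (median) strengths. Returns (H, omnibus p, pairwise
    table with BH-adjusted q-values). The Dunn statistic uses tie-corrected
    rank sums with two-sided normal p-values.
    """
    groups = {k: np.asarray(v, dtype=float)
              for k, v in strengths_by_timepoint.items()}
    if len(groups) < 2 or any(len(v) < 3 for v in groups.values()):
        raise ValueError("need >= 2 timepoints with >= 3 values each")
    keys = sorted(groups)
    h_stat, omnibus_p = stats.kruskal(*[groups[k] for k in keys])

    pooled = np.concatenate([groups[k] for k in keys])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_rank, sizes, pos = {}, {}, 0
    for k in keys:
        nk = len(groups[k])
        mean_rank[k] = ranks[pos:pos + nk].mean()
        sizes[k] = nk
        pos += nk
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            se = np.sqrt(var_base * (1 / sizes[a] + 1 / sizes[b]))
            z = (mean_rank[a] - mean_rank[b]) / se
            p = 2 * stats.norm.sf(abs(z))
            rows.append({"timepoint_a": a, "timepoint_b": b,
                         "z": float(z), "p_value": float(p)})
    table = pd.DataFrame(rows)
    table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return float(h_stat), float(omnibus_p), table
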