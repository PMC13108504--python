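"""Mixed-model slopes, case-control permutation inference, coupling, Dunn tests."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mindrat as mr
from mindrat import PipelineError
from mindrat import pipeline as pl
from mindrat import synthetic as syn


def make_cohort_strengths(truth, parc, n_subjects=12, timepoints=(20, 35),
                          groups=None, seed=0):
    """Generate a cohort and return its long strength table."""
    spec = syn.CohortSpec(n_subjects=n_subjects, timepoints=list(timepoints),
                         groups=groups or {"control": 1.0}, seed=seed)
    scans, cohort = syn.generate_cohort(spec, truth)
    params = mr.MindParams(estimator="analytic")
    nets = {sid: mr.build_mind_network(v, parc, params)
            for sid, v in scans.items()}
    return pl.strength_table(nets, cohort), nets, cohort


class TestNormalizeMeasure:
    def test_sample_sd_default(self):
        out = mr.normalize_measure([1.0, 2.0, 3.0])
        assert np.allclose(out, [-1.0, 0.0, 1.0])

    def test_idempotent_on_standardized(self, rng):
        v = mr.normalize_measure(rng.normal(size=50))
        assert np.allclose(mr.normalize_measure(v), v, atol=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            mr.normalize_measure([2.0, 2.0, 2.0])


class TestSelectEpoch:
    @pytest.fixture
    def cohort(self):
        return pd.DataFrame({"scan_id": list("abcd"),
                             "age_pnd": [20.0, 35.0, 63.0, 230.0]})

    def test_development_window(self, cohort):
        sub = mr.select_epoch(cohort, "development")
        assert sorted(sub.age_pnd) == [20.0, 35.0]

    def test_aging_window(self, cohort):
        sub = mr.select_epoch(cohort, "aging")
        assert sorted(sub.age_pnd) == [63.0, 230.0]

    def test_empty_epoch_rejected(self):
        cohort = pd.DataFrame({"scan_id": ["a"], "age_pnd": [50.0]})
        with pytest.raises(PipelineError):
            mr.select_epoch(cohort, "development")

    def test_unknown_epoch_rejected(self, cohort):
        with pytest.raises(ValueError):
            mr.select_epoch(cohort, "adolescence")


class TestNodeSlope:
    def test_planted_slope_sign_recovered(self, truth, parcellation):
        """The development slope planted on system S00 changes targeted
        strengths in the direction given by the analytic truth, and the
        fitted age t statistics recover that direction in most cohorts."""
        from conftest import true_strengths

        expected = np.sign(true_strengths(truth, 35.0)
                           - true_strengths(truth, 20.0))
        target = [m.region_id for m in truth.region_models
                  if m.system_id == "S00"]
        hits = total = 0
        for c in range(5):
            st, _, _ = make_cohort_strengths(truth, parcellation, seed=100 + c)
            sub = mr.select_epoch(st, "development")
            for region, g in sub.groupby("unit"):
                if region in target:
                    res = mr.fit_node_slope(g, region)
                    hits += np.sign(res.t_stat) == expected[region]
                    total += 1
        assert hits / total >= 0.9

    def test_single_timepoint_falls_back(self, truth, parcellation):
        st, _, _ = make_cohort_strengths(truth, parcellation, n_subjects=6,
                                         timepoints=(63,), seed=7)
        g = st[st.unit == st.unit.iloc[0]]
        res = mr.fit_node_slope(g, g.unit.iloc[0], epoch="aging")
        assert res.fallback_ols

    def test_degenerate_constant_values_flagged(self):
        g = pd.DataFrame({"subject": ["s1", "s2"], "age_pnd": [20.0, 35.0],
                          "tbv": [1.0, 1.0], "value": [0.5, 0.5]})
        res = mr.fit_node_slope(g, "r")
        assert res.flagged


class TestSystemEdgeSlope:
    def test_single_roi_edge_falls_back(self):
        rng = np.random.default_rng(3)
        g = pd.DataFrame({
            "subject": np.repeat([f"s{i}" for i in range(6)], 2),
            "age_pnd": [20.0, 35.0] * 6,
            "tbv": rng.normal(1500, 20, 12),
            "roi_edge": ["a--b"] * 12,
            "value": rng.uniform(0.2, 0.8, 12)})
        res = mr.fit_system_edge_slope(g, ("S0", "S1"))
        assert res.fallback_ols

    def test_planted_edge_slope_direction(self, truth, parcellation):
        """Cross-system edges involving the targeted system S00 change in
        the direction the analytic truth dictates during development."""
        from conftest import true_edge_weights

        w20 = true_edge_weights(truth, 20.0)
        w35 = true_edge_weights(truth, 35.0)
        systems = parcellation.systems()
        expect = {}
        for (a, b) in w20:
            pair = "--".join(sorted((systems[a], systems[b])))
            expect.setdefault(pair, 0.0)
            expect[pair] += w35[(a, b)] - w20[(a, b)]
        hits = total = 0
        for c in range(5):
            st, nets, cohort = make_cohort_strengths(truth, parcellation,
                                                     seed=300 + c)
            et = pl.edge_table(nets, cohort, parcellation.systems())
            sub = mr.select_epoch(et, "development")
            for pair, g in sub.groupby("system_pair"):
                if "S00" in pair and pair != "S00--S00":
                    res = mr.fit_system_edge_slope(g, tuple(pair.split("--")))
                    hits += np.sign(res.t_stat) == np.sign(expect[pair])
                    total += 1
        assert hits / total >= 0.9


class TestEpochCoupling:
    def _slopes(self, ts, epoch):
        return [mr.SlopeResult(unit=f"u{i}", epoch=epoch, beta_age=t,
                               t_stat=t, p_value=0.5, significant=False,
                               n_obs=10) for i, t in enumerate(ts)]

    def test_identical_vectors_give_unit_r(self):
        ts = [0.5, -1.0, 2.0, 0.1]
        r, p, n = mr.epoch_coupling(self._slopes(ts, "development"),
                                    self._slopes(ts, "aging"))
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_planted_anticorrelation_recovered(self, rng):
        dev = rng.normal(size=40)
        age = -0.8 * dev + 0.3 * rng.normal(size=40)
        r, p, _ = mr.epoch_coupling(self._slopes(dev, "development"),
                                    self._slopes(age, "aging"))
        assert r < 0
        assert p < 0.05

    def test_independent_vectors_near_zero(self, rng):
        hits = 0
        for _ in range(40):
            a, b = rng.normal(size=30), rng.normal(size=30)
            r, _, _ = mr.epoch_coupling(self._slopes(a, "development"),
                                        self._slopes(b, "aging"))
            hits += abs(r) <= 2 / np.sqrt(30)
        assert hits / 40 >= 0.85

    def test_mismatched_units_rejected(self):
        a = self._slopes([1.0, 2.0], "development")
        b = self._slopes([1.0, 2.0, 3.0], "aging")
        with pytest.raises(ValueError):
            mr.epoch_coupling(a, b)


def adult_strengths(truth, parc, seed, n_subjects=12):
    spec = syn.CohortSpec(n_subjects=n_subjects, timepoints=[63],
                          groups={"control": 0.5, "stressed": 0.5}, seed=seed)
    scans, cohort = syn.generate_cohort(spec, truth)
    params = mr.MindParams(estimator="analytic")
    nets = {sid: mr.build_mind_network(v, parc, params)
            for sid, v in scans.items()}
    return pl.strength_table(nets, cohort)


class TestGroupEffect:
    def test_single_group_rejected(self, truth, parcellation):
        st = adult_strengths(truth, parcellation, seed=5)
        g = st[st.unit == st.unit.iloc[0]].copy()
        g["group"] = "control"
        with pytest.raises(ValueError):
            mr.fit_group_effect(g, "r")

    def test_missing_tbv_dropped_with_warning(self, truth, parcellation):
        st = adult_strengths(truth, parcellation, seed=5)
        g = st[st.unit == st.unit.iloc[0]].copy()
        g.loc[g.index[0], "tbv"] = np.nan
        with pytest.warns(UserWarning, match="TBV"):
            mr.fit_group_effect(g, "r")

    def test_planted_offset_sign_recovered(self, truth, parcellation):
        """The negative MTR offset moves the targeted (high-mu) system
        toward the rest, so stressed strengths rise: positive effect."""
        target = [m.region_id for m in truth.region_models
                  if m.system_id == "S00"][0]
        signs = []
        for c in range(6):
            st = adult_strengths(truth, parcellation, seed=600 + c)
            g = st[st.unit == target]
            signs.append(np.sign(mr.fit_group_effect(g, target)))
        assert np.mean(np.array(signs) == signs[0]) >= 0.9

    def test_no_offset_effects_centered(self, truth, parcellation):
        flat = syn.make_truth(truth.region_models, subject_sd=0.005)
        effects = []
        for c in range(6):
            st = adult_strengths(flat, parcellation, seed=700 + c)
            region = st.unit.iloc[0]
            effects.append(mr.fit_group_effect(st[st.unit == region], region))
        assert abs(np.mean(effects)) < 1.0  # normalized scale, null-centered


class TestPermutedGroupNull:
    def test_fixed_seed_reproducible(self, truth, parcellation):
        st = adult_strengths(truth, parcellation, seed=8)
        region = st.unit.iloc[0]
        g = st[st.unit == region]
        a = mr.permuted_group_null(g, region, n_perm=100, seed=3)
        b = mr.permuted_group_null(g, region, n_perm=100, seed=3)
        assert a.z_perm == b.z_perm

    def test_planted_offset_detected(self, truth, parcellation):
        target = [m.region_id for m in truth.region_models
                  if m.system_id == "S00"][0]
        hits = 0
        for c in range(5):
            st = adult_strengths(truth, parcellation, seed=800 + c)
            g = st[st.unit == target]
            res = mr.permuted_group_null(g, target, n_perm=200, seed=c)
            hits += res.significant
        assert hits >= 4

    def test_subject_level_permutation_keeps_scans_together(self, truth,
                                                            parcellation,
                                                            monkeypatch):
        """All scans of one subject must carry the same permuted label."""
        spec = syn.CohortSpec(n_subjects=6, timepoints=[63, 230],
                              groups={"control": 0.5, "stressed": 0.5},
                              seed=4)
        scans, cohort = syn.generate_cohort(spec, truth)
        params = mr.MindParams(estimator="analytic")
        nets = {sid: mr.build_mind_network(v, parcellation, params)
                for sid, v in scans.items()}
        st = pl.strength_table(nets, cohort)
        region = st.unit.iloc[0]
        g = st[st.unit == region]
        seen = []
        real_fit = mr.fit_group_effect

        def spy(df, unit, edge_level=False):
            seen.append(df[["subject", "group"]])
            return real_fit(df, unit, edge_level=edge_level)

        monkeypatch.setattr(mr.inference, "fit_group_effect", spy)
        mr.inference.permuted_group_null(g, region, n_perm=100, seed=1)
        for df in seen[1:]:  # first call is the observed fit
            per_subject = df.groupby("subject")["group"].nunique()
            assert (per_subject == 1).all()


class TestStressDevelopmentCoupling:
    def test_exact_identity_minimum_p(self, rng):
        v = dict(enumerate(rng.normal(size=30)))
        res = mr.stress_development_coupling(v, v, n_perm=1000, seed=0)
        assert res.observed == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 1001)

    def test_noisy_linear_coupling_detected(self, rng):
        dev = rng.normal(size=40)
        eff = 0.8 * dev + 0.3 * rng.normal(size=40)
        res = mr.stress_development_coupling(dict(enumerate(eff)),
                                             dict(enumerate(dev)),
                                             n_perm=1000, seed=1)
        assert res.observed > 0
        assert res.p < 0.05

    def test_mismatched_edges_rejected(self):
        with pytest.raises(ValueError):
            mr.stress_development_coupling({"a": 1.0}, {"b": 1.0})


class TestStrengthDistributionTests:
    def test_identical_distributions_rarely_reject(self, rng):
        hits = 0
        for _ in range(100):
            groups = {f"t{i}": rng.normal(size=20) for i in range(4)}
            _, p, _ = mr.strength_distribution_tests(groups)
            hits += p > 0.05
        assert hits >= 90

    def test_planted_shift_found_in_pairwise_table(self, rng):
        groups = {"pnd20": rng.normal(0, 1, 30),
                  "pnd35": rng.normal(0, 1, 30),
                  "pnd63": rng.normal(2.0, 1, 30)}
        h, p, table = mr.strength_distribution_tests(groups)
        assert p < 0.05
        hit = table[(table.timepoint_a == "pnd20")
                    & (table.timepoint_b == "pnd63")]
        assert hit.q_value.iloc[0] < 0.05

    def test_dunn_z_matches_hand_computation_without_ties(self):
        groups = {"a": [1.0, 2.0, 5.0], "b": [3.0, 4.0, 9.0]}
        _, _, table = mr.strength_distribution_tests(groups)
        # ranks: a -> {1,2,5}, b -> {3,4,6}; mean ranks 8/3 and 13/3
        n = 6
        se = np.sqrt(n * (n + 1) / 12 * (1 / 3 + 1 / 3))
        z_expect = (8 / 3 - 13 / 3) / se
        assert table.z.iloc[0] == pytest.approx(z_expect)

    def test_single_timepoint_rejected(self, rng):
        with pytest.raises(ValueError):
            mr.strength_distribution_tests({"t0": rng.normal(size=10)})


class TestSlopeGridMonotonicity:
    def test_mean_t_monotone_in_planted_slope(self, parcellation,
                                              region_models):
        """Across planted slopes {-2c, -c, 0, c, 2c} the mean estimated age
        t statistic for targeted regions is monotone in the plant."""
        c = 0.0004
        target = [m.region_id for m in region_models
                  if m.system_id == "S00"]
        from conftest import true_strengths

        mean_ts, mean_true = [], []
        for slope in (-2 * c, -c, 0.0, c, 2 * c):
            t_vals = []
            truth = syn.make_truth(region_models,
                                   dev_slope={"S00": slope},
                                   subject_sd=0.005)
            diff = (true_strengths(truth, 35.0)
                    - true_strengths(truth, 20.0))[target]
            mean_true.append(diff.mean())
            st, _, _ = make_cohort_strengths(truth, parcellation,
                                            n_subjects=10, seed=55)
            sub = mr.select_epoch(st, "development")
            for region, g in sub.groupby("unit"):
                if region in target:
                    t_vals.append(mr.fit_node_slope(g, region).t_stat)
            mean_ts.append(np.mean(t_vals))
        # estimated t must be monotone in the same direction as the true
        # strength response to the planted slope
        direction = np.sign(mean_true[-1] - mean_true[0])
        ordered = np.sign(np.diff(mean_ts))
        assert np.all(ordered == direction)
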