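"""File formats, the per-voxel MTR feature, centroids and distances.

Voxel tables are two-column CSVs (``Label,MTR``): one row per voxel, labelled
with its parcellation region. Parcellations are JSON descriptors mapping each
region to its system, hemisphere, cortical-inclusion flag and centroid.
Distances are Euclidean, between region centers in world coordinates.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from ._common import FormatError, LabeledMatrix, MissingRegionError

log = logging.getLogger(__name__)

VOXEL_COLUMNS = ("Label", "MTR")


def read_voxel_table(path) -> pd.DataFrame:
    """Read a ``Label,MTR`` voxel CSV; extra columns are dropped with a warning."""
    try:
        df = pd.read_csv(path, dtype={"Label": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty voxel table") from exc
    missing = [c for c in VOXEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in VOXEL_COLUMNS]
    if extra:
        msg = f"{path}: ignoring extra columns {extra}"
        log.warning(msg)
        warnings.warn(msg, stacklevel=2)
    if len(df) == 0:
        raise FormatError(f"{path}: voxel table has no rows")
    values = pd.to_numeric(df["MTR"], errors="coerce")
    bad = values.isna() & df["MTR"].notna() | df["MTR"].isna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise FormatError(f"{path}: non-numeric MTR value at data row {row}")
    if (df["Label"].astype(str).str.len() == 0).any():
        raise FormatError(f"{path}: empty region label")
    return pd.DataFrame({"Label": df["Label"].astype(str), "MTR": values})


def write_voxel_table(voxels: pd.DataFrame, path) -> None:
    voxels.loc[:, list(VOXEL_COLUMNS)].to_csv(path, index=False)


class MTRResult(NamedTuple):
    values: np.ndarray  # (PD - MT)/PD, NaN where PD <= 0
    n_invalid: int


def compute_mtr(pd_values, mt_values) -> MTRResult:
    """Per-voxel magnetization transfer ratio, (PD - MT)/PD.

    Voxels with nonpositive proton density are undefined: they become NaN and
    are counted in the returned diagnostic.
    """
    pd_arr = np.asarray(pd_values, dtype=float)
    mt_arr = np.asarray(mt_values, dtype=float)
    if pd_arr.shape != mt_arr.shape:
        raise ValueError(
            f"PD and MT lengths differ: {pd_arr.shape} vs {mt_arr.shape}")
    valid = pd_arr > 0
    out = np.full(pd_arr.shape, np.nan)
    out[valid] = (pd_arr[valid] - mt_arr[valid]) / pd_arr[valid]
    return MTRResult(values=out, n_invalid=int((~valid).sum()))


@dataclass
class Parcellation:
    """Region registry: system membership, hemisphere, inclusion, centroid."""

    table: pd.DataFrame  # region_id, system_id, hemisphere, include_flag, cx, cy, cz
    meta: dict = field(default_factory=dict)

    REQUIRED = ("region_id", "system_id", "hemisphere", "include_flag")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"parcellation missing columns {missing}")
        if self.table["region_id"].duplicated().any():
            dups = self.table.loc[self.table["region_id"].duplicated(),
                                  "region_id"].tolist()
            raise ValueError(f"duplicate region ids: {dups}")
        inc = self.table[self.table["include_flag"]]
        if inc["system_id"].isna().any():
            raise ValueError("every included region needs a system")
        self.table = self.table.reset_index(drop=True)

    @property
    def region_ids(self) -> list[str]:
        return self.table["region_id"].tolist()

    @property
    def included_ids(self) -> list[str]:
        return self.table.loc[self.table["include_flag"], "region_id"].tolist()

    def systems(self) -> dict[str, str]:
        return dict(zip(self.table["region_id"], self.table["system_id"]))

    def centroids(self) -> dict[str, np.ndarray]:
        if not {"cx", "cy", "cz"}.issubset(self.table.columns):
            raise ValueError("parcellation has no centroid columns")
        return {r: np.array([x, y, z]) for r, x, y, z in zip(
            self.table["region_id"], self.table["cx"],
            self.table["cy"], self.table["cz"])}

    def to_json(self, path) -> None:
        payload = {"regions": self.table.to_dict(orient="records"),
                   "meta": self.meta}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Parcellation":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(table=pd.DataFrame(payload["regions"]),
                   meta=payload.get("meta", {}))

    @classmethod
    def from_region_models(cls, models, include_all: bool = True
                           ) -> "Parcellation":
        """Build a parcellation from synthetic generative region models."""
        rows = [{"region_id": m.region_id, "system_id": m.system_id,
                 "hemisphere": "midline", "include_flag": include_all,
                 "cx": m.centroid[0], "cy": m.centroid[1], "cz": m.centroid[2]}
                for m in models]
        return cls(table=pd.DataFrame(rows))


def filter_to_included(voxels: pd.DataFrame, parcellation: Parcellation
                       ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep only voxels of included regions; report drops per excluded label."""
    included = set(parcellation.included_ids)
    keep = voxels["Label"].isin(included)
    dropped = voxels.loc[~keep, "Label"].value_counts().to_dict()
    if dropped:
        log.info("filter_to_included dropped %d voxels across %d labels",
                 sum(dropped.values()), len(dropped))
    return voxels.loc[keep].reset_index(drop=True), dropped


def load_label_volume(path):
    """Load a NIfTI parcellation label volume (.nii / .nii.gz)."""
    import nibabel as nib

    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise FormatError(f"{path}: expected a 3-D label volume, "
                          f"got shape {img.shape}")
    return img


def region_centroids(label_volume, affine=None, regions=None
                     ) -> dict[int, np.ndarray]:
    """Internal centers of labelled regions in a 3-D parcellation volume.

    For each region the arithmetic centroid of its voxels' world coordinates
    is snapped to the nearest voxel belonging to that region, guaranteeing
    the reported center lies inside the region even for concave shapes.

    ``label_volume`` is a nibabel spatial image, or an integer array combined
    with an ``affine``. Label 0 is background. Returns region -> 3-vector.
    """
    if hasattr(label_volume, "get_fdata"):  # nibabel image
        data = np.asarray(label_volume.get_fdata()).astype(int)
        affine = label_volume.affine
    else:
        data = np.asarray(label_volume).astype(int)
        if affine is None:
            affine = np.eye(4)
    present = set(int(v) for v in np.unique(data)) - {0}
    wanted = present if regions is None else set(int(r) for r in regions)
    absent = wanted - present
    if absent:
        raise MissingRegionError(absent)

    centers: dict[int, np.ndarray] = {}
    for region in sorted(wanted):
        idx = np.argwhere(data == region)  # (n_vox, 3) voxel indices
        world = idx @ affine[:3, :3].T + affine[:3, 3]
        mean = world.mean(axis=0)
        snapped = world[np.argmin(((world - mean) ** 2).sum(axis=1))]
        centers[region] = snapped
    return centers


def edge_distances(centroids: dict) -> LabeledMatrix:
    """Symmetric Euclidean distance matrix between region centers."""
    if len(centroids) < 2:
        raise ValueError("need at least 2 regions for a distance matrix")
    labels = [str(k) for k in centroids]
    pts = np.asarray([np.asarray(centroids[k], dtype=float)
                      for k in centroids])
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite centroid coordinates")
    dm = cdist(pts, pts)
    # enforce exact symmetry/zero diagonal against float noise
    dm = 0.5 * (dm + dm.T)
    np.fill_diagonal(dm, 0.0)
    return LabeledMatrix(labels=labels, values=dm, meta={"kind": "distance"})
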