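"""Shared plumbing: exceptions, seed derivation, labeled symmetric matrices."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np


class MindratError(Exception):
    """Base class for package errors."""


class FormatError(MindratError):
    """A file or table does not match the expected format."""


class InsufficientDataError(MindratError):
    """Not enough observations to perform an operation."""


class MissingRegionError(MindratError):
    """Requested regions are absent from the input."""

    def __init__(self, regions):
        self.regions = sorted(regions)
        super().__init__(f"regions absent from input: {self.regions}")


class PipelineError(MindratError):
    """A pipeline stage cannot proceed."""


def derive_seed(*parts) -> int:
    """Deterministically derive a 31-bit seed from arbitrary hashable parts.

    Strings and numbers are serialised to a canonical byte string and
    CRC-mixed so the derivation is stable across runs and platforms.
    """
    payload = "\x1f".join(str(p) for p in parts).encode()
    return zlib.crc32(payload) & 0x7FFFFFFF


def _check_labels(labels):
    labels = list(labels)
    if len(set(labels)) != len(labels):
        raise ValueError("node labels must be unique")
    return labels


@dataclass
class LabeledMatrix:
    """A square matrix with ordered node labels (base for networks/distances)."""

    labels: list[str]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = _check_labels(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def triu_pairs(self):
        """Yield (label_i, label_j, value) over unique off-diagonal pairs."""
        iu, ju = np.triu_indices(self.n, k=1)
        for i, j in zip(iu, ju):
            yield self.labels[i], self.labels[j], self.values[i, j]

    def triu_values(self) -> np.ndarray:
        iu, ju = np.triu_indices(self.n, k=1)
        return self.values[iu, ju]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path):
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(labels=[str(c) for c in df.columns], values=df.to_numpy())
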