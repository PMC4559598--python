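"""Shared domain containers: parcellations, regional time series, edge bookkeeping.

A parcellation lists the brain regions (nodes) of the analysis: each region
has a hemisphere, a contralateral homolog, and a volume (used to normalise
streamline counts into structural connection strengths). Regions are indexed
0..N-1 with the left hemisphere first, mirroring the conventional left-then-
right atlas ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Parcellation",
    "RegionalTimeSeries",
    "edge_index",
    "upper_triangle",
]

NO_HOMOLOG = -1


@dataclass(frozen=True)
class Parcellation:
    """Region table: ids, labels, hemispheres, homolog mapping, volumes.

    Invariants (checked in ``__post_init__``): region ids are 0..N-1,
    the homolog mapping is an involution that crosses hemispheres, and
    all volumes are strictly positive.
    """

    region_id: np.ndarray
    name: tuple
    hemisphere: np.ndarray  # array of "L"/"R"
    homolog_id: np.ndarray  # NO_HOMOLOG where a region has no homolog
    volume: np.ndarray

    def __post_init__(self):
        n = len(self.region_id)
        if not np.array_equal(np.asarray(self.region_id), np.arange(n)):
            raise ValueError("region ids must be contiguous 0..N-1")
        if np.any(np.asarray(self.volume) <= 0):
            raise ValueError("volumes must be strictly positive")
        hom = np.asarray(self.homolog_id)
        for i in range(n):
            j = hom[i]
            if j == NO_HOMOLOG:
                continue
            if not (0 <= j < n) or hom[j] != i:
                raise ValueError(f"homolog mapping not symmetric at region {i}")
            if self.hemisphere[i] == self.hemisphere[j]:
                raise ValueError(f"homolog pair ({i},{j}) does not cross hemispheres")

    @property
    def n_regions(self) -> int:
        return len(self.region_id)

    def homotopic_pairs(self) -> list[tuple[int, int]]:
        """Unordered (i, homolog(i)) pairs with i < homolog(i)."""
        hom = np.asarray(self.homolog_id)
        return [(i, int(hom[i])) for i in range(self.n_regions)
                if hom[i] != NO_HOMOLOG and i < hom[i]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "region_id": np.asarray(self.region_id),
            "name": list(self.name),
            "hemisphere": np.asarray(self.hemisphere),
            "homolog_id": np.asarray(self.homolog_id),
            "volume": np.asarray(self.volume),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Parcellation":
        df = df.sort_values("region_id").reset_index(drop=True)
        return cls(
            region_id=df["region_id"].to_numpy(int),
            name=tuple(df["name"].astype(str)),
            hemisphere=df["hemisphere"].to_numpy(str),
            homolog_id=df["homolog_id"].to_numpy(int),
            volume=df["volume"].to_numpy(float),
        )


@dataclass
class RegionalTimeSeries:
    """T x N matrix of regional signals sampled every ``sampling_interval`` s."""

    values: np.ndarray
    sampling_interval: float
    subject_id: str = "sub-00"
    state_sequence: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 2:
            raise ValueError("time series must be T x N with T >= 2")
        if np.isnan(self.values).any():
            raise ValueError("time series contains missing values")
        if self.sampling_interval <= 0:
            raise ValueError("sampling interval must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


def edge_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical edge ordering: upper-triangle (i < j) row/column indices."""
    return np.triu_indices(n, k=1)


def upper_triangle(matrix: np.ndarray) -> np.ndarray:
    """Vector of the N(N-1)/2 off-diagonal upper-triangle entries (i < j)."""
    m = np.asarray(matrix)
    iu, ju = edge_index(m.shape[0])
    return m[iu, ju]
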