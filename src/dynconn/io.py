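"""Delimited-text I/O for matrices, parcellations and time series.

All matrices travel as TSV with a region-id header row and column;
round-trips are lossless at 17 significant digits. Time series are TSV
(first row = region ids, rows = time points) with a key=value sidecar
carrying the sampling interval and subject id.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Parcellation, RegionalTimeSeries

__all__ = [
    "save_matrix", "load_matrix",
    "save_parcellation", "load_parcellation",
    "save_timeseries", "load_timeseries",
]

_SYM_TOL = 1e-10


def save_matrix(path: str | Path, matrix: np.ndarray, region_ids=None) -> None:
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("format error: matrix must be square")
    ids = np.arange(m.shape[0]) if region_ids is None else np.asarray(region_ids)
    df = pd.DataFrame(m, index=ids, columns=ids)
    df.to_csv(path, sep="\t", float_format="%.17g", index_label="region_id")


def load_matrix(path: str | Path, region_ids=None) -> np.ndarray:
    """Load a square symmetric matrix; asymmetry beyond 1e-10 is rejected,
    smaller asymmetry symmetrized with a warning."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    m = df.to_numpy(float)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"format error: non-square matrix in {path}")
    cols = df.columns.astype(int).to_numpy()
    rows = df.index.astype(int).to_numpy()
    if not np.array_equal(cols, rows):
        raise ValueError(f"format error: row/column ids disagree in {path}")
    if region_ids is not None and not np.array_equal(cols, np.asarray(region_ids)):
        raise ValueError(f"format error: region ids do not match parcellation in {path}")
    if np.isnan(m).any():
        i, j = np.argwhere(np.isnan(m))[0]
        raise ValueError(f"format error: NaN at row {rows[i]}, column {cols[j]} in {path}")
    asym = np.abs(m - m.T).max()
    if asym > _SYM_TOL:
        raise ValueError(f"format error: matrix asymmetric (max |m - m.T| = {asym:g}) in {path}")
    if asym > 0:
        warnings.warn(f"symmetrized matrix with asymmetry {asym:g}")
        m = (m + m.T) / 2.0
    return m


def save_parcellation(path: str | Path, parcellation: Parcellation) -> None:
    parcellation.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_parcellation(path: str | Path) -> Parcellation:
    return Parcellation.from_frame(
        pd.read_csv(path, sep="\t", float_precision="round_trip"))


def save_timeseries(path: str | Path, ts: RegionalTimeSeries) -> None:
    path = Path(path)
    pd.DataFrame(ts.values, columns=np.arange(ts.n_regions)).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )
    meta = path.with_suffix(path.suffix + ".meta")
    meta.write_text(
        f"sampling_interval={ts.sampling_interval!r}\nsubject_id={ts.subject_id}\n"
    )


def load_timeseries(path: str | Path) -> RegionalTimeSeries:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", float_precision="round_trip").to_numpy(float)
    meta_path = path.with_suffix(path.suffix + ".meta")
    meta = {}
    if meta_path.exists():
        for line in meta_path.read_text().splitlines():
            if "=" in line:
                k, v = line.split("=", 1)
                meta[k.strip()] = v.strip()
    return RegionalTimeSeries(
        values=values,
        sampling_interval=float(meta.get("sampling_interval", "1.0")),
        subject_id=meta.get("subject_id", path.stem),
    )
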