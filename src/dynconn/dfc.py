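"""Sliding-window dynamic functional connectivity and its temporal statistics.

Within each rectangular window of L samples (stepped by a fixed number of
samples), the pairwise Pearson correlation of the regional signals gives one
symmetric N x N connectivity matrix; the ordered set of these matrices is
the dynamic functional connectivity (D-FC) series. Static FC (S-FC) is the
same correlation over the whole scan. Per-edge temporal statistics are

    strength(i,j)    = (1/T)     * sum_t r_t(i,j)
    variability(i,j) = (1/(T-1)) * sum_t (r_t(i,j) - strength(i,j))^2

computed on raw correlations, negative values included. Edges are
partitioned into homotopic (region vs its contralateral homolog),
heterotopic (other interhemispheric) and intrahemispheric categories, and
category differences are assessed with label-shuffling permutation tests,
Bonferroni-corrected over the three category pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import NO_HOMOLOG, Parcellation, RegionalTimeSeries, edge_index, upper_triangle
from .stats import PermutationResult, permutation_diff_test

__all__ = [
    "SlidingWindowSpec",
    "DFCSeries",
    "TemporalEdgeStats",
    "CategoryComparison",
    "window_count",
    "window_samples_from_seconds",
    "sliding_window_dfc",
    "static_fc",
    "fisher_z",
    "spatial_similarity",
    "temporal_edge_stats",
    "temporal_mean_var",
    "classify_edges",
    "category_comparison",
    "CATEGORIES",
]

CATEGORIES = ("homotopic", "heterotopic", "intrahemispheric")


@dataclass(frozen=True)
class SlidingWindowSpec:
    """Window length and step, both in samples."""

    length: int
    step: int = 1

    def __post_init__(self):
        if self.length <= 2:
            raise ValueError("window length must exceed 2 samples")
        if self.step < 1:
            raise ValueError("step must be >= 1")


@dataclass
class DFCSeries:
    """Ordered windowed correlation matrices with their onset samples."""

    matrices: np.ndarray  # T_w x N x N
    window_onsets: np.ndarray
    spec: SlidingWindowSpec

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_regions(self) -> int:
        return self.matrices.shape[1]


@dataclass
class TemporalEdgeStats:
    """Per-edge temporal mean (strength) and variance-style variability."""

    strength: np.ndarray
    variability: np.ndarray
    variability_kind: str = "var"


def window_samples_from_seconds(seconds: float, sampling_interval: float) -> int:
    """Window length in samples: round(seconds / TR). 100 s at TR 0.645 -> 155."""
    return int(round(seconds / sampling_interval))


def window_count(n_timepoints: int, spec: SlidingWindowSpec) -> int:
    """Number of windows: floor((T - L)/step) + 1."""
    if spec.length > n_timepoints:
        raise ValueError(
            f"invalid window: length {spec.length} exceeds series length {n_timepoints}"
        )
    return (n_timepoints - spec.length) // spec.step + 1


def _window_corr(x: np.ndarray, onset: int, w: int) -> np.ndarray:
    seg = x[onset:onset + w]
    sd = seg.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"undefined correlation: region {bad[0]} constant in window at sample {onset}"
        )
    m = np.corrcoef(seg, rowvar=False)
    m = (m + m.T) / 2.0  # exact symmetry (corrcoef is symmetric only to fp error)
    return m


def sliding_window_dfc(ts: RegionalTimeSeries, spec: SlidingWindowSpec) -> DFCSeries:
    """Windowed Pearson correlation matrices at onsets 0, step, 2*step, ...

    Each matrix is symmetric with unit diagonal (never consumed downstream).
    Fails fast, naming window and region, if a regional signal is constant
    within any window.
    """
    t_w = window_count(ts.n_timepoints, spec)
    onsets = np.arange(t_w) * spec.step
    mats = np.empty((t_w, ts.n_regions, ts.n_regions))
    for t, onset in enumerate(onsets):
        mats[t] = _window_corr(ts.values, int(onset), spec.length)
    return DFCSeries(matrices=mats, window_onsets=onsets, spec=spec)


def static_fc(ts: RegionalTimeSeries) -> np.ndarray:
    """Whole-scan Pearson correlation matrix."""
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 time points for static FC")
    return _window_corr(ts.values, 0, ts.n_timepoints)


def fisher_z(values: np.ndarray, clip: bool = True) -> np.ndarray:
    """Fisher r-to-z transform, z = atanh(r).

    With ``clip`` (default) correlations are clipped to +/-(1 - 1e-12)
    first so exact +/-1 entries stay finite; otherwise |r| = 1 raises.
    """
    v = np.asarray(values, float)
    if clip:
        v = np.clip(v, -1 + 1e-12, 1 - 1e-12)
    elif np.any(np.abs(v) >= 1):
        raise ValueError("|r| = 1 outside the domain of atanh (clipping disabled)")
    return np.arctanh(v)


def spatial_similarity(sfc: np.ndarray, dfc: DFCSeries) -> np.ndarray:
    """Per-window Pearson similarity between S-FC and each D-FC matrix.

    Both matrices are Fisher-z transformed entrywise and compared over the
    upper triangle (diagonal excluded).
    """
    n = dfc.n_regions
    if n < 3:
        raise ValueError("too few edges: need at least 3 regions")
    if sfc.shape[0] != n:
        raise ValueError("S-FC and D-FC region counts differ")
    zs = fisher_z(upper_triangle(sfc))
    out = np.empty(dfc.n_windows)
    for t in range(dfc.n_windows):
        zd = fisher_z(upper_triangle(dfc.matrices[t]))
        out[t] = np.corrcoef(zs, zd)[0, 1]
    return out


def temporal_mean_var(series: np.ndarray, axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Temporal mean and 1/(T-1)-normalised variance along ``axis``.

    The shared kernel behind the edge-level and network-level temporal
    statistics.
    """
    series = np.asarray(series, float)
    if series.shape[axis] < 2:
        raise ValueError("temporal variability undefined for fewer than 2 windows")
    return series.mean(axis=axis), series.var(axis=axis, ddof=1)


def temporal_edge_stats(dfc: DFCSeries, variability: str = "var") -> TemporalEdgeStats:
    """Per-edge temporal strength and variability across windows (raw r).

    ``variability="std"`` reports the square root of the 1/(T-1) variance;
    every sign-level conclusion is invariant to this monotone choice.
    """
    if variability not in ("var", "std"):
        raise ValueError("variability must be 'var' or 'std'")
    mean, var = temporal_mean_var(dfc.matrices, axis=0)
    np.fill_diagonal(mean, 0.0)
    np.fill_diagonal(var, 0.0)
    if variability == "std":
        var = np.sqrt(var)
    return TemporalEdgeStats(strength=mean, variability=var, variability_kind=variability)


def classify_edges(parcellation: Parcellation) -> np.ndarray:
    """Category label per canonical (i < j) edge.

    homotopic = contralateral homolog pairs; heterotopic = other
    interhemispheric pairs; intrahemispheric = same-hemisphere pairs.
    """
    n = parcellation.n_regions
    hom = np.asarray(parcellation.homolog_id)
    if np.any((hom != NO_HOMOLOG) & ((hom < 0) | (hom >= n))):
        raise ValueError("parcellation error: invalid homolog reference")
    hemi = np.asarray(parcellation.hemisphere)
    iu, ju = edge_index(n)
    same_hemi = hemi[iu] == hemi[ju]
    homotopic = hom[iu] == ju
    cats = np.where(same_hemi, "intrahemispheric",
                    np.where(homotopic, "homotopic", "heterotopic"))
    return cats


@dataclass(frozen=True)
class CategoryComparison:
    """One category-pair contrast with its Bonferroni-adjusted p-value."""

    pair: tuple
    result: PermutationResult
    p_adjusted: float


def category_comparison(
    stat_matrix: np.ndarray,
    categories: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[CategoryComparison]:
    """Permutation contrasts of an edge statistic between category pairs.

    For each of the three category pairs the observed statistic is the
    difference of category means; the null is built by shuffling category
    labels ``n_perm`` times; two-sided p-values are Bonferroni-adjusted by
    the fixed factor 3.
    """
    values = upper_triangle(stat_matrix) if stat_matrix.ndim == 2 else np.asarray(stat_matrix)
    categories = np.asarray(categories)
    if values.shape != categories.shape:
        raise ValueError("statistic and category vectors differ in length")
    ss = np.random.SeedSequence(seed)
    out = []
    pairs = [(a, b) for k, a in enumerate(CATEGORIES) for b in CATEGORIES[k + 1:]]
    for child, (a, b) in zip(ss.spawn(len(pairs)), pairs):
        res = permutation_diff_test(
            values[categories == a],
            values[categories == b],
            n_perm=n_perm,
            rng=np.random.default_rng(child),
        )
        out.append(CategoryComparison(pair=(a, b), result=res,
                                      p_adjusted=min(1.0, 3.0 * res.p_value)))
    return out
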