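"""Per-window network topology, its temporal statistics, and hub persistence.

Each windowed correlation matrix is thresholded into a graph and measured
with the global metrics (including the null-normalised versions against a
matched random ensemble per window); the resulting metric time series get
the same temporal mean/variability treatment as edges, plus normalised
histograms for group summaries. A node is a hub within a window when its
degree strictly exceeds the network mean; its hub probability is the
fraction of windows in which it qualifies, and it is a persistent hub when
that probability strictly exceeds 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dfc import DFCSeries, temporal_mean_var
from .metrics import degree_centrality, global_metrics
from .networks import ThresholdPolicy, binarize

__all__ = [
    "NullSpec",
    "MetricTimeSeries",
    "HubProfile",
    "metric_time_series",
    "temporal_metric_stats",
    "normalized_histogram",
    "group_average_histograms",
    "window_hubs",
    "hub_persistence",
]

METRIC_COLUMNS = ["S", "Cp", "Lp", "gamma", "lambda", "sigma", "alpha",
                  "alpha_z", "n_components", "largest_component"]


@dataclass(frozen=True)
class NullSpec:
    """Matched-random-ensemble settings for the per-window normalisation."""

    n_rand: int = 100
    swaps_per_edge: int = 10
    seed: int = 0


@dataclass
class MetricTimeSeries:
    """Per-window global metrics (rows) and per-window nodal degrees."""

    metrics: pd.DataFrame          # T_w x len(METRIC_COLUMNS)
    degree: np.ndarray             # T_w x N
    window_onsets: np.ndarray = field(default=None)


@dataclass
class HubProfile:
    """Per-node hub occurrence probability, persistence flag, degree variability."""

    probability: np.ndarray
    persistent: np.ndarray
    degree_tvar: np.ndarray | None = None


def metric_time_series(
    dfc: DFCSeries,
    policy: ThresholdPolicy,
    null: NullSpec = NullSpec(),
    normalized: bool = True,
) -> MetricTimeSeries:
    """Threshold and measure every window's network.

    The null ensemble of window t is seeded from (null.seed, t), so reruns
    are reproducible and windows are uncorrelated.
    """
    n_samples = dfc.spec.length
    rows = []
    degree = np.empty((dfc.n_windows, dfc.n_regions), dtype=int)
    for t in range(dfc.n_windows):
        g = binarize(dfc.matrices[t], policy, n_samples=n_samples)
        seed_t = int(np.random.SeedSequence([null.seed, t]).generate_state(1)[0] % 2**31)
        try:
            m = global_metrics(g, n_rand=null.n_rand,
                               swaps_per_edge=null.swaps_per_edge,
                               seed=seed_t, normalized=normalized)
        except ValueError as exc:
            raise ValueError(f"window {t}: {exc}") from exc
        rows.append(m.as_dict())
        degree[t] = degree_centrality(g)
    return MetricTimeSeries(
        metrics=pd.DataFrame(rows, columns=METRIC_COLUMNS),
        degree=degree,
        window_onsets=dfc.window_onsets,
    )


def temporal_metric_stats(series: MetricTimeSeries) -> pd.DataFrame:
    """Temporal mean and 1/(T-1) variability of every global metric."""
    vals = series.metrics[METRIC_COLUMNS[:8]].to_numpy(float)
    mean, var = temporal_mean_var(vals, axis=0)
    return pd.DataFrame({"tMean": mean, "tVar": var}, index=METRIC_COLUMNS[:8])


def normalized_histogram(
    values: np.ndarray, bins: int | np.ndarray = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram whose bin masses sum to 1; returns (masses, edges)."""
    values = np.asarray(values, float).ravel()
    if values.size == 0:
        raise ValueError("histogram undefined for empty input")
    counts, edges = np.histogram(values, bins=bins)
    return counts / values.size, edges


def group_average_histograms(histograms: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Mean and per-bin sd of per-participant normalised histograms.

    All histograms must share one fixed bin grid; the average then still
    sums to 1.
    """
    h = np.asarray(histograms, float)
    return h.mean(axis=0), h.std(axis=0)


def window_hubs(degree: np.ndarray) -> np.ndarray:
    """Hub flags for one window: degree strictly above the network mean."""
    degree = np.asarray(degree)
    if degree.size < 2:
        raise ValueError("need at least 2 nodes")
    return degree > degree.mean()


def hub_persistence(degree_series: np.ndarray) -> HubProfile:
    """Hub probability, persistence (> 0.5, strict) and degree variability
    per node from a T_w x N degree series."""
    d = np.asarray(degree_series, float)
    if d.ndim != 2 or d.shape[0] < 1:
        raise ValueError("degree series must be T_w x N with T_w >= 1")
    flags = d > d.mean(axis=1, keepdims=True)
    prob = flags.mean(axis=0)
    tvar = temporal_mean_var(d, axis=0)[1] if d.shape[0] >= 2 else None
    return HubProfile(probability=prob, persistent=prob > 0.5, degree_tvar=tvar)
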