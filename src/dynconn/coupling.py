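"""Structure-function coupling at connection, global and nodal levels.

Connection level: are edges with a direct structural connection stronger
and less variable functionally than edges without one (label-shuffling
permutation test), and within the structurally connected edges, how does
structural strength correlate with functional strength/variability
(Pearson, after rank-based Gaussian resampling to mean +/- sd = 0.5 +/-
0.1)? Global level: across-subject Pearson correlation between structural
topology and the temporal features of functional topology. Nodal level:
Spearman correlation (structural hub probability is discrete) between
structural hubness/degree and the temporal variability of functional
degree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import upper_triangle
from .dfc import TemporalEdgeStats
from .stats import PermutationResult, gaussian_resample, permutation_diff_test
from .structural import BackboneNetwork, StructuralNetwork

__all__ = [
    "CouplingReport",
    "gaussian_resample",
    "sc_presence_test",
    "sc_strength_coupling",
    "global_topology_coupling",
    "nodal_coupling",
]


@dataclass
class CouplingReport:
    """Edge-level SC-vs-D-FC correlations over structurally connected pairs."""

    r_strength_sc: float
    p_strength_sc: float
    r_variability_sc: float
    p_variability_sc: float
    n_edges_sc_present: int
    level: str = "subject"
    resampled: bool = True


def _sc_mask(sc) -> np.ndarray:
    if isinstance(sc, (StructuralNetwork, BackboneNetwork)):
        w = sc.weights
    else:
        w = np.asarray(sc)
    return w


def sc_presence_test(
    edge_stats: TemporalEdgeStats,
    sc: StructuralNetwork | BackboneNetwork | np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict[str, PermutationResult]:
    """Permutation contrast of D-FC strength/variability between edges with
    and without a direct structural connection (two-sided)."""
    w = _sc_mask(sc)
    if w.shape[0] != edge_stats.strength.shape[0]:
        raise ValueError("structural and functional region counts differ")
    present = upper_triangle(w) > 0
    if present.sum() == 0 or (~present).sum() == 0:
        raise ValueError("degenerate groups: need both SC-present and SC-absent edges")
    ss = np.random.SeedSequence(seed)
    out = {}
    for child, (name, mat) in zip(
        ss.spawn(2),
        [("strength", edge_stats.strength), ("variability", edge_stats.variability)],
    ):
        v = upper_triangle(mat)
        out[name] = permutation_diff_test(
            v[present], v[~present], n_perm=n_perm, rng=np.random.default_rng(child)
        )
    return out


def sc_strength_coupling(
    edge_stats: TemporalEdgeStats,
    sc: StructuralNetwork | BackboneNetwork | np.ndarray,
    resample: bool = True,
    level: str = "subject",
) -> CouplingReport:
    """Pearson correlation of SC strength with D-FC strength/variability over
    the structurally connected edges, optionally after Gaussian resampling
    of every variable."""
    w = _sc_mask(sc)
    sc_v = upper_triangle(w)
    present = sc_v > 0
    n_present = int(present.sum())
    if n_present < 3:
        raise ValueError("insufficient data: need at least 3 SC-present edges")
    x = sc_v[present]
    ys = {
        "strength": upper_triangle(edge_stats.strength)[present],
        "variability": upper_triangle(edge_stats.variability)[present],
    }
    if resample:
        x = gaussian_resample(x)
        ys = {k: gaussian_resample(v) for k, v in ys.items()}
    rs, rv = sps.pearsonr(x, ys["strength"]), sps.pearsonr(x, ys["variability"])
    return CouplingReport(
        r_strength_sc=float(rs.statistic), p_strength_sc=float(rs.pvalue),
        r_variability_sc=float(rv.statistic), p_variability_sc=float(rv.pvalue),
        n_edges_sc_present=n_present, level=level, resampled=resample,
    )


def global_topology_coupling(
    sc_metrics: pd.DataFrame, dfc_temporal: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Across-subject Pearson r between each structural global metric and
    each temporal feature (tMean, tVar) of the same functional metric.

    ``sc_metrics``: subjects x metrics. ``dfc_temporal``: feature name ->
    subjects x metrics frame. Raises on fewer than 3 subjects; a metric
    that is constant across subjects raises a correlation-undefined error.
    """
    if len(sc_metrics) < 3:
        raise ValueError("insufficient data: need at least 3 subjects")
    rows = []
    for feature, frame in dfc_temporal.items():
        for metric in sc_metrics.columns:
            if metric not in frame.columns:
                continue
            x = sc_metrics[metric].to_numpy(float)
            y = frame[metric].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                raise ValueError(f"correlation undefined: {metric} constant across subjects")
            r = sps.pearsonr(x, y)
            rows.append({"metric": metric, "feature": feature,
                         "r": float(r.statistic), "p": float(r.pvalue)})
    return pd.DataFrame(rows)


def nodal_coupling(
    functional_degree_tvar: np.ndarray,
    structural_hub_prob: np.ndarray,
    structural_degree: np.ndarray,
) -> pd.DataFrame:
    """Across-node Spearman correlations with the temporal variability of
    functional degree (average-rank ties, two-sided p)."""
    y = np.asarray(functional_degree_tvar, float)
    if y.size < 5:
        raise ValueError("need at least 5 nodes")
    rows = []
    for name, x in [("structural_hub_probability", structural_hub_prob),
                    ("structural_degree", structural_degree)]:
        x = np.asarray(x, float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(f"correlation undefined: constant input for {name}")
        res = sps.spearmanr(x, y)
        rows.append({"predictor": name, "r": float(res.statistic), "p": float(res.pvalue)})
    return pd.DataFrame(rows)
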