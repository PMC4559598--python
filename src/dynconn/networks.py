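"""Thresholding correlation matrices into binary or weighted graphs.

Negative correlations are always excluded. Three policies:

* ``bonferroni_r`` — keep r > tau where tau is the positive correlation
  whose two-sided Pearson test at df = L - 2 reaches the Bonferroni-
  corrected per-edge alpha (alpha_corr divided by N(N-1)/2 pairs);
* ``fixed_r`` — keep r > tau for a user-supplied tau;
* ``sparsity`` — keep the top floor(S * N(N-1)/2) positive correlations,
  ties broken by descending r then ascending (i, j).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import edge_index

__all__ = [
    "BinaryGraph",
    "WeightedGraph",
    "ThresholdPolicy",
    "bonferroni_r_threshold",
    "binarize",
    "weight_graph",
]


@dataclass
class BinaryGraph:
    """Undirected simple graph as a symmetric 0/1 adjacency with zero diagonal."""

    adjacency: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        self.adjacency = (a != 0).astype(np.uint8)
        np.fill_diagonal(self.adjacency, 0)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class WeightedGraph:
    """Undirected weighted graph; weights > 0 exactly where edges exist."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, float).copy()
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def binary(self) -> BinaryGraph:
        return BinaryGraph(self.weights > 0)


@dataclass(frozen=True)
class ThresholdPolicy:
    """Exactly one of alpha_corr (bonferroni_r), tau (fixed_r) or
    target_sparsity (sparsity) is active, selected by ``mode``."""

    mode: str
    alpha_corr: float | None = None
    tau: float | None = None
    target_sparsity: float | None = None
    one_sided: bool = False

    def __post_init__(self):
        active = {
            "bonferroni_r": self.alpha_corr,
            "fixed_r": self.tau,
            "sparsity": self.target_sparsity,
        }
        if self.mode not in active:
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if active[self.mode] is None:
            raise ValueError(f"mode {self.mode!r} requires its parameter")
        others = [v for k, v in active.items() if k != self.mode]
        if any(v is not None for v in others):
            raise ValueError("exactly one mode parameter may be set")
        if self.mode == "sparsity" and not (0 < self.target_sparsity < 1):
            raise ValueError("target_sparsity must lie in (0, 1)")


def bonferroni_r_threshold(
    n_samples: int, n_regions: int, alpha_corr: float = 0.01, one_sided: bool = False
) -> float:
    """Correlation cutoff for Bonferroni-corrected edge significance.

    Per-edge alpha = alpha_corr / (N(N-1)/2); tau is the positive r whose
    Pearson test at df = n_samples - 2 attains that alpha, via
    r = t / sqrt(df + t^2).
    """
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    if not (0 < alpha_corr <= 1):
        raise ValueError("alpha_corr must lie in (0, 1]")
    n_pairs = n_regions * (n_regions - 1) // 2
    alpha_edge = alpha_corr / n_pairs
    if alpha_edge <= 0:
        raise ValueError("per-edge alpha underflow")
    df = n_samples - 2
    tail = alpha_edge if one_sided else alpha_edge / 2
    t = sps.t.isf(tail, df)
    return float(t / np.sqrt(df + t * t))


def _resolve_tau(matrix: np.ndarray, policy: ThresholdPolicy, n_samples: int | None) -> float:
    if policy.mode == "fixed_r":
        return float(policy.tau)
    if n_samples is None:
        raise ValueError("bonferroni_r mode needs n_samples (the window length)")
    return bonferroni_r_threshold(
        n_samples, matrix.shape[0], policy.alpha_corr, policy.one_sided
    )


def _edge_mask(matrix: np.ndarray, policy: ThresholdPolicy, n_samples: int | None) -> np.ndarray:
    """Boolean keep-mask over canonical (i < j) edges."""
    n = matrix.shape[0]
    iu, ju = edge_index(n)
    r = matrix[iu, ju]
    if policy.mode in ("bonferroni_r", "fixed_r"):
        tau = max(_resolve_tau(matrix, policy, n_samples), 0.0)
        return r > tau
    n_pairs = r.size
    k = int(np.floor(policy.target_sparsity * n_pairs))
    positive = r > 0
    if positive.sum() < k:
        warnings.warn(
            f"sparsity shortfall: only {int(positive.sum())} positive correlations "
            f"for {k} requested edges; achieved sparsity {positive.sum() / n_pairs:.4f}",
            stacklevel=3,
        )
        return positive
    # ties: descending r, then ascending (i, j) lexicographic
    order = np.lexsort((ju, iu, -r))
    keep = np.zeros(n_pairs, dtype=bool)
    keep[order[:k]] = True
    return keep & positive


def binarize(
    matrix: np.ndarray, policy: ThresholdPolicy, n_samples: int | None = None
) -> BinaryGraph:
    """Threshold a correlation matrix into a binary graph (edge iff r > tau,
    or top-k positive r in sparsity mode)."""
    n = matrix.shape[0]
    iu, ju = edge_index(n)
    keep = _edge_mask(matrix, policy, n_samples)
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[iu[keep], ju[keep]] = 1
    return BinaryGraph(adj + adj.T)


def weight_graph(
    matrix: np.ndarray, policy: ThresholdPolicy, n_samples: int | None = None
) -> WeightedGraph:
    """Same edge set as :func:`binarize` but retaining the correlation values."""
    n = matrix.shape[0]
    iu, ju = edge_index(n)
    keep = _edge_mask(matrix, policy, n_samples)
    w = np.zeros((n, n))
    w[iu[keep], ju[keep]] = matrix[iu[keep], ju[keep]]
    return WeightedGraph(w + w.T)
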