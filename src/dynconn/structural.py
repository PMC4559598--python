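"""Structural networks from streamline counts; group backbone; structural hubs.

A structural connection's strength is the normalized streamline number —
the streamline count divided by the mean volume of the two regions. The
group backbone keeps the edges whose presence across subjects rejects a
one-tailed sign test (null: no connection; success = strictly positive
strength, zeros count as failures) at alpha = 0.05, assigning each retained
edge the mean strength across all subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import Parcellation
from .dynamics import HubProfile
from .metrics import degree_centrality
from .networks import BinaryGraph

__all__ = [
    "StructuralNetwork",
    "BackboneNetwork",
    "sc_from_streamlines",
    "group_backbone",
    "structural_hub_profile",
]


@dataclass
class StructuralNetwork:
    """Per-subject weighted structural matrix (normalized streamline number)."""

    weights: np.ndarray
    subject_id: str = "sub-00"

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def binary(self) -> BinaryGraph:
        return BinaryGraph(self.weights > 0)


@dataclass
class BackboneNetwork:
    """Group-level structural backbone with per-edge sign-test p-values."""

    weights: np.ndarray
    p_values: np.ndarray
    alpha: float

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


def sc_from_streamlines(counts: np.ndarray, parcellation: Parcellation) -> StructuralNetwork:
    """weight(i, j) = counts(i, j) / ((volume_i + volume_j) / 2)."""
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("counts must be a square matrix")
    if np.any(counts < 0):
        raise ValueError("invalid input: negative streamline counts")
    if not np.array_equal(counts, counts.T):
        raise ValueError("invalid input: counts matrix not symmetric")
    if counts.shape[0] != parcellation.n_regions:
        raise ValueError("counts size does not match parcellation")
    vol = np.asarray(parcellation.volume, float)
    mean_vol = (vol[:, None] + vol[None, :]) / 2.0
    w = counts / mean_vol
    np.fill_diagonal(w, 0.0)
    return StructuralNetwork(weights=w)


def group_backbone(
    networks: list[StructuralNetwork], alpha: float = 0.05, mean_over: str = "all"
) -> BackboneNetwork:
    """Sign-test backbone across subjects.

    For each edge, k = number of subjects with a strictly positive weight
    out of n; one-tailed binomial p = P(X >= k | n, 1/2). Edges with
    p < alpha are retained with the mean strength across subjects
    (``mean_over="all"``, the default, averages over every subject
    including absent connections; ``"nonzero"`` averages the present ones).
    """
    if len(networks) < 2:
        raise ValueError("need at least 2 subjects")
    n = networks[0].n_regions
    if any(net.n_regions != n for net in networks):
        raise ValueError("invalid input: inconsistent region counts across subjects")
    if mean_over not in ("all", "nonzero"):
        raise ValueError("mean_over must be 'all' or 'nonzero'")
    stack = np.stack([net.weights for net in networks])
    n_sub = stack.shape[0]
    k = (stack > 0).sum(axis=0)
    p = sps.binom.sf(k - 1, n_sub, 0.5)
    np.fill_diagonal(p, 1.0)
    keep = p < alpha
    if mean_over == "all":
        mean_w = stack.mean(axis=0)
    else:
        with np.errstate(invalid="ignore"):
            mean_w = np.where(k > 0, stack.sum(axis=0) / np.maximum(k, 1), 0.0)
    weights = np.where(keep, mean_w, 0.0)
    np.fill_diagonal(weights, 0.0)
    return BackboneNetwork(weights=weights, p_values=p, alpha=alpha)


def structural_hub_profile(networks: list[StructuralNetwork]) -> HubProfile:
    """Across-subject hub occurrence from binarized structural networks.

    Per subject a node is a hub when its binary degree strictly exceeds the
    subject mean; probability = fraction of subjects; persistent at a
    strict > 0.5.
    """
    if not networks:
        raise ValueError("need at least 1 subject")
    flags = []
    for net in networks:
        deg = degree_centrality(net.binary())
        flags.append(deg > deg.mean())
    flags = np.asarray(flags)
    prob = flags.mean(axis=0)
    return HubProfile(probability=prob, persistent=prob > 0.5)
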