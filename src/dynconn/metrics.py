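"""Global and nodal graph topology with degree-preserving random nulls.

Global metrics: sparsity S = 2E/(N(N-1)); clustering coefficient Cp (mean
over all nodes of the Watts-Strogatz local clustering, degree-<2 nodes
contributing 0); characteristic path length Lp (mean shortest path over
connected node pairs, with a component census reported alongside); Newman
degree assortativity alpha. Normalised versions gamma = Cp/<Cp_rand>,
lambda = Lp/<Lp_rand>, small-worldness sigma = gamma/lambda and
alpha_z = (alpha - <alpha_rand>)/std(alpha_rand) are estimated against an
ensemble of Maslov-Sneppen degree-preserving rewired networks (default 100).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.sparse.csgraph import connected_components, dijkstra, shortest_path

__all__ = [
    "GlobalMetrics",
    "sparsity",
    "clustering_coefficient",
    "characteristic_path_length",
    "assortativity",
    "degree_centrality",
    "maslov_sneppen_rewire",
    "normalized_metrics",
    "global_metrics",
    "weighted_metrics",
]

from .networks import BinaryGraph, WeightedGraph


@dataclass
class GlobalMetrics:
    """One graph's global topology vector."""

    S: float
    Cp: float
    Lp: float
    gamma: float = np.nan
    lam: float = np.nan
    sigma: float = np.nan
    alpha: float = np.nan
    alpha_z: float = np.nan
    n_components: int = 1
    largest_component: int = 0

    def as_dict(self) -> dict:
        return {
            "S": self.S, "Cp": self.Cp, "Lp": self.Lp, "gamma": self.gamma,
            "lambda": self.lam, "sigma": self.sigma, "alpha": self.alpha,
            "alpha_z": self.alpha_z, "n_components": self.n_components,
            "largest_component": self.largest_component,
        }


def sparsity(g: BinaryGraph) -> float:
    """Fraction of possible edges present: 2E/(N(N-1))."""
    n = g.n_nodes
    if n < 2:
        raise ValueError("invalid graph: need at least 2 nodes")
    return 2.0 * g.n_edges / (n * (n - 1))


def clustering_coefficient(g: BinaryGraph) -> tuple[float, np.ndarray]:
    """(Cp, per-node values): fraction of closed triples around each node."""
    a = g.adjacency.astype(float)
    if g.n_nodes < 3:
        raise ValueError("invalid graph: need at least 3 nodes for clustering")
    k = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2.0
    denom = k * (k - 1) / 2.0
    local = np.where(denom > 0, triangles / np.maximum(denom, 1), 0.0)
    return float(local.mean()), local


def characteristic_path_length(g: BinaryGraph) -> tuple[float, int, int]:
    """(Lp, n_components, largest_component).

    Lp is the mean BFS shortest-path length over *connected* unordered node
    pairs; disconnected pairs are excluded and the component census is
    returned so the exclusion is always visible.
    """
    if g.n_edges == 0:
        raise ValueError("path length undefined: graph has no edges")
    d = shortest_path(g.adjacency, method="D", unweighted=True, directed=False)
    iu = np.triu_indices(g.n_nodes, k=1)
    finite = np.isfinite(d[iu])
    ncomp, labels = connected_components(g.adjacency, directed=False)
    largest = int(np.bincount(labels).max())
    return float(d[iu][finite].mean()), int(ncomp), largest


def assortativity(g: BinaryGraph) -> float:
    """Newman degree assortativity: Pearson correlation of degrees over edge
    endpoints (both orientations). NaN for degree-regular edge sets."""
    if g.n_edges < 2:
        raise ValueError("assortativity needs at least 2 edges")
    deg = g.adjacency.sum(axis=1).astype(float)
    i, j = np.nonzero(np.triu(g.adjacency, 1))
    x = np.concatenate([deg[i], deg[j]])
    y = np.concatenate([deg[j], deg[i]])
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def degree_centrality(g: BinaryGraph) -> np.ndarray:
    """Per-node degree: row sums of the adjacency."""
    return g.adjacency.sum(axis=1).astype(int)


@njit(cache=True)
def _swap_kernel(adj, edges, e1s, e2s, flips):  # pragma: no cover - jit
    n_success = 0
    for t in range(e1s.shape[0]):
        e1 = e1s[t]
        e2 = e2s[t]
        if e1 == e2:
            continue
        a = edges[e1, 0]
        b = edges[e1, 1]
        c = edges[e2, 0]
        d = edges[e2, 1]
        if flips[t]:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        edges[e1, 1] = d
        edges[e2, 1] = b
        if flips[t]:
            edges[e2, 0] = c
            edges[e2, 1] = b
        n_success += 1
    return n_success


def maslov_sneppen_rewire(
    g: BinaryGraph, swaps_per_edge: int = 10, seed: int | np.random.Generator = 0
) -> BinaryGraph:
    """Degree-preserving randomisation by repeated double-edge swaps.

    Attempts ``swaps_per_edge * E`` swaps, rejecting any that would create a
    self-loop or multi-edge; the degree sequence is conserved exactly. If no
    swap succeeds (e.g. a complete triangle admits none) the input graph is
    returned unchanged with a warning.
    """
    e = g.n_edges
    if e < 2:
        warnings.warn("graph admits no double-edge swap; returned unchanged")
        return BinaryGraph(g.adjacency.copy())
    rng = np.random.default_rng(seed)
    adj = g.adjacency.astype(bool).copy()
    i, j = np.nonzero(np.triu(adj, 1))
    edges = np.stack([i, j], axis=1).astype(np.int64)
    attempts = int(swaps_per_edge) * e
    e1s = rng.integers(0, e, size=attempts)
    e2s = rng.integers(0, e, size=attempts)
    flips = rng.random(attempts) < 0.5
    n_success = _swap_kernel(adj, edges, e1s, e2s, flips)
    if n_success == 0:
        warnings.warn("no valid double-edge swap found; graph returned unchanged")
    return BinaryGraph(adj)


def normalized_metrics(
    g: BinaryGraph,
    n_rand: int = 100,
    swaps_per_edge: int = 10,
    seed: int = 0,
) -> tuple[float, float, float, float]:
    """(gamma, lambda, sigma, alpha_z) against a matched random ensemble.

    Every null network is produced by :func:`maslov_sneppen_rewire` and
    measured with this module's own metric implementations; alpha_z uses the
    sample (n-1) standard deviation of the null assortativities.
    """
    if n_rand < 2:
        raise ValueError("need at least 2 random networks")
    cp, _ = clustering_coefficient(g)
    lp, _, _ = characteristic_path_length(g)
    al = assortativity(g)
    ss = np.random.SeedSequence(seed)
    cps = np.empty(n_rand)
    lps = np.empty(n_rand)
    als = np.empty(n_rand)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r, child in enumerate(ss.spawn(n_rand)):
            rnd = maslov_sneppen_rewire(g, swaps_per_edge, np.random.default_rng(child))
            cps[r], _ = clustering_coefficient(rnd)
            lps[r], _, _ = characteristic_path_length(rnd)
            als[r] = assortativity(rnd)
    if cps.mean() == 0 or lps.mean() == 0:
        raise ValueError("normalization failure: degenerate random ensemble")
    gamma = cp / cps.mean()
    lam = lp / lps.mean()
    alpha_sd = als.std(ddof=1)
    alpha_z = (al - als.mean()) / alpha_sd if alpha_sd > 0 else np.nan
    return float(gamma), float(lam), float(gamma / lam), float(alpha_z)


def global_metrics(
    g: BinaryGraph,
    n_rand: int = 100,
    swaps_per_edge: int = 10,
    seed: int = 0,
    normalized: bool = True,
) -> GlobalMetrics:
    """All global metrics of one graph, optionally with the null-normalised
    versions (gamma, lambda, sigma, alpha_z)."""
    s = sparsity(g)
    cp, _ = clustering_coefficient(g)
    lp, ncomp, largest = characteristic_path_length(g)
    al = assortativity(g)
    m = GlobalMetrics(S=s, Cp=cp, Lp=lp, alpha=al,
                      n_components=ncomp, largest_component=largest)
    if normalized:
        m.gamma, m.lam, m.sigma, m.alpha_z = normalized_metrics(
            g, n_rand=n_rand, swaps_per_edge=swaps_per_edge, seed=seed
        )
    return m


def weighted_metrics(g: WeightedGraph) -> tuple[float, float, np.ndarray]:
    """(Cp_w, Lp_w, strength) for a positively weighted graph.

    Cp_w is Onnela's geometric-mean triangle clustering on weights
    normalised by the maximum weight; Lp_w is the mean Dijkstra shortest
    path with edge length 1/weight over connected pairs; strength is the
    weighted degree.
    """
    w = g.weights
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if w.max() == 0:
        raise ValueError("path length undefined: graph has no edges")
    strength = w.sum(axis=1)
    what = (w / w.max()) ** (1.0 / 3.0)
    k = (w > 0).sum(axis=1)
    tri = np.diag(what @ what @ what) / 2.0
    denom = k * (k - 1) / 2.0
    local = np.where(denom > 0, tri / np.maximum(denom, 1), 0.0)
    cp_w = float(local.mean())
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    d = dijkstra(lengths, directed=False)
    iu = np.triu_indices(w.shape[0], k=1)
    finite = np.isfinite(d[iu])
    lp_w = float(d[iu][finite].mean())
    return cp_w, lp_w, strength
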