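"""Synthetic cohort generator with planted, recoverable network effects.

The generator produces everything the downstream analysis consumes:

* a parcellation of homologous left/right region pairs,
* a ground-truth structural graph with designated hub nodes,
* streamline-count matrices (Poisson counts scaled by region volume),
* BOLD-like regional time series whose covariance switches slowly among a
  small set of latent states (a hidden-Markov covariance model).

The time-series model plants four effects the pipeline is expected to
recover: (a) inter-regional correlation rises monotonically with structural
weight (``coupling_gain``); (b) homotopic pairs carry an extra shared
component present in every state (``homotopic_boost``), making them both
strong and temporally stable; (c) state-specific covariance fluctuations are
damped on structurally stabilised edges, so weakly connected pairs vary
more over time; (d) hub nodes have twice the degree of non-hubs, so their
functional degree is reliably above average.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import NO_HOMOLOG, Parcellation, RegionalTimeSeries, edge_index

__all__ = [
    "GroundTruth",
    "generate_parcellation",
    "generate_structural_truth",
    "make_state_covariances",
    "simulate_streamline_counts",
    "simulate_bold",
    "analytic_average_correlation",
    "default_preset",
    "DEFAULT_PRESET",
]


@dataclass
class GroundTruth:
    """Ground-truth generative parameters for one synthetic cohort."""

    structural_weights: np.ndarray          # symmetric, nonnegative, zero diagonal
    hub_nodes: np.ndarray                   # region ids of planted hubs
    state_covariances: list = field(default_factory=list)
    state_dwell_mean: float = 150.0         # samples
    homotopic_boost: float = 0.45
    coupling_gain: float = 0.7
    noise_sd: float = 0.25

    @property
    def n_regions(self) -> int:
        return self.structural_weights.shape[0]

    @property
    def n_states(self) -> int:
        return len(self.state_covariances)


def generate_parcellation(n_pairs: int, seed: int) -> Parcellation:
    """Parcellation of ``2*n_pairs`` regions in mirrored left/right pairs.

    Regions 0..n_pairs-1 are left-hemisphere, n_pairs..2*n_pairs-1 right;
    homolog(i) = i + n_pairs for left regions (and symmetrically back).
    Volumes are log-normal, with a small independent left/right jitter on a
    shared per-pair base so homologs have similar but unequal volumes.
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    rng = np.random.default_rng(seed)
    n = 2 * n_pairs
    base = rng.lognormal(mean=np.log(8.0), sigma=0.4, size=n_pairs)
    jitter = rng.lognormal(mean=0.0, sigma=0.05, size=(2, n_pairs))
    volumes = np.concatenate([base * jitter[0], base * jitter[1]])
    homolog = np.concatenate([np.arange(n_pairs) + n_pairs, np.arange(n_pairs)])
    names = tuple(
        f"{'L' if i < n_pairs else 'R'}_ROI_{(i % n_pairs) + 1:03d}" for i in range(n)
    )
    return Parcellation(
        region_id=np.arange(n),
        name=names,
        hemisphere=np.array(["L"] * n_pairs + ["R"] * n_pairs),
        homolog_id=homolog,
        volume=volumes,
    )


def _hub_deficit(adj: np.ndarray, hubs: np.ndarray, factor: float) -> float:
    deg = adj.sum(axis=1)
    non = np.setdiff1d(np.arange(len(deg)), hubs)
    target = factor * deg[non].mean()
    return float(np.max(target - deg[hubs])) if len(hubs) else -np.inf


def generate_structural_truth(
    parcellation: Parcellation,
    density: float = 0.21,
    n_hubs: int = 4,
    homotopic_guarantee: bool = True,
    seed: int = 0,
    hub_degree_factor: float = 2.5,
    n_modules: int = 4,
    module_affinity: float = 8.0,
) -> GroundTruth:
    """Ground-truth structural graph at a requested binary density.

    Edges are sampled preferentially toward designated hub nodes until the
    degree of every hub is at least twice the non-hub mean (the sampling
    targets ``hub_degree_factor`` for margin); all homotopic pairs are wired
    when ``homotopic_guarantee`` is set. Sampling also favours pairs inside
    the same bilateral module by a factor ``1 + module_affinity`` — white-
    matter networks are strongly modular, and the resulting clustering
    (well above the degree-preserving null) is what puts the graph in the
    small-world regime. Edge weights are log-normal.
    """
    n = parcellation.n_regions
    if not (0.0 < density <= 1.0):
        raise ValueError("density must lie in (0, 1]")
    n_possible = n * (n - 1) // 2
    m_target = int(round(density * n_possible))
    rng = np.random.default_rng(seed)

    pairs = parcellation.homotopic_pairs()
    if homotopic_guarantee and m_target < len(pairs):
        raise ValueError(
            "infeasible configuration: density too low to wire all homotopic pairs"
        )
    adj = np.zeros((n, n), dtype=bool)
    if homotopic_guarantee:
        for i, j in pairs:
            adj[i, j] = adj[j, i] = True

    hubs = np.sort(rng.choice(n, size=n_hubs, replace=False)) if n_hubs else np.array([], int)

    # preferential degree targets: hubs aim for hub_degree_factor x non-hub mean
    t = np.ones(n)
    t[hubs] = hub_degree_factor
    iu, ju = edge_index(n)
    free = ~adj[iu, ju]
    need = m_target - int(adj.sum() // 2)
    if need > 0:
        labels = _module_assignment(parcellation, n_modules)
        same_module = labels[iu] == labels[ju]
        w = t[iu] * t[ju] * (1.0 + module_affinity * same_module)
        keys = np.log(w[free]) + rng.gumbel(size=free.sum())
        pick = np.argsort(keys)[::-1][:need]
        fi, fj = iu[free][pick], ju[free][pick]
        adj[fi, fj] = adj[fj, fi] = True

    # repair: move non-hub edges onto deficient hubs until the 2x constraint holds
    if n_hubs and density < 1.0:
        for _ in range(10 * m_target):
            if _hub_deficit(adj, hubs, 2.0) <= 0:
                break
            deg = adj.sum(axis=1)
            non = np.setdiff1d(np.arange(n), hubs)
            h = hubs[np.argmin(deg[hubs])]
            cand = np.flatnonzero(~adj[h] & (np.arange(n) != h))
            if cand.size == 0:
                raise ValueError("infeasible configuration: hub already saturated")
            # remove a removable non-hub edge (not homotopic, not hub-incident)
            hom = np.asarray(parcellation.homolog_id)
            ei, ej = np.nonzero(np.triu(adj, 1))
            mask = ~np.isin(ei, hubs) & ~np.isin(ej, hubs)
            if homotopic_guarantee:
                mask &= hom[ei] != ej
            rem = np.flatnonzero(mask)
            if rem.size == 0:
                raise ValueError("infeasible configuration: no removable edge")
            k = rng.choice(rem)
            adj[ei[k], ej[k]] = adj[ej[k], ei[k]] = False
            c = rng.choice(cand)
            adj[h, c] = adj[c, h] = True
        else:
            raise ValueError("infeasible configuration: hub constraint unreachable")
        if _hub_deficit(adj, hubs, 2.0) > 0:
            raise ValueError("infeasible configuration: hub constraint unreachable")
    elif n_hubs and density >= 1.0:
        raise ValueError("infeasible configuration: complete graph admits no hubs")

    weights = np.zeros((n, n))
    ei, ej = np.nonzero(np.triu(adj, 1))
    w = rng.lognormal(mean=0.0, sigma=0.5, size=ei.size)
    weights[ei, ej] = weights[ej, ei] = w
    return GroundTruth(structural_weights=weights, hub_nodes=hubs)


def _nearest_pd_correlation(c: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Clip eigenvalues at ``eig_floor`` and rescale to unit diagonal."""
    c = (c + c.T) / 2.0
    vals, vecs = np.linalg.eigh(c)
    vals = np.clip(vals, eig_floor, None)
    c = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return c


def _module_assignment(parcellation: Parcellation, n_modules: int) -> np.ndarray:
    """Module label per region: homotopic pairs grouped into contiguous
    blocks, both homologs sharing a module (bilateral communities)."""
    n = parcellation.n_regions
    hom = np.asarray(parcellation.homolog_id)
    labels = np.full(n, -1)
    pairs = parcellation.homotopic_pairs()
    for p, (i, j) in enumerate(pairs):
        m = p * n_modules // max(len(pairs), 1)
        labels[i] = labels[j] = m
    unpaired = np.flatnonzero(labels < 0)
    labels[unpaired] = np.arange(len(unpaired)) % n_modules
    return labels


def make_state_covariances(
    truth: GroundTruth,
    parcellation: Parcellation,
    n_states: int = 3,
    seed: int = 0,
    n_modules: int = 4,
    module_strength: tuple[float, float] = (0.15, 0.45),
    fluct_scale: float = 0.15,
    base_cap: float = 0.8,
) -> GroundTruth:
    """Attach K latent-state correlation matrices to a structural truth.

    Each state's raw correlation is ``I + base + modules + fluctuation``:

    * base — ``coupling_gain * Wn + homotopic_boost * H`` capped at
      ``base_cap``, where Wn is the structural weight normalised by its
      90th percentile (clipped at 1) and H marks homotopic pairs; identical
      across states, so structurally coupled and homotopic edges are strong
      *and stable*;
    * modules — bilateral communities of homotopic-pair blocks whose
      within-module correlation is redrawn per state from
      ``module_strength`` (uniform), producing slow, genuine D-FC
      fluctuation concentrated on weakly anchored edges;
    * fluctuation — a state-specific symmetric Gaussian perturbation of
      scale ``fluct_scale``, damped toward zero on edges already stabilised
      by base + modules.

    Each raw matrix is repaired to the nearest unit-diagonal positive-
    definite correlation (eigenvalue clipping at 1e-8); the repaired
    matrices are the analytic ground truth stored on the returned object.
    """
    n = truth.n_regions
    rng = np.random.default_rng(seed)
    w = truth.structural_weights
    if w.max() > 0:
        ref = np.quantile(w[w > 0], 0.9)
        wn = np.clip(w / ref, 0.0, 1.0)
    else:
        wn = w
    hom = np.asarray(parcellation.homolog_id)
    h = np.zeros((n, n))
    for i in range(n):
        if hom[i] != NO_HOMOLOG:
            h[i, hom[i]] = 1.0
    base = np.clip(truth.coupling_gain * wn + truth.homotopic_boost * h, 0.0, base_cap)
    np.fill_diagonal(base, 0.0)
    labels = _module_assignment(parcellation, n_modules)
    same_module = labels[:, None] == labels[None, :]
    covs = []
    lo, hi = module_strength
    for _ in range(n_states):
        a = rng.uniform(lo, hi, size=n_modules)
        mod = np.where(same_module, a[labels], 0.0)
        np.fill_diagonal(mod, 0.0)
        anchored = np.clip(base + mod, 0.0, 0.9)
        damp = 1.0 - anchored / 0.9
        g = rng.standard_normal((n, n))
        pert = fluct_scale * damp * (g + g.T) / np.sqrt(2.0)
        off = np.clip(base + mod + pert, -0.95, 0.95)
        np.fill_diagonal(off, 0.0)
        covs.append(_nearest_pd_correlation(np.eye(n) + off))
    return replace(truth, state_covariances=covs)


def simulate_streamline_counts(
    truth: GroundTruth, parcellation: Parcellation, scale: float, seed: int
) -> np.ndarray:
    """Poisson streamline counts: mean = scale * weight * mean pair volume."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    n = truth.n_regions
    if parcellation.n_regions != n:
        raise ValueError("parcellation does not match ground truth")
    rng = np.random.default_rng(seed)
    vol = np.asarray(parcellation.volume)
    mean_vol = (vol[:, None] + vol[None, :]) / 2.0
    lam = scale * truth.structural_weights * mean_vol
    iu, ju = edge_index(n)
    counts = np.zeros((n, n), dtype=int)
    counts[iu, ju] = rng.poisson(lam[iu, ju])
    counts = counts + counts.T
    return counts


def simulate_bold(
    truth: GroundTruth,
    parcellation: Parcellation,
    n_timepoints: int,
    sampling_interval: float = 0.645,
    seed: int = 0,
    subject_id: str = "sub-00",
) -> RegionalTimeSeries:
    """Sample a state-switching multivariate Gaussian regional time series.

    The hidden state follows a Markov chain with stay probability
    ``1 - 1/state_dwell_mean`` (geometric dwell with the requested mean) and
    uniform switching among the other states. Within a state, samples are
    i.i.d. draws from that state's correlation matrix; white observation
    noise of sd ``noise_sd`` is added. The realised state sequence is
    attached to the returned series for diagnostics.
    """
    if truth.n_states == 0:
        raise ValueError("truth has no state covariances; call make_state_covariances")
    if n_timepoints < 2:
        raise ValueError("need at least 2 time points")
    k = truth.n_states
    n = truth.n_regions
    rng = np.random.default_rng(seed)
    chols = []
    for s, c in enumerate(truth.state_covariances):
        try:
            chols.append(np.linalg.cholesky(c))
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"generation failure: state {s} covariance not positive definite") from exc

    p_stay = 1.0 - 1.0 / truth.state_dwell_mean if k > 1 else 1.0
    states = np.empty(n_timepoints, dtype=int)
    states[0] = rng.integers(k)
    u = rng.random(n_timepoints)
    for t in range(1, n_timepoints):
        if u[t] < p_stay:
            states[t] = states[t - 1]
        else:
            step = rng.integers(1, k) if k > 1 else 0
            states[t] = (states[t - 1] + step) % k
    z = rng.standard_normal((n_timepoints, n))
    x = np.empty_like(z)
    for s in range(k):
        idx = states == s
        x[idx] = z[idx] @ chols[s].T
    x += truth.noise_sd * rng.standard_normal((n_timepoints, n))
    return RegionalTimeSeries(
        values=x,
        sampling_interval=sampling_interval,
        subject_id=subject_id,
        state_sequence=states,
    )


def analytic_average_correlation(truth: GroundTruth) -> np.ndarray:
    """State-averaged observed correlation implied by the generator.

    Averages the (repaired) state correlations with equal stationary weight
    and attenuates by the observation noise: corr_obs = corr / (1 + sd^2).
    """
    if truth.n_states == 0:
        raise ValueError("truth has no state covariances")
    c = np.mean(truth.state_covariances, axis=0)
    c = c / (1.0 + truth.noise_sd**2)
    np.fill_diagonal(c, 1.0)
    return c


@dataclass(frozen=True)
class _Preset:
    n_pairs: int = 20
    n_states: int = 3
    state_dwell_mean: float = 150.0
    n_timepoints: int = 2000
    sampling_interval: float = 0.645
    density: float = 0.21
    n_hubs: int = 4
    coupling_gain: float = 0.7
    homotopic_boost: float = 0.45
    noise_sd: float = 0.25
    n_modules: int = 4
    module_strength: tuple = (0.15, 0.45)
    fluct_scale: float = 0.15


DEFAULT_PRESET = _Preset()


def default_preset(seed: int = 0):
    """Default synthetic conditions: (parcellation, ground truth).

    N=40 regions (20 homotopic pairs), K=3 covariance states with mean dwell
    150 samples, structural density 0.21 with 4 planted hubs — small enough
    for routine testing, large enough for stable 155-sample windowed
    correlations at T=2000.
    """
    p = DEFAULT_PRESET
    ss = np.random.SeedSequence(seed)
    s_parc, s_struct, s_states = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    parc = generate_parcellation(p.n_pairs, seed=s_parc)
    truth = generate_structural_truth(
        parc, density=p.density, n_hubs=p.n_hubs, homotopic_guarantee=True, seed=s_struct
    )
    truth = replace(
        truth,
        state_dwell_mean=p.state_dwell_mean,
        homotopic_boost=p.homotopic_boost,
        coupling_gain=p.coupling_gain,
        noise_sd=p.noise_sd,
    )
    truth = make_state_covariances(
        truth, parc, n_states=p.n_states, seed=s_states, n_modules=p.n_modules,
        module_strength=p.module_strength, fluct_scale=p.fluct_scale,
    )
    return parc, truth
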