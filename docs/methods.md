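# Methods

This note records the models, conventions and numerical choices behind
`dynconn`, in the spirit of a package's methods appendix: what is computed,
what is assumed, and where a genuinely open design choice was resolved.

## Sliding-window dynamic connectivity

Windows are rectangular, left-aligned at onsets 0, step, 2·step, …, so the
window count is ⌊(T − L)/step⌋ + 1. A window length in seconds is converted
to samples as round(seconds/TR); 100 s at TR = 0.645 s gives L = 155
samples, and 883 retained samples then yield 729 unit-step windows. No
taper is applied (tapered windows, DCC-type estimators and phase synchrony
are out of scope). Within each window the estimator is the plain Pearson
correlation; a region constant within any window is a hard error naming
the window and region, not a silent NaN.

Temporal edge statistics are computed on raw correlations, negative values
included: strength is the arithmetic mean across windows and variability
the 1/(T−1)-normalised squared deviation. Whether the variability of the
analysis should be a variance or its square root is ambiguous in the
literature this pipeline follows; the variance is the default and
`variability="std"` computes the root. Every sign-level conclusion is
invariant to this monotone choice, which is why it is an option rather
than a fork.

The Fisher r-to-z transform (atanh) is applied only where a second-level
correlation is computed over correlation values — i.e. inside the
S-FC/D-FC spatial-similarity measure, which correlates the z-transformed
upper triangles (diagonal excluded) of the static matrix and each window's
matrix. Correlations are clipped to ±(1 − 1e-12) before atanh so that
exactly ±1 entries (identical signals) stay finite; tMean/tVar use raw r.

Edges are partitioned by the parcellation's homolog mapping into homotopic
(region vs its contralateral homolog), heterotopic (other
interhemispheric) and intrahemispheric pairs. Category contrasts use a
label-shuffling permutation test on the difference of category means with
the add-one p estimator p = (1 + #{|null| ≥ |obs|})/(n_perm + 1) — p is
never exactly zero, and with 10,000 shuffles the smallest reportable
two-sided p is ≈ 1e-4. The test is two-sided (sidedness is not dictated by
the method; the direction is reported separately) and Bonferroni-corrected
by the fixed factor 3 (the number of category pairs).

## Network construction

The default threshold is significance-based: per-edge α = α_corr/(N(N−1)/2)
with α_corr = 0.01, mapped to a correlation cutoff via the inverse-t
relation r = t/√(df + t²) at df = L − 2. The per-edge test is read as
two-sided (the conventional reading; a one-sided flag exists) and edges
require r strictly greater than τ; negative correlations are always
excluded, as their physiological interpretation in functional networks is
contested. Sparsity-based thresholding keeps the top ⌊S·N(N−1)/2⌋ positive
correlations with a deterministic tie-break (descending r, then ascending
(i, j)); if fewer positive correlations exist than requested, the achieved
sparsity is reported with a warning rather than padding. Weighted
construction retains the correlation values on the same edge set.

## Graph topology

Clustering uses the Watts–Strogatz local coefficient; nodes with degree
< 2 contribute 0 (not excluded), keeping C_p a mean over all N nodes. Path
length is the mean BFS shortest path over *connected* node pairs only,
with the component census (count, largest) always reported alongside —
averaging over connected pairs avoids infinities for the occasional
disconnected window while keeping values comparable, and the census makes
the exclusion visible. Assortativity is the Pearson correlation of degrees
over edge endpoints (both orientations); degree-regular edge sets make it
undefined and it is reported as NaN.

Null normalisation uses Maslov–Sneppen double-edge swaps rejecting
self-loops and multi-edges, which conserves the degree sequence exactly.
The number of swaps is not canonical anywhere; the default is 10 attempted
swaps per edge. The swap kernel is numba-compiled with all randomness
pre-drawn from a seeded numpy Generator, so rewiring is reproducible and
fast enough for per-window ensembles (the default analysis rewires
100 nulls × ~1,800 windows per subject). γ, λ, σ = γ/λ are ratios against
the ensemble means; α_z uses the sample (n−1) standard deviation. A graph
admitting no valid swap (e.g. a complete triangle) is returned unchanged
with a warning. Weighted variants use Onnela's geometric-mean triangle
clustering on weights normalised by the maximum, and Dijkstra path lengths
on edge lengths 1/weight; these formulas are conventions, not uniquely
determined, so only sign-level conclusions are claimed for weighted runs.

## Hubs and temporal statistics of topology

A window hub has degree strictly above the network mean ("exceeds" is read
strictly, so regular graphs have no hubs); a persistent hub has occurrence
probability strictly above 0.5. The same 1/(T−1) temporal kernel used for
edges applies to every global metric and to per-node degree. Normalised
histograms (masses summing to 1) use a fixed bin grid shared across
participants so group averaging preserves normalisation. Per-window null
ensembles are seeded from (base seed, window index): reruns are
reproducible and windows uncorrelated.

## Structural networks and backbone

A structural connection's strength is the streamline count divided by the
mean volume of the two regions. The group backbone applies, per edge, a
one-tailed sign test of the null "no connection": success is a strictly
positive strength, zeros count as failures (this reading makes the test an
exact binomial, P(X ≥ k | n, ½), reproducible to machine precision), and
edges with p < 0.05 are retained with the mean strength across *all*
subjects (a mean over the present subjects is available as an option).
With 10 subjects this retains edges present in ≥ 8 (p = 56/1024 ≈ 0.055
fails at 8, 11/1024 passes at 9). Structural topology is computed on the
binarized individual networks so it is comparable with the binary
functional networks.

## Structure–function coupling

"Gaussian resampling" is implemented as the rank-based inverse-normal
transform: average ranks for ties, rankit plotting positions
(rank − ½)/n mapped through the standard normal quantile, scaled to
mean ± sd = 0.5 ± 0.1. The rankit constant is one of several standard
plotting positions (Blom's is another); sign-level results are invariant
to the choice. Connection-level coupling restricts to SC-present edges and
treats edges as independent in the Pearson p-values (df = n_edges − 2),
which overstates precision for spatially correlated edges — a known
limitation inherited from the analysis convention, relevant to p-values
but not to the reported signs.

## The synthetic generator

The generator is a testing device that plants the statistical structure
the analysis assumes; it is not a biophysical model (no hemodynamic or
neural-mass dynamics, no tractography).

Regional signals follow a hidden-Markov covariance model: a latent state
with geometric dwell (mean 150 samples ≈ 97 s at TR = 0.645 s, so windows
straddle state changes often enough to create genuine drift) selects one
of K = 3 correlation matrices, within which samples are i.i.d. Gaussian,
plus white observation noise (sd 0.25, which attenuates all observed
correlations by 1/(1 + sd²) without reordering them). Each state's
correlation is composed of

* a stable base: coupling_gain × structural weight (normalised by its 90th
  percentile, capped) plus a homotopic boost on homolog pairs, identical
  across states — so structurally coupled and homotopic edges are strong
  *and* temporally stable;
* bilateral community factors: homotopic-pair blocks (4 modules) whose
  within-module correlation is redrawn per state from U(0.15, 0.45) — the
  main source of genuine, slow connectivity fluctuation, concentrated on
  edges not anchored by structure;
* a small state-specific symmetric perturbation (scale 0.15), damped
  toward zero on anchored edges.

The composed matrix is repaired to the nearest unit-diagonal positive-
definite correlation by eigenvalue clipping at 1e-8; the *repaired*
matrices are stored as the analytic ground truth, so tests compare sample
statistics against what was actually sampled from. The structural graph is
drawn at a requested density (default 0.21) with edges preferring
within-module pairs (affinity factor 9) and designated hub nodes
(preferential sampling plus a repair pass guaranteeing each hub at least
twice the non-hub mean degree); homotopic pairs are always wired by
default. The modular wiring is what makes the structural graph
small-world (γ ≫ 1, λ ≈ 1) rather than merely dense. Streamline counts
are Poisson with mean scale × weight × mean pair volume, so the
volume-normalised count recovers scale × weight in expectation.

Default preset: N = 40 regions (20 pairs), T = 2,000 samples, K = 3
states — small enough that the full unit-step analysis with 100-null
ensembles per window runs in minutes on one CPU, large enough for stable
155-sample windowed correlations. What passing recovery tests on this
preset shows is that the pipeline detects planted effects of realistic
sign and rough magnitude under Gaussian, stationary-within-state dynamics;
it does not validate the analysis against non-Gaussian BOLD features,
scanner noise structure, motion artefacts, or hemodynamic confounds, none
of which the generator emulates.

## Determinism and problem sizes

Every public generator and test consumes an explicit seed or Generator; no
global random state is touched. The pipeline derives per-stage seeds from
the master seed by hashing the stage name, records them in the run
manifest, and checksums every output; identical (config, seed) pairs give
identical manifests. The test suite and the acceptance script run the
default preset at full resolution (unit-step windows, 100 nulls per
window) for the single-subject recovery checks, and moderate sizes
(stepped windows, smaller ensembles) where only sign-level or structural
behaviour is exercised; calibration checks use 200 replicates of
1,000-shuffle tests. Matrices travel as TSV at 17 significant digits and
are re-read with round-trip float parsing, so save→load is bit-exact.
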