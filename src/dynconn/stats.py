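"""Permutation machinery and rank-based normalisation shared across stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["PermutationResult", "permutation_diff_test", "gaussian_resample"]


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a label-shuffling test on a difference of group means.

    ``p_value`` uses the add-one estimator (1 + #{|null| >= |obs|})/(n_perm + 1),
    so p is never exactly zero.
    """

    observed: float
    null_mean: float
    null_sd: float
    p_value: float
    n_perm: int
    direction: str = "two_sided"


def permutation_diff_test(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
    direction: str = "two_sided",
) -> PermutationResult:
    """Test mean(x) - mean(y) by shuffling group labels.

    Parameters
    ----------
    x, y : 1-D arrays of edge-level (or node-level) values.
    n_perm : number of label shuffles (>= 100).
    rng : seed or Generator; all randomness flows through it.
    direction : "two_sided", "greater" or "less".
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if len(x) < 2 or len(y) < 2:
        raise ValueError("degenerate category: each group needs >= 2 values")
    rng = np.random.default_rng(rng)
    combined = np.concatenate([x, y])
    nx, n = len(x), len(combined)
    observed = float(x.mean() - y.mean())

    # mean(x) - mean(y) is affine in sum(x); permute via random index matrices
    # in memory-bounded blocks.
    total = combined.sum()
    null = np.empty(n_perm)
    block = max(1, int(2e7 // n))
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        idx = np.argsort(rng.random((b, n)), axis=1)[:, :nx]
        sx = combined[idx].sum(axis=1)
        null[done:done + b] = sx / nx - (total - sx) / (n - nx)
        done += b

    if direction == "two_sided":
        exceed = np.abs(null) >= abs(observed)
    elif direction == "greater":
        exceed = null >= observed
    elif direction == "less":
        exceed = null <= observed
    else:
        raise ValueError(f"unknown direction {direction!r}")
    p = (1.0 + int(exceed.sum())) / (n_perm + 1.0)
    return PermutationResult(
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        p_value=float(p),
        n_perm=n_perm,
        direction=direction,
    )


def gaussian_resample(
    values: np.ndarray, target_mean: float = 0.5, target_sd: float = 0.1
) -> np.ndarray:
    """Rank-based inverse-normal transform to a prescribed mean and sd.

    Values are replaced by standard-normal quantiles at the rankit plotting
    positions (rank - 0.5)/n (average ranks for ties), then scaled and
    shifted to (target_mean, target_sd). Strictly rank-preserving for
    untied inputs; invariant to any strictly monotone pre-transformation.
    """
    v = np.asarray(values, float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(v) == 0:
        raise ValueError("degenerate input: all values identical")
    ranks = sps.rankdata(v, method="average")
    z = sps.norm.ppf((ranks - 0.5) / v.size)
    return target_mean + target_sd * z
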