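"""Shared fixtures: one synthetic cohort at the default preset, computed once.

The preset subject (seed fixed) is the workhorse of the recovery tests:
its windowed connectivity, edge statistics and degree series are reused
across modules so the expensive simulation happens a single time per
session.
"""

from __future__ import annotations

import numpy as np
import pytest

import dynconn as dc

PRESET_SEED = 1
SUBJECT_SEED = 11


@pytest.fixture(scope="session")
def preset():
    return dc.default_preset(PRESET_SEED)


@pytest.fixture(scope="session")
def bold(preset):
    parc, truth = preset
    return dc.simulate_bold(truth, parc, dc.DEFAULT_PRESET.n_timepoints,
                            dc.DEFAULT_PRESET.sampling_interval, seed=SUBJECT_SEED)


@pytest.fixture(scope="session")
def dfc_series(bold):
    return dc.sliding_window_dfc(bold, dc.SlidingWindowSpec(length=155, step=1))


@pytest.fixture(scope="session")
def edge_stats(dfc_series):
    return dc.temporal_edge_stats(dfc_series)


@pytest.fixture(scope="session")
def bonferroni_policy():
    return dc.ThresholdPolicy(mode="bonferroni_r", alpha_corr=0.01)


@pytest.fixture(scope="session")
def degree_series(dfc_series, bonferroni_policy):
    """Per-window degree matrix of the preset subject (no null ensembles)."""
    mts = dc.metric_time_series(dfc_series, bonferroni_policy, normalized=False)
    return mts


@pytest.fixture(scope="session")
def structural_cohort(preset):
    """Six subjects' streamline counts and structural networks from one truth."""
    parc, truth = preset
    counts = [dc.simulate_streamline_counts(truth, parc, scale=30.0, seed=100 + i)
              for i in range(6)]
    nets = [dc.sc_from_streamlines(c, parc) for c in counts]
    return counts, nets


def random_binary_graph(rng: np.random.Generator, n: int, p: float) -> dc.BinaryGraph:
    """Erdos-Renyi helper used across metric tests."""
    a = rng.random((n, n)) < p
    a = np.triu(a, 1)
    return dc.BinaryGraph(a + a.T)
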