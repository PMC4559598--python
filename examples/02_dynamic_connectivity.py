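"""Sliding-window connectivity, temporal edge statistics, edge categories.

A 155-sample (100 s at TR = 0.645 s) window stepped by one sample turns one
regional time series into a sequence of correlation matrices; per edge, the
temporal mean is its strength and the 1/(T-1) variance its variability.
"""

import dynconn as dc
import numpy as np

parc, truth = dc.default_preset(seed=1)
ts = dc.simulate_bold(truth, parc, 2000, 0.645, seed=11)

spec = dc.SlidingWindowSpec(length=dc.window_samples_from_seconds(100, 0.645), step=1)
dfc = dc.sliding_window_dfc(ts, spec)
print(f"{dfc.n_windows} windows of {spec.length} samples")

sim = dc.spatial_similarity(dc.static_fc(ts), dfc)
print(f"S-FC/D-FC spatial similarity: mean {sim.mean():.3f}, "
      f"range [{sim.min():.3f}, {sim.max():.3f}]")
# High similarity (> 0.7) means the whole-brain correlation pattern is
# fluctuating around a stable backbone, not reorganising at random.

stats = dc.temporal_edge_stats(dfc)
cats = dc.classify_edges(parc)
s, v = dc.upper_triangle(stats.strength), dc.upper_triangle(stats.variability)
for c in ("homotopic", "heterotopic", "intrahemispheric"):
    print(f"{c:17s} strength {s[cats == c].mean():.3f}  "
          f"variability {v[cats == c].mean():.5f}")

comps = dc.category_comparison(stats.strength, cats, n_perm=10_000, seed=0)
for c in comps:
    print(f"{c.pair[0]} vs {c.pair[1]}: diff {c.result.observed:+.3f}, "
          f"Bonferroni p = {c.p_adjusted:.2g}")
# Homotopic edges come out strongest and most stable: the shared
# interhemispheric component the generator plants is recovered.
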