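"""Preprocess one subject and compute sliding-window connectivity.

Shows the in-scope temporal preprocessing (discard 10 volumes, detrend,
band-pass 0.01-0.08 Hz) and the 30-volume / 3-volume-step window grid that
turns 230 retained volumes into 67 Fisher-Z connectivity matrices, plus the
across-window variability map.
"""

import numpy as np

import dfcstates as d

cfg = d.CohortConfig(seed=2, n_group_a=1, n_group_b=1, n_regions=30)
series, _, _ = d.generate_cohort(cfg)
ts = series[0]

pre = d.preprocess(ts, n_discard=10, detrend=True, band=(0.01, 0.08))
print(f"{ts.subject_id}: {ts.n_volumes} acquired -> {pre.n_volumes} retained volumes")

spec = d.WindowSpec(window_len=30, step=3)
wfc = d.windowed_fc(pre, spec)
print(f"windows: {wfc.n_windows}  first {wfc.windows[0]}  last {wfc.windows[-1]}")
print(f"connectivity stack shape: {wfc.z.shape}  (windows x regions x regions)")

vm = d.variability_map(wfc)
edge_sd = d.upper_vec(vm.sd_z)
print(f"dFC variability (sd of Z across windows): median {np.median(edge_sd):.3f}, "
      f"max {edge_sd.max():.3f}")
# Each window holds the Pearson correlation of all region pairs over 60 s of
# signal, arctanh-transformed; the variability map is the per-edge standard
# deviation of that value over time — the basic dFC summary.
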