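"""Detect time-resolved communities with multilayer modularity.

The supra-modularity matrix couples each region to itself across adjacent
windows (omega = 1) and scores within-window structure against the
Newman-Girvan null (gamma = 1); iterated Louvain maximises Q.
"""
import numpy as np
from sklearn.metrics import adjusted_rand_score

import dynflex as dx

spec = dx.CohortSpec(n_subjects_per_group=(1, 1), n_regions=40,
                     n_timepoints=120, n_modules=4, seed=3)
truth = dx.generate_partition_sequence(spec, 0, 30)
ts = dx.simulate_timeseries(truth, spec, 31)
stack = dx.dynamic_connectivity(ts, dx.WindowScheme(30, 1))

tensor = dx.build_modularity_tensor(stack, dx.QualityParams(gamma=1.0, omega=1.0))
part = dx.louvain_multilayer(tensor, seed=0)
print(f"S matrix: {part.S.shape[0]} regions x {part.S.shape[1]} layers, "
      f"Q = {part.Q:.3f}, {np.unique(part.S).size} communities")

aris = [adjusted_rand_score(
    truth.labels[:, truth.epoch_of_time(int(s) + 15)], part.S[:, l])
    for l, s in enumerate(stack.window_starts)]
print(f"per-layer agreement with planted modules: median ARI {np.median(aris):.3f}")
# ARI near 1 means the detected communities recover the planted modules
# layer by layer; Q is the fraction of supra-matrix weight captured.
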