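"""Robustness of the group contrast to the sliding-window geometry.

The full analysis is repeated across window (width, step) settings with
shared seeds; subjects' global flexibility should rank almost identically
and the group t statistic should keep its sign.
"""
import dynflex as dx
from dynflex.pipeline import PipelineConfig, run_sweep
from dynflex.stats import ComparisonSpec

config = PipelineConfig(
    cohort=dx.CohortSpec(n_subjects_per_group=(4, 4), n_regions=30,
                         n_timepoints=90, n_modules=3,
                         switch_rate_per_group=(0.05, 0.40), seed=7),
    n_reps=3,
    comparison=ComparisonSpec(n_permutations=200, seed=0),
    include_nodal=False,
    out_dir="example_output/sweep",
    sweep_settings=[(30, 1), (30, 2), (40, 1), (20, 1)],
)
table = run_sweep(config)
flex = table.query("metric == 'flexibility'")
print(flex.round(3).to_string(index=False))
# rank_correlation rows: Spearman rho of per-subject global flexibility
# between two window settings (near 1 = stable ranking).  global_t rows:
# the group t per setting; a consistent negative sign reproduces the
# planted low-switch < high-switch direction under every geometry.
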