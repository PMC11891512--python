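"""Temporal core-periphery classification from flexibility deciles.

The 10% least flexible regions form the temporal core (stable community
membership), the 10% most flexible the periphery; the composition table
shows which functional networks populate each class.
"""
import pandas as pd

import dynflex as dx
from dynflex.core_periphery import assign_core_periphery, network_composition
from dynflex.metrics import average_over_repetitions, node_dynamics

spec = dx.CohortSpec(n_subjects_per_group=(1, 1), n_regions=60,
                     n_timepoints=120, n_modules=4,
                     switch_rate_per_group=(0.2, 0.2), seed=5)
truth = dx.generate_partition_sequence(spec, 0, 50)
ts = dx.simulate_timeseries(truth, spec, 51)
stack = dx.dynamic_connectivity(ts, dx.WindowScheme(30, 1))
parts = dx.repeat_partitions(stack, n_reps=5, base_seed=0)
table = average_over_repetitions(
    [node_dynamics(p.S, ts.region_ids) for p in parts])

assignment = assign_core_periphery(table["flexibility"], fraction=0.10)
print(f"core: {len(assignment.core_nodes)} regions, "
      f"periphery: {len(assignment.periphery_nodes)} regions")
nets = pd.Series(ts.network_labels, index=table.index)
comp = network_composition(assignment, nets)
print(comp.pivot(index="network", columns="class", values="proportion")
      .fillna(0).round(2))
# Each column sums to 1: the share of core (or periphery) nodes that each
# functional network contributes.
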