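"""Temporal core–periphery classification from flexibility quantiles.

Nodes in the lowest decile of (group-mean) flexibility form the temporal
core — regions stably affiliated with their community — and nodes in the
highest decile form the temporal periphery.  The decile count is
round-half-away-from-zero of fraction·N (10% of 227 regions → 23 nodes per
class); boundary ties are broken by stable input order with a warning.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError


@dataclass
class CorePeripheryAssignment:
    core_nodes: list[str]
    periphery_nodes: list[str]
    fraction: float
    flexibility: pd.Series  # group-mean nodal flexibility used as the basis


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def assign_core_periphery(flex: pd.Series, fraction: float = 0.10
                          ) -> CorePeripheryAssignment:
    """Split nodes into lowest-``fraction`` core and highest-``fraction``
    periphery by flexibility."""
    if not 0 < fraction <= 0.5:
        raise ContractError("fraction must lie in (0, 0.5]")
    n = len(flex)
    k = _round_half_away(fraction * n)
    if k < 1:
        raise ContractError("fraction too small: no nodes selected")
    values = flex.to_numpy()
    order = np.argsort(values, kind="stable")
    core_idx = order[:k]
    per_idx = order[n - k:]
    # a tie across the selection boundary means membership depends on input order
    if (k < n and values[order[k - 1]] == values[order[k]]) or (
            n - k > 0 and values[order[n - k]] == values[order[n - k - 1]]):
        warnings.warn(
            "flexibility ties at the core/periphery boundary; membership "
            "resolved by stable input order", stacklevel=2,
        )
    return CorePeripheryAssignment(
        core_nodes=[flex.index[i] for i in core_idx],
        periphery_nodes=[flex.index[i] for i in per_idx],
        fraction=fraction,
        flexibility=flex,
    )


def network_composition(assignment: CorePeripheryAssignment,
                        network_labels: pd.Series) -> pd.DataFrame:
    """Per-network share of the core and of the periphery.

    Returns a tidy frame (class, network, proportion); proportions sum to 1
    within each class.
    """
    if not set(assignment.flexibility.index) <= set(network_labels.index):
        raise ContractError("network labels do not cover all regions")
    rows = []
    for cls, members in (("core", assignment.core_nodes),
                         ("periphery", assignment.periphery_nodes)):
        if not members:
            raise ContractError(f"{cls} class is empty")
        nets = network_labels.loc[members]
        counts = nets.value_counts()
        for net, c in counts.items():
            rows.append((cls, net, c / len(members)))
    return pd.DataFrame(rows, columns=["class", "network", "proportion"])


def assignment_table(assignment: CorePeripheryAssignment,
                     network_labels: pd.Series) -> pd.DataFrame:
    """Region-level table (region, network, class in {core, periphery, neither})."""
    cls = pd.Series("neither", index=assignment.flexibility.index, name="class")
    cls.loc[assignment.core_nodes] = "core"
    cls.loc[assignment.periphery_nodes] = "periphery"
    return pd.DataFrame({
        "network": network_labels.loc[cls.index],
        "class": cls,
    }).rename_axis("region").reset_index()
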