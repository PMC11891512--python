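"""Temporal reconfiguration metrics of a multilayer partition.

All four metrics are per-node functions of the community matrix S
(regions × layers) and are label-free:

* flexibility  F_i = m / (L − 1), the fraction of layer transitions at
  which node i changes community (m = number of changes);
* promiscuity  P_i = c_p / C, the fraction of all C detected communities
  node i ever joins (c_p = communities visited);
* cohesion     fraction of transitions at which i changes community
  together with at least one other node sharing both its source and its
  destination community;
* disjointedness  fraction of transitions at which i changes alone.

Cohesion and disjointedness are both normalised by L − 1 change
opportunities, which makes ``flexibility = cohesion + disjointedness`` an
exact node-wise identity — every change is either coordinated or solo.
Because the Louvain optimiser is stochastic, metrics are computed per
repetition and averaged.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ContractError, UndefinedMetricError

METRICS = ("flexibility", "promiscuity", "cohesion", "disjointedness")


def _check_layers(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S)
    if S.ndim != 2:
        raise ContractError("S must be a 2-D regions x layers matrix")
    if S.shape[1] < 2:
        raise UndefinedMetricError(
            "temporal metrics need at least 2 layers (one transition)"
        )
    return S


def flexibility(S: np.ndarray) -> np.ndarray:
    """F_i = (#community changes) / (L − 1) per node, in [0, 1]."""
    S = _check_layers(S)
    return (S[:, 1:] != S[:, :-1]).mean(axis=1)


def promiscuity(S: np.ndarray) -> np.ndarray:
    """P_i = (#distinct communities of node i) / C, in [1/C, 1]."""
    S = np.asarray(S)
    if S.ndim != 2:
        raise ContractError("S must be a 2-D regions x layers matrix")
    C = np.unique(S).size
    visited = np.array([np.unique(row).size for row in S])
    return visited / C


def classify_changes(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-node (cohesive, disjoint) change counts over layer transitions.

    A change of node i at transition l is cohesive iff some other node j
    has the same community as i in layer l AND in layer l+1 (such a j has
    necessarily changed too, sharing i's source and destination); otherwise
    the change is disjoint.
    """
    S = _check_layers(S)
    N, L = S.shape
    cohesive = np.zeros(N, dtype=np.int64)
    disjoint = np.zeros(N, dtype=np.int64)
    span = int(S.max()) + 1
    for l in range(L - 1):
        a, b = S[:, l], S[:, l + 1]
        changed = np.flatnonzero(a != b)
        if changed.size == 0:
            continue
        codes = a[changed].astype(np.int64) * span + b[changed]
        uniq, counts = np.unique(codes, return_counts=True)
        shared = np.isin(codes, uniq[counts >= 2])
        cohesive[changed[shared]] += 1
        disjoint[changed[~shared]] += 1
    return cohesive, disjoint


def cohesion_disjointedness(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cohesive and disjoint change counts normalised by L − 1."""
    S = _check_layers(S)
    cohesive, disjoint = classify_changes(S)
    denom = S.shape[1] - 1
    return cohesive / denom, disjoint / denom


def node_dynamics(S: np.ndarray, region_ids: list[str] | None = None
                  ) -> pd.DataFrame:
    """All four metrics for one partition, indexed by region."""
    S = _check_layers(S)
    coh, dis = cohesion_disjointedness(S)
    idx = region_ids if region_ids is not None else [
        f"R{i + 1:03d}" for i in range(S.shape[0])
    ]
    table = pd.DataFrame(
        {
            "flexibility": flexibility(S),
            "promiscuity": promiscuity(S),
            "cohesion": coh,
            "disjointedness": dis,
        },
        index=pd.Index(idx, name="region"),
    )
    table.attrs["n_reps_averaged"] = 1
    return table


def average_over_repetitions(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Element-wise mean of per-repetition metric tables."""
    if not tables:
        raise ContractError("need at least one repetition")
    ref = tables[0].index
    for t in tables[1:]:
        if not t.index.equals(ref):
            raise ContractError("repetitions cover inconsistent region sets")
    mean = sum(t[list(METRICS)] for t in tables) / len(tables)
    mean.attrs["n_reps_averaged"] = len(tables)
    return mean


def aggregate(table: pd.DataFrame, network_labels: list[str]) -> pd.DataFrame:
    """Unweighted network-level and global means of every metric.

    Returns a tidy frame with columns (level, unit, metric, value); the
    global mean averages all node values, network means average member
    nodes only.
    """
    if len(network_labels) != len(table):
        raise ContractError("every region needs a network label")
    rows = []
    for metric in METRICS:
        rows.append(("global", "all", metric, float(table[metric].mean())))
    grouped = table.groupby(pd.Series(network_labels, index=table.index,
                                      name="network"))
    for net, sub in grouped:
        for metric in METRICS:
            rows.append(("network", net, metric, float(sub[metric].mean())))
    return pd.DataFrame(rows, columns=["level", "unit", "metric", "value"])
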