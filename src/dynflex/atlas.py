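"""Region bookkeeping for the 264-node functional parcellation.

The analysis operates on a 227-region subset of the Power 264-node atlas:
37 regions without a stable resting-state network assignment are dropped,
leaving 214 cortical and 13 subcortical regions organised into ten
functional networks.  Only the counts and network names are needed by the
pipeline (node identity never enters the maths), so this module carries the
bookkeeping table and a validator for input region manifests.  The concrete
region ids produced by :func:`full_atlas_table` are synthetic placeholders
with the correct counts, not MNI coordinates.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ContractError

ATLAS_TOTAL_REGIONS = 264
EXCLUDED_REGIONS = 37
RETAINED_REGIONS = 227
CORTICAL_REGIONS = 214
SUBCORTICAL_REGIONS = 13

#: Ten resting-state functional networks with their region counts.
NETWORK_SIZES: dict[str, int] = {
    "SMN": 35,   # sensorimotor
    "CON": 14,   # cingulo-opercular
    "AUN": 13,   # auditory
    "DMN": 58,   # default mode
    "VSN": 31,   # visual
    "FPN": 25,   # frontoparietal
    "SAN": 18,   # salience
    "SUN": 13,   # subcortical
    "VAN": 9,    # ventral attention
    "DAN": 11,   # dorsal attention
}

#: Networks whose members are subcortical; everything else is cortical.
SUBCORTICAL_NETWORKS: tuple[str, ...] = ("SUN",)

NETWORK_NAMES: tuple[str, ...] = tuple(NETWORK_SIZES)


def canonical_network_labels() -> list[str]:
    """Network label per region for the full 227-region set, in atlas order."""
    labels: list[str] = []
    for name, size in NETWORK_SIZES.items():
        labels.extend([name] * size)
    return labels


def make_network_labels(n_regions: int) -> list[str]:
    """Network labels for an ``n_regions``-node parcellation.

    The canonical 227-region set gets the real network sizes; any other size
    gets the ten network names allocated proportionally to those sizes so
    that downstream network-level aggregation always has all ten networks
    represented (each network keeps at least one member when
    ``n_regions >= 10``).
    """
    if n_regions == RETAINED_REGIONS:
        return canonical_network_labels()
    if n_regions < len(NETWORK_SIZES):
        # degenerate toy sizes: cycle through the names
        return [NETWORK_NAMES[i % len(NETWORK_NAMES)] for i in range(n_regions)]
    sizes = np.array(list(NETWORK_SIZES.values()), dtype=float)
    alloc = np.maximum(1, np.floor(sizes / sizes.sum() * n_regions).astype(int))
    # distribute the remainder to the largest networks first
    order = np.argsort(-sizes)
    i = 0
    while alloc.sum() < n_regions:
        alloc[order[i % len(order)]] += 1
        i += 1
    while alloc.sum() > n_regions:
        j = order[i % len(order)]
        if alloc[j] > 1:
            alloc[j] -= 1
        i += 1
    labels = []
    for name, k in zip(NETWORK_NAMES, alloc):
        labels.extend([name] * int(k))
    return labels


def full_atlas_table() -> pd.DataFrame:
    """Synthetic 264-row atlas manifest with the retained/excluded split.

    Columns: ``region_id``, ``network`` (``"none"`` for the 37 excluded
    regions), ``retained`` (bool), ``division`` (cortical/subcortical/excluded).
    """
    rows = []
    for i, net in enumerate(canonical_network_labels()):
        division = "subcortical" if net in SUBCORTICAL_NETWORKS else "cortical"
        rows.append((f"ROI{i + 1:03d}", net, True, division))
    for j in range(EXCLUDED_REGIONS):
        rows.append((f"ROI{RETAINED_REGIONS + j + 1:03d}", "none", False, "excluded"))
    return pd.DataFrame(rows, columns=["region_id", "network", "retained", "division"])


def retained_regions(atlas: pd.DataFrame) -> pd.DataFrame:
    """Filter an atlas manifest to its retained, network-labelled regions."""
    for col in ("region_id", "network", "retained"):
        if col not in atlas.columns:
            raise ContractError(f"atlas manifest lacks column {col!r}")
    return atlas.loc[atlas["retained"]].reset_index(drop=True)


def validate_region_manifest(manifest: pd.DataFrame) -> dict:
    """Validate a 227-region input manifest and return its summary counts.

    Checks that every region carries one of the ten network labels, that the
    per-network counts match the parcellation, and returns
    ``{"n_regions", "n_cortical", "n_subcortical", "per_network"}``.
    """
    if "network" not in manifest.columns:
        raise ContractError("manifest lacks a 'network' column")
    bad = set(manifest["network"]) - set(NETWORK_NAMES)
    if bad:
        raise ContractError(f"unknown network labels: {sorted(bad)}")
    per_network = manifest["network"].value_counts().to_dict()
    n = len(manifest)
    n_sub = int(manifest["network"].isin(SUBCORTICAL_NETWORKS).sum())
    summary = {
        "n_regions": n,
        "n_cortical": n - n_sub,
        "n_subcortical": n_sub,
        "per_network": per_network,
    }
    if n == RETAINED_REGIONS and per_network != NETWORK_SIZES:
        raise ContractError(
            "227-region manifest does not match the canonical network sizes"
        )
    return summary
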