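"""Sliding-window dynamic functional connectivity.

The subject's time series is decomposed into overlapping windows; each
window yields one Pearson correlation matrix ("layer").  With the default
width of 30 samples and step of 1, a 230-sample series produces 201 layers.
Edge weights are raw correlations (no Fisher transform) and negative edges
are kept, matching the convention of the generalized-Louvain toolchain the
multilayer stage follows; both behaviours are switchable.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cohort import SubjectTimeSeries
from .errors import ContractError, DegenerateWindowError, InvalidWindowError

EDGE_POLICIES = ("keep", "zero-negative", "absolute")


@dataclass(frozen=True)
class WindowScheme:
    """Sliding-window geometry in samples."""

    width: int = 30
    step: int = 1

    def __post_init__(self) -> None:
        if self.width < 2:
            raise InvalidWindowError("window width must be >= 2 samples")
        if self.step < 1:
            raise InvalidWindowError("step must be >= 1")

    def n_windows(self, series_length: int) -> int:
        if self.width > series_length:
            raise InvalidWindowError(
                f"window width {self.width} exceeds series length {series_length}"
            )
        return (series_length - self.width) // self.step + 1


@dataclass
class DynamicConnectivityStack:
    """N × N × L stack of windowed correlation matrices (the A_ijl)."""

    tensor: np.ndarray
    region_ids: list[str]
    window_starts: np.ndarray
    scheme: WindowScheme

    @property
    def n_regions(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_layers(self) -> int:
        return self.tensor.shape[2]


def enumerate_windows(series_length: int, scheme: WindowScheme
                      ) -> list[tuple[int, int]]:
    """Half-open ``[start, start + width)`` intervals of the scheme."""
    n = scheme.n_windows(series_length)
    return [(s * scheme.step, s * scheme.step + scheme.width) for s in range(n)]


def apply_edge_policy(tensor: np.ndarray, policy: str) -> np.ndarray:
    """Apply the negative-edge policy to a correlation stack."""
    if policy not in EDGE_POLICIES:
        raise ContractError(f"unknown edge policy {policy!r}; use one of {EDGE_POLICIES}")
    if policy == "zero-negative":
        return np.where(tensor < 0, 0.0, tensor)
    if policy == "absolute":
        return np.abs(tensor)
    return tensor


def dynamic_connectivity(ts: SubjectTimeSeries, scheme: WindowScheme,
                         fisher_z: bool = False,
                         edge_policy: str = "keep") -> DynamicConnectivityStack:
    """Windowed Pearson correlation stack for one subject.

    Each layer is the correlation matrix of one window with the diagonal
    zeroed (self-edges never contribute to layer strength or the null
    model).  Raises :class:`DegenerateWindowError` naming the first region
    with zero variance inside a window.
    """
    windows = enumerate_windows(ts.n_timepoints, scheme)
    N = ts.n_regions
    tensor = np.empty((N, N, len(windows)))
    for l, (a, b) in enumerate(windows):
        seg = ts.data[a:b]
        sd = seg.std(axis=0)
        if np.any(sd == 0):
            region = ts.region_ids[int(np.argmax(sd == 0))]
            raise DegenerateWindowError(
                f"region {region} has zero variance in window {l} [{a}, {b})"
            )
        C = np.corrcoef(seg, rowvar=False)
        np.clip(C, -1.0, 1.0, out=C)
        np.fill_diagonal(C, 0.0)
        tensor[:, :, l] = C
    if fisher_z:
        tensor = np.arctanh(np.clip(tensor, -1 + 1e-12, 1 - 1e-12))
        for l in range(tensor.shape[2]):
            np.fill_diagonal(tensor[:, :, l], 0.0)
    tensor = apply_edge_policy(tensor, edge_policy)
    return DynamicConnectivityStack(
        tensor=tensor, region_ids=list(ts.region_ids),
        window_starts=np.array([a for a, _ in windows]), scheme=scheme,
    )


def save_stack(stack: DynamicConnectivityStack, out_dir: str | Path) -> Path:
    """Write the stack as L delimited N × N matrices plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for l in range(stack.n_layers):
        np.savetxt(out / f"layer{l + 1:04d}.tsv", stack.tensor[:, :, l],
                   delimiter="\t", fmt="%.6f")
    sidecar = {
        "region_ids": stack.region_ids,
        "window_starts": stack.window_starts.tolist(),
        "scheme": {"width": stack.scheme.width, "step": stack.scheme.step},
        "n_layers": stack.n_layers,
    }
    path = out / "stack.json"
    path.write_text(json.dumps(sidecar, indent=2))
    return path


def load_stack(sidecar_path: str | Path) -> DynamicConnectivityStack:
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    L = meta["n_layers"]
    N = len(meta["region_ids"])
    tensor = np.empty((N, N, L))
    for l in range(L):
        tensor[:, :, l] = np.loadtxt(sidecar_path.parent / f"layer{l + 1:04d}.tsv",
                                     delimiter="\t")
    return DynamicConnectivityStack(
        tensor=tensor, region_ids=meta["region_ids"],
        window_starts=np.array(meta["window_starts"]),
        scheme=WindowScheme(**meta["scheme"]),
    )
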