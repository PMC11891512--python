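"""Synthetic two-group cohorts with planted time-varying community structure.

Real resting-state cohorts are not redistributable, so every downstream
stage is exercised on simulated region × time series whose community
dynamics are known exactly.  The generative model is piecewise stationary:
time is divided into epochs; within an epoch each region belongs to one of
``n_modules`` communities and signals follow a one-factor-per-module
Gaussian model whose implied correlation is ``within_module_corr`` inside a
module and 0 between modules.  At each epoch boundary every region switches
module independently with a group-specific probability; a controllable
fraction of switchers move in coordinated groups (sharing source and
destination module — "cohesive" changes) while the rest move alone to a
destination no co-mover of their module takes ("disjoint" changes).

Group-specific switch rates are the planted effect: a low-switch group has
genuinely lower flexibility than a high-switch group, which is what the
recovery and power checks downstream assert.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import make_network_labels
from .errors import ContractError, InvalidSpecError

_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated two-group cohort.

    Defaults mirror the target study geometry: 227 regions, 230 retained
    time points at a 2 s sampling interval, 13 + 14 subjects, and epochs as
    long as the 30-sample analysis window.
    """

    n_subjects_per_group: tuple[int, int] = (13, 14)
    n_regions: int = 227
    n_timepoints: int = 230
    n_modules: int = 5
    epoch_length: int = 30
    switch_rate_per_group: tuple[float, float] = (0.05, 0.30)
    cohesive_fraction: float = 0.5
    within_module_corr: float = 0.6
    noise_sd: float = 0.1
    sampling_interval_s: float = 2.0
    fd_group_gap: float = 0.0  # optional covariate confound: added to group 2's mean FD
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_subjects_per_group):
            raise InvalidSpecError("each group needs at least one subject")
        if self.n_modules < 2:
            raise InvalidSpecError("need at least 2 modules")
        if self.n_modules > self.n_regions:
            raise InvalidSpecError("more modules than regions")
        if self.epoch_length < 2:
            raise InvalidSpecError("epoch_length must be >= 2")
        if self.n_timepoints < self.epoch_length:
            raise InvalidSpecError("fewer time points than one epoch")
        if not all(0.0 <= r <= 1.0 for r in self.switch_rate_per_group):
            raise InvalidSpecError("switch rates must lie in [0, 1]")
        if not 0.0 <= self.cohesive_fraction <= 1.0:
            raise InvalidSpecError("cohesive_fraction must lie in [0, 1]")
        if not 0.0 <= self.within_module_corr < 1.0:
            raise InvalidSpecError("within_module_corr must lie in [0, 1)")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be non-negative")
        if self.sampling_interval_s <= 0:
            raise InvalidSpecError("sampling_interval_s must be positive")

    @property
    def n_epochs(self) -> int:
        return int(np.ceil(self.n_timepoints / self.epoch_length))


@dataclass
class PlantedPartitionSequence:
    """Ground-truth module labels, one column per epoch.

    ``labels`` is ``n_regions x n_epochs`` with values in ``1..n_modules``;
    ``epoch_boundaries`` holds the start index of each epoch and covers
    ``[0, n_timepoints)``.
    """

    labels: np.ndarray
    epoch_boundaries: np.ndarray
    n_timepoints: int

    def epoch_of_time(self, t: int) -> int:
        """Index of the epoch containing time point ``t``."""
        return int(np.searchsorted(self.epoch_boundaries, t, side="right") - 1)

    def switch_counts(self) -> np.ndarray:
        """Per-region number of module changes across epoch boundaries."""
        return (self.labels[:, 1:] != self.labels[:, :-1]).sum(axis=1)


@dataclass
class SubjectTimeSeries:
    """One subject's time (rows) × regions (columns) signal matrix."""

    data: np.ndarray
    region_ids: list[str]
    network_labels: list[str]
    covariates: dict[str, float]

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ContractError("time series must be 2-D (time x regions)")
        if self.data.shape[1] != len(self.region_ids):
            raise ContractError("region_ids length does not match data columns")
        if len(self.network_labels) != len(self.region_ids):
            raise ContractError("network_labels length does not match regions")
        if not np.all(np.isfinite(self.data)):
            raise ContractError("time series contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class SubjectRecord:
    subject_id: str
    group: int  # 0-based group index
    timeseries: SubjectTimeSeries
    truth: PlantedPartitionSequence
    seed: int


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list[SubjectRecord] = field(default_factory=list)

    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    def covariates_frame(self) -> pd.DataFrame:
        rows = [
            {"subject": s.subject_id, "group": s.group, **s.timeseries.covariates}
            for s in self.subjects
        ]
        return pd.DataFrame(rows).set_index("subject")


def _initial_assignment(n_regions: int, n_modules: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Balanced random module assignment with every module non-empty."""
    base = np.array([(i % n_modules) + 1 for i in range(n_regions)])
    return rng.permutation(base)


def _draw_cohesive_count(n_movers: int, cohesive_fraction: float,
                         rng: np.random.Generator) -> int:
    """Number of movers (out of ``n_movers`` >= 2) that move as one group.

    Randomised rounding keeps the expected count at
    ``n_movers * cohesive_fraction`` while never producing a group of one
    (a lone mover cannot be coordinated, so a provisional count of 1 is
    split evenly between 0 and 2).
    """
    target = n_movers * cohesive_fraction
    count = int(np.floor(target))
    if rng.random() < target - count:
        count += 1
    if count == 1:
        count = 2 if rng.random() < 0.5 else 0
    return min(count, n_movers)


def _apply_switches(prev: np.ndarray, spec: CohortSpec, rate: float,
                    rng: np.random.Generator) -> np.ndarray:
    """One epoch-boundary update of the module labels."""
    modules = np.arange(1, spec.n_modules + 1)
    for _ in range(_MAX_REDRAWS):
        new = prev.copy()
        flagged = rng.random(prev.shape[0]) < rate
        for m in modules:
            movers = np.flatnonzero(flagged & (prev == m))
            if movers.size == 0:
                continue
            rng.shuffle(movers)
            n_coh = 0
            if movers.size >= 2:
                n_coh = _draw_cohesive_count(movers.size, spec.cohesive_fraction, rng)
            taken: list[int] = []
            others = modules[modules != m]
            if n_coh >= 2:
                dest = int(rng.choice(others))
                new[movers[:n_coh]] = dest
                taken.append(dest)
            for i in movers[n_coh:]:
                avail = [c for c in others if c not in taken]
                if not avail:  # destinations exhausted; accept a collision
                    avail = list(others)
                dest = int(rng.choice(avail))
                new[i] = dest
                taken.append(dest)
        if len(np.unique(new)) == spec.n_modules:
            return new
    raise InvalidSpecError(
        "could not keep every module occupied; lower the switch rate or "
        "increase n_regions relative to n_modules"
    )


def generate_partition_sequence(spec: CohortSpec, group_index: int,
                                rng_seed: int) -> PlantedPartitionSequence:
    """Planted module labels over epochs for one subject of ``group_index``."""
    if group_index not in (0, 1):
        raise InvalidSpecError("group_index must be 0 or 1")
    rng = np.random.default_rng(rng_seed)
    rate = spec.switch_rate_per_group[group_index]
    labels = np.empty((spec.n_regions, spec.n_epochs), dtype=np.int64)
    labels[:, 0] = _initial_assignment(spec.n_regions, spec.n_modules, rng)
    for e in range(1, spec.n_epochs):
        labels[:, e] = _apply_switches(labels[:, e - 1], spec, rate, rng)
    boundaries = np.arange(0, spec.n_timepoints, spec.epoch_length)
    return PlantedPartitionSequence(labels=labels, epoch_boundaries=boundaries,
                                    n_timepoints=spec.n_timepoints)


def simulate_timeseries(partitions: PlantedPartitionSequence, spec: CohortSpec,
                        rng_seed: int) -> SubjectTimeSeries:
    """Sample the region × time signals implied by a planted partition.

    Within an epoch, region i's signal is
    ``sqrt(r) * f_{m(i)} + sqrt(1 - r) * e_i`` with standard-normal module
    factor ``f`` and idiosyncratic term ``e`` — a one-factor model whose
    exact correlation matrix has ``r = within_module_corr`` inside modules
    and 0 elsewhere — plus independent measurement noise of sd ``noise_sd``.
    """
    if partitions.labels.shape != (spec.n_regions, spec.n_epochs):
        raise ContractError("partition sequence does not match the spec geometry")
    rng = np.random.default_rng(rng_seed)
    r = spec.within_module_corr
    T, N = spec.n_timepoints, spec.n_regions
    data = np.empty((T, N))
    starts = partitions.epoch_boundaries
    for e in range(spec.n_epochs):
        t0 = int(starts[e])
        t1 = int(starts[e + 1]) if e + 1 < len(starts) else T
        n_t = t1 - t0
        z = partitions.labels[:, e]
        factors = rng.standard_normal((n_t, spec.n_modules))
        idio = rng.standard_normal((n_t, N))
        data[t0:t1] = np.sqrt(r) * factors[:, z - 1] + np.sqrt(1.0 - r) * idio
    if spec.noise_sd > 0:
        data += spec.noise_sd * rng.standard_normal((T, N))
    covariates = {
        "age": float(rng.integers(17, 29)),
        "gender": float(rng.integers(0, 2)),
        "mean_fd": float(np.clip(rng.normal(0.13, 0.05), 0.03, 0.30)),
    }
    region_ids = [f"R{i + 1:03d}" for i in range(N)]
    return SubjectTimeSeries(data=data, region_ids=region_ids,
                             network_labels=make_network_labels(N),
                             covariates=covariates)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Deterministically generate the full two-group cohort."""
    root = np.random.default_rng(spec.seed)
    cohort = Cohort(spec=spec)
    for g, n_subj in enumerate(spec.n_subjects_per_group):
        for s in range(n_subj):
            sub_seed = int(root.integers(0, 2**31 - 1))
            truth = generate_partition_sequence(spec, g, sub_seed)
            ts = simulate_timeseries(truth, spec, sub_seed + 1)
            if g == 1 and spec.fd_group_gap != 0.0:
                ts.covariates["mean_fd"] = float(
                    np.clip(ts.covariates["mean_fd"] + spec.fd_group_gap, 0.01, 1.0)
                )
            cohort.subjects.append(
                SubjectRecord(subject_id=f"g{g + 1}s{s + 1:02d}", group=g,
                              timeseries=ts, truth=truth, seed=sub_seed)
            )
    return cohort


# ---------------------------------------------------------------------------
# on-disk format: one TSV per subject, truth files, JSON manifest


def write_subject_timeseries(ts: SubjectTimeSeries, path: Path) -> None:
    df = pd.DataFrame(ts.data, columns=ts.region_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_subject_timeseries(path: Path, network_labels: list[str] | None = None,
                            covariates: dict[str, float] | None = None
                            ) -> SubjectTimeSeries:
    df = pd.read_csv(path, sep="\t")
    ids = list(df.columns)
    return SubjectTimeSeries(
        data=df.to_numpy(dtype=float), region_ids=ids,
        network_labels=network_labels or make_network_labels(len(ids)),
        covariates=covariates or {},
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write per-subject series + truth files and a JSON manifest; return
    the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in cohort.subjects:
        ts_path = out / f"{rec.subject_id}_timeseries.tsv"
        truth_path = out / f"{rec.subject_id}_truth.tsv"
        write_subject_timeseries(rec.timeseries, ts_path)
        np.savetxt(truth_path, rec.truth.labels, fmt="%d", delimiter="\t")
        entries.append({
            "subject": rec.subject_id,
            "group": rec.group,
            "covariates": rec.timeseries.covariates,
            "seed": rec.seed,
            "timeseries": ts_path.name,
            "truth": truth_path.name,
        })
    manifest = {
        "spec": dataclasses.asdict(cohort.spec),
        "network_labels": cohort.subjects[0].timeseries.network_labels,
        "subjects": entries,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def load_cohort(manifest_path: str | Path) -> Cohort:
    """Load a cohort previously written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    spec_kwargs = manifest["spec"]
    for key in ("n_subjects_per_group", "switch_rate_per_group"):
        spec_kwargs[key] = tuple(spec_kwargs[key])
    spec = CohortSpec(**spec_kwargs)
    cohort = Cohort(spec=spec)
    nets = manifest["network_labels"]
    base = manifest_path.parent
    for entry in manifest["subjects"]:
        ts = read_subject_timeseries(base / entry["timeseries"],
                                     network_labels=nets,
                                     covariates=entry["covariates"])
        labels = np.loadtxt(base / entry["truth"], dtype=np.int64, delimiter="\t")
        labels = np.atleast_2d(labels)
        truth = PlantedPartitionSequence(
            labels=labels,
            epoch_boundaries=np.arange(0, spec.n_timepoints, spec.epoch_length),
            n_timepoints=spec.n_timepoints,
        )
        cohort.subjects.append(SubjectRecord(
            subject_id=entry["subject"], group=entry["group"],
            timeseries=ts, truth=truth, seed=entry["seed"],
        ))
    return cohort
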