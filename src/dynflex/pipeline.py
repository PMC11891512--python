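"""End-to-end orchestration: cohort → dFC → communities → metrics → stats.

A :class:`PipelineConfig` (built in code or loaded from YAML) fixes every
stage parameter and every seed, making a run bit-reproducible.  ``run_full``
executes the whole analysis and writes delimited-text tables plus a JSON
run report; ``run_sweep`` repeats it over several window settings with
shared seeds and reports the cross-setting concordance of subject-level
global metrics and the sign-consistency of the group t statistics.
"""
from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from . import __version__
from .cohort import Cohort, CohortSpec, SubjectTimeSeries, generate_cohort, \
    load_cohort, write_cohort
from .community import QualityParams, repeat_partitions
from .core_periphery import assign_core_periphery, assignment_table, \
    network_composition
from .dfc import WindowScheme, dynamic_connectivity
from .errors import ContractError, InvalidSpecError
from .metrics import average_over_repetitions, node_dynamics
from .stats import ComparisonSpec, compare_groups, metrics_long_table


@dataclass
class PipelineConfig:
    """Everything a full run needs, including all seeds."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    manifest: str | None = None  # load this cohort instead of simulating
    window: WindowScheme = field(default_factory=WindowScheme)
    quality: QualityParams = field(default_factory=QualityParams)
    edge_policy: str = "keep"
    fisher_z: bool = False
    n_reps: int = 100
    comparison: ComparisonSpec = field(default_factory=ComparisonSpec)
    core_fraction: float = 0.10
    include_nodal: bool = True
    out_dir: str = "dynflex_results"
    sweep_settings: list[tuple[int, int]] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "cohort" in raw:
            c = dict(raw["cohort"])
            for key in ("n_subjects_per_group", "switch_rate_per_group"):
                if key in c:
                    c[key] = tuple(c[key])
            kwargs["cohort"] = CohortSpec(**c)
        if "window" in raw:
            kwargs["window"] = WindowScheme(**raw["window"])
        if "quality" in raw:
            kwargs["quality"] = QualityParams(**raw["quality"])
        if "comparison" in raw:
            c = dict(raw["comparison"])
            if "covariates" in c:
                c["covariates"] = tuple(c["covariates"])
            kwargs["comparison"] = ComparisonSpec(**c)
        if "sweep_settings" in raw:
            kwargs["sweep_settings"] = [tuple(s) for s in raw["sweep_settings"]]
        for key in ("manifest", "edge_policy", "fisher_z", "n_reps",
                    "core_fraction", "include_nodal", "out_dir"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window"] = {"width": self.window.width, "step": self.window.step}
        return d


@dataclass
class RunResult:
    config: PipelineConfig
    metrics_long: pd.DataFrame          # tidy per-subject features
    node_tables: dict[str, pd.DataFrame]
    stats: pd.DataFrame
    core_periphery: dict[int, pd.DataFrame]   # composition per group
    out_dir: Path


def analyze_subject(ts: SubjectTimeSeries, window: WindowScheme,
                    quality: QualityParams, n_reps: int, base_seed: int,
                    edge_policy: str = "keep",
                    fisher_z: bool = False) -> pd.DataFrame:
    """Repetition-averaged nodal metric table for one subject."""
    stack = dynamic_connectivity(ts, window, fisher_z=fisher_z,
                                 edge_policy=edge_policy)
    parts = repeat_partitions(stack, quality, n_reps=n_reps, base_seed=base_seed)
    tables = [node_dynamics(p.S, ts.region_ids) for p in parts]
    return average_over_repetitions(tables)


def _obtain_cohort(config: PipelineConfig) -> Cohort:
    if config.manifest is not None:
        return load_cohort(config.manifest)
    return generate_cohort(config.cohort)


def run_full(config: PipelineConfig, write_outputs: bool = True) -> RunResult:
    """Execute every stage; all seeds derive from the config."""
    t_start = time.time()
    stages: dict[str, float] = {}
    out = Path(config.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)

    t0 = time.time()
    cohort = _obtain_cohort(config)
    if write_outputs and config.manifest is None:
        write_cohort(cohort, out / "cohort")
    stages["cohort"] = time.time() - t0

    nets = cohort.subjects[0].timeseries.network_labels
    t0 = time.time()
    node_tables: dict[str, pd.DataFrame] = {}
    groups: dict[str, int] = {}
    for rec in cohort.subjects:
        try:
            node_tables[rec.subject_id] = analyze_subject(
                rec.timeseries, config.window, config.quality,
                config.n_reps, base_seed=rec.seed,
                edge_policy=config.edge_policy, fisher_z=config.fisher_z)
        except Exception as exc:  # name the failing subject, then abort
            raise type(exc)(f"subject {rec.subject_id}: {exc}") from exc
        groups[rec.subject_id] = rec.group
    stages["communities_metrics"] = time.time() - t0

    long = metrics_long_table(node_tables, groups, nets,
                              include_nodal=config.include_nodal)

    t0 = time.time()
    stats = compare_groups(long, cohort.covariates_frame(), config.comparison)
    stages["stats"] = time.time() - t0

    # group-mean flexibility -> temporal core / periphery per group
    t0 = time.time()
    net_series = pd.Series(nets, index=node_tables[cohort.subjects[0].subject_id].index)
    compositions: dict[int, pd.DataFrame] = {}
    for g in sorted(set(groups.values())):
        members = [sid for sid, gg in groups.items() if gg == g]
        mean_flex = sum(node_tables[s]["flexibility"] for s in members) / len(members)
        assignment = assign_core_periphery(mean_flex, config.core_fraction)
        compositions[g] = network_composition(assignment, net_series)
        if write_outputs:
            assignment_table(assignment, net_series).to_csv(
                out / f"core_periphery_group{g + 1}.tsv", sep="\t", index=False)
            compositions[g].to_csv(out / f"composition_group{g + 1}.tsv",
                                   sep="\t", index=False)
    stages["core_periphery"] = time.time() - t0

    if write_outputs:
        long.to_csv(out / "metrics_long.tsv", sep="\t", index=False)
        stats.to_csv(out / "group_stats.tsv", sep="\t", index=False)
        stats.to_json(out / "group_stats.json", orient="records", indent=2)
        for sid, table in node_tables.items():
            table.to_csv(out / f"metrics_{sid}.tsv", sep="\t")
        report = {
            "dynflex_version": __version__,
            "config": config.to_dict(),
            "n_subjects": len(cohort.subjects),
            "stage_seconds": {k: round(v, 3) for k, v in stages.items()},
            "total_seconds": round(time.time() - t_start, 3),
        }
        (out / "run_report.json").write_text(json.dumps(report, indent=2))
    return RunResult(config=config, metrics_long=long, node_tables=node_tables,
                     stats=stats, core_periphery=compositions, out_dir=out)


def global_metric_by_subject(result: RunResult, metric: str) -> pd.Series:
    """Per-subject global value of one metric from a run result."""
    sel = result.metrics_long.query("level == 'global' and metric == @metric")
    return sel.set_index("subject")["value"]


def run_sweep(config: PipelineConfig) -> pd.DataFrame:
    """Repeat the full run across window settings with shared seeds.

    Returns a concordance table: Spearman rank correlation of per-subject
    global metrics between every pair of settings, plus the global group-t
    sign per setting and metric.  Raises when fewer than 2 settings are
    configured.
    """
    settings = config.sweep_settings
    if len(settings) < 2:
        raise InvalidSpecError("sweep needs at least 2 window settings")
    results: dict[tuple[int, int], RunResult] = {}
    for width, step in settings:
        cfg = dataclasses.replace(
            config, window=WindowScheme(width, step),
            out_dir=str(Path(config.out_dir) / f"w{width}_s{step}"),
            sweep_settings=[])
        results[(width, step)] = run_full(cfg)
    rows = []
    metrics = sorted(results[settings[0]].metrics_long["metric"].unique())
    for metric in metrics:
        series = {s: global_metric_by_subject(results[s], metric)
                  for s in settings}
        for i, a in enumerate(settings):
            for b in settings[i + 1:]:
                rho = scipy.stats.spearmanr(series[a], series[b]).statistic
                rows.append({"kind": "rank_correlation", "metric": metric,
                             "setting_a": f"{a[0]}x{a[1]}",
                             "setting_b": f"{b[0]}x{b[1]}", "value": float(rho)})
        for s in settings:
            stats = results[s].stats
            t = stats.query("level == 'global' and metric == @metric")["t"]
            rows.append({"kind": "global_t", "metric": metric,
                         "setting_a": f"{s[0]}x{s[1]}", "setting_b": "",
                         "value": float(t.iloc[0])})
    table = pd.DataFrame(rows)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "sweep_concordance.tsv", sep="\t", index=False)
    return table
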