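"""End-to-end pipeline: cohort -> thresholding -> metrics -> hubs -> stats.

Given a configuration (synthetic cohort spec or a participants table of
matrix files), the runner thresholds every network, computes the four global
topology metrics, builds the control hub reference, fits every participant's
hub index, averages control repeat scans, and runs the group statistics.
Every artefact is written to the output directory and registered in a run
manifest; the whole run is deterministic given the master seed.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .hubs import build_hub_reference, hub_index
from .io import (
    read_matrix,
    read_participants_table,
    write_matrix,
    write_participants_table,
)
from .metrics import global_metrics
from .network import ParameterError, WeightedNetwork
from .nulls import select_threshold, small_world_sweep
from .stats import control_aggregate, run_group_analysis
from .synthetic import CohortSpec, ParticipantRecord, generate_cohort
from .threshold import binarize, threshold_absolute, threshold_proportional

log = logging.getLogger("comanet")

#: Study defaults: absolute threshold 0.10, proportional density 0.08.
DEFAULT_THRESHOLDS = {"absolute": 0.10, "proportional": 0.08}


@dataclass
class PipelineConfig:
    outdir: str = "comanet-out"
    synthetic: CohortSpec | None = None
    participants_tsv: str | None = None
    threshold_mode: str = "absolute"
    threshold: float | str | None = None  # None -> study default; "auto" -> sweep
    design: str = "long"
    control_group: str = "Control"
    seed: int = 0
    sweep_iter_per_edge: int = 40
    sweep_n_null: int = 1
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.participants_tsv is None):
            raise ParameterError(
                "exactly one input source: synthetic spec or participants table"
            )
        if self.threshold_mode not in DEFAULT_THRESHOLDS:
            raise ParameterError(f"unknown threshold mode {self.threshold_mode!r}")
        if self.threshold is None:
            self.threshold = DEFAULT_THRESHOLDS[self.threshold_mode]

    def to_json(self, path) -> None:
        d = {k: v for k, v in self.__dict__.items()}
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        if d.get("synthetic") is not None:
            d["synthetic"] = CohortSpec.from_dict(d["synthetic"])
        return cls(**d)


@dataclass
class RunManifest:
    config: dict
    version: str
    started: str
    finished: str = ""
    outputs: dict = field(default_factory=dict)
    selected_threshold: float | None = None

    def register(self, name: str, path: Path) -> None:
        if not path.exists():
            raise RuntimeError(f"stage output {name} missing at {path}")
        self.outputs[name] = str(path)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


def _load_cohort(config: PipelineConfig) -> list[ParticipantRecord]:
    if config.synthetic is not None:
        return generate_cohort(config.synthetic)
    df = read_participants_table(config.participants_tsv)
    return [
        ParticipantRecord(
            str(r.participant_id), str(r.group), int(r.scan_index),
            read_matrix(r.path),
        )
        for r in df.itertuples()
    ]


def _threshold_one(net: WeightedNetwork, mode: str, value: float):
    if mode == "absolute":
        return binarize(threshold_absolute(net, value))
    return threshold_proportional(net, value)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=json.loads(json.dumps(config.__dict__, default=lambda o: o.to_dict()
                                     if hasattr(o, "to_dict") else str(o))),
        version=__version__,
        started=datetime.datetime.now().isoformat(timespec="seconds"),
    )

    log.info("stage: cohort")
    records = _load_cohort(config)
    if config.synthetic is not None:
        mat_dir = outdir / "matrices"
        mat_dir.mkdir(exist_ok=True)
        paths = []
        for r in records:
            p = mat_dir / f"{r.participant_id}_scan{r.scan_index}.tsv"
            write_matrix(r.network, p)
            paths.append(p)
        ptable = outdir / "participants.tsv"
        write_participants_table(records, paths, ptable)
        manifest.register("participants", ptable)

    controls = [r for r in records if r.group == config.control_group]
    if not controls:
        raise ParameterError(f"no {config.control_group!r} scans in cohort")

    mode = config.threshold_mode
    if config.threshold == "auto":
        log.info("stage: threshold sweep (mode=%s)", mode)
        sweep = small_world_sweep(
            [r.network for r in controls],
            mode=mode,
            iter_per_edge=config.sweep_iter_per_edge,
            n_null=config.sweep_n_null,
            seed=config.seed,
        )
        sweep_path = outdir / "sweep.tsv"
        sweep.to_tsv(sweep_path)
        manifest.register("sweep", sweep_path)
        tau, _ = select_threshold(sweep)
        log.info("selected threshold: %.2f", tau)
    else:
        tau = float(config.threshold)
    manifest.selected_threshold = tau

    log.info("stage: thresholding + metrics (tau=%.3g)", tau)
    variant = "binary" if mode == "absolute" else "weighted"
    thresholded = [(r, _threshold_one(r.network, mode, tau)) for r in records]
    metric_rows = []
    for r, net in thresholded:
        gm = global_metrics(net, variant)
        vals = {
            "clustering": gm.clustering,
            "efficiency": gm.efficiency,
            ("degree" if variant == "binary" else "strength"): (
                gm.degree if variant == "binary" else gm.strength
            ),
        }
        for metric, value in vals.items():
            metric_rows.append(
                {
                    "participant_id": r.participant_id,
                    "group": r.group,
                    "scan_index": r.scan_index,
                    "threshold": tau,
                    "metric": metric,
                    "value": value,
                }
            )

    log.info("stage: hub analysis")
    basis = "degree" if variant == "binary" else "strength"
    reference = build_hub_reference(
        [net for r, net in thresholded if r.group == config.control_group],
        basis=basis,
    )
    ref_path = outdir / "hub_reference.tsv"
    pd.DataFrame(
        {
            "node": reference.node_labels,
            "mean_value": reference.mean_values,
            "rank": reference.ranks,
        }
    ).to_csv(ref_path, sep="\t", index=False)
    manifest.register("hub_reference", ref_path)

    for r, net in thresholded:
        h = hub_index(net, reference)
        metric_rows.append(
            {
                "participant_id": r.participant_id,
                "group": r.group,
                "scan_index": r.scan_index,
                "threshold": tau,
                "metric": "hub_index",
                "value": h.slope,
            }
        )

    metrics = pd.DataFrame(metric_rows)
    metrics_path = outdir / "metrics.tsv"
    metrics.to_csv(metrics_path, sep="\t", index=False, float_format="%.10g")
    manifest.register("metrics", metrics_path)

    log.info("stage: group statistics (design=%s)", config.design)
    aggregated = control_aggregate(metrics)
    agg_path = outdir / "metrics_aggregated.tsv"
    aggregated.to_csv(agg_path, sep="\t", index=False, float_format="%.10g")
    manifest.register("metrics_aggregated", agg_path)

    results = run_group_analysis(aggregated, design=config.design)
    stats_path = outdir / "stats.tsv"
    results.to_csv(stats_path, sep="\t", index=False, float_format="%.6g")
    manifest.register("stats", stats_path)

    manifest.finished = datetime.datetime.now().isoformat(timespec="seconds")
    manifest_path = outdir / "manifest.json"
    manifest.write(manifest_path)
    log.info("pipeline complete: %s", manifest_path)
    return manifest
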