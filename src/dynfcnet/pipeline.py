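"""End-to-end pipeline driver.

Stages: (simulate | load) -> sliding-window FC (low/high order) -> subject
split -> t-test edge mask (training fold only) -> clustering-coefficient
features + normalized adjacencies -> GCN-LSTM training with validation
early stopping -> held-out evaluation -> optional network ablations.

Every artifact lands in a self-describing run directory: the resolved
configuration alone reproduces the run (all randomness derives from the
seed). The edge mask is fitted strictly on training subjects — test labels
never influence feature selection.
"""

from __future__ import annotations

import csv
import logging
import time
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np

from . import dynfc, edge_select, graph_features, io, metrics, model, simulate
from .config import RunConfig

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "build_fc", "cohort_from_config"]


@dataclass
class PipelineResult:
    report: metrics.MetricReport
    run_dir: Path
    model: model.TrainedModel
    mask: edge_select.EdgeMask
    ablations: dict = field(default_factory=dict)  # network -> (report, delta)
    split: dict = field(default_factory=dict)  # fold -> list of subject ids


def cohort_from_config(config: RunConfig) -> simulate.RoiTimeSeriesSet:
    if config.manifest is not None:
        return io.read_cohort(config.manifest)
    spec = simulate.SimSpec(seed=config.seed, **{
        k: (tuple(tuple(e) for e in v) if k == "effect_edges" else v)
        for k, v in config.simulate.items()
    })
    return simulate.make_cohort(spec)


def build_fc(
    cohort: simulate.RoiTimeSeriesSet, config: RunConfig
) -> list:
    """Per-subject DynamicFC at the configured order; validates window length."""
    spec = dynfc.WindowSpec(L=config.window_length, s=config.window_step)
    fcs = []
    for sub in cohort:
        series = sub.series
        if config.drop_volumes:
            series = dynfc.drop_initial_volumes(series, config.drop_volumes)
        if spec.L > series.shape[1]:
            raise ValueError(
                f"windowing failed for subject {sub.subject_id}: window length "
                f"L={spec.L} exceeds series length M={series.shape[1]}"
            )
        low = dynfc.build_low_order(series, spec, subject_id=sub.subject_id)
        if config.fc_order == "high":
            fcs.append(dynfc.build_high_order(low, centered=config.high_order_centered))
        else:
            fcs.append(low)
    return fcs


def _stage(name: str, t0: float, **counts) -> float:
    extras = " ".join(f"{k}={v}" for k, v in counts.items())
    t1 = time.perf_counter()
    logger.info("stage=%s elapsed=%.2fs %s", name, t1 - t0, extras)
    return t1


def run_pipeline(config: RunConfig, run_name: str | None = None) -> PipelineResult:
    """Execute the full pipeline; returns the held-out metric report.

    Deterministic given (config, seed): two runs produce identical reports.
    """
    run_dir = Path(config.output_dir) / (
        run_name or datetime.now().strftime("run-%Y%m%d-%H%M%S-%f")
    )
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    t0 = time.perf_counter()

    cohort = cohort_from_config(config)
    labels = cohort.labels()
    t0 = _stage("cohort", t0, subjects=len(cohort), regions=cohort.n_regions)

    fcs = build_fc(cohort, config)
    t0 = _stage("dynfc", t0, order=config.fc_order, K=fcs[0].n_windows)

    tr_idx, va_idx, te_idx = model.stratified_split(labels, config.split, config.seed)
    if len(va_idx) == 0 or len(te_idx) == 0:
        raise ValueError(
            f"degenerate split: {len(tr_idx)} train / {len(va_idx)} val / "
            f"{len(te_idx)} test subjects"
        )
    split_ids = {
        "train": [cohort.subjects[i].subject_id for i in tr_idx],
        "val": [cohort.subjects[i].subject_id for i in va_idx],
        "test": [cohort.subjects[i].subject_id for i in te_idx],
    }

    mask = edge_select.fit_mask(
        [fcs[i] for i in tr_idx],
        labels[tr_idx],
        config.p_threshold,
        welch=config.welch,
        per_window_stack=config.per_window_stack,
    )
    edge_select.save_mask(mask, run_dir / "edge_mask")
    t0 = _stage("edge_select", t0, kept=mask.n_kept, p=config.p_threshold)

    masked = [edge_select.apply_mask(fc, mask) for fc in fcs]
    seqs = [
        graph_features.build_graph_sequence(
            fc, negative_policy=config.negative_policy, eq3_literal=config.eq3_literal
        )
        for fc in masked
    ]
    t0 = _stage("graph_features", t0)

    model_cfg = config.model_config(cohort.n_regions, fcs[0].n_windows)
    trained = model.train(
        [seqs[i] for i in tr_idx],
        labels[tr_idx],
        config.train_config(),
        model_cfg,
        val_seqs=[seqs[i] for i in va_idx],
        val_labels=labels[va_idx],
    )
    model.save_checkpoint(trained, run_dir / "checkpoint")
    with open(run_dir / "history.csv", "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["epoch", "train_loss", "train_acc", "val_loss", "val_acc"]
        )
        writer.writeheader()
        writer.writerows(trained.history)
    t0 = _stage(
        "train", t0, epochs=len(trained.history), best_epoch=trained.best_epoch
    )

    report = metrics.evaluate_model(trained, [seqs[i] for i in te_idx], labels[te_idx])
    report.to_json(run_dir / "metrics.json")
    t0 = _stage("evaluate", t0, test_subjects=len(te_idx), acc=f"{report.ACC:.2f}")

    ablations: dict = {}
    if config.ablate and config.partition is not None:
        partition = metrics.load_partition(config.partition)
        test_fcs = [masked[i] for i in te_idx]
        rows = []
        for net in partition.labels:
            rep, delta = metrics.ablate_network(
                test_fcs,
                labels[te_idx],
                partition,
                net,
                trained,
                baseline=report,
                negative_policy=config.negative_policy,
                eq3_literal=config.eq3_literal,
            )
            ablations[net] = (rep, delta)
            rows.append({"network": net, "ACC": rep.ACC, "delta": delta})
        with open(run_dir / "ablation.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["network", "ACC", "delta"])
            writer.writeheader()
            writer.writerows(rows)
        t0 = _stage("ablate", t0, networks=len(ablations))

    with open(run_dir / "split.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "fold"])
        for fold, ids in split_ids.items():
            for sid in ids:
                writer.writerow([sid, fold])

    return PipelineResult(
        report=report,
        run_dir=run_dir,
        model=trained,
        mask=mask,
        ablations=ablations,
        split=split_ids,
    )
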