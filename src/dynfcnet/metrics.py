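"""Confusion-matrix metrics and resting-state-network ablation.

The six standard binary-classification indicators, with the patient group
(eMCI) as the positive class, all reported as percentages:

    TPR = TP/(TP+FN)        sensitivity / recall
    TNR = TN/(TN+FP)        specificity
    PPV = TP/(TP+FP)        precision
    NPV = TN/(TN+FN)
    ACC = (TP+TN)/N
    F1  = 2*TP/(2*TP+FN+FP)

The ablation asks which functional grouping of regions (default-mode,
executive-attention, visual, sensorimotor, subcortical, cerebellar — or any
user-supplied partition) the trained classifier relies on: all edges
incident to a group's regions are removed from the sparsified connectivity,
node features and normalized adjacencies are recomputed (the ablated
regions' features drop to zero since they lose every neighbour), and the
*already-trained* model is re-evaluated. The larger the accuracy drop, the
more discriminative the group.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dynfc import DynamicFC
from .graph_features import build_graph_sequence
from .model import TrainedModel, predict

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "NetworkPartition",
    "compute_metrics",
    "confusion_from_predictions",
    "ablate_fc",
    "ablate_network",
    "load_partition",
]

RSN_LABELS = ("DMN", "EAN", "VN", "SMN", "SR", "CER")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN with eMCI as the positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricReport:
    """The six indicators in percent; undefined ratios are NaN."""

    counts: ConfusionCounts
    TPR: float
    TNR: float
    PPV: float
    NPV: float
    ACC: float
    F1: float

    def to_dict(self) -> dict:
        return {
            "counts": {
                "TP": self.counts.TP,
                "TN": self.counts.TN,
                "FP": self.counts.FP,
                "FN": self.counts.FN,
            },
            **{
                m: (None if math.isnan(getattr(self, m)) else getattr(self, m))
                for m in ("TPR", "TNR", "PPV", "NPV", "ACC", "F1")
            },
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _pct(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """All six indicators from the confusion counts; never raises on a zero
    denominator — the affected metric is NaN ("undefined")."""
    if counts.total < 1:
        raise ValueError("need at least one test subject")
    return MetricReport(
        counts=counts,
        TPR=_pct(counts.TP, counts.TP + counts.FN),
        TNR=_pct(counts.TN, counts.TN + counts.FP),
        PPV=_pct(counts.TP, counts.TP + counts.FP),
        NPV=_pct(counts.TN, counts.TN + counts.FN),
        ACC=_pct(counts.TP + counts.TN, counts.total),
        F1=_pct(2 * counts.TP, 2 * counts.TP + counts.FN + counts.FP),
    )


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label/prediction length mismatch")
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


@dataclass
class NetworkPartition:
    """Region index (0-based) -> functional-network label, every region once.

    ``declared_labels`` may list networks beyond those appearing in the
    mapping; ablating such an empty network is a no-op rather than an error.
    """

    mapping: dict
    n_regions: int = 0
    declared_labels: tuple = ()

    def __post_init__(self) -> None:
        if self.n_regions == 0:
            self.n_regions = len(self.mapping)
        missing = set(range(self.n_regions)) - set(self.mapping)
        if missing:
            raise ValueError(f"regions without a network label: {sorted(missing)[:10]}")

    @property
    def labels(self) -> tuple:
        return tuple(sorted(set(self.mapping.values()) | set(self.declared_labels)))

    def regions_of(self, network_label: str) -> np.ndarray:
        if network_label not in self.labels:
            raise KeyError(
                f"unknown network {network_label!r}; have {self.labels}"
            )
        return np.array(
            sorted(r for r, lab in self.mapping.items() if lab == network_label),
            dtype=int,
        )


def load_partition(path, index_base: int = 1) -> NetworkPartition:
    """Two-column delimited table (region_index, network_label).

    Region indices are 1-based in the file by convention (AAL tables);
    pass index_base=0 for 0-based files.
    """
    table = pd.read_csv(path, sep=None, engine="python")
    idx_col, lab_col = table.columns[:2]
    mapping = {
        int(row[idx_col]) - index_base: str(row[lab_col]).strip()
        for _, row in table.iterrows()
    }
    return NetworkPartition(mapping=mapping)


def ablate_fc(fc: DynamicFC, regions: np.ndarray) -> DynamicFC:
    """Remove every edge incident to the given regions in all windows."""
    mats = fc.matrices.copy()
    diag = np.diagonal(mats, axis1=1, axis2=2).copy()
    mats[:, regions, :] = 0.0
    mats[:, :, regions] = 0.0
    # diagonal preserved: ablation removes connections, not the node itself
    idx = np.arange(fc.n_regions)
    mats[:, idx, idx] = diag
    return DynamicFC(subject_id=fc.subject_id, order=fc.order, matrices=mats)


def evaluate_model(model: TrainedModel, graph_seqs, labels) -> MetricReport:
    """Metric report of a trained model on a labelled set of graph sequences."""
    y_pred = predict(model, graph_seqs)
    return compute_metrics(confusion_from_predictions(labels, y_pred))


def ablate_network(
    masked_fcs,
    labels,
    partition: NetworkPartition,
    network_label: str,
    model: TrainedModel,
    *,
    baseline: MetricReport | None = None,
    negative_policy: str = "abs",
    eq3_literal: bool = False,
):
    """Re-evaluate the trained model with one functional network knocked out.

    masked_fcs are the test subjects' sparsified DynamicFC; node features and
    normalized adjacencies are recomputed after zeroing all edges incident to
    the network's regions, and no retraining happens. Returns
    (degraded MetricReport, accuracy delta vs baseline in percentage points).
    """
    regions = partition.regions_of(network_label)  # raises on unknown label
    if baseline is None:
        base_seqs = [
            build_graph_sequence(
                fc, negative_policy=negative_policy, eq3_literal=eq3_literal
            )
            for fc in masked_fcs
        ]
        baseline = evaluate_model(model, base_seqs, labels)
    ablated_seqs = [
        build_graph_sequence(
            ablate_fc(fc, regions),
            negative_policy=negative_policy,
            eq3_literal=eq3_literal,
        )
        for fc in masked_fcs
    ]
    report = evaluate_model(model, ablated_seqs, labels)
    delta = baseline.ACC - report.ACC
    return report, delta
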