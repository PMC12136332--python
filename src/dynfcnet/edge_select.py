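"""Edge sparsification by two-sample t-tests on connectivity values.

Whole-brain FC graphs are dense; most edges carry no group signal and only
slow down and destabilise the graph network. Each edge gets a two-sample
two-tailed t-test across training subjects (patient vs control), and only
edges with p below the threshold survive. The mask is **fitted on training
subjects only** and then frozen — fitting on all subjects would leak test
labels into the features.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dynfc import DynamicFC

logger = logging.getLogger(__name__)

__all__ = ["EdgeMask", "fit_mask", "apply_mask", "save_mask", "load_mask"]


@dataclass
class EdgeMask:
    """Symmetric retained-edge mask with its per-edge p-values.

    ``keep[i, j]`` is True iff ``p_values[i, j] < p_threshold``; the diagonal
    is never tested (self-loops are reinstated downstream by the A + I
    augmentation regardless).
    """

    keep: np.ndarray  # (R, R) bool, symmetric, False diagonal
    p_values: np.ndarray  # (R, R) in [0, 1], symmetric, 1.0 diagonal
    p_threshold: float
    fitted_on: list
    order: str = "low"
    options: dict = field(default_factory=dict)

    @property
    def n_regions(self) -> int:
        return self.keep.shape[0]

    @property
    def n_kept(self) -> int:
        """Number of retained undirected edges."""
        return int(np.triu(self.keep, 1).sum())


def _edge_samples(fcs: list, per_window_stack: bool) -> np.ndarray:
    """Per-subject edge statistics: (n_samples, R, R).

    Default: each subject contributes its FC averaged over the K windows —
    one independent sample per subject. ``per_window_stack`` instead stacks
    every window of every subject as a sample (samples then autocorrelated
    within subject; provided for sensitivity analysis only).
    """
    if per_window_stack:
        return np.concatenate([fc.matrices for fc in fcs], axis=0)
    return np.stack([fc.matrices.mean(axis=0) for fc in fcs])


def fit_mask(
    train_fc: list,
    labels,
    p_threshold: float = 0.05,
    *,
    welch: bool = False,
    per_window_stack: bool = False,
) -> EdgeMask:
    """Fit the retained-edge mask on training subjects.

    Parameters
    ----------
    train_fc : list of DynamicFC sharing R and order (training fold only).
    labels : binary array, 1 = patient group.
    p_threshold : two-tailed significance level; edges with p below it are kept.
    welch : use the unequal-variance t-test instead of pooled-variance Student.
    per_window_stack : test per-window values instead of per-subject means.
    """
    labels = np.asarray(labels)
    if len(train_fc) != len(labels):
        raise ValueError("labels and train_fc length mismatch")
    orders = {fc.order for fc in train_fc}
    regions = {fc.n_regions for fc in train_fc}
    if len(orders) > 1 or len(regions) > 1:
        raise ValueError("all DynamicFC must share order and region count")
    n_pos, n_neg = int((labels == 1).sum()), int((labels == 0).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError(
            f"need >=2 training subjects per label, got {n_neg} controls, "
            f"{n_pos} patients"
        )

    if per_window_stack:
        a = _edge_samples([fc for fc, l in zip(train_fc, labels) if l == 1], True)
        b = _edge_samples([fc for fc, l in zip(train_fc, labels) if l == 0], True)
    else:
        samples = _edge_samples(train_fc, False)
        a, b = samples[labels == 1], samples[labels == 0]

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant edges are handled below (p set to 1); silence scipy's
        # precision-loss warning for them
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(a, b, axis=0, equal_var=not welch)
    p = np.asarray(p)
    n_degenerate = int(np.isnan(np.triu(p, 1)).sum())
    if n_degenerate:
        logger.warning(
            "%d edges with zero pooled variance, p set to 1", n_degenerate
        )
    p = np.where(np.isnan(p), 1.0, p)
    p = (p + p.T) / 2.0
    np.fill_diagonal(p, 1.0)

    keep = p < p_threshold
    np.fill_diagonal(keep, False)
    mask = EdgeMask(
        keep=keep,
        p_values=p,
        p_threshold=float(p_threshold),
        fitted_on=[fc.subject_id for fc in train_fc],
        order=train_fc[0].order,
        options={"welch": welch, "per_window_stack": per_window_stack},
    )
    logger.info(
        "edge mask: %d/%d edges retained at p<%g",
        mask.n_kept,
        mask.n_regions * (mask.n_regions - 1) // 2,
        p_threshold,
    )
    return mask


def apply_mask(fc: DynamicFC, mask: EdgeMask) -> DynamicFC:
    """Zero masked-out edges in every window; diagonal untouched."""
    if fc.n_regions != mask.n_regions:
        raise ValueError(
            f"region count mismatch: FC has {fc.n_regions}, mask {mask.n_regions}"
        )
    keep = mask.keep | np.eye(mask.n_regions, dtype=bool)
    return DynamicFC(
        subject_id=fc.subject_id, order=fc.order, matrices=fc.matrices * keep
    )


def save_mask(mask: EdgeMask, prefix) -> None:
    """Persist as an upper-triangle edge list (CSV) plus a JSON sidecar."""
    prefix = Path(prefix)
    iu = np.triu_indices(mask.n_regions, k=1)
    pd.DataFrame(
        {
            "i": iu[0],
            "j": iu[1],
            "p_value": mask.p_values[iu],
            "keep": mask.keep[iu].astype(int),
        }
    ).to_csv(prefix.with_suffix(".csv"), index=False, float_format="%.17g")
    sidecar = {
        "n_regions": mask.n_regions,
        "p_threshold": mask.p_threshold,
        "fitted_on": list(mask.fitted_on),
        "order": mask.order,
        "options": mask.options,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_mask(prefix) -> EdgeMask:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    edges = pd.read_csv(prefix.with_suffix(".csv"), float_precision="round_trip")
    R = meta["n_regions"]
    p = np.ones((R, R))
    keep = np.zeros((R, R), dtype=bool)
    i, j = edges["i"].to_numpy(), edges["j"].to_numpy()
    p[i, j] = p[j, i] = edges["p_value"].to_numpy()
    keep[i, j] = keep[j, i] = edges["keep"].to_numpy().astype(bool)
    return EdgeMask(
        keep=keep,
        p_values=p,
        p_threshold=meta["p_threshold"],
        fitted_on=meta["fitted_on"],
        order=meta["order"],
        options=meta["options"],
    )
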