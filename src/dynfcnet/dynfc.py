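"""Dynamic functional connectivity from ROI time series.

Builds the two kinds of sliding-window connectivity network used by the
classifier:

* **low-order**: windowed Pearson correlation between pairs of regional BOLD
  series — the edge weight of the brain graph within each window;
* **high-order**: cosine similarity between whole connectivity profiles, i.e.
  between columns of the low-order matrix, capturing how similarly two regions
  connect to the rest of the brain within a window.

A series of M time points cut with window length ``L`` and step ``s`` yields
``K = floor((M - L) / s) + 1`` overlapping windows, so a 137-point series at
L=30, s=2 produces 54 connectivity snapshots per subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "DynamicFC",
    "n_windows",
    "slide_windows",
    "drop_initial_volumes",
    "low_order_fc",
    "build_low_order",
    "build_high_order",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window parameters: length ``L`` and step ``s``, in time points."""

    L: int = 30
    s: int = 2

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError(f"window length L must be >= 1, got {self.L}")
        if self.s < 1:
            raise ValueError(f"step size s must be >= 1, got {self.s}")


@dataclass
class DynamicFC:
    """A subject's sequence of K symmetric R x R connectivity matrices."""

    subject_id: str
    order: str  # "low" | "high"
    matrices: np.ndarray = field(repr=False)  # (K, R, R)

    def __post_init__(self) -> None:
        if self.order not in ("low", "high"):
            raise ValueError(f"order must be 'low' or 'high', got {self.order!r}")
        self.matrices = np.asarray(self.matrices, dtype=np.float64)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError(
                f"matrices must be (K, R, R), got shape {self.matrices.shape}"
            )

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_regions(self) -> int:
        return self.matrices.shape[1]


def n_windows(M: int, L: int, s: int) -> int:
    """Closed-form window count ``K = floor((M - L) / s) + 1``."""
    if L > M:
        raise ValueError(f"window length L={L} exceeds series length M={M}")
    return (M - L) // s + 1


def drop_initial_volumes(series: np.ndarray, n_discard: int = 3) -> np.ndarray:
    """Discard the first ``n_discard`` time points (magnetisation equilibrium).

    Scanners need a few repetitions before the longitudinal magnetisation
    settles; those volumes are conventionally dropped before any analysis.
    A 140-volume acquisition retains 137 usable time points.
    """
    series = np.asarray(series)
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= series.shape[-1]:
        raise ValueError(
            f"cannot discard {n_discard} of {series.shape[-1]} time points"
        )
    return series[..., n_discard:]


def slide_windows(series: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """Cut an (R, M) series into K overlapping (R, L) segments.

    Segment k covers time indices ``[k*s, k*s + L)`` (0-based, half-open);
    trailing points that do not fill a complete window are dropped.
    Returns a view-backed array of shape (K, R, L).
    """
    series = np.asarray(series)
    if series.ndim != 2:
        raise ValueError(f"series must be 2-D (regions x time), got {series.ndim}-D")
    M = series.shape[1]
    K = n_windows(M, spec.L, spec.s)  # raises if L > M
    starts = np.arange(K) * spec.s
    return np.stack([series[:, t : t + spec.L] for t in starts])


def low_order_fc(segment_i: np.ndarray, segment_j: np.ndarray) -> float:
    """Pearson correlation between two equal-length signal segments.

    Both segments are mean-centred within the window; a constant segment has
    zero variance, in which case the correlation is undefined and 0 is
    returned (degenerate-window fallback).
    """
    x = np.asarray(segment_i, dtype=np.float64).ravel()
    y = np.asarray(segment_j, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError(f"segment length mismatch: {x.shape[0]} vs {y.shape[0]}")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def _window_correlation(segment: np.ndarray) -> np.ndarray:
    """All-pairs Pearson correlation of an (R, L) segment, degenerate-safe."""
    R = segment.shape[0]
    centred = segment - segment.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    degenerate = norms == 0.0
    safe = np.where(degenerate, 1.0, norms)
    corr = (centred @ centred.T) / np.outer(safe, safe)
    if degenerate.any():
        corr[degenerate, :] = 0.0
        corr[:, degenerate] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return corr


def build_low_order(
    series: np.ndarray, spec: WindowSpec, subject_id: str = ""
) -> DynamicFC:
    """Windowed Pearson-correlation network sequence for one subject.

    Each of the K windows yields a symmetric R x R matrix with unit diagonal;
    regions with zero variance inside a window get correlation 0 to every
    other region (logged once per subject).
    """
    segments = slide_windows(series, spec)
    mats = np.stack([_window_correlation(seg) for seg in segments])
    n_flat = sum(
        int((seg.std(axis=1) == 0).sum()) for seg in segments
    )
    if n_flat:
        logger.warning(
            "subject %s: %d zero-variance region-windows, correlations set to 0",
            subject_id or "<unnamed>",
            n_flat,
        )
    return DynamicFC(subject_id=subject_id, order="low", matrices=mats)


def build_high_order(low: DynamicFC, centered: bool = False) -> DynamicFC:
    """Connectivity-profile similarity network from a low-order sequence.

    Entry (i, j) of window k is the cosine similarity between columns i and j
    of the low-order matrix — two regions are strongly connected in the
    high-order network when they connect to the rest of the brain in the same
    way. ``centered=True`` mean-centres each column first, turning the cosine
    into a Pearson correlation of profiles (sensitivity-analysis variant;
    the default matches the plain inner-product definition).

    Zero-norm columns (possible only after sparsification or centring) fall
    back to similarity 0, diagonal 1.
    """
    if low.order != "low":
        raise ValueError(f"input must be a low-order network, got {low.order!r}")
    out = np.empty_like(low.matrices)
    for k, G in enumerate(low.matrices):
        cols = G - G.mean(axis=0, keepdims=True) if centered else G
        norms = np.linalg.norm(cols, axis=0)
        degenerate = norms == 0.0
        safe = np.where(degenerate, 1.0, norms)
        sim = (cols.T @ cols) / np.outer(safe, safe)
        if degenerate.any():
            sim[degenerate, :] = 0.0
            sim[:, degenerate] = 0.0
        np.clip(sim, -1.0, 1.0, out=sim)
        np.fill_diagonal(sim, 1.0)
        out[k] = sim
    return DynamicFC(subject_id=low.subject_id, order="high", matrices=out)
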