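"""Synthetic two-group BOLD-like cohort generator.

Emulates what the downstream pipeline actually consumes: per-subject
region x time matrices whose *windowed correlation structure* differs between
two groups (controls ``NC`` vs patients ``eMCI``) on a designated set of
edges. Time points are drawn from a small set of latent covariance states
visited by a sticky Markov chain, so windowed connectivity fluctuates over
the scan the way resting-state dynamics do; the group effect is a shift of
the correlation on the planted edges, present in every state.

No haemodynamics, drift or motion — this is a statistical stand-in for a
preprocessed ROI-level dataset, not an fMRI forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SimSpec", "Subject", "RoiTimeSeriesSet", "simulate_subject", "make_cohort"]

LABELS = ("NC", "eMCI")

_EIG_FLOOR = 1e-6


@dataclass(frozen=True)
class SimSpec:
    """Parameters of a synthetic cohort.

    effect_size is the correlation shift applied on each planted edge for the
    patient group, in [0, 1); it must stay below 1 so the shifted matrices
    remain positive definite after projection. noise_sd is the standard
    deviation of independent observation noise added on top of the unit-
    variance latent signal.
    """

    n_regions: int = 116
    n_timepoints: int = 137
    n_per_group: int = 40
    effect_edges: tuple = ()
    effect_size: float = 0.0
    n_states: int = 3
    switch_prob: float = 0.05
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 time points")
        if self.n_per_group < 1:
            raise ValueError("need at least 1 subject per group")
        if not (0.0 <= self.effect_size < 1.0):
            raise ValueError(f"effect_size must be in [0, 1), got {self.effect_size}")
        if not (0.0 <= self.switch_prob <= 1.0):
            raise ValueError("switch_prob must be in [0, 1]")
        if self.n_states < 1:
            raise ValueError("need at least 1 latent state")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        edges = tuple(tuple(sorted(e)) for e in self.effect_edges)
        for i, j in edges:
            if i == j:
                raise ValueError(f"effect edge ({i},{j}) joins a region to itself")
            if not (0 <= i < self.n_regions and 0 <= j < self.n_regions):
                raise ValueError(f"effect edge ({i},{j}) out of range")
        object.__setattr__(self, "effect_edges", edges)


@dataclass
class Subject:
    subject_id: str
    label: str
    series: np.ndarray = field(repr=False)  # (R, M)


@dataclass
class RoiTimeSeriesSet:
    """A cohort of region x time matrices with binary labels."""

    subjects: list  # list[Subject]

    def __post_init__(self) -> None:
        regions = {s.series.shape[0] for s in self.subjects}
        if len(regions) > 1:
            raise ValueError(f"subjects disagree on region count: {sorted(regions)}")
        bad = {s.label for s in self.subjects} - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    @property
    def n_regions(self) -> int:
        return self.subjects[0].series.shape[0]

    def labels(self) -> np.ndarray:
        """Binary labels, 1 = eMCI (positive class)."""
        return np.array([1 if s.label == "eMCI" else 0 for s in self.subjects])

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)


def nearest_positive_definite(mat: np.ndarray, floor: float = _EIG_FLOOR) -> np.ndarray:
    """Project a symmetric matrix to positive definiteness by eigenvalue clipping.

    Eigenvalues below ``floor`` are raised to it; the result is rescaled back
    to a correlation matrix (unit diagonal). Deterministic.
    """
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    clipped = (vecs * np.maximum(vals, floor)) @ vecs.T
    d = np.sqrt(np.diag(clipped))
    corr = clipped / np.outer(d, d)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    if np.linalg.eigvalsh(corr).min() <= 0:
        raise np.linalg.LinAlgError(
            "state covariance not positive definite after projection"
        )
    return corr


def _base_state_correlations(spec: SimSpec) -> list:
    """One base correlation matrix per latent state, shared by both groups.

    Each state's matrix comes from a random sparse positive-weight graph,
    symmetrised and diagonally loaded — this plants genuine triangles so that
    clustering-coefficient node features carry structure.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5747]))
    R = spec.n_regions
    states = []
    for _ in range(spec.n_states):
        density = rng.uniform(0.08, 0.15)
        raw = rng.uniform(0.3, 0.7, size=(R, R)) * (rng.random((R, R)) < density)
        sym = np.triu(raw, 1)
        sym = sym + sym.T
        # diagonal loading: strictly dominant diagonal, then rescale to correlation
        cov = sym + np.eye(R) * (sym.sum(axis=1).max() + 1.0)
        d = np.sqrt(np.diag(cov))
        corr = cov / np.outer(d, d)
        np.fill_diagonal(corr, 1.0)
        states.append(corr)
    return states


def _group_state_correlations(spec: SimSpec, group: str) -> list:
    """State correlation matrices for one group, effect applied for eMCI."""
    if group not in LABELS:
        raise ValueError(f"group must be one of {LABELS}, got {group!r}")
    states = _base_state_correlations(spec)
    if group == "NC" or spec.effect_size == 0.0 or not spec.effect_edges:
        return states
    shifted = []
    for corr in states:
        mod = corr.copy()
        for i, j in spec.effect_edges:
            base = mod[i, j]
            # shift away from the PD boundary: up unless that would exceed it
            delta = spec.effect_size if base + spec.effect_size <= 0.95 else -spec.effect_size
            mod[i, j] = mod[j, i] = np.clip(base + delta, -0.95, 0.95)
        shifted.append(nearest_positive_definite(mod))
    return shifted


def simulate_subject(spec: SimSpec, group: str, subject_seed: int) -> np.ndarray:
    """Draw one subject's (n_regions, n_timepoints) matrix.

    A sticky Markov chain picks a latent state per time point
    (stay probability ``1 - switch_prob``, otherwise jump uniformly to
    another state); each sample is zero-mean multivariate normal with the
    state's correlation matrix, plus independent N(0, noise_sd^2) noise.
    Deterministic given (spec, group, subject_seed).
    """
    corrs = _group_state_correlations(spec, group)
    chols = [np.linalg.cholesky(c) for c in corrs]
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, subject_seed]))
    M, R, S = spec.n_timepoints, spec.n_regions, spec.n_states
    # latent state path
    states = np.empty(M, dtype=np.intp)
    states[0] = rng.integers(S)
    for t in range(1, M):
        if S > 1 and rng.random() < spec.switch_prob:
            states[t] = (states[t - 1] + 1 + rng.integers(S - 1)) % S
        else:
            states[t] = states[t - 1]
    z = rng.standard_normal((M, R))
    x = np.empty((M, R))
    for s_idx in range(S):
        at = states == s_idx
        if at.any():
            x[at] = z[at] @ chols[s_idx].T
    if spec.noise_sd > 0:
        x += spec.noise_sd * rng.standard_normal((M, R))
    return np.ascontiguousarray(x.T)


def make_cohort(spec: SimSpec) -> RoiTimeSeriesSet:
    """Simulate the full two-group cohort: n_per_group subjects per label.

    Subject seeds are derived deterministically from spec.seed, so the cohort
    is a pure function of the spec.
    """
    subjects = []
    idx = 0
    for label in LABELS:
        for g in range(spec.n_per_group):
            sid = f"sub-{label.lower()}{g:03d}"
            series = simulate_subject(spec, label, subject_seed=idx + 1)
            subjects.append(Subject(subject_id=sid, label=label, series=series))
            idx += 1
    return RoiTimeSeriesSet(subjects=subjects)
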