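"""Node features and normalized adjacencies for the per-window graphs.

Each window's sparsified FC matrix plays two roles in the classifier:

* its weighted **local clustering coefficient** per region is the node
  feature — the geometric-mean triangle intensity around node i,

      n_i = 2 / (k_i (k_i - 1)) * sum_{j<h in N(i), A_jh != 0}
            (w_ij w_ih w_jh)^(1/3),

  with weights normalized to [0, 1] by the window's maximum |weight|, so the
  coefficient reduces to the binary clustering coefficient when all retained
  weights are equal;
* its absolute value, self-loop augmented and symmetrically normalized
  (D^{-1/2} (A + I) D^{-1/2}), is the propagation operator of the graph
  convolution.

Negative correlations are handled by taking absolute values before both
computations: fractional powers and D^{-1/2} are undefined for negative
weights, and |FC| preserves connection strength, which is what both formulas
consume (``clip_zero`` discards negative edges instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynfc import DynamicFC

__all__ = [
    "GraphSequence",
    "local_clustering",
    "clustering_coefficients",
    "node_feature_sequence",
    "normalize_adjacency",
    "build_graph_sequence",
]


@dataclass
class GraphSequence:
    """Per-subject inputs to the sequence classifier.

    node_features: (K, R) clustering coefficients per window and region.
    norm_adj: (K, R, R) symmetric normalized weighted adjacencies.
    """

    subject_id: str
    node_features: np.ndarray = field(repr=False)
    norm_adj: np.ndarray = field(repr=False)

    @property
    def n_windows(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_regions(self) -> int:
        return self.node_features.shape[1]


def _apply_negative_policy(adj: np.ndarray, negative_policy: str) -> np.ndarray:
    if negative_policy == "abs":
        return np.abs(adj)
    if negative_policy == "clip_zero":
        return np.maximum(adj, 0.0)
    raise ValueError(f"negative_policy must be 'abs' or 'clip_zero', got {negative_policy!r}")


def _normalized_weights(adj: np.ndarray, negative_policy: str) -> np.ndarray:
    """Nonnegative off-diagonal weights scaled into [0, 1] by the matrix max."""
    w = _apply_negative_policy(np.asarray(adj, dtype=np.float64), negative_policy)
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    wmax = w.max()
    if wmax > 0:
        w = w / wmax
    return w


def clustering_coefficients(
    adj: np.ndarray,
    *,
    negative_policy: str = "abs",
    eq3_literal: bool = False,
) -> np.ndarray:
    """Weighted local clustering coefficient of every node at once.

    ``adj`` is a symmetric weighted matrix; the diagonal is ignored and
    weights are max-normalized internally. Nodes with fewer than two
    neighbours get 0. Vectorized via the cube-root-matrix identity: the
    triangle intensity around i is the i-th diagonal entry of W^{1/3} cubed.

    ``eq3_literal`` computes the single-neighbour sum variant
    2 * sum_j w_ij^{1/3} / (k_i (k_i - 1)) instead (comparison mode; not a
    clustering coefficient and not bounded by 1).
    """
    adj = np.asarray(adj, dtype=np.float64)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError(f"adjacency must be square, got {adj.shape}")
    if not np.allclose(adj, adj.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    w = _normalized_weights(adj, negative_policy)
    degree = (w > 0).sum(axis=1)
    denom = degree * (degree - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        if eq3_literal:
            num = 2.0 * np.cbrt(w).sum(axis=1)
        else:
            w3 = np.cbrt(w)
            num = np.einsum("ij,jk,ki->i", w3, w3, w3)  # = 2 * sum over j<h
        coeff = np.where(denom > 0, num / np.where(denom > 0, denom, 1), 0.0)
    return coeff


def local_clustering(
    adj: np.ndarray,
    i: int,
    *,
    negative_policy: str = "abs",
    eq3_literal: bool = False,
) -> float:
    """Clustering coefficient of a single node (see clustering_coefficients)."""
    coeffs = clustering_coefficients(
        adj, negative_policy=negative_policy, eq3_literal=eq3_literal
    )
    return float(coeffs[i])


def node_feature_sequence(
    fc: DynamicFC,
    *,
    negative_policy: str = "abs",
    eq3_literal: bool = False,
) -> np.ndarray:
    """(K, R) clustering-coefficient features, one row per window.

    Expects an already-sparsified FC; weights are |FC(k)| off-diagonal,
    max-normalized per window.
    """
    return np.stack(
        [
            clustering_coefficients(
                m, negative_policy=negative_policy, eq3_literal=eq3_literal
            )
            for m in fc.matrices
        ]
    )


def normalize_adjacency(
    fc_window: np.ndarray, *, negative_policy: str = "abs"
) -> np.ndarray:
    """Symmetric normalization D^{-1/2} (A + I) D^{-1/2} of one window.

    A is the masked FC with the negative-weight policy applied and zero
    diagonal; self-loops are then added (A + I) and rows/columns scaled by
    the inverse square-root degree. For nonnegative A every degree is >= 1
    (the self-loop), so the scaling is always defined, and all eigenvalues
    of the result lie in [-1, 1].
    """
    fc_window = np.asarray(fc_window, dtype=np.float64)
    if fc_window.ndim != 2 or fc_window.shape[0] != fc_window.shape[1]:
        raise ValueError(f"window must be square, got {fc_window.shape}")
    a = _apply_negative_policy(fc_window, negative_policy).copy()
    np.fill_diagonal(a, 0.0)
    a_tilde = a + np.eye(a.shape[0])
    deg = a_tilde.sum(axis=1)
    if (deg <= 0).any():
        raise AssertionError("non-positive degree after self-loop augmentation")
    inv_sqrt = 1.0 / np.sqrt(deg)
    return a_tilde * np.outer(inv_sqrt, inv_sqrt)


def build_graph_sequence(
    fc: DynamicFC,
    *,
    negative_policy: str = "abs",
    eq3_literal: bool = False,
) -> GraphSequence:
    """Bundle node features and normalized adjacencies for one subject."""
    feats = node_feature_sequence(
        fc, negative_policy=negative_policy, eq3_literal=eq3_literal
    )
    adjs = np.stack(
        [normalize_adjacency(m, negative_policy=negative_policy) for m in fc.matrices]
    )
    return GraphSequence(subject_id=fc.subject_id, node_features=feats, norm_adj=adjs)
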