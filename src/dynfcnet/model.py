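"""Dynamically weighted GCN + LSTM sequence classifier.

Per window k the graph convolution propagates clustering-coefficient node
features through that window's normalized weighted adjacency S(k):

    H^{l+1}(k) = ReLU( S(k) H^l(k) W^l ),

with input and output width 1 so each window reduces to an R-vector. The
K-vector sequence then feeds a stacked LSTM whose final hidden state goes
through a fully connected softmax head scoring {control, patient}.

The whole network, its gradients and the Adam training loop are implemented
directly on NumPy arrays. Training uses cross-entropy with an L2 penalty and
dropout, mini-batches, and early stopping on validation loss; every source of
randomness (initialization, batch order, dropout, splits) derives from the
supplied seeds, so runs are reproducible bit-for-bit on one machine.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainedModel",
    "init_params",
    "gcn_layer_forward",
    "lstm_cell_forward",
    "forward",
    "loss_and_grads",
    "train",
    "predict",
    "stratified_split",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    gcn_widths are the per-layer feature dimensions including input and
    output; (1, 16, 1) means two graph-convolution layers. The scalar
    clustering coefficient enters at width 1 and leaves at width 1 so the
    per-window output is again one value per region.
    """

    n_regions: int = 116
    gcn_widths: tuple = (1, 16, 1)
    lstm_hidden: int = 64
    lstm_layers: int = 3
    n_classes: int = 2
    share_gcn_weights: bool = True
    n_windows: int = 0  # required only when share_gcn_weights=False

    def __post_init__(self) -> None:
        if self.gcn_widths[0] != 1 or self.gcn_widths[-1] != 1:
            raise ValueError("GCN input and output width must be 1")
        if not self.share_gcn_weights and self.n_windows < 1:
            raise ValueError("per-window GCN weights need n_windows >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    Defaults: Adam at learning rate 1e-3, batches of 64, up to 400 epochs
    with early stopping on validation loss, L2 penalty 5e-4, dropout 0.5,
    stratified 70/15/15 subject split.
    """

    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 400
    l2_weight: float = 5e-4
    dropout_rate: float = 0.5
    patience: int = 40
    seed: int = 0
    split: tuple = (0.7, 0.15, 0.15)

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.epochs, self.patience) <= 0:
            raise ValueError("learning_rate, batch_size, epochs, patience must be positive")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.l2_weight < 0:
            raise ValueError("l2_weight must be non-negative")
        if len(self.split) != 3 or abs(sum(self.split) - 1.0) > 1e-9 or min(self.split) < 0:
            raise ValueError("split must be three non-negative fractions summing to 1")


@dataclass
class TrainedModel:
    params: dict
    model_config: ModelConfig
    train_config: TrainConfig
    history: list = field(default_factory=list)
    best_epoch: int = -1


# ---------------------------------------------------------------------------
# parameters


def _glorot(rng: np.random.Generator, shape, dtype) -> np.ndarray:
    fan_in, fan_out = shape[-2], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def init_params(cfg: ModelConfig, seed: int, dtype=np.float32) -> dict:
    """Glorot-uniform weights; LSTM forget-gate bias starts at 1.

    GCN weights start nonnegative (|Glorot|): node features and normalized
    adjacencies are nonnegative, so under ReLU any channel with a negative
    weight is identically zero at initialization and its gradient is zero —
    it could never recover. Nonnegative starts keep every channel alive;
    training is free to drive weights negative afterwards.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1D17]))
    params: dict = {}
    for l in range(len(cfg.gcn_widths) - 1):
        shape = (cfg.gcn_widths[l], cfg.gcn_widths[l + 1])
        if not cfg.share_gcn_weights:
            shape = (cfg.n_windows,) + shape
        params[f"gcn.{l}.W"] = np.abs(_glorot(rng, shape, dtype))
    d_in = cfg.n_regions
    H = cfg.lstm_hidden
    for l in range(cfg.lstm_layers):
        params[f"lstm.{l}.Wx"] = _glorot(rng, (d_in, 4 * H), dtype)
        params[f"lstm.{l}.Wh"] = _glorot(rng, (H, 4 * H), dtype)
        b = np.zeros(4 * H, dtype=dtype)
        b[:H] = 1.0  # forget gate open at start
        params[f"lstm.{l}.b"] = b
        d_in = H
    params["head.W"] = _glorot(rng, (H, cfg.n_classes), dtype)
    params["head.b"] = np.zeros(cfg.n_classes, dtype=dtype)
    return params


def _is_weight(key: str) -> bool:
    return not key.endswith(".b")


# ---------------------------------------------------------------------------
# primitive forward ops (also used standalone by tests)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def gcn_layer_forward(H: np.ndarray, norm_adj: np.ndarray, W: np.ndarray) -> np.ndarray:
    """One graph-convolution layer: ReLU(norm_adj @ H @ W)."""
    H = np.asarray(H)
    norm_adj = np.asarray(norm_adj)
    W = np.asarray(W)
    if norm_adj.shape[-1] != H.shape[-2] or H.shape[-1] != W.shape[-2]:
        raise ValueError(
            f"shape mismatch: adj {norm_adj.shape}, H {H.shape}, W {W.shape}"
        )
    return np.maximum(norm_adj @ H @ W, 0.0)


def lstm_cell_forward(h_prev, C_prev, x, Wx, Wh, b):
    """One LSTM step; gate layout along the last axis is [f, i, g, o].

        f = sigmoid(Wf [h_prev, x] + bf)   (forget)
        i = sigmoid(Wi [h_prev, x] + bi)   (input)
        g = tanh  (WC [h_prev, x] + bC)    (candidate cell)
        C = f * C_prev + i * g
        o = sigmoid(Wo [h_prev, x] + bo)   (output)
        h = o * tanh(C)

    Returns (h, C).
    """
    h_prev = np.asarray(h_prev)
    x = np.asarray(x)
    H = h_prev.shape[-1]
    if Wx.shape[0] != x.shape[-1] or Wh.shape[0] != H or Wx.shape[1] != 4 * H:
        raise ValueError(
            f"dimension mismatch: x {x.shape}, h {h_prev.shape}, "
            f"Wx {Wx.shape}, Wh {Wh.shape}"
        )
    z = x @ Wx + h_prev @ Wh + b
    f = _sigmoid(z[..., :H])
    i = _sigmoid(z[..., H : 2 * H])
    g = np.tanh(z[..., 2 * H : 3 * H])
    o = _sigmoid(z[..., 3 * H :])
    C = f * C_prev + i * g
    h = o * np.tanh(C)
    return h, C


# ---------------------------------------------------------------------------
# full forward / backward


def _gcn_forward(params, cfg, adj, feats):
    """adj (B,K,R,R), feats (B,K,R) -> seq (B,K,R), cache."""
    Hcur = feats[..., None]
    layers = []
    n_layers = len(cfg.gcn_widths) - 1
    for l in range(n_layers):
        W = params[f"gcn.{l}.W"]
        P = adj @ Hcur  # (B,K,R,d_in)
        if cfg.share_gcn_weights:
            Z = P @ W
        else:
            Z = np.einsum("bkri,kio->bkro", P, W)
        Hn = np.maximum(Z, 0.0)
        layers.append((Hcur, P, Z))
        Hcur = Hn
    return Hcur[..., 0], layers


def _gcn_backward(params, cfg, adj, dseq, layers):
    grads = {}
    dH = dseq[..., None]
    for l in reversed(range(len(layers))):
        Hprev, P, Z = layers[l]
        W = params[f"gcn.{l}.W"]
        dZ = dH * (Z > 0)
        if cfg.share_gcn_weights:
            grads[f"gcn.{l}.W"] = np.einsum("bkri,bkro->io", P, dZ)
            dP = dZ @ W.T
        else:
            grads[f"gcn.{l}.W"] = np.einsum("bkri,bkro->kio", P, dZ)
            dP = np.einsum("bkro,kio->bkri", dZ, W)
        dH = np.swapaxes(adj, -1, -2) @ dP
    return grads, dH[..., 0]


def _lstm_layer_forward(x_seq, Wx, Wh, b):
    """x_seq (B,K,D) -> h_seq (B,K,H), cache of per-step gate values."""
    B, K, _ = x_seq.shape
    H = Wh.shape[0]
    h = np.zeros((B, H), dtype=x_seq.dtype)
    c = np.zeros((B, H), dtype=x_seq.dtype)
    h_seq = np.empty((B, K, H), dtype=x_seq.dtype)
    steps = []
    for k in range(K):
        x = x_seq[:, k]
        z = x @ Wx + h @ Wh + b
        f = _sigmoid(z[:, :H])
        i = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        steps.append((x, h, c, f, i, g, o, tanh_c))
        h, c = h_new, c_new
        h_seq[:, k] = h
    return h_seq, steps


def _lstm_layer_backward(dh_seq, Wx, Wh, steps):
    B, K, H = dh_seq.shape
    D = Wx.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H, dtype=Wx.dtype)
    dx_seq = np.empty((B, K, D), dtype=Wx.dtype)
    dh_next = np.zeros((B, H), dtype=Wx.dtype)
    dc_next = np.zeros((B, H), dtype=Wx.dtype)
    for k in reversed(range(K)):
        x, h_prev, c_prev, f, i, g, o, tanh_c = steps[k]
        dh = dh_seq[:, k] + dh_next
        do = dh * tanh_c
        dc = dc_next + dh * o * (1.0 - tanh_c**2)
        df = dc * c_prev
        di = dc * g
        dg = dc * i
        dc_next = dc * f
        dz = np.concatenate(
            [
                df * f * (1.0 - f),
                di * i * (1.0 - i),
                dg * (1.0 - g**2),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dWx += x.T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dx_seq[:, k] = dz @ Wx.T
        dh_next = dz @ Wh.T
    return dx_seq, dWx, dWh, db


def forward(
    params: dict,
    cfg: ModelConfig,
    adj: np.ndarray,
    feats: np.ndarray,
    *,
    dropout_rate: float = 0.0,
    dropout_rng: np.random.Generator | None = None,
    return_cache: bool = False,
):
    """Class scores for a batch of graph sequences.

    adj: (B, K, R, R) normalized adjacencies; feats: (B, K, R) node features.
    Dropout (inverted scaling) is applied between LSTM layers and before the
    head only when both dropout_rate > 0 and a generator is supplied —
    inference is deterministic otherwise.
    """
    adj = np.asarray(adj)
    feats = np.asarray(feats)
    if adj.ndim != 4 or feats.ndim != 3:
        raise ValueError("adj must be (B,K,R,R) and feats (B,K,R)")
    if adj.shape[1] == 0:
        raise ValueError("empty window sequence")
    train_mode = dropout_rate > 0.0 and dropout_rng is not None
    keep = 1.0 - dropout_rate

    seq, gcn_cache = _gcn_forward(params, cfg, adj, feats)
    x = seq
    lstm_cache = []
    drop_masks = []
    for l in range(cfg.lstm_layers):
        h_seq, steps = _lstm_layer_forward(
            x, params[f"lstm.{l}.Wx"], params[f"lstm.{l}.Wh"], params[f"lstm.{l}.b"]
        )
        lstm_cache.append(steps)
        if train_mode and l < cfg.lstm_layers - 1:
            mask = (dropout_rng.random(h_seq.shape) < keep).astype(h_seq.dtype) / keep
            h_seq = h_seq * mask
            drop_masks.append(mask)
        else:
            drop_masks.append(None)
        x = h_seq
    h_last = x[:, -1, :]
    if train_mode:
        head_mask = (dropout_rng.random(h_last.shape) < keep).astype(h_last.dtype) / keep
        h_last = h_last * head_mask
    else:
        head_mask = None
    logits = h_last @ params["head.W"] + params["head.b"]
    if not return_cache:
        return logits
    cache = {
        "adj": adj,
        "gcn": gcn_cache,
        "lstm": lstm_cache,
        "drop_masks": drop_masks,
        "head_mask": head_mask,
        "h_last": h_last,
    }
    return logits, cache


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def loss_and_grads(
    params: dict,
    cfg: ModelConfig,
    adj: np.ndarray,
    feats: np.ndarray,
    y: np.ndarray,
    *,
    l2_weight: float = 0.0,
    dropout_rate: float = 0.0,
    dropout_rng: np.random.Generator | None = None,
):
    """Mean cross-entropy + L2 penalty and its gradient wrt every parameter."""
    y = np.asarray(y)
    B = adj.shape[0]
    logits, cache = forward(
        params,
        cfg,
        adj,
        feats,
        dropout_rate=dropout_rate,
        dropout_rng=dropout_rng,
        return_cache=True,
    )
    probs = _softmax(logits.astype(np.float64))
    loss = float(-np.log(np.maximum(probs[np.arange(B), y], 1e-300)).mean())
    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits = (dlogits / B).astype(adj.dtype)

    grads: dict = {}
    grads["head.W"] = cache["h_last"].T @ dlogits
    grads["head.b"] = dlogits.sum(axis=0)
    dh_last = dlogits @ params["head.W"].T
    if cache["head_mask"] is not None:
        dh_last = dh_last * cache["head_mask"]

    # gradient wrt the top LSTM layer's output sequence: only the final step
    B_, K = adj.shape[0], adj.shape[1]
    dh_seq = np.zeros((B_, K, cfg.lstm_hidden), dtype=adj.dtype)
    dh_seq[:, -1] = dh_last
    for l in reversed(range(cfg.lstm_layers)):
        if cache["drop_masks"][l] is not None:
            dh_seq = dh_seq * cache["drop_masks"][l]
        dx_seq, dWx, dWh, db = _lstm_layer_backward(
            dh_seq, params[f"lstm.{l}.Wx"], params[f"lstm.{l}.Wh"], cache["lstm"][l]
        )
        grads[f"lstm.{l}.Wx"] = dWx
        grads[f"lstm.{l}.Wh"] = dWh
        grads[f"lstm.{l}.b"] = db
        dh_seq = dx_seq

    gcn_grads, _ = _gcn_backward(params, cfg, cache["adj"], dh_seq, cache["gcn"])
    grads.update(gcn_grads)

    if l2_weight > 0:
        for key, value in params.items():
            if _is_weight(key):
                loss += l2_weight * float((value.astype(np.float64) ** 2).sum())
                grads[key] = grads[key] + 2.0 * l2_weight * value
    return loss, grads, logits


# ---------------------------------------------------------------------------
# optimization


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k in params:
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= (
                self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)
            ).astype(params[k].dtype)


def stratified_split(labels, fractions, seed: int):
    """Deterministic stratified subject split -> (train, val, test) index arrays.

    Within each class the shuffled indices are cut at the cumulative
    fractions; rounding remainders go to the training fold.
    """
    labels = np.asarray(labels)
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be three values summing to 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5BE7]))
    train, val, test = [], [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n = len(idx)
        n_val = int(np.floor(fractions[1] * n))
        n_test = int(np.floor(fractions[2] * n))
        n_train = n - n_val - n_test
        train.extend(idx[:n_train])
        val.extend(idx[n_train : n_train + n_val])
        test.extend(idx[n_train + n_val :])
    return (
        np.sort(np.array(train, dtype=int)),
        np.sort(np.array(val, dtype=int)),
        np.sort(np.array(test, dtype=int)),
    )


def stack_sequences(graph_seqs, dtype=np.float32):
    """Stack GraphSequences into (N,K,R,R) adjacency and (N,K,R) feature arrays."""
    shapes = {(g.n_windows, g.n_regions) for g in graph_seqs}
    if len(shapes) != 1:
        raise ValueError(f"subjects disagree on (K, R): {sorted(shapes)}")
    adj = np.stack([g.norm_adj for g in graph_seqs]).astype(dtype)
    feats = np.stack([g.node_features for g in graph_seqs]).astype(dtype)
    return adj, feats


def train(
    graph_seqs,
    labels,
    cfg: TrainConfig,
    model_cfg: ModelConfig | None = None,
    *,
    val_seqs=None,
    val_labels=None,
) -> TrainedModel:
    """Fit the classifier; returns the best-validation checkpoint and history.

    If no validation set is passed, one is carved out of ``graph_seqs`` with
    the val fraction of cfg.split (stratified, from cfg.seed). Early stopping
    restores the parameters of the epoch with the lowest validation loss.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    if model_cfg is None:
        model_cfg = ModelConfig(n_regions=graph_seqs[0].n_regions)

    if val_seqs is None:
        frac_val = cfg.split[1] / (cfg.split[0] + cfg.split[1])
        tr_idx, va_idx, _ = stratified_split(
            labels, (1.0 - frac_val, frac_val, 0.0), cfg.seed
        )
        if len(va_idx) == 0:
            raise ValueError("validation split is empty; pass val_seqs or more data")
        val_seqs = [graph_seqs[i] for i in va_idx]
        val_labels = labels[va_idx]
        graph_seqs = [graph_seqs[i] for i in tr_idx]
        labels = labels[tr_idx]
    val_labels = np.asarray(val_labels)

    adj_tr, x_tr = stack_sequences(graph_seqs)
    adj_va, x_va = stack_sequences(val_seqs)
    y_tr = labels.astype(int)
    n = len(y_tr)

    params = init_params(model_cfg, cfg.seed)
    optimizer = _Adam(params, cfg.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xBA7C]))
    dropout_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xD807]))

    best_loss = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    best_epoch = -1
    wait = 0
    history = []
    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            take = order[start : start + cfg.batch_size]
            loss, grads, _ = loss_and_grads(
                params,
                model_cfg,
                adj_tr[take],
                x_tr[take],
                y_tr[take],
                l2_weight=cfg.l2_weight,
                dropout_rate=cfg.dropout_rate,
                dropout_rng=dropout_rng,
            )
            optimizer.step(params, grads)
            epoch_loss += loss * len(take)
        epoch_loss /= n

        tr_logits = forward(params, model_cfg, adj_tr, x_tr)
        va_logits = forward(params, model_cfg, adj_va, x_va)
        tr_acc = float((tr_logits.argmax(1) == y_tr).mean())
        va_probs = _softmax(va_logits.astype(np.float64))
        va_loss = float(
            -np.log(
                np.maximum(va_probs[np.arange(len(val_labels)), val_labels], 1e-300)
            ).mean()
        )
        va_acc = float((va_logits.argmax(1) == val_labels).mean())
        history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss,
                "train_acc": tr_acc,
                "val_loss": va_loss,
                "val_acc": va_acc,
            }
        )
        if va_loss < best_loss - 1e-6:
            best_loss = va_loss
            best_params = {k: v.copy() for k, v in params.items()}
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= cfg.patience:
                logger.info("early stopping at epoch %d (best %d)", epoch, best_epoch)
                break
    return TrainedModel(
        params=best_params,
        model_config=model_cfg,
        train_config=cfg,
        history=history,
        best_epoch=best_epoch,
    )


def predict(model: TrainedModel, graph_seqs) -> np.ndarray:
    """Predicted labels (1 = patient) for a list of GraphSequences."""
    adj, feats = stack_sequences(graph_seqs)
    logits = forward(model.params, model.model_config, adj, feats)
    return logits.argmax(axis=1)


# ---------------------------------------------------------------------------
# persistence


def save_checkpoint(model: TrainedModel, path) -> None:
    """All parameters plus both configs and history, as .npz + JSON sidecar."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.params)
    meta = {
        "model_config": asdict(model.model_config),
        "train_config": asdict(model.train_config),
        "history": model.history,
        "best_epoch": model.best_epoch,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path) -> TrainedModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    for cfg in (meta["model_config"], meta["train_config"]):
        for key, value in cfg.items():
            if isinstance(value, list):
                cfg[key] = tuple(value)
    with np.load(path.with_suffix(".npz")) as data:
        params = {k: data[k] for k in data.files}
    return TrainedModel(
        params=params,
        model_config=ModelConfig(**meta["model_config"]),
        train_config=TrainConfig(**meta["train_config"]),
        history=meta["history"],
        best_epoch=meta["best_epoch"],
    )
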