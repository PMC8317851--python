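"""The attention-gated dual-branch survival classifier.

Two gene groups are encoded separately by two-layer ReLU networks into
10-dimensional codes g1', g2'.  The codes are fused by a sigmoid attention
gate — G = [sig(g2') * g1', sig(g1') * g2'] — so each branch modulates the
other elementwise, and a two-layer decoder maps G to a death probability
y' = sig(w32 . ReLU(w31 G + b31) + b32).  Training minimises the focal loss

    L = -alpha (1-y')^gamma log y'        (y = 1, dead)
    L = -(1-alpha) y'^gamma log(1-y')     (y = 0, alive)

with Adam, full-batch by default, inverted dropout on every hidden layer and
on the encoder codes (never on the inputs or on G), glorot-uniform weight
initialisation, and early stopping on a held-out validation split.

Everything here is plain numpy; gradients are hand-derived backpropagation
and are checked against central finite differences in the test suite.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict, replace

import numpy as np

EPS_CLIP = 1e-7
MODEL_FORMAT_VERSION = 1

_WEIGHT_FANS = {
    # name: (fan_in attr, fan_out attr) measured on the layer the matrix feeds
    "w11": ("d1", "h_enc"),
    "w12": ("h_enc", "d_code"),
    "w21": ("d2", "h_enc"),
    "w22": ("h_enc", "d_code"),
    "w31": ("g_dim", "h_dec"),
    "w32": ("h_dec", "out"),
}
PARAM_NAMES = ("w11", "b11", "w12", "b12", "w21", "b21", "w22", "b22",
               "w31", "b31", "w32", "b32")


@dataclass
class NetworkConfig:
    d1: int
    d2: int
    h_enc: int = 32
    d_code: int = 10
    h_dec: int = 10
    dropout_rate: float = 0.2
    alpha: float = 0.2
    gamma: float = 2.0
    learning_rate: float = 0.01
    epochs: int = 300
    batch_size: int | str = "full"
    seed: int = 0
    threshold: float = 0.5
    patience: int = 30
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.d_code < 1:
            raise ValueError("d_code must be >= 1")

    @property
    def g_dim(self) -> int:
        return 2 * self.d_code

    @property
    def out(self) -> int:
        return 1


@dataclass
class NetworkParams:
    """All weights and biases; shapes follow (out_dim, in_dim) / (out_dim,)."""

    w11: np.ndarray; b11: np.ndarray
    w12: np.ndarray; b12: np.ndarray
    w21: np.ndarray; b21: np.ndarray
    w22: np.ndarray; b22: np.ndarray
    w31: np.ndarray; b31: np.ndarray
    w32: np.ndarray; b32: np.ndarray

    def items(self):
        for name in PARAM_NAMES:
            yield name, getattr(self, name)

    def copy(self) -> "NetworkParams":
        return NetworkParams(**{n: v.copy() for n, v in self.items()})

    def check_finite(self) -> None:
        for n, v in self.items():
            if not np.all(np.isfinite(v)):
                raise FloatingPointError(f"non-finite values in {n}")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_auc: list[float] = field(default_factory=list)
    best_epoch: int = -1


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def glorot_init(config: NetworkConfig, seed: int) -> NetworkParams:
    """Glorot/Xavier uniform weights on +-sqrt(6/(fan_in+fan_out)); zero biases."""
    rng = np.random.default_rng(seed)
    arrays: dict[str, np.ndarray] = {}
    for wname, (fi, fo) in _WEIGHT_FANS.items():
        fan_in = getattr(config, fi)
        fan_out = getattr(config, fo)
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        arrays[wname] = rng.uniform(-bound, bound, size=(fan_out, fan_in))
        arrays["b" + wname[1:]] = np.zeros(fan_out)
    return NetworkParams(**arrays)


def _dropout_masks(shape_rng, shapes, rate):
    """Inverted-dropout multipliers (mask / keep-prob), one array per layer."""
    keep = 1.0 - rate
    return [
        (shape_rng.random(s) < keep).astype(float) / keep if rate > 0 else np.ones(s)
        for s in shapes
    ]


def _forward_cache(params: NetworkParams, X1: np.ndarray, X2: np.ndarray,
                   masks=None) -> dict:
    """Batched forward pass; returns every intermediate needed by backprop.

    ``masks`` is None (dropout off) or the 5 inverted-dropout multiplier
    arrays for (h1, g1, h2, g2, hd) in that order.
    """
    n = X1.shape[0]
    if masks is None:
        m_h1 = m_g1 = m_h2 = m_g2 = m_hd = 1.0
    else:
        m_h1, m_g1, m_h2, m_g2, m_hd = masks

    a11 = X1 @ params.w11.T + params.b11
    h1 = relu(a11) * m_h1
    a12 = h1 @ params.w12.T + params.b12
    g1 = relu(a12) * m_g1
    a21 = X2 @ params.w21.T + params.b21
    h2 = relu(a21) * m_h2
    a22 = h2 @ params.w22.T + params.b22
    g2 = relu(a22) * m_g2

    s1 = sigmoid(g1)
    s2 = sigmoid(g2)
    G = np.concatenate([s2 * g1, s1 * g2], axis=1)

    a3 = G @ params.w31.T + params.b31
    hd = relu(a3) * m_hd
    z = hd @ params.w32.T + params.b32  # (n, 1)
    p = sigmoid(z[:, 0])
    return dict(X1=X1, X2=X2, a11=a11, h1=h1, a12=a12, g1=g1,
                a21=a21, h2=h2, a22=a22, g2=g2, s1=s1, s2=s2, G=G,
                a3=a3, hd=hd, p=p,
                m_h1=m_h1, m_g1=m_g1, m_h2=m_h2, m_g2=m_g2, m_hd=m_hd)


def forward(params: NetworkParams, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Death probability y' in (0,1); accepts single vectors or batches."""
    single = np.asarray(x1).ndim == 1
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    if x1.shape[1] != params.w11.shape[1] or x2.shape[1] != params.w21.shape[1]:
        raise ValueError(
            f"input dims ({x1.shape[1]}, {x2.shape[1]}) do not match network "
            f"({params.w11.shape[1]}, {params.w21.shape[1]})"
        )
    p = _forward_cache(params, x1, x2)["p"]
    return float(p[0]) if single else p


def focal_loss(y: np.ndarray, y_pred: np.ndarray, alpha: float = 0.2,
               gamma: float = 2.0) -> float:
    """Mean focal loss over a batch; probabilities clipped away from {0,1}."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    p = np.clip(np.atleast_1d(np.asarray(y_pred, dtype=float)), EPS_CLIP, 1 - EPS_CLIP)
    pos = -alpha * (1 - p) ** gamma * np.log(p)
    neg = -(1 - alpha) * p ** gamma * np.log(1 - p)
    return float(np.mean(np.where(y == 1, pos, neg)))


def _focal_dLdp(y, p, alpha, gamma):
    """d(mean focal loss)/dp at the clipped probability (per sample, pre-mean)."""
    dpos = alpha * gamma * (1 - p) ** (gamma - 1) * np.log(p) - alpha * (1 - p) ** gamma / p
    dneg = -(1 - alpha) * gamma * p ** (gamma - 1) * np.log(1 - p) \
        + (1 - alpha) * p ** gamma / (1 - p)
    return np.where(y == 1, dpos, dneg)


def loss_gradient(params: NetworkParams, X1: np.ndarray, X2: np.ndarray,
                  y: np.ndarray, alpha: float = 0.2, gamma: float = 2.0,
                  masks=None) -> tuple[float, NetworkParams]:
    """Mean focal loss and its gradient w.r.t. every weight and bias.

    Hand-derived backpropagation through the decoder, the attention gate
    (both the gating sigmoid and the gated code receive gradient) and the two
    encoders.  Dropout multipliers, when given, are treated as constants.
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    n = X1.shape[0]
    c = _forward_cache(params, X1, X2, masks)
    p_raw = c["p"]
    p = np.clip(p_raw, EPS_CLIP, 1 - EPS_CLIP)
    loss = focal_loss(y, p_raw, alpha, gamma)

    inside = (p_raw > EPS_CLIP) & (p_raw < 1 - EPS_CLIP)  # clip blocks gradient
    dLdp = _focal_dLdp(y, p, alpha, gamma) / n
    dz = dLdp * inside * p_raw * (1 - p_raw)  # (n,)

    g = {}
    g["w32"] = dz[None, :] @ c["hd"]
    g["b32"] = np.array([dz.sum()])
    d_hd = np.outer(dz, params.w32[0]) * c["m_hd"] * (c["a3"] > 0)
    g["w31"] = d_hd.T @ c["G"]
    g["b31"] = d_hd.sum(axis=0)
    dG = d_hd @ params.w31
    dc = params.w31.shape[1] // 2
    dG1, dG2 = dG[:, :dc], dG[:, dc:]

    s1, s2, g1, g2 = c["s1"], c["s2"], c["g1"], c["g2"]
    d_g1 = s2 * dG1 + s1 * (1 - s1) * g2 * dG2
    d_g2 = s2 * (1 - s2) * g1 * dG1 + s1 * dG2

    d_a12 = d_g1 * c["m_g1"] * (c["a12"] > 0)
    g["w12"] = d_a12.T @ c["h1"]
    g["b12"] = d_a12.sum(axis=0)
    d_a11 = (d_a12 @ params.w12) * c["m_h1"] * (c["a11"] > 0)
    g["w11"] = d_a11.T @ X1
    g["b11"] = d_a11.sum(axis=0)

    d_a22 = d_g2 * c["m_g2"] * (c["a22"] > 0)
    g["w22"] = d_a22.T @ c["h2"]
    g["b22"] = d_a22.sum(axis=0)
    d_a21 = (d_a22 @ params.w22) * c["m_h2"] * (c["a21"] > 0)
    g["w21"] = d_a21.T @ X2
    g["b21"] = d_a21.sum(axis=0)

    return loss, NetworkParams(**g)


class _Adam:
    def __init__(self, params: NetworkParams, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {n: np.zeros_like(v) for n, v in params.items()}
        self.v = {n: np.zeros_like(v) for n, v in params.items()}
        self.t = 0

    def step(self, params: NetworkParams, grads: NetworkParams) -> None:
        self.t += 1
        for n, gval in grads.items():
            self.m[n] = self.b1 * self.m[n] + (1 - self.b1) * gval
            self.v[n] = self.b2 * self.v[n] + (1 - self.b2) * gval**2
            mhat = self.m[n] / (1 - self.b1**self.t)
            vhat = self.v[n] / (1 - self.b2**self.t)
            getattr(params, n)[...] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def branch_inputs(expr, features) -> tuple[np.ndarray, np.ndarray]:
    """Samples-x-genes input matrices for the two feature groups."""
    g1_genes = features.genes_in_group(1)
    g2_genes = features.genes_in_group(2)
    if not g1_genes or not g2_genes:
        raise ValueError("both feature groups must be non-empty")
    X1 = expr.subset_genes(g1_genes).values.T
    X2 = expr.subset_genes(g2_genes).values.T
    return X1, X2


def train(expr, features, labels: np.ndarray, config: NetworkConfig
          ) -> tuple[NetworkParams, TrainingHistory]:
    """Fit the classifier with Adam on the mean focal loss.

    A ``val_fraction`` random holdout of the given samples monitors
    generalisation; training stops after ``patience`` epochs without a new
    best validation loss and the best-validation parameters are returned.
    All randomness (init, split, dropout) derives from ``config.seed``.
    """
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("training labels contain a single class")
    X1, X2 = branch_inputs(expr, features)
    cfg = replace(config, d1=X1.shape[1], d2=X2.shape[1])

    ss = np.random.SeedSequence(cfg.seed)
    init_seed, split_seed, drop_seed = (int(s.generate_state(1)[0] % (2**31 - 1))
                                        for s in ss.spawn(3))
    params = glorot_init(cfg, init_seed)

    n = X1.shape[0]
    n_val = int(round(cfg.val_fraction * n))
    perm = np.random.default_rng(split_seed).permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if labels[tr_idx].min() == labels[tr_idx].max():
        raise ValueError("validation split left a single-class training set")
    Xt1, Xt2, yt = X1[tr_idx], X2[tr_idx], labels[tr_idx]
    Xv1, Xv2, yv = X1[val_idx], X2[val_idx], labels[val_idx]

    drop_rng = np.random.default_rng(drop_seed)
    opt = _Adam(params, cfg.learning_rate)
    hist = TrainingHistory()
    best = params.copy()
    best_val = np.inf
    since_best = 0
    shapes = [(len(tr_idx), cfg.h_enc), (len(tr_idx), cfg.d_code),
              (len(tr_idx), cfg.h_enc), (len(tr_idx), cfg.d_code),
              (len(tr_idx), cfg.h_dec)]
    for epoch in range(cfg.epochs):
        masks = (_dropout_masks(drop_rng, shapes, cfg.dropout_rate)
                 if cfg.dropout_rate > 0 else None)
        loss, grads = loss_gradient(params, Xt1, Xt2, yt, cfg.alpha, cfg.gamma, masks)
        opt.step(params, grads)
        hist.train_loss.append(loss)
        if len(val_idx) > 0:
            pv = forward(params, Xv1, Xv2)
            vloss = focal_loss(yv, pv, cfg.alpha, cfg.gamma)
            hist.val_loss.append(vloss)
            hist.val_auc.append(_safe_auc(yv, pv))
            if vloss < best_val - 1e-12:
                best_val = vloss
                best = params.copy()
                hist.best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
        else:
            best = params
            hist.best_epoch = epoch
    best.check_finite()
    return best, hist


def _safe_auc(y, p) -> float:
    from sklearn.metrics import roc_auc_score

    y = np.asarray(y)
    if y.min() == y.max():
        return float("nan")
    return float(roc_auc_score(y, p))


def predict_proba(params: NetworkParams, expr, features) -> np.ndarray:
    """Per-sample death probability, dropout off."""
    X1, X2 = branch_inputs(expr, features)
    return np.atleast_1d(forward(params, X1, X2))


def classify(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """0 = alive below the threshold, 1 = dead at or above it."""
    return (np.asarray(probs) >= threshold).astype(int)


def save_params(path, params: NetworkParams, config: NetworkConfig,
                feature_set=None) -> None:
    """Write model as JSON (float64 repr round-trips losslessly)."""
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "config": asdict(config),
        "params": {n: v.tolist() for n, v in params.items()},
    }
    if feature_set is not None:
        doc["features"] = feature_set.to_dict()
    parent = os.path.dirname(os.path.abspath(os.fspath(path)))
    os.makedirs(parent, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True)


def load_params(path) -> tuple[NetworkParams, NetworkConfig, dict | None]:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"corrupt model file {path}: {exc}") from exc
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {doc.get('format_version')!r}")
    config = NetworkConfig(**doc["config"])
    arrays = {n: np.asarray(v, dtype=float) for n, v in doc["params"].items()}
    params = NetworkParams(**arrays)
    for wname, (fi, fo) in _WEIGHT_FANS.items():
        expect = (getattr(config, fo), getattr(config, fi))
        if arrays[wname].shape != expect:
            raise ValueError(f"{wname} shape {arrays[wname].shape} conflicts with config {expect}")
    return params, config, doc.get("features")
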