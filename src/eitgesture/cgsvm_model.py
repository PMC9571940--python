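"""CG-SVM: dual-branch CNN + GRU feature extractor with an auxiliary
dense classifier trained under the center distance loss, and an SVM main
classifier.

The upper branch runs the raw 40-value measurement sequence through three
1-D convolution blocks (kernels 5, 4, 3 with 16, 32, 64 channels, ReLU,
no pooling) and flattens; the lower branch first-order-differences the
sequence and feeds it to a single-layer GRU whose final hidden state is
the branch output.  Both branches concatenate into the deep feature
vector x_i in R^d.

Training minimises, as printed batch sums,

    L = Ls + lambda1 * Lc + lambda2 * Ld

where Ls is the softmax loss of the auxiliary dense classifier, Lc the
center loss pulling each feature to its class center c_y, and Ld the
center distance penalty sum_i max(0, K - ||c_{y_i} - c_j||^2) over the
other-class centers j, pushing centers apart until their squared gaps
exceed the margin K.  Class centers are kept by a mini-batch moving
average plus an explicit gradient step on lambda2 * Ld.  After the
extractor converges, an RBF SVM is fitted on the (frozen) train-set
features and serves as the inference-time classifier; the auxiliary head
is discarded at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.svm import SVC

from . import _nn
from .synthetic_gestures import DatasetSplit, first_order_difference

__all__ = [
    "CGSVMConfig",
    "LossComponents",
    "TrainedCGSVM",
    "init_params",
    "extract_features",
    "softmax_loss",
    "center_loss",
    "center_distance_penalty",
    "total_loss",
    "update_centers",
    "center_penalty_grad",
    "aux_loss_and_feature_grad",
    "train",
    "predict",
]


@dataclass(frozen=True)
class CGSVMConfig:
    """Architecture and training hyperparameters.

    Kernel/channel sequence and the 0.5 dropout follow the published
    architecture table; loss weights default to lambda1 = 0.003,
    lambda2 = 0.01 (tuned for batch-sum loss scale).  ``K = None`` sets
    the margin to the median pairwise squared center distance after a
    one-epoch warm-up, then freezes it.  ``penalty_mode`` selects whether
    Ld sums the hinge over all other-class centers or only the nearest.
    ``arch`` is "cgsvm" or "cnn_softmax" (upper branch + softmax head,
    the plain-CNN comparison network).
    """

    n_classes: int = 5
    input_len: int = 40
    conv_blocks: tuple[tuple[int, int], ...] = ((5, 16), (4, 32), (3, 64))
    gru_hidden: int = 64
    aux_hidden: int = 64
    dropout_rate: float = 0.5
    lambda1: float = 0.003
    lambda2: float = 0.01
    K: float | None = None
    center_update_alpha: float = 0.5
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0
    penalty_mode: str = "all"  # or "nearest"
    arch: str = "cgsvm"

    def __post_init__(self) -> None:
        if self.dropout_rate < 0 or self.dropout_rate >= 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be non-negative")
        if self.K is not None and self.K <= 0:
            raise ValueError("distance margin K must be positive")
        if self.penalty_mode not in ("all", "nearest"):
            raise ValueError("penalty_mode must be 'all' or 'nearest'")
        if self.arch not in ("cgsvm", "cnn_softmax"):
            raise ValueError("arch must be 'cgsvm' or 'cnn_softmax'")

    @property
    def conv_out_len(self) -> int:
        n = self.input_len
        for k, _ in self.conv_blocks:
            n = n - k + 1
        return n

    @property
    def feature_dim(self) -> int:
        d = self.conv_out_len * self.conv_blocks[-1][1]
        if self.arch == "cgsvm":
            d += self.gru_hidden
        return d


@dataclass(frozen=True)
class LossComponents:
    """The loss terms on one batch; ``total = ls + l1*lc + l2*ld``."""

    ls: float
    lc: float
    ld: float
    total: float


def init_params(config: CGSVMConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    p: dict[str, np.ndarray] = {}
    cin = 1
    for i, (k, cout) in enumerate(config.conv_blocks, start=1):
        p[f"c{i}w"] = _nn.glorot(rng, k, cin, cout)
        p[f"c{i}b"] = np.zeros(cout)
        cin = cout
    if config.arch == "cgsvm":
        h = config.gru_hidden
        for gate in ("z", "r", "n"):
            p[f"gru_W{gate}"] = _nn.glorot(rng, 1, h)
            p[f"gru_U{gate}"] = _nn.glorot(rng, h, h)
            p[f"gru_b{gate}"] = np.zeros(h)
    p["d1w"] = _nn.glorot(rng, config.feature_dim, config.aux_hidden)
    p["d1b"] = np.zeros(config.aux_hidden)
    p["d2w"] = _nn.glorot(rng, config.aux_hidden, config.n_classes)
    p["d2b"] = np.zeros(config.n_classes)
    return p


def _gru_view(params: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {k[4:]: v for k, v in params.items() if k.startswith("gru_")}


def _forward_features(
    x: np.ndarray, params: dict[str, np.ndarray], config: CGSVMConfig
) -> tuple[np.ndarray, dict]:
    """Feature extractor forward on standardized input (B, 40)."""
    cache: dict = {}
    a = x[:, :, None]
    cache["conv_in"] = [a]
    for i in range(1, len(config.conv_blocks) + 1):
        z = _nn.conv1d_forward(a, params[f"c{i}w"], params[f"c{i}b"])
        cache[f"conv_pre{i}"] = z
        a = _nn.relu(z)
        cache["conv_in"].append(a)
    flat = a.reshape(a.shape[0], -1)
    if config.arch == "cnn_softmax":
        cache["gru"] = None
        return flat, cache
    xg = np.zeros_like(x)
    xg[:, 1:] = np.diff(x, axis=1)
    h, gcache = _nn.gru_forward(xg[:, :, None], _gru_view(params))
    cache["gru"] = gcache
    return np.concatenate([flat, h], axis=1), cache


def extract_features(
    sample: np.ndarray, params: dict[str, np.ndarray], config: CGSVMConfig
) -> np.ndarray:
    """Deep feature vector(s) for one 40-vector or a (B, 40) batch.

    Inference mode: dropout disabled.  The CNN branch consumes the raw
    sequence; the GRU branch its first-order difference; outputs are
    concatenated (d = conv_flatten + gru_hidden).
    """
    x = np.asarray(sample, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != config.input_len:
        raise ValueError(f"expected input length {config.input_len}, got {x.shape[1]}")
    f, _ = _forward_features(x, params, config)
    return f[0] if single else f


# ------------------------------------------------------------ loss terms

def softmax_loss(
    features: np.ndarray, labels: np.ndarray, w: np.ndarray, b: np.ndarray
) -> float:
    """Batch-sum softmax loss  -sum_i log softmax(W^T x_i + b)[y_i]."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=int)
    n = w.shape[1]
    if np.any((y < 0) | (y >= n)):
        raise ValueError("label out of range")
    logits = x @ w + b
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-logp[np.arange(len(y)), y].sum())


def center_loss(features: np.ndarray, labels: np.ndarray, centers: np.ndarray) -> float:
    """Half the summed squared distances of features to their class centers."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=int)
    if x.shape[1] != centers.shape[1]:
        raise ValueError("feature/center dimension mismatch")
    d = x - centers[y]
    return float(0.5 * np.sum(d * d))


def _center_gaps(centers: np.ndarray) -> np.ndarray:
    diff = centers[:, None, :] - centers[None, :, :]
    return np.sum(diff * diff, axis=-1)


def center_distance_penalty(
    labels: np.ndarray, centers: np.ndarray, k: float, mode: str = "all"
) -> float:
    """Hinge penalty on squared center gaps below the margin K.

    For each sample i, the hinge max(0, K - ||c_{y_i} - c_j||^2) is summed
    over all other-class centers j ("all", default) or only the nearest
    other center ("nearest").
    """
    if k <= 0:
        raise ValueError("distance margin K must be positive")
    if len(centers) < 2:
        raise ValueError("need at least two class centers")
    y = np.asarray(labels, dtype=int)
    gaps = _center_gaps(centers)
    total = 0.0
    for yi in y:
        others = np.delete(gaps[yi], yi)
        h = np.maximum(0.0, k - others)
        total += float(h.sum() if mode == "all" else h[np.argmin(others)])
    return total


def total_loss(ls: float, lc: float, ld: float,
               lambda1: float, lambda2: float) -> float:
    """L = Ls + lambda1 * Lc + lambda2 * Ld."""
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("loss weights must be non-negative")
    return ls + lambda1 * lc + lambda2 * ld


def update_centers(
    features: np.ndarray, labels: np.ndarray, centers: np.ndarray, alpha: float
) -> np.ndarray:
    """Mini-batch moving-average center update.

    c_j <- c_j - alpha * sum_{i: y_i = j}(c_j - x_i) / (1 + count_j);
    classes absent from the batch are unchanged.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=int)
    out = centers.copy()
    for j in np.unique(y):
        sel = y == j
        delta = (out[j] - x[sel]).sum(axis=0) / (1.0 + sel.sum())
        out[j] = out[j] - alpha * delta
    return out


def center_penalty_grad(
    labels: np.ndarray, centers: np.ndarray, k: float, mode: str = "all"
) -> np.ndarray:
    """Gradient of the center distance penalty with respect to the centers."""
    if k <= 0:
        raise ValueError("distance margin K must be positive")
    y = np.asarray(labels, dtype=int)
    g = np.zeros_like(centers)
    gaps = _center_gaps(centers)
    n = len(centers)
    for yi in y:
        js = [j for j in range(n) if j != yi]
        if mode == "nearest":
            js = [min(js, key=lambda j: gaps[yi, j])]
        for j in js:
            if gaps[yi, j] < k:
                diff = centers[yi] - centers[j]
                g[yi] += -2.0 * diff
                g[j] += 2.0 * diff
    return g


def aux_loss_and_feature_grad(
    features: np.ndarray,
    labels: np.ndarray,
    params: dict[str, np.ndarray],
    centers: np.ndarray,
    config: CGSVMConfig,
    dropout_mask: np.ndarray | None = None,
) -> tuple[LossComponents, np.ndarray, dict[str, np.ndarray]]:
    """Loss components on a batch plus gradients w.r.t. the features and
    the dense-head parameters.

    The softmax path runs features (optionally dropout-masked) through the
    two dense layers; the center loss acts on the raw features; the center
    distance penalty depends on the centers only, so it contributes to the
    loss value but not to the feature gradient.
    """
    f = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=int)
    fin = f if dropout_mask is None else f * dropout_mask
    z1 = _nn.dense_forward(fin, params["d1w"], params["d1b"])
    a1 = _nn.relu(z1)
    logits = _nn.dense_forward(a1, params["d2w"], params["d2b"])
    ls = softmax_loss(a1, y, params["d2w"], params["d2b"])
    lc = center_loss(f, y, centers)
    if config.lambda2 > 0 and config.K is not None:
        ld = center_distance_penalty(y, centers, config.K, config.penalty_mode)
    else:
        ld = 0.0
    comps = LossComponents(
        ls=ls, lc=lc, ld=ld,
        total=total_loss(ls, lc, ld, config.lambda1, config.lambda2),
    )
    # backprop (batch-sum scale)
    dlogits = _nn.softmax(logits)
    dlogits[np.arange(len(y)), y] -= 1.0
    da1, dd2w, dd2b = _nn.dense_backward(a1, params["d2w"], dlogits)
    dz1 = _nn.relu_backward(z1, da1)
    dfin, dd1w, dd1b = _nn.dense_backward(fin, params["d1w"], dz1)
    df = dfin if dropout_mask is None else dfin * dropout_mask
    df = df + config.lambda1 * (f - centers[y])
    head_grads = {"d1w": dd1w, "d1b": dd1b, "d2w": dd2w, "d2b": dd2b}
    return comps, df, head_grads


# -------------------------------------------------------------- training

@dataclass
class TrainedCGSVM:
    """Fitted extractor, centers, SVM head and training history."""

    config: CGSVMConfig
    params: dict[str, np.ndarray]
    centers: np.ndarray
    k_used: float | None
    mu: np.ndarray
    sd: np.ndarray
    svm: SVC | None
    history: pd.DataFrame

    def save(self, path: str) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str) -> "TrainedCGSVM":
        return joblib.load(path)


def _standardize_stats(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return mu, sd


def _backprop_extractor(
    x: np.ndarray, df: np.ndarray, params: dict[str, np.ndarray],
    cache: dict, config: CGSVMConfig,
) -> dict[str, np.ndarray]:
    grads: dict[str, np.ndarray] = {}
    nconv = len(config.conv_blocks)
    flat_dim = config.conv_out_len * config.conv_blocks[-1][1]
    dflat = df[:, :flat_dim]
    da = dflat.reshape(x.shape[0], config.conv_out_len, config.conv_blocks[-1][1])
    for i in range(nconv, 0, -1):
        dz = _nn.relu_backward(cache[f"conv_pre{i}"], da)
        din, dw, db = _nn.conv1d_backward(
            cache["conv_in"][i - 1], params[f"c{i}w"], dz
        )
        grads[f"c{i}w"], grads[f"c{i}b"] = dw, db
        da = din
    if config.arch == "cgsvm":
        dh = df[:, flat_dim:]
        _, ggrads = _nn.gru_backward(dh, _gru_view(params), cache["gru"])
        for k, v in ggrads.items():
            grads[f"gru_{k}"] = v
    return grads


def train(split: DatasetSplit, config: CGSVMConfig = CGSVMConfig()) -> TrainedCGSVM:
    """Two-phase training.

    Phase 1: minimise L = Ls + l1*Lc + l2*Ld end-to-end with Adam,
    updating class centers each batch (moving average + penalty-gradient
    step).  If ``config.K`` is None, the margin is set after a one-epoch
    warm-up to the median pairwise squared center distance, then frozen.
    Phase 2: freeze the extractor, extract train-set features and fit the
    RBF SVM head (skipped for the cnn_softmax architecture, whose softmax
    head is the classifier).
    """
    xtr_raw = split.train.X()
    ytr = split.train.y()
    if len(xtr_raw) == 0:
        raise ValueError("empty training set")
    mu, sd = _standardize_stats(xtr_raw)
    x = (xtr_raw - mu) / sd
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    params = init_params(config, rng)
    opt = _nn.Adam(params, lr=config.learning_rate)
    centers = np.zeros((config.n_classes, config.feature_dim))
    cfg = config
    k_used = config.K
    history: list[dict] = []
    n = len(x)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        ep = {"epoch": epoch, "ls": 0.0, "lc": 0.0, "ld": 0.0, "loss": 0.0}
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x[idx], ytr[idx]
            f, cache = _forward_features(xb, params, cfg)
            if cfg.dropout_rate > 0:
                mask = (rng.random(f.shape) >= cfg.dropout_rate) / (
                    1.0 - cfg.dropout_rate
                )
            else:
                mask = None
            comps, df, head_grads = aux_loss_and_feature_grad(
                f, yb, params, centers, cfg, dropout_mask=mask
            )
            if not np.isfinite(comps.total):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            grads = _backprop_extractor(xb, df, params, cache, cfg)
            grads.update(head_grads)
            opt.step(grads)
            if cfg.lambda1 > 0 or cfg.lambda2 > 0:
                centers = update_centers(f, yb, centers, cfg.center_update_alpha)
            if cfg.lambda2 > 0 and cfg.K is not None:
                centers = centers - cfg.center_update_alpha * cfg.lambda2 * (
                    center_penalty_grad(yb, centers, cfg.K, cfg.penalty_mode)
                )
            ep["ls"] += comps.ls
            ep["lc"] += comps.lc
            ep["ld"] += comps.ld
            ep["loss"] += comps.total
        if epoch == 0 and config.K is None and cfg.lambda2 > 0:
            gaps = _center_gaps(centers)
            med = float(np.median(gaps[np.triu_indices(len(centers), 1)]))
            k_used = max(med, 1e-12)
            cfg = replace(cfg, K=k_used)
        # epoch-end diagnostics in eval mode
        feats, _ = _forward_features(x, params, cfg)
        comps_eval, _, _ = aux_loss_and_feature_grad(feats, ytr, params, centers, cfg)
        z1 = _nn.relu(_nn.dense_forward(feats, params["d1w"], params["d1b"]))
        logits = _nn.dense_forward(z1, params["d2w"], params["d2b"])
        ep["train_acc"] = float((np.argmax(logits, axis=1) == ytr).mean())
        ep["mean_center_dist"] = float(
            np.linalg.norm(feats - centers[ytr], axis=1).mean()
        )
        gaps = _center_gaps(centers)
        ep["min_center_gap"] = float(gaps[np.triu_indices(len(centers), 1)].min())
        history.append(ep)
    svm: SVC | None = None
    if config.arch == "cgsvm":
        feats, _ = _forward_features(x, params, cfg)
        svm = SVC(kernel="rbf", C=1.0, gamma="scale")
        svm.fit(feats, ytr)
    return TrainedCGSVM(
        config=cfg, params=params, centers=centers, k_used=k_used,
        mu=mu, sd=sd, svm=svm, history=pd.DataFrame(history),
    )


def predict(model: TrainedCGSVM, samples: np.ndarray | Sequence) -> np.ndarray:
    """Class labels for raw 40-vector samples (batch or single).

    The SVM head decides for the cgsvm architecture; the softmax argmax
    for cnn_softmax.  The auxiliary dense head is otherwise ignored."""
    x = np.asarray(samples, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != model.config.input_len:
        raise ValueError(
            f"expected input length {model.config.input_len}, got {x.shape[1]}"
        )
    xs = (x - model.mu) / model.sd
    feats, _ = _forward_features(xs, model.params, model.config)
    if model.svm is not None:
        out = model.svm.predict(feats)
    else:
        z1 = _nn.relu(
            _nn.dense_forward(feats, model.params["d1w"], model.params["d1b"])
        )
        logits = _nn.dense_forward(z1, model.params["d2w"], model.params["d2b"])
        out = np.argmax(logits, axis=1)
    out = np.asarray(out, dtype=int)
    return out[0] if single else out
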