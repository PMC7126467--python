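"""Residual network for beta-beta pairing prediction, in pure NumPy.

The model maps a C x L x L feature tensor to a symmetric L x L pairing
probability matrix.  Each residual block applies two repeats of
(normalization, leaky ReLU, 3x3 convolution) around a shortcut connection;
the first repeat's normalization is the average of row normalization (RN)
and column normalization (CN) — per-row / per-column standardization over
masked-in pairs, the operations that make contact-map features comparable
across rows and columns of very different contact density — and the second
repeat uses instance normalization (IN).  Forward and backward passes are
written out explicitly (convolutions as im2col matrix products), and
training uses Adam on a masked binary cross-entropy.  Everything is plain
NumPy, so runs are bit-reproducible given the seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .features import FeatureTensor, channel_registry
from .io import PairingLabels, PairingProbMap

logger = logging.getLogger(__name__)

_DTYPE = np.float32


class ConfigurationError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Architecture hyper-parameters.

    The reference configuration is 15 blocks and 45 channels with RN/CN
    enabled; desk-scale experiments use smaller values.
    """

    n_blocks: int = 15
    n_channels: int = 45
    use_rncn: bool = True
    leaky_slope: float = 0.01
    epsilon: float = 1e-5
    in_channels: int = len(channel_registry())

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.n_channels < 1:
            raise ConfigurationError("n_blocks and n_channels must be >= 1")
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be positive")


@dataclass
class TrainConfig:
    """Optimization protocol: Adam at learning_rate, k-fold cross validation,
    early stopping on pooled validation F1 at the running optimal cutoff."""

    learning_rate: float = 1e-4
    n_folds: int = 5
    max_epochs: int = 30
    patience: int = 5
    seed: int = 0
    positive_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigurationError("learning rate must be positive")
        if self.n_folds < 2:
            raise ConfigurationError("cross validation needs at least 2 folds")


# ---------------------------------------------------------------------------
# primitive layers (forward + explicit backward)
# ---------------------------------------------------------------------------

def _norm_axes(kind: str):
    return {"row": (2,), "col": (1,), "inst": (1, 2)}[kind]


def masked_normalize(x, mask, gain, bias, epsilon, kind, want_cache=False):
    """Standardize x over masked-in entries along rows / columns / the whole map.

    Per channel, the mean and std are computed over entries where mask is
    True along the reduction axes of ``kind`` ("row": over j for each i;
    "col": over i for each j; "inst": over all pixels).  Slices with fewer
    than 2 valid entries pass through unchanged.  All positions (including
    masked-out ones) are shifted/scaled by the slice statistics, then a
    per-channel learnable gain and bias is applied.
    """
    axes = _norm_axes(kind)
    m = mask.astype(x.dtype)[None]
    cnt = m.sum(axis=axes, keepdims=True)
    valid = cnt >= 2
    safe_cnt = np.maximum(cnt, 1.0)
    mu = (x * m).sum(axis=axes, keepdims=True) / safe_cnt
    var = (((x - mu) ** 2) * m).sum(axis=axes, keepdims=True) / safe_cnt
    sigma = np.sqrt(var)
    s = sigma + epsilon
    y = np.where(valid, (x - mu) / s, x)
    out = gain[:, None, None] * y + bias[:, None, None]
    if not want_cache:
        return out
    cache = dict(y=y, s=s, sigma=sigma, cnt=cnt, valid=valid, m=m, gain=gain, axes=axes)
    return out, cache


def masked_normalize_backward(dout, cache):
    y, s, sigma = cache["y"], cache["s"], cache["sigma"]
    cnt, valid, m = cache["cnt"], cache["valid"], cache["m"]
    axes = cache["axes"]
    dgain = (dout * y).sum(axis=(1, 2))
    dbias = dout.sum(axis=(1, 2))
    ghat = dout * cache["gain"][:, None, None]
    g1 = ghat.sum(axis=axes, keepdims=True)
    g2 = (ghat * y).sum(axis=axes, keepdims=True)
    safe_cnt = np.maximum(cnt, 1.0)
    inv_sigma = np.where(sigma > 1e-12, 1.0 / np.maximum(sigma, 1e-12), 0.0)
    dx_norm = ghat / s - m * (g1 / (safe_cnt * s) + y * g2 * inv_sigma / safe_cnt)
    dx = np.where(valid, dx_norm, ghat)
    return dx, dgain, dbias


def leaky_relu(x, slope):
    return np.where(x > 0, x, slope * x)


def leaky_relu_backward(dout, x, slope):
    return np.where(x > 0, dout, slope * dout)


def conv1x1(x, w, b):
    """Pointwise channel mixing: w is (C_out, C_in)."""
    c, l1, l2 = x.shape
    out = (w @ x.reshape(c, -1)).reshape(w.shape[0], l1, l2)
    return out + b[:, None, None]


def conv1x1_backward(dout, x, w):
    o, l1, l2 = dout.shape
    df = dout.reshape(o, -1)
    xf = x.reshape(x.shape[0], -1)
    dw = df @ xf.T
    db = df.sum(axis=1)
    dx = (w.T @ df).reshape(x.shape)
    return dx, dw, db


def _im2col3(x):
    c, length, _ = x.shape
    xpad = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xpad, (3, 3), axis=(1, 2))  # (C, L, L, 3, 3)
    cols = np.ascontiguousarray(win.transpose(0, 3, 4, 1, 2)).reshape(c * 9, length * length)
    return cols


def conv3x3(x, w, b, want_cache=False):
    """Same-size 3x3 convolution with zero padding; w is (C_out, C_in, 3, 3)."""
    c, length, _ = x.shape
    cols = _im2col3(x)
    wf = w.reshape(w.shape[0], -1)
    out = (wf @ cols).reshape(w.shape[0], length, length) + b[:, None, None]
    if not want_cache:
        return out
    return out, cols


def conv3x3_backward(dout, cols, w, in_shape):
    c, length, _ = in_shape
    o = dout.shape[0]
    df = dout.reshape(o, -1)
    dw = (df @ cols.T).reshape(w.shape)
    db = df.sum(axis=1)
    dcols = (w.reshape(o, -1).T @ df).reshape(c, 3, 3, length, length)
    dxpad = np.zeros((c, length + 2, length + 2), dtype=dout.dtype)
    for di in range(3):
        for dj in range(3):
            dxpad[:, di:di + length, dj:dj + length] += dcols[:, di, dj]
    return dxpad[:, 1:length + 1, 1:length + 1], dw, db


def row_normalize(x, mask, epsilon=1e-5, gain=None, bias=None):
    """Standardize each row of each channel over masked-in entries."""
    c = x.shape[0]
    gain = np.ones(c, dtype=x.dtype) if gain is None else gain
    bias = np.zeros(c, dtype=x.dtype) if bias is None else bias
    return masked_normalize(x, mask, gain, bias, epsilon, "row")


def column_normalize(x, mask, epsilon=1e-5, gain=None, bias=None):
    """Row normalization with rows and columns exchanged."""
    c = x.shape[0]
    gain = np.ones(c, dtype=x.dtype) if gain is None else gain
    bias = np.zeros(c, dtype=x.dtype) if bias is None else bias
    return masked_normalize(x, mask, gain, bias, epsilon, "col")


def instance_normalize(x, mask, epsilon=1e-5, gain=None, bias=None):
    """Standardize each channel over all masked-in pixels."""
    c = x.shape[0]
    gain = np.ones(c, dtype=x.dtype) if gain is None else gain
    bias = np.zeros(c, dtype=x.dtype) if bias is None else bias
    return masked_normalize(x, mask, gain, bias, epsilon, "inst")


def resnet_block(x, params, mask, config: ModelConfig):
    """One residual block: y = x + Conv(LReLU(IN(Conv(LReLU(NORM1(x)))))).

    NORM1 is the average of RN and CN when config.use_rncn, else IN.
    ``params`` holds the block's parameters under the keys used by PairNet
    without the block prefix ("rn.g", "cn.g" or "n1.g", "W1", "b1",
    "in.g", "in.b", "W2", "b2").
    """
    if x.shape[0] != config.n_channels:
        raise ConfigurationError(
            f"block expects {config.n_channels} channels, got {x.shape[0]}")
    eps = config.epsilon
    if config.use_rncn:
        n1 = (masked_normalize(x, mask, params["rn.g"], params["rn.b"], eps, "row")
              + masked_normalize(x, mask, params["cn.g"], params["cn.b"], eps, "col")) / 2.0
    else:
        n1 = masked_normalize(x, mask, params["n1.g"], params["n1.b"], eps, "inst")
    c1 = conv3x3(leaky_relu(n1, config.leaky_slope), params["W1"], params["b1"])
    n2 = masked_normalize(c1, mask, params["in.g"], params["in.b"], eps, "inst")
    c2 = conv3x3(leaky_relu(n2, config.leaky_slope), params["W2"], params["b2"])
    return x + c2


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class PairNet:
    """One residual network instance (a single cross-validation fold's model)."""

    def __init__(self, config: ModelConfig, seed: int = 0, params: dict | None = None):
        self.config = config
        self.params = params if params is not None else self._init_params(seed)

    def _init_params(self, seed: int) -> dict:
        rng = np.random.default_rng(seed)
        cfg = self.config
        c = cfg.n_channels

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(_DTYPE)

        p = {"in.W": he((c, cfg.in_channels), cfg.in_channels),
             "in.b": np.zeros(c, dtype=_DTYPE)}
        for k in range(cfg.n_blocks):
            if cfg.use_rncn:
                p[f"b{k}.rn.g"] = np.ones(c, dtype=_DTYPE)
                p[f"b{k}.rn.b"] = np.zeros(c, dtype=_DTYPE)
                p[f"b{k}.cn.g"] = np.ones(c, dtype=_DTYPE)
                p[f"b{k}.cn.b"] = np.zeros(c, dtype=_DTYPE)
            else:
                p[f"b{k}.n1.g"] = np.ones(c, dtype=_DTYPE)
                p[f"b{k}.n1.b"] = np.zeros(c, dtype=_DTYPE)
            p[f"b{k}.W1"] = he((c, c, 3, 3), c * 9)
            p[f"b{k}.b1"] = np.zeros(c, dtype=_DTYPE)
            p[f"b{k}.in.g"] = np.ones(c, dtype=_DTYPE)
            p[f"b{k}.in.b"] = np.zeros(c, dtype=_DTYPE)
            p[f"b{k}.W2"] = he((c, c, 3, 3), c * 9)
            p[f"b{k}.b2"] = np.zeros(c, dtype=_DTYPE)
        p["out.W"] = he((1, c), c)
        p["out.b"] = np.zeros(1, dtype=_DTYPE)
        return p

    # -- forward ----------------------------------------------------------

    def _forward(self, x, mask, want_cache=False):
        cfg, p = self.config, self.params
        eps = cfg.epsilon
        caches = []
        h = conv1x1(x, p["in.W"], p["in.b"])
        x_in = x
        for k in range(cfg.n_blocks):
            cb = {"h_in": h}
            if cfg.use_rncn:
                rn = masked_normalize(h, mask, p[f"b{k}.rn.g"], p[f"b{k}.rn.b"], eps,
                                      "row", want_cache)
                cn = masked_normalize(h, mask, p[f"b{k}.cn.g"], p[f"b{k}.cn.b"], eps,
                                      "col", want_cache)
                if want_cache:
                    (rn, cb["rn"]), (cn, cb["cn"]) = rn, cn
                n1 = (rn + cn) / 2.0
            else:
                n1 = masked_normalize(h, mask, p[f"b{k}.n1.g"], p[f"b{k}.n1.b"], eps,
                                      "inst", want_cache)
                if want_cache:
                    n1, cb["n1_cache"] = n1
            a1 = leaky_relu(n1, cfg.leaky_slope)
            c1 = conv3x3(a1, p[f"b{k}.W1"], p[f"b{k}.b1"], want_cache)
            if want_cache:
                c1, cb["cols1"] = c1
            n2 = masked_normalize(c1, mask, p[f"b{k}.in.g"], p[f"b{k}.in.b"], eps,
                                  "inst", want_cache)
            if want_cache:
                n2, cb["in"] = n2
            a2 = leaky_relu(n2, cfg.leaky_slope)
            c2 = conv3x3(a2, p[f"b{k}.W2"], p[f"b{k}.b2"], want_cache)
            if want_cache:
                c2, cb["cols2"] = c2
            if want_cache:
                cb.update(n1=n1, a1=a1, c1=c1, n2=n2, a2=a2)
            h = h + c2
            caches.append(cb)
        z = conv1x1(h, p["out.W"], p["out.b"])[0]
        zs = (z + z.T) / 2.0
        if not want_cache:
            return zs
        return zs, {"x": x_in, "blocks": caches, "h_out": h}

    def forward(self, features: FeatureTensor) -> PairingProbMap:
        """Predict the pairing probability map for one protein."""
        if features.n_channels != self.config.in_channels:
            raise ConfigurationError(
                f"feature tensor has {features.n_channels} channels, "
                f"model expects {self.config.in_channels}")
        x = features.channels.astype(_DTYPE)
        zs = self._forward(x, features.mask)
        probs = _sigmoid(zs.astype(np.float64))
        probs[~features.mask] = 0.0
        probs = (probs + probs.T) / 2.0
        return PairingProbMap(probs)

    # -- loss and gradients -----------------------------------------------

    def loss_and_grads(self, features: FeatureTensor, labels: PairingLabels,
                       positive_weight: float = 1.0):
        """Masked weighted binary cross-entropy plus gradients for all params."""
        cfg, p = self.config, self.params
        x = features.channels.astype(_DTYPE)
        mask = features.mask
        zs, cache = self._forward(x, mask, want_cache=True)
        y = labels.to_matrix()
        mf = mask.astype(np.float64)
        w = np.where(y > 0, positive_weight, 1.0) * mf
        denom = w.sum()
        if denom <= 0:
            raise ValueError("no valid pairs under the mask")
        zs64 = zs.astype(np.float64)
        # -log p = softplus(-z); -log(1-p) = softplus(z)
        softplus = np.logaddexp(0.0, np.where(y > 0, -zs64, zs64))
        loss = float((w * softplus).sum() / denom)
        prob = _sigmoid(zs64)
        dzs = (mf * np.where(y > 0, positive_weight * (prob - 1.0), prob) / denom)
        dz = ((dzs + dzs.T) / 2.0).astype(_DTYPE)

        grads = {}
        dh, grads["out.W"], grads["out.b"] = conv1x1_backward(
            dz[None], cache["h_out"], p["out.W"])
        for k in reversed(range(cfg.n_blocks)):
            cb = cache["blocks"][k]
            dc2 = dh  # residual: dh flows to both the branch and the shortcut
            da2, grads[f"b{k}.W2"], grads[f"b{k}.b2"] = conv3x3_backward(
                dc2, cb["cols2"], p[f"b{k}.W2"], cb["a2"].shape)
            dn2 = leaky_relu_backward(da2, cb["n2"], cfg.leaky_slope)
            dc1, grads[f"b{k}.in.g"], grads[f"b{k}.in.b"] = masked_normalize_backward(
                dn2, cb["in"])
            da1, grads[f"b{k}.W1"], grads[f"b{k}.b1"] = conv3x3_backward(
                dc1, cb["cols1"], p[f"b{k}.W1"], cb["a1"].shape)
            dn1 = leaky_relu_backward(da1, cb["n1"], cfg.leaky_slope)
            if cfg.use_rncn:
                drn, grads[f"b{k}.rn.g"], grads[f"b{k}.rn.b"] = masked_normalize_backward(
                    dn1 / 2.0, cb["rn"])
                dcn, grads[f"b{k}.cn.g"], grads[f"b{k}.cn.b"] = masked_normalize_backward(
                    dn1 / 2.0, cb["cn"])
                dh = dh + drn + dcn
            else:
                dn, grads[f"b{k}.n1.g"], grads[f"b{k}.n1.b"] = masked_normalize_backward(
                    dn1, cb["n1_cache"])
                dh = dh + dn
        _, grads["in.W"], grads["in.b"] = conv1x1_backward(dh, cache["x"], p["in.W"])
        return loss, grads

    def copy_params(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}


class Adam:
    """Standard Adam optimizer over a parameter dictionary."""

    def __init__(self, params: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            g = g.astype(params[k].dtype)
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


# ---------------------------------------------------------------------------
# training and the fold ensemble
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """Mean-of-folds predictor: the deployed model averages the per-fold nets."""

    models: list
    config: ModelConfig
    cutoff: float = 0.5

    def predict(self, features: FeatureTensor) -> PairingProbMap:
        if not self.models:
            raise ValueError("empty ensemble")
        acc = None
        for net in self.models:
            p = net.forward(features).probs
            acc = p if acc is None else acc + p
        return PairingProbMap(acc / len(self.models))


def _has_positives(dataset, indices) -> bool:
    return any(len(dataset[i][1].pairs) > 0 for i in indices)


def train(dataset, mcfg: ModelConfig | None = None, tcfg: TrainConfig | None = None):
    """Train the fold ensemble with early stopping on pooled validation F1.

    dataset is a list of (FeatureTensor, PairingLabels).  Proteins are
    split into n_folds folds under the run seed; each fold's model trains
    on the remaining folds with Adam on the masked cross-entropy, and the
    pooled validation F1 at the running optimal cutoff drives early
    stopping.  Returns (EnsembleModel, histories) where histories is one
    list of per-epoch records per fold; the ensemble carries the cutoff
    selected from the pooled out-of-fold predictions.
    """
    from .evaluation import select_cutoff, _best_f1_over_cutoffs, _pool_scores

    mcfg = mcfg or ModelConfig()
    tcfg = tcfg or TrainConfig()
    if not dataset:
        raise ValueError("empty training dataset")
    for feats, labels in dataset:
        if feats.length != labels.length:
            raise ValueError("feature tensor and labels disagree on length")

    rng = np.random.default_rng(tcfg.seed)
    order = rng.permutation(len(dataset))
    folds = np.array_split(order, tcfg.n_folds)

    models, histories, oof = [], [], []
    for f, val_idx in enumerate(folds):
        val_set = set(int(i) for i in val_idx)
        train_idx = [int(i) for i in order if int(i) not in val_set]
        if not _has_positives(dataset, train_idx) or not _has_positives(dataset, val_idx):
            warnings.warn(f"fold {f} has no positive pairs; skipped")
            histories.append([])
            continue
        net = PairNet(mcfg, seed=int(rng.integers(2 ** 31)))
        opt = Adam(net.params, tcfg.learning_rate)
        epoch_rng = np.random.default_rng(int(rng.integers(2 ** 31)))
        best_params, best_f1, stall = net.copy_params(), -1.0, 0
        history = []
        for epoch in range(tcfg.max_epochs):
            losses = []
            for i in epoch_rng.permutation(train_idx):
                loss, grads = net.loss_and_grads(dataset[i][0], dataset[i][1],
                                                 tcfg.positive_weight)
                opt.step(net.params, grads)
                losses.append(loss)
            val_pairs = [(net.forward(dataset[int(i)][0]), dataset[int(i)][1])
                         for i in val_idx]
            scores, truths = _pool_scores(val_pairs)
            val_f1, val_cut = _best_f1_over_cutoffs(scores, truths)
            history.append({"fold": f, "epoch": epoch,
                            "train_loss": float(np.mean(losses)),
                            "val_f1": val_f1, "val_cutoff": val_cut})
            logger.info("fold %d epoch %d: loss %.4f, val F1 %.4f at cutoff %.3f",
                        f, epoch, history[-1]["train_loss"], val_f1, val_cut)
            if val_f1 > best_f1 + 1e-6:
                best_f1, best_params, stall = val_f1, net.copy_params(), 0
            else:
                stall += 1
                if stall > tcfg.patience:
                    break
        net.params = best_params
        models.append(net)
        histories.append(history)
        oof.extend((net.forward(dataset[int(i)][0]), dataset[int(i)][1])
                   for i in val_idx)
    if not models:
        raise ValueError("all folds were degenerate; nothing was trained")
    cutoff = select_cutoff(oof)
    return EnsembleModel(models=models, config=mcfg, cutoff=cutoff), histories


def predict(ensemble: EnsembleModel, features: FeatureTensor) -> PairingProbMap:
    """Ensemble prediction: the arithmetic mean of the per-fold outputs."""
    return ensemble.predict(features)
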