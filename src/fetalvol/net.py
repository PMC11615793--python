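"""3D encoder-decoder segmentation network, implemented in NumPy.

The architecture is a U-Net-style encoder-decoder: each encoder level is a
convolution (kernel 5 or 3) + batch normalization + ReLU with ``f * 2**level``
filters followed by 2×2×2 max pooling; the bottleneck adds dropout; each
decoder level nearest-neighbour upsamples, projects channels down with a 1³
convolution, concatenates the matching encoder feature map (skip
connection), and applies another convolution block.  A final 1³ convolution
and per-voxel 2-class softmax produce background/intracranial probabilities
at the input resolution.

Forward and backward passes are written directly against NumPy: convolution
as an im2col matrix product (input gradients via the transposed, spatially
flipped kernel, which for odd kernels and same-padding is again a single
im2col product), and Adam for optimization with the sparse categorical
cross-entropy loss.  Normalization statistics are computed per sample over
the spatial dimensions — the stable choice when gradient steps accumulate
volume by volume — and identically at inference, so prediction is
deterministic.

Tie rule: a voxel whose two softmax probabilities are exactly equal is
labelled background, the conservative choice for volume estimates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .volumes import BinaryMask, Volume

__all__ = [
    "NetworkConfig",
    "TrainedNetwork",
    "build_network",
    "train_network",
    "predict_mask",
    "save_checkpoint",
    "load_checkpoint",
]

DTYPE = np.float32

F_BOUNDS = (8, 64)
BATCH_BOUNDS = (16, 64)
LR_BOUNDS = (1e-4, 1e-2)


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of one network.

    ``base_filters`` (f), ``batch_size`` and ``learning_rate`` are the three
    searched hyperparameters; the remainder are architectural/training
    settings with declared defaults (3 encoder levels, kernel 5 at the first
    level then 3, dropout 0.5 at the bottleneck, 50 epochs).
    """

    base_filters: int = 16
    batch_size: int = 16
    learning_rate: float = 1e-3
    depth: int = 3
    kernel_sizes: tuple[int, ...] = ()
    dropout_rate: float = 0.5
    input_shape: tuple[int, int, int] = (128, 128, 128)
    epochs: int = 50
    steps_per_epoch: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not F_BOUNDS[0] <= self.base_filters <= F_BOUNDS[1]:
            raise ValueError(f"base_filters must be in {F_BOUNDS}")
        if not BATCH_BOUNDS[0] <= self.batch_size <= BATCH_BOUNDS[1]:
            raise ValueError(f"batch_size must be in {BATCH_BOUNDS}")
        if not LR_BOUNDS[0] <= self.learning_rate <= LR_BOUNDS[1]:
            raise ValueError(f"learning_rate must be in {LR_BOUNDS}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        ks = self.kernel_sizes or (5,) + (3,) * (self.depth - 1)
        if len(ks) != self.depth:
            raise ValueError("kernel_sizes must have one entry per level")
        if any(k not in (3, 5) for k in ks):
            raise ValueError("kernel sizes must be 3 or 5")
        object.__setattr__(self, "kernel_sizes", tuple(ks))
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        shape = tuple(int(s) for s in self.input_shape)
        object.__setattr__(self, "input_shape", shape)
        step = 2**self.depth
        if any(s % step != 0 for s in shape):
            raise ValueError(
                f"input_shape {shape} must be divisible by 2**depth = {step}"
            )

    def with_(self, **kw) -> "NetworkConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class _Conv:
    """Same-padded 3D convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int, rng) -> None:
        fan_in = c_in * k**3
        self.W = (rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)).astype(
            DTYPE
        )
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        self._col = None
        self.zero_grad()

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # channels-last (D, H, W, C); window trailing order is (C, k, k, k),
        # matching the weight layout, so no transpose copy is needed
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((p, p), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(xp, (k, k, k), axis=(0, 1, 2))
        return win.reshape(-1, self.c_in * k**3)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape[:3]
        col = self._im2col(x)
        if training:
            self._col = col
        out = col @ self.W.T + self.b
        return out.reshape(*self._shape, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dflat = dout.reshape(-1, self.c_out)
        self.gW += (dflat.T @ self._col).astype(DTYPE)
        self.gb += dflat.sum(axis=0).astype(DTYPE)
        self._col = None
        # input gradient = same-padded convolution with flipped/transposed W
        k = self.k
        w = self.W.reshape(self.c_out, self.c_in, k, k, k)
        w_t = np.ascontiguousarray(
            w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        ).reshape(self.c_in, self.c_out * k**3)
        p = k // 2
        dp = np.pad(dout, ((p, p), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(dp, (k, k, k), axis=(0, 1, 2))
        col = win.reshape(-1, self.c_out * k**3)
        dx = col @ w_t.T
        return dx.reshape(*self._shape, self.c_in)

    def zero_grad(self) -> None:
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params_grads(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class _Norm:
    """Channel-wise normalization over the spatial dimensions of one sample,
    with learned scale and shift (batch-norm statistics at batch size one;
    identical at train and inference)."""

    EPS = 1e-5

    def __init__(self, c: int) -> None:
        self.gamma = np.ones(c, dtype=DTYPE)
        self.beta = np.zeros(c, dtype=DTYPE)
        self.c = c
        self.zero_grad()

    @property
    def n_params(self) -> int:
        return 2 * self.c

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        flat = x.reshape(-1, self.c)
        mu = flat.mean(axis=0)
        var = flat.var(axis=0)
        ivar = 1.0 / np.sqrt(var + self.EPS)
        xhat = (flat - mu) * ivar
        if training:
            self._xhat, self._ivar = xhat, ivar
        out = self.gamma * xhat + self.beta
        return out.reshape(x.shape).astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        shape = dout.shape
        dflat = dout.reshape(-1, self.c)
        n = dflat.shape[0]
        xhat, ivar = self._xhat, self._ivar
        self.ggamma += (dflat * xhat).sum(axis=0).astype(DTYPE)
        self.gbeta += dflat.sum(axis=0).astype(DTYPE)
        dxhat = dflat * self.gamma
        dx = (
            ivar
            / n
            * (
                n * dxhat
                - dxhat.sum(axis=0)
                - xhat * (dxhat * xhat).sum(axis=0)
            )
        )
        self._xhat = self._ivar = None
        return dx.reshape(shape).astype(DTYPE)

    def zero_grad(self) -> None:
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)

    def params_grads(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]


class _ReLU:
    n_params = 0

    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        out = dout * self._mask
        self._mask = None
        return out

    def zero_grad(self):
        pass

    def params_grads(self):
        return []


class _MaxPool2:
    n_params = 0

    def forward(self, x, training):
        d, h, w, c = x.shape
        r = x.reshape(d // 2, 2, h // 2, 2, w // 2, 2, c)
        out = r.max(axis=(1, 3, 5))
        mask = r == out[:, None, :, None, :, None, :]
        # break ties deterministically: keep only the first max per window
        flat = mask.transpose(0, 2, 4, 6, 1, 3, 5).reshape(-1, 8)
        first = np.zeros_like(flat)
        first[np.arange(flat.shape[0]), flat.argmax(axis=1)] = True
        self._mask = first.reshape(
            d // 2, h // 2, w // 2, c, 2, 2, 2
        ).transpose(0, 4, 1, 5, 2, 6, 3)
        self._in_shape = x.shape
        return out

    def backward(self, dout):
        grad = self._mask * dout[:, None, :, None, :, None, :]
        self._mask = None
        return grad.reshape(self._in_shape)

    def zero_grad(self):
        pass

    def params_grads(self):
        return []


class _Upsample2:
    n_params = 0

    def forward(self, x, training):
        return np.repeat(np.repeat(np.repeat(x, 2, axis=0), 2, axis=1), 2, axis=2)

    def backward(self, dout):
        d, h, w, c = dout.shape
        return dout.reshape(d // 2, 2, h // 2, 2, w // 2, 2, c).sum(axis=(1, 3, 5))

    def zero_grad(self):
        pass

    def params_grads(self):
        return []


class _Dropout:
    n_params = 0

    def __init__(self, rate: float, rng) -> None:
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        out = dout * self._mask
        self._mask = None
        return out

    def zero_grad(self):
        pass

    def params_grads(self):
        return []


class _Block:
    """conv + norm + ReLU."""

    def __init__(self, c_in, c_out, k, rng):
        self.layers = [_Conv(c_in, c_out, k, rng), _Norm(c_out), _ReLU()]

    @property
    def n_params(self):
        return sum(l.n_params for l in self.layers)

    def forward(self, x, training):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout

    def zero_grad(self):
        for l in self.layers:
            l.zero_grad()

    def params_grads(self):
        return [pg for l in self.layers for pg in l.params_grads()]


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

class SegmentationNetwork:
    """Untrained/trainable encoder-decoder built from a NetworkConfig."""

    def __init__(self, config: NetworkConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        self._dropout_rng = np.random.default_rng(config.seed + 1)
        f = config.base_filters
        L = config.depth
        ks = config.kernel_sizes

        self.enc_blocks = []
        self.pools = []
        c = 1
        for lvl in range(L):
            c_out = f * 2**lvl
            self.enc_blocks.append(_Block(c, c_out, ks[lvl], rng))
            self.pools.append(_MaxPool2())
            c = c_out
        self.bottleneck = _Block(c, f * 2**L, 3, rng)
        self.dropout = _Dropout(config.dropout_rate, self._dropout_rng)

        self.ups = []
        self.up_projs = []
        self.dec_blocks = []
        c = f * 2**L
        for lvl in reversed(range(L)):
            c_skip = f * 2**lvl
            self.ups.append(_Upsample2())
            self.up_projs.append(_Block(c, c_skip, 1, rng))
            self.dec_blocks.append(_Block(2 * c_skip, c_skip, 3, rng))
            c = c_skip
        self.head = _Conv(c, 2, 1, rng)

        self._all_layers = (
            self.enc_blocks
            + self.pools
            + [self.bottleneck, self.dropout]
            + self.ups
            + self.up_projs
            + self.dec_blocks
            + [self.head]
        )

    # -- introspection ------------------------------------------------------
    @property
    def level_filters(self) -> tuple[int, ...]:
        f, L = self.config.base_filters, self.config.depth
        return tuple(f * 2**lvl for lvl in range(L))

    def num_parameters(self) -> int:
        return sum(l.n_params for l in self._all_layers)

    # -- forward / backward -------------------------------------------------
    def _forward_cl(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Channels-last core: input ``(D,H,W)``, softmax probs ``(D,H,W,2)``."""
        if tuple(x.shape) != self.config.input_shape:
            raise ValueError(
                f"input shape {x.shape} != configured {self.config.input_shape}"
            )
        a = np.asarray(x, dtype=DTYPE)[..., None]
        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            a = blk.forward(a, training)
            skips.append(a)
            a = pool.forward(a, training)
        a = self.bottleneck.forward(a, training)
        a = self.dropout.forward(a, training)
        for up, proj, blk, skip in zip(
            self.ups, self.up_projs, self.dec_blocks, reversed(skips)
        ):
            a = up.forward(a, training)
            a = proj.forward(a, training)
            a = np.concatenate([skip, a], axis=-1)
            a = blk.forward(a, training)
        logits = self.head.forward(a, training)
        logits = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=-1, keepdims=True)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Input ``(D,H,W)`` in [0,1]; returns softmax probs ``(2,D,H,W)``."""
        return np.moveaxis(self._forward_cl(x, training), -1, 0)

    def _backward(self, dlogits: np.ndarray) -> None:
        grad = self.head.backward(dlogits)
        L = self.config.depth
        skip_grads = [None] * L
        # decoder stages were applied i = 0..L-1 (deepest first); unwind them
        # in reverse
        for i in reversed(range(L)):
            lvl = L - 1 - i
            grad = self.dec_blocks[i].backward(grad)
            c_skip = self.config.base_filters * 2**lvl
            skip_grads[lvl] = grad[..., :c_skip]
            grad = self.up_projs[i].backward(grad[..., c_skip:])
            grad = self.ups[i].backward(grad)
        grad = self.dropout.backward(grad)
        grad = self.bottleneck.backward(grad)
        for lvl in reversed(range(L)):
            grad = self.pools[lvl].backward(grad)
            grad = grad + skip_grads[lvl]
            grad = self.enc_blocks[lvl].backward(grad)

    def zero_grad(self) -> None:
        for l in self._all_layers:
            l.zero_grad()

    def params_grads(self):
        return [pg for l in self._all_layers for pg in l.params_grads()]

    # -- weights ------------------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p for p, _ in self.params_grads()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.get_weights()
        if len(own) != len(weights):
            raise ValueError("weight list length mismatch")
        for dst, src in zip(own, weights):
            if dst.shape != src.shape:
                raise ValueError("weight shape mismatch")
            dst[...] = src


@dataclass
class TrainedNetwork:
    """A fitted network: its config, weights (inside ``network``) and the
    per-epoch training history (loss / voxel accuracy / DSC)."""

    config: NetworkConfig
    network: SegmentationNetwork
    history: dict = field(default_factory=dict)


def build_network(cfg: NetworkConfig) -> SegmentationNetwork:
    """Instantiate an untrained network from a config."""
    return SegmentationNetwork(cfg)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params_grads, lr):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params_grads]
        self.v = [np.zeros_like(p) for p, _ in params_grads]

    def step(self, params_grads):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for (p, g), m, v in zip(params_grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _loss_and_grad(probs: np.ndarray, labels: np.ndarray):
    """Sparse categorical cross-entropy (mean over voxels) and the gradient
    at the logits; ``probs`` is channels-last (D,H,W,2)."""
    n = labels.size
    lab = labels.reshape(-1)
    p = probs.reshape(-1, 2)
    p_true = np.clip(p[np.arange(n), lab], 1e-12, None)
    loss = float(-np.mean(np.log(p_true)))
    grad = p.copy()
    grad[np.arange(n), lab] -= 1.0
    grad /= n
    return loss, grad.reshape(probs.shape).astype(DTYPE)


def _soft_metrics(probs: np.ndarray, labels: np.ndarray):
    pred = probs[..., 1] > probs[..., 0]
    truth = labels > 0
    acc = float(np.mean(pred == truth))
    denom = pred.sum() + truth.sum()
    d = 1.0 if denom == 0 else 2.0 * float(np.sum(pred & truth)) / float(denom)
    return acc, d


def train_network(
    cfg: NetworkConfig,
    train_pairs: list[tuple[Volume, BinaryMask]],
    seed: int | None = None,
) -> TrainedNetwork:
    """Fit a network on (volume, mask) pairs with Adam.

    One epoch iterates over shuffled mini-batches of ``batch_size`` volumes
    (gradients accumulate volume by volume, so memory stays per-volume);
    ``steps_per_epoch`` caps the updates per epoch for scaled-down runs.
    History holds per-epoch mean training loss, voxel accuracy and DSC.
    """
    if not train_pairs:
        raise ValueError("no training data")
    cfg = cfg if seed is None else cfg.with_(seed=seed)
    net = SegmentationNetwork(cfg)
    opt = _Adam(net.params_grads(), cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 17)

    xs = [np.asarray(v.data, dtype=DTYPE) for v, _ in train_pairs]
    ys = [m.data.astype(np.int64) for _, m in train_pairs]
    n = len(xs)
    history = {"loss": [], "accuracy": [], "dsc": []}

    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        batches = [
            order[i : i + cfg.batch_size] for i in range(0, n, cfg.batch_size)
        ]
        if cfg.steps_per_epoch is not None:
            batches = batches[: cfg.steps_per_epoch]
        ep_loss, ep_acc, ep_dsc, seen = 0.0, 0.0, 0.0, 0
        for batch in batches:
            net.zero_grad()
            for i in batch:
                probs = net._forward_cl(xs[i], training=True)
                loss, dlogits = _loss_and_grad(probs, ys[i])
                acc, d = _soft_metrics(probs, ys[i])
                net._backward(dlogits)
                ep_loss += loss
                ep_acc += acc
                ep_dsc += d
                seen += 1
            pg = net.params_grads()
            inv = 1.0 / len(batch)
            for _, g in pg:
                g *= inv
            opt.step(pg)
        history["loss"].append(ep_loss / max(seen, 1))
        history["accuracy"].append(ep_acc / max(seen, 1))
        history["dsc"].append(ep_dsc / max(seen, 1))

    return TrainedNetwork(config=cfg, network=net, history=history)


def predict_mask(trained: TrainedNetwork, v: Volume) -> BinaryMask:
    """Argmax segmentation of a volume; exact probability ties go to
    background."""
    if tuple(v.shape) != trained.config.input_shape:
        raise ValueError(
            f"volume shape {v.shape} != network input {trained.config.input_shape}"
        )
    probs = trained.network._forward_cl(v.data, training=False)
    label = (probs[..., 1] > probs[..., 0]).astype(np.uint8)
    return BinaryMask(label, v.grid)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(trained: TrainedNetwork, path) -> None:
    """Serialize weights + config (as JSON metadata) to a single file."""
    meta = json.dumps(
        {"config": asdict(trained.config), "history": trained.history}
    )
    weights = trained.network.get_weights()
    np.savez(
        path,
        meta=np.frombuffer(meta.encode(), dtype=np.uint8),
        **{f"w{i}": w for i, w in enumerate(weights)},
    )


def load_checkpoint(path) -> TrainedNetwork:
    with np.load(path if str(path).endswith(".npz") else f"{path}.npz") as data:
        meta = json.loads(bytes(data["meta"]).decode())
        cfg_d = meta["config"]
        for key in ("kernel_sizes", "input_shape"):
            cfg_d[key] = tuple(cfg_d[key])
        cfg = NetworkConfig(**cfg_d)
        net = SegmentationNetwork(cfg)
        weights = [data[f"w{i}"] for i in range(len(net.get_weights()))]
        net.set_weights(weights)
    return TrainedNetwork(config=cfg, network=net, history=meta["history"])
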