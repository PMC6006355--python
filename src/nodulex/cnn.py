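"""Small multi-channel 2-D CNNs for nodule patches, in pure numpy.

The networks are deliberately shallow: a couple of convolution /
max-pooling blocks feeding two fully-connected layers, the last hidden
layer fixed at 200 units (the "feature layer" exported for the
Random-Forest fusion) and a 2-unit softmax output.  Transverse slices (Z)
enter as input channels, so the convolutions are 2-D but see the full
sub-volume.  Training is mini-batch SGD with momentum on the
cross-entropy, with on-the-fly shift/rotation/scale augmentation, an
inner 80/20 split of the training set redrawn per run, checkpointing on
improved inner-test loss, and retention of the final weights plus the
three checkpoints with the highest inner-test accuracy.

Everything runs on CPU and is deterministic under the configured seeds
(single-threaded BLAS assumed for bit reproducibility).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .patches import PatchRecord, PatchSize

__all__ = [
    "ArchitectureConfig",
    "TrainConfig",
    "TrainedModel",
    "CNN21",
    "CNN47",
    "ARCHITECTURES",
    "build_model",
    "augment",
    "apply_affine",
    "train",
    "predict",
    "extract_features",
    "records_to_arrays",
]

FEATURE_UNITS = 200  # penultimate fully-connected width (exported features)
N_CLASSES = 2


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchitectureConfig:
    """Layer plan: conv blocks with optional pooling, then FC layers.

    ``fc_widths`` lists the hidden fully-connected widths and must end
    with the 200-unit feature layer; the 2-unit softmax output is
    implicit.  ``pool_specs`` aligns with ``conv_blocks`` (None = no
    pooling after that block).  ``dropout_rates`` is (after conv stack,
    after first FC).
    """

    name: str
    input_size: PatchSize
    conv_blocks: tuple[tuple[int, int, int], ...]  # (filter_w, filter_h, n_filters)
    pool_specs: tuple[tuple[int, int, int] | None, ...]  # (w, h, stride)
    dropout_rates: tuple[float, float] = (0.25, 0.5)
    fc_widths: tuple[int, ...] = (512, FEATURE_UNITS)

    def __post_init__(self) -> None:
        if len(self.conv_blocks) != len(self.pool_specs):
            raise ValueError("conv_blocks and pool_specs lengths differ")
        if not self.fc_widths or self.fc_widths[-1] != FEATURE_UNITS:
            raise ValueError(
                f"the last hidden FC layer must have {FEATURE_UNITS} units"
            )
        for spec in self.pool_specs:
            if spec is not None and not (spec[0] == spec[1] == spec[2]):
                raise ValueError("only size == stride pooling is supported")


CNN47 = ArchitectureConfig(
    name="cnn47",
    input_size=PatchSize(47, 47, 5),
    conv_blocks=((5, 5, 32), (3, 3, 64)),
    pool_specs=((2, 2, 2), (2, 2, 2)),
)
CNN21 = ArchitectureConfig(
    name="cnn21",
    input_size=PatchSize(21, 21, 5),
    conv_blocks=((5, 5, 32), (3, 3, 64)),
    pool_specs=((2, 2, 2), None),
)
ARCHITECTURES = {"cnn21": CNN21, "cnn47": CNN47}


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters.

    Epochs of 200-400 match a full run; tests use far fewer.  Shifts are
    bounded by 30% of the patch size per in-plane axis and rotations drawn
    from [0, 180] degrees.
    """

    epochs: int = 200
    batch_size: int = 64
    optimizer: str = "adam"  # "adam" or "sgd" (momentum)
    learning_rate: float = 1e-3
    momentum: float = 0.9
    augmentation: bool = True
    max_shift_fraction: float = 0.30
    rotation_range_deg: tuple[float, float] = (0.0, 180.0)
    scale_jitter: float = 0.10
    inner_split: float = 0.8
    seed: int = 0
    n_best_checkpoints: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.inner_split < 1:
            raise ValueError("inner_split must be in (0, 1)")
        if self.max_shift_fraction > 0.5:
            raise ValueError("max_shift_fraction must be <= 0.5")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Conv2D:
    def __init__(self, in_ch, out_ch, kh, kw, rng):
        fan_in = in_ch * kh * kw
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in))
        self.b = np.zeros(out_ch)
        self.kh, self.kw = kh, kw
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def out_shape(self, c, h, w):
        return (self.w.shape[0], h - self.kh + 1, w - self.kw + 1)

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        oh, ow = h - self.kh + 1, w - self.kw + 1
        cols = sliding_window_view(x, (self.kh, self.kw), axis=(2, 3))
        cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, -1)
        self._cols, self._in_shape = cols, x.shape
        out = cols @ self.w.T + self.b
        return out.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, oc, oh, ow = grad.shape
        g = grad.transpose(0, 2, 3, 1).reshape(-1, oc)
        self.grads[0][...] = g.T @ self._cols
        self.grads[1][...] = g.sum(axis=0)
        dcols = g @ self.w  # (n*oh*ow, c*kh*kw)
        _, c, h, w = self._in_shape
        dcols = dcols.reshape(n, oh, ow, c, self.kh, self.kw)
        dx = np.zeros(self._in_shape)
        for i in range(self.kh):
            for j in range(self.kw):
                dx[:, :, i:i + oh, j:j + ow] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        return dx


class _MaxPool2D:
    def __init__(self, size):
        self.s = size
        self.params, self.grads = [], []

    def out_shape(self, c, h, w):
        return (c, h // self.s, w // self.s)

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        s = self.s
        hc, wc = (h // s) * s, (w // s) * s
        xc = x[:, :, :hc, :wc].reshape(n, c, hc // s, s, wc // s, s)
        out = xc.max(axis=(3, 5))
        self._mask = xc == out[:, :, :, None, :, None]
        self._shape = x.shape
        return out

    def backward(self, grad):
        n, c, oh, ow = grad.shape
        s = self.s
        g = self._mask * grad[:, :, :, None, :, None]
        # split credit among ties so the gradient stays well-defined
        ties = self._mask.sum(axis=(3, 5), keepdims=True)
        g = g / ties
        dx = np.zeros(self._shape)
        dx[:, :, : oh * s, : ow * s] = g.reshape(n, c, oh * s, ow * s)
        return dx


class _ReLU:
    params, grads = [], []

    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class _Dropout:
    def __init__(self, rate):
        self.rate = rate
        self.params, self.grads = [], []

    def forward(self, x, train=False, rng=None):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.uniform(size=x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class _Flatten:
    params, grads = [], []

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class _Dense:
    def __init__(self, n_in, n_out, rng):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.w.T


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class ConvNet:
    """A feed-forward stack built from an :class:`ArchitectureConfig`."""

    def __init__(self, config: ArchitectureConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        c = config.input_size.z
        h, w = config.input_size.y, config.input_size.x
        layers: list = []
        for block, pool in zip(config.conv_blocks, config.pool_specs):
            fw, fh, nf = block
            conv = _Conv2D(c, nf, fh, fw, rng)
            c, h, w = conv.out_shape(c, h, w)
            if h < 1 or w < 1:
                raise ValueError(
                    f"{config.name}: spatial dims collapsed to {h}x{w} after "
                    f"conv {block}; layer trace: {[type(l).__name__ for l in layers]}"
                )
            layers += [conv, _ReLU()]
            if pool is not None:
                mp = _MaxPool2D(pool[2])
                c, h, w = mp.out_shape(c, h, w)
                if h < 1 or w < 1:
                    raise ValueError(
                        f"{config.name}: spatial dims collapsed after pool {pool}"
                    )
                layers.append(mp)
        layers += [_Dropout(config.dropout_rates[0]), _Flatten()]
        n_in = c * h * w
        for i, width in enumerate(config.fc_widths):
            layers += [_Dense(n_in, width, rng), _ReLU()]
            if i == 0 and len(config.fc_widths) > 1:
                layers.append(_Dropout(config.dropout_rates[1]))
            n_in = width
        self.feature_index = len(layers) - 1  # output of the 200-unit ReLU
        layers.append(_Dense(n_in, N_CLASSES, rng))
        self.layers = layers
        self._velocity = [
            [np.zeros_like(p) for p in layer.params] for layer in layers
        ]
        self._adam_m = [
            [np.zeros_like(p) for p in layer.params] for layer in layers
        ]
        self._adam_v = [
            [np.zeros_like(p) for p in layer.params] for layer in layers
        ]
        self._adam_t = 0

    # -- inference ---------------------------------------------------------
    def forward(self, x, train=False, rng=None):
        feats = None
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, train=train, rng=rng)
            if i == self.feature_index:
                feats = x
        return x, feats

    def predict_proba(self, x) -> np.ndarray:
        logits, _ = self.forward(x, train=False)
        return _softmax(logits)

    def penultimate(self, x) -> np.ndarray:
        _, feats = self.forward(x, train=False)
        return feats

    # -- training ----------------------------------------------------------
    def train_step(self, x, y, cfg: "TrainConfig", rng) -> float:
        logits, _ = self.forward(x, train=True, rng=rng)
        probs = _softmax(logits)
        n = x.shape[0]
        loss = float(-np.log(probs[np.arange(n), y] + 1e-12).mean())
        grad = probs
        grad[np.arange(n), y] -= 1.0
        grad /= n
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        if cfg.optimizer == "sgd":
            for layer, vel in zip(self.layers, self._velocity):
                for p, g, v in zip(layer.params, layer.grads, vel):
                    v *= cfg.momentum
                    v -= cfg.learning_rate * g
                    p += v
        else:  # adam
            b1, b2, eps = 0.9, 0.999, 1e-8
            self._adam_t += 1
            t = self._adam_t
            for layer, ms, vs in zip(self.layers, self._adam_m, self._adam_v):
                for p, g, m, v in zip(layer.params, layer.grads, ms, vs):
                    m *= b1
                    m += (1 - b1) * g
                    v *= b2
                    v += (1 - b2) * g * g
                    mhat = m / (1 - b1**t)
                    vhat = v / (1 - b2**t)
                    p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        return loss

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [p for layer in self.layers for p in layer.params]
        if len(flat) != len(weights):
            raise ValueError("weight count mismatch")
        for p, w in zip(flat, weights):
            p[...] = w


def build_model(config: ArchitectureConfig, seed: int = 0) -> ConvNet:
    """Instantiate an untrained network with seeded He-normal weights."""
    return ConvNet(config, seed=seed)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def apply_affine(
    patch: np.ndarray,
    shift_xy: tuple[float, float] = (0.0, 0.0),
    angle_deg: float = 0.0,
    scale: float = 1.0,
) -> np.ndarray:
    """Shift/rotate/scale a (C, H, W) patch in-plane, same transform per channel.

    Bilinear interpolation; out-of-frame samples take the patch minimum.
    Identity parameters return the patch unchanged (no resampling).
    """
    if shift_xy == (0.0, 0.0) and angle_deg == 0.0 and scale == 1.0:
        return patch.copy()
    c, h, w = patch.shape
    theta = np.deg2rad(angle_deg)
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    # output -> input mapping in (row=y, col=x) order
    matrix = rot.T / scale
    matrix[np.abs(matrix) < 1e-12] = 0.0  # exact axis-aligned rotations
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    shift_rc = np.array([shift_xy[1], shift_xy[0]])
    offset = center - matrix @ (center + shift_rc)
    near = np.abs(offset - np.round(offset)) < 1e-9
    offset[near] = np.round(offset[near])
    cval = float(patch.min())
    out = np.empty_like(patch, dtype=float)
    for ch in range(c):
        out[ch] = ndimage.affine_transform(
            patch[ch].astype(float), matrix, offset=offset, order=1,
            mode="constant", cval=cval,
        )
    return out


def augment(patch: np.ndarray, rng: np.random.Generator,
            cfg: TrainConfig) -> np.ndarray:
    """Random shift (<= 30% per axis), rotation (0-180 deg) and scale jitter."""
    _, h, w = patch.shape
    sx = rng.uniform(-cfg.max_shift_fraction, cfg.max_shift_fraction) * w
    sy = rng.uniform(-cfg.max_shift_fraction, cfg.max_shift_fraction) * h
    angle = rng.uniform(*cfg.rotation_range_deg)
    scale = 1.0 + rng.uniform(-cfg.scale_jitter, cfg.scale_jitter)
    return apply_affine(patch, (sx, sy), angle, scale)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def records_to_arrays(
    records: list[PatchRecord], normalize: bool = True
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack patch records into (N, C, H, W) inputs, labels and keys.

    Intensities are rescaled to [0, 1] using each record's whole-scan
    min/max HU (the extremes stored in the patch datasets).
    """
    xs, ys, keys = [], [], []
    for rec in records:
        x = rec.voxels.transpose(2, 1, 0).astype(float)  # (Z, Y, X)
        if normalize:
            span = rec.scan_max_hu - rec.scan_min_hu
            x = (x - rec.scan_min_hu) / (span if span > 0 else 1.0)
        xs.append(x)
        ys.append(rec.class_id)
        keys.append(rec.key)
    return np.stack(xs), np.asarray(ys, dtype=int), keys


@dataclass
class TrainedModel:
    """A trained network plus its training history and retained checkpoints.

    ``retained_checkpoints`` holds the final weights and up to three
    loss-improvement checkpoints with the highest inner-test accuracy
    (at most 4 entries).
    """

    model: ConvNet
    config: ArchitectureConfig
    train_config: TrainConfig
    training_log: list[dict] = field(default_factory=list)
    retained_checkpoints: list[dict] = field(default_factory=list)


def _eval_loss_acc(model: ConvNet, x, y, batch: int = 256) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(x), batch):
        probs = model.predict_proba(x[i:i + batch])
        yi = y[i:i + batch]
        losses.append(-np.log(probs[np.arange(len(yi)), yi] + 1e-12))
        correct += int((probs.argmax(axis=1) == yi).sum())
    return float(np.concatenate(losses).mean()), correct / len(x)


def train(
    x: np.ndarray,
    y: np.ndarray,
    arch: ArchitectureConfig,
    cfg: TrainConfig,
) -> TrainedModel:
    """Train a network on (N, C, H, W) inputs with binary labels.

    The training set is split 80/20 into an inner training and testing
    group (redrawn from ``cfg.seed`` each run); a checkpoint is saved
    whenever the inner-test loss improves, and the final weights plus the
    three highest-accuracy checkpoints are retained.
    """
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(cfg.seed)
    model = build_model(arch, seed=int(rng.integers(2**31 - 1)))

    perm = rng.permutation(len(x))
    n_inner = max(int(round(cfg.inner_split * len(x))), 1)
    n_inner = min(n_inner, len(x) - 1)
    tr_idx, te_idx = perm[:n_inner], perm[n_inner:]
    xtr, ytr = x[tr_idx], y[tr_idx]
    xte, yte = x[te_idx], y[te_idx]

    log: list[dict] = []
    checkpoints: list[dict] = []
    best_loss = np.inf
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(xtr))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = xtr[idx]
            if cfg.augmentation:
                xb = np.stack([augment(p, rng, cfg) for p in xb])
            epoch_losses.append(model.train_step(xb, ytr[idx], cfg, rng))
        test_loss, test_acc = _eval_loss_acc(model, xte, yte)
        log.append(
            dict(epoch=epoch, train_loss=float(np.mean(epoch_losses)),
                 test_loss=test_loss, test_accuracy=test_acc)
        )
        if test_loss < best_loss:
            best_loss = test_loss
            checkpoints.append(
                dict(epoch=epoch, test_loss=test_loss, test_accuracy=test_acc,
                     weights=model.get_weights())
            )

    best = sorted(
        checkpoints, key=lambda c: (-c["test_accuracy"], c["test_loss"])
    )[: cfg.n_best_checkpoints]
    retained = [
        dict(epoch=len(log) - 1, kind="final", weights=model.get_weights())
    ] + [dict(kind="checkpoint", **c) for c in best]
    return TrainedModel(
        model=model, config=arch, train_config=cfg, training_log=log,
        retained_checkpoints=retained,
    )


def predict(trained: TrainedModel | ConvNet, x: np.ndarray) -> np.ndarray:
    """Per-patch probability of the positive class, batch order preserved."""
    model = trained.model if isinstance(trained, TrainedModel) else trained
    expected = (model.config.input_size.z, model.config.input_size.y,
                model.config.input_size.x)
    if x.shape[1:] != expected:
        raise ValueError(f"input shape {x.shape[1:]} != expected {expected}")
    return model.predict_proba(x)[:, 1]


def extract_features(trained: TrainedModel | ConvNet, x: np.ndarray) -> np.ndarray:
    """Penultimate-layer activations: one 200-value vector per patch."""
    model = trained.model if isinstance(trained, TrainedModel) else trained
    feats = model.penultimate(x)
    assert feats.shape[1] == FEATURE_UNITS
    return feats
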