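"""Convolutional feature extraction and synthetic image fixtures.

A small three-conv-layer network (12, 14, 8 filters of 5x5, each layer
followed by 2x2 max pooling) compresses a 40x40 RGB image into eight 5x5
feature maps. The network is trained once as a classifier (flatten +
3-way softmax head, Adam, cross-entropy, early stopping on validation
loss), after which the head is discarded and the convolutional stack is
used as a fixed feature extractor. Feature maps are min-max normalized
to [0, 1] per map so they can drive the latency transform of the pulse
encoder.

The network is implemented directly in NumPy (im2col convolutions with
exact gradients); it is small enough that a few hundred 40x40 images
train in seconds on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from PIL import Image as PILImage

__all__ = [
    "Image",
    "ExtractorConfig",
    "ExtractorParams",
    "FeatureMapSet",
    "relu",
    "generate_synthetic_images",
    "train_feature_extractor",
    "extract_features",
]

CLASS_NAMES = ("apple", "car", "cup")


def relu(x):
    """Rectified linear unit: x for x > 0, else 0. Rejects non-finite input."""
    arr = np.asarray(x, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("relu requires finite input")
    out = np.maximum(arr, 0.0)
    return float(out) if np.isscalar(x) else out


@dataclass
class Image:
    """An RGB raster with intensities in [0, 1] and an optional class label."""

    pixels: np.ndarray
    label: int | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError("image must be height x width x 3")
        if not np.isfinite(p).all() or p.min() < 0 or p.max() > 1:
            raise ValueError("pixel intensities must be finite and in [0, 1]")
        self.pixels = p

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class ExtractorConfig:
    filters_per_layer: tuple[int, int, int] = (12, 14, 8)
    kernel_size: int = 5
    conv_stride: int = 1
    pool_size: int = 2
    pool_stride: int = 2
    input_side: int = 40
    learning_rate: float = 0.0005
    max_epochs: int = 50
    patience: int = 5
    batch_size: int = 16
    n_classes: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.filters_per_layer) != 3:
            raise ValueError("three conv layers expected")
        if self.filters_per_layer[-1] != 8:
            raise ValueError("last conv layer must have 8 filters (8 channels)")
        side = self.input_side
        for _ in range(3):
            if side % 2:
                raise ValueError("input_side must pool down evenly three times")
            side //= 2
        if side != 5:
            raise ValueError(
                "input_side must reduce to 5 after three 2x poolings (use 40)"
            )


@dataclass
class ExtractorParams:
    """Trained convolution weights plus training metadata.

    ``weights[l]`` has shape (filters, k, k, in_channels); ``biases[l]``
    has shape (filters,). The classification head used during training
    is kept only for bookkeeping.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    head_w: np.ndarray
    head_b: np.ndarray
    config: ExtractorConfig
    val_loss: float = float("nan")
    val_accuracy: float = float("nan")
    epochs_run: int = 0
    loss_history: list[float] = field(default_factory=list)


@dataclass
class FeatureMapSet:
    """Eight 5x5 feature maps with values min-max normalized to [0, 1]."""

    maps: np.ndarray
    source: str | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.maps, dtype=float)
        if m.shape != (8, 5, 5):
            raise ValueError("expected 8 maps of shape 5x5")
        if not np.isfinite(m).all() or m.min() < -1e-12 or m.max() > 1 + 1e-12:
            raise ValueError("feature map values must lie in [0, 1]")
        self.maps = np.clip(m, 0.0, 1.0)


# ---------------------------------------------------------------------------
# synthetic image fixtures (stand-in for a small 3-class object dataset)
# ---------------------------------------------------------------------------

def _disc(yy, xx, cy, cx, r):
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def generate_synthetic_images(
    n_per_class: int, side: int = 40, seed: int = 0
) -> list[Image]:
    """Generate three visually distinct silhouette classes.

    Class 0 ("apple"): a filled reddish disc. Class 1 ("car"): an
    elongated bluish rectangle with two dark wheels. Class 2 ("cup"): a
    grey-green disc body with a rectangular handle. Per-image jitter in
    position, scale and hue; deterministic given the seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if side < 40:
        raise ValueError("side must be >= 40 (extractor geometry)")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    images: list[Image] = []
    for label in range(3):
        for _ in range(n_per_class):
            img = rng.uniform(0.0, 0.08, size=(side, side, 3))
            cy = side * (0.5 + rng.uniform(-0.08, 0.08))
            cx = side * (0.5 + rng.uniform(-0.08, 0.08))
            scale = 1.0 + rng.uniform(-0.15, 0.15)
            if label == 0:  # apple: filled disc, red-dominant
                r = 0.28 * side * scale
                mask = _disc(yy, xx, cy, cx, r)
                color = np.array(
                    [rng.uniform(0.7, 0.95), rng.uniform(0.05, 0.3), rng.uniform(0.05, 0.2)]
                )
                img[mask] = color
            elif label == 1:  # car: wide rectangle + wheels, blue-dominant
                h = 0.14 * side * scale
                w = 0.38 * side * scale
                body = (np.abs(yy - cy) <= h) & (np.abs(xx - cx) <= w)
                color = np.array(
                    [rng.uniform(0.05, 0.25), rng.uniform(0.1, 0.35), rng.uniform(0.6, 0.95)]
                )
                img[body] = color
                for dx in (-0.6 * w, 0.6 * w):
                    wheel = _disc(yy, xx, cy + h, cx + dx, 0.3 * h + 1.5)
                    img[wheel] = 0.12
            else:  # cup: disc body + handle, green-grey
                r = 0.24 * side * scale
                body = _disc(yy, xx, cy, cx, r)
                handle = (np.abs(yy - cy) <= 0.45 * r) & (
                    (xx - cx >= r * 0.8) & (xx - cx <= r * 1.6)
                )
                color = np.array(
                    [rng.uniform(0.3, 0.5), rng.uniform(0.55, 0.8), rng.uniform(0.3, 0.5)]
                )
                img[body | handle] = color
            img += rng.normal(0.0, 0.02, size=img.shape)
            images.append(Image(pixels=np.clip(img, 0.0, 1.0), label=label))
    return images


# ---------------------------------------------------------------------------
# NumPy CNN: im2col convolutions with exact gradients
# ---------------------------------------------------------------------------

def _resize(pixels: np.ndarray, side: int) -> np.ndarray:
    if pixels.shape[0] == side and pixels.shape[1] == side:
        return pixels
    im = PILImage.fromarray((pixels * 255).astype(np.uint8))
    im = im.resize((side, side), PILImage.BILINEAR)
    return np.asarray(im, dtype=float) / 255.0


def _conv_same(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Stride-1 zero-padded convolution, NHWC layout, kernel (F,k,k,C)."""
    k = w.shape[1]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # N,H,W,C,k,k
    return np.einsum("nhwcij,fijc->nhwf", win, w, optimize=True) + b


def _conv_same_backward(x, w, dout):
    k = w.shape[1]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))
    dw = np.einsum("nhwcij,nhwf->fijc", win, dout, optimize=True)
    db = dout.sum(axis=(0, 1, 2))
    dp = np.pad(dout, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    dwin = sliding_window_view(dp, (k, k), axis=(1, 2))  # N,H,W,F,k,k
    w_rot = w[:, ::-1, ::-1, :]
    dx = np.einsum("nhwfij,fijc->nhwc", dwin, w_rot, optimize=True)
    return dx, dw, db


def _pool2(x: np.ndarray):
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
    flat = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _pool2_backward(dout, idx, in_shape):
    n, h, w, c = in_shape
    dflat = np.zeros((n, h // 2, w // 2, c, 4))
    np.put_along_axis(dflat, idx[..., None], dout[..., None], axis=-1)
    dx = dflat.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
    return dx.reshape(n, h, w, c)


def _forward_conv_stack(x, params):
    caches = []
    a = x
    for w, b in zip(params.weights, params.biases):
        z = _conv_same(a, w, b)
        r = np.maximum(z, 0.0)
        p, idx = _pool2(r)
        caches.append((a, z, r, idx))
        a = p
    return a, caches


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, shapes, lr):
        self.lr = lr
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mh = self.m[i] / (1 - b1**self.t)
            vh = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + eps)


def _init_params(cfg: ExtractorConfig, rng: np.random.Generator) -> ExtractorParams:
    k = cfg.kernel_size
    chans = (3,) + cfg.filters_per_layer
    weights, biases = [], []
    for cin, cout in zip(chans[:-1], chans[1:]):
        std = np.sqrt(2.0 / (k * k * cin))
        weights.append(rng.normal(0.0, std, size=(cout, k, k, cin)))
        biases.append(np.zeros(cout))
    flat = 5 * 5 * cfg.filters_per_layer[-1]
    head_w = rng.normal(0.0, np.sqrt(2.0 / flat), size=(flat, cfg.n_classes))
    head_b = np.zeros(cfg.n_classes)
    return ExtractorParams(
        weights=weights, biases=biases, head_w=head_w, head_b=head_b, config=cfg
    )


def _batch_pixels(images: Sequence[Image], side: int) -> np.ndarray:
    return np.stack([_resize(im.pixels, side) for im in images])


def _loss_and_grads(x, y_onehot, params):
    feat, caches = _forward_conv_stack(x, params)
    n = x.shape[0]
    flat = feat.reshape(n, -1)
    logits = flat @ params.head_w + params.head_b
    prob = _softmax(logits)
    loss = -np.log(np.clip(prob[np.arange(n), y_onehot.argmax(1)], 1e-12, None)).mean()
    dlogit = (prob - y_onehot) / n
    dhw = flat.T @ dlogit
    dhb = dlogit.sum(0)
    dflat = dlogit @ params.head_w.T
    da = dflat.reshape(feat.shape)
    dws, dbs = [], []
    for (a, z, r, idx), w in zip(reversed(caches), reversed(params.weights)):
        dr = _pool2_backward(da, idx, r.shape)
        dz = dr * (z > 0)
        da, dw, db = _conv_same_backward(a, w, dz)
        dws.append(dw)
        dbs.append(db)
    return loss, prob, list(reversed(dws)), list(reversed(dbs)), dhw, dhb


def _evaluate(x, y, params):
    feat, _ = _forward_conv_stack(x, params)
    flat = feat.reshape(x.shape[0], -1)
    prob = _softmax(flat @ params.head_w + params.head_b)
    loss = -np.log(np.clip(prob[np.arange(len(y)), y], 1e-12, None)).mean()
    acc = float((prob.argmax(1) == y).mean())
    return float(loss), acc


def train_feature_extractor(
    train: Sequence[Image],
    val: Sequence[Image],
    cfg: ExtractorConfig = ExtractorConfig(),
) -> ExtractorParams:
    """Train the six-layer extractor (+ temporary softmax head).

    Adam on the cross-entropy loss, early stopping on validation loss
    with best-weight restore. Deterministic given ``cfg.seed``.
    """
    if cfg.max_epochs < 1:
        raise ValueError("max_epochs must be >= 1 to train the extractor")
    labels = sorted({im.label for im in train})
    if len(labels) < 2:
        raise ValueError("training set must contain at least 2 classes")
    if not val:
        raise ValueError("validation set required for early stopping")
    rng = np.random.default_rng(cfg.seed)
    params = _init_params(cfg, rng)
    xtr = _batch_pixels(train, cfg.input_side)
    ytr = np.array([labels.index(im.label) for im in train])
    onehot = np.eye(cfg.n_classes)[ytr]
    xva = _batch_pixels(val, cfg.input_side)
    yva = np.array([labels.index(im.label) for im in val])

    tensors = params.weights + params.biases + [params.head_w, params.head_b]
    opt = _Adam([t.shape for t in tensors], cfg.learning_rate)
    best = None
    best_loss = np.inf
    wait = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(xtr))
        ep_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            loss, _, dws, dbs, dhw, dhb = _loss_and_grads(
                xtr[sel], onehot[sel], params
            )
            opt.step(tensors, dws + dbs + [dhw, dhb])
            ep_loss += loss * len(sel)
        params.loss_history.append(ep_loss / len(order))
        vloss, vacc = _evaluate(xva, yva, params)
        params.epochs_run = epoch + 1
        if vloss < best_loss - 1e-9:
            best_loss = vloss
            best = ([w.copy() for w in params.weights],
                    [b.copy() for b in params.biases],
                    params.head_w.copy(), params.head_b.copy(), vloss, vacc)
            wait = 0
        else:
            wait += 1
            if wait >= cfg.patience:
                break
    if best is not None:
        params.weights, params.biases, params.head_w, params.head_b, \
            params.val_loss, params.val_accuracy = best
    return params


def extract_features(img: Image, params: ExtractorParams) -> FeatureMapSet:
    """Apply the fixed extractor: image -> eight 5x5 normalized maps.

    Each map is min-max scaled to [0, 1] independently; a constant map
    scales to all zeros.
    """
    for w, f in zip(params.weights, params.config.filters_per_layer):
        if w.shape[0] != f:
            raise ValueError("extractor parameters inconsistent with config")
    x = _resize(np.asarray(img.pixels, dtype=float), params.config.input_side)
    feat, _ = _forward_conv_stack(x[None], params)  # 1,5,5,8
    maps = feat[0].transpose(2, 0, 1)  # 8,5,5
    lo = maps.min(axis=(1, 2), keepdims=True)
    hi = maps.max(axis=(1, 2), keepdims=True)
    span = hi - lo
    out = np.where(span > 1e-12, (maps - lo) / np.where(span > 1e-12, span, 1.0), 0.0)
    src = str(img.label) if img.label is not None else None
    return FeatureMapSet(maps=out, source=src)
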