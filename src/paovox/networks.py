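"""3D encoder–decoder networks with skip connections (EDS), in pure numpy.

Two identical volume-to-volume networks are used: network A regresses the
per-voxel blood oxygen saturation and network B the vessel segmentation;
they differ only in their training targets.  The architecture is a
U-Net-like encoder–decoder: per scale two 3x3x3 convolutions with ReLU,
2x max-pool downsampling, 2x transposed-convolution upsampling, and skip
concatenation at matching scales — deliberately smaller than the classic
U-Net (fewer scales and channels) to limit the receptive field.

The implementation is deliberately framework-free: forward and backward
passes are written against numpy primitives (im2col convolutions, explicit
col2im gradients) and optimized with Adam.  Everything is deterministic
given the seeds, so training runs are bit-reproducible on CPU.

Input image sets are normalized by a single scalar — the maximum absolute
value over all four wavelength channels — so the inter-wavelength amplitude
ratios that encode sO2 are preserved (per-channel normalization would
destroy them).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "EDSConfig",
    "TrainConfig",
    "EDSNet",
    "TrainResult",
    "normalize_image_set",
    "squared_error_loss",
    "build_eds",
    "train",
    "predict",
]


@dataclass(frozen=True)
class EDSConfig:
    """Architecture parameters.

    ``base_channels`` feature maps at the finest scale, doubling per scale
    over ``n_scales`` scales; 3x3x3 kernels, 2x max-pool / transposed-conv
    resampling, concatenation skips; 4 input channels (one per wavelength),
    1 output channel.
    """

    n_scales: int = 3
    base_channels: int = 16
    in_channels: int = 4
    out_channels: int = 1
    dtype: type = np.float32

    def __post_init__(self) -> None:
        if self.n_scales < 1 or self.base_channels < 1:
            raise ValueError("n_scales and base_channels must be >= 1")

    def channels(self, scale: int) -> int:
        return self.base_channels * 2**scale

    def check_shape(self, spatial: tuple[int, int, int]) -> None:
        div = 2 ** (self.n_scales - 1)
        bad = [n for n in spatial if n % div]
        if bad:
            raise ValueError(
                f"spatial dims {spatial} not divisible by {div}; pad the "
                f"volume to multiples of {div} before building the network"
            )


@dataclass(frozen=True)
class TrainConfig:
    """Adam training parameters with validation-based early stopping."""

    lr: float = 1e-4
    batch_size: int = 5
    max_epochs: int = 150
    patience: int = 10
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


def normalize_image_set(images: np.ndarray) -> np.ndarray:
    """Scale a multi-channel image set by its single global max |value|.

    All channels are divided by one scalar so the inter-wavelength ratios
    (the spectral information) are untouched; the result has max |value| 1.
    An all-zero set is returned unchanged with a warning.
    """
    images = np.asarray(images, dtype=np.float64)
    peak = float(np.max(np.abs(images)))
    if peak == 0.0:
        warnings.warn("all-zero image set: normalization skipped", stacklevel=2)
        return images.copy()
    return images / peak


def squared_error_loss(
    pred: np.ndarray, target: np.ndarray, reduction: str = "mean"
) -> float:
    """Squared L2 training loss over all voxels.

    ``reduction='sum'`` is the plain squared L2 norm of the difference;
    ``'mean'`` divides by the voxel count (the default used for training —
    the normalization constant only rescales the loss curve).
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError("prediction and target shapes differ")
    sq = float(np.sum((pred - target) ** 2))
    if reduction == "sum":
        return sq
    if reduction == "mean":
        return sq / pred.size
    raise ValueError(f"unknown reduction {reduction!r}")


# ---------------------------------------------------------------------------
# layer primitives (single sample: channel-first volumes)


def _conv3_forward(x, W, b):
    """Same-padded 3x3x3 convolution as 27 shifted GEMMs.

    Returns (y, padded input) — the padded input is the backward cache.
    """
    c_out = W.shape[0]
    c_in, D, H, Wd = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    N = D * H * Wd
    yf = np.zeros((c_out, N), dtype=W.dtype)
    for dz in range(3):
        for dh in range(3):
            for dw in range(3):
                xs = xp[:, dz : dz + D, dh : dh + H, dw : dw + Wd].reshape(
                    c_in, N
                )
                yf += W[:, :, dz, dh, dw] @ xs
    y = yf.reshape(c_out, D, H, Wd) + b[:, None, None, None]
    return y, xp


def _conv3_backward(dy, xp, W, x_shape):
    """Gradients of the same-padded 3x3x3 convolution."""
    c_out = W.shape[0]
    c_in, D, H, Wd = x_shape
    N = D * H * Wd
    dyf = np.ascontiguousarray(dy.reshape(c_out, N))
    db = dyf.sum(axis=1)
    dW = np.empty_like(W)
    dxp = np.zeros_like(xp)
    for dz in range(3):
        for dh in range(3):
            for dw in range(3):
                xs = xp[:, dz : dz + D, dh : dh + H, dw : dw + Wd].reshape(
                    c_in, N
                )
                dW[:, :, dz, dh, dw] = dyf @ xs.T
                dxp[:, dz : dz + D, dh : dh + H, dw : dw + Wd] += (
                    W[:, :, dz, dh, dw].T @ dyf
                ).reshape(c_in, D, H, Wd)
    return dxp[:, 1:-1, 1:-1, 1:-1], dW, db


def _pool_forward(x):
    """2x2x2 max pooling; gradient is split evenly across tied maxima."""
    c, D, H, W = x.shape
    xr = x.reshape(c, D // 2, 2, H // 2, 2, W // 2, 2)
    y = xr.max(axis=(2, 4, 6))
    mask = xr == y[:, :, None, :, None, :, None]
    norm = mask.sum(axis=(2, 4, 6), keepdims=True)
    return y, (mask / norm)


def _pool_backward(dy, mask):
    c, D2, _, H2, _, W2, _ = mask.shape
    dyr = dy[:, :, None, :, None, :, None]
    return (mask * dyr).reshape(c, D2 * 2, H2 * 2, W2 * 2)


def _tconv2_forward(x, W, b):
    """Transposed convolution, kernel 2, stride 2 (exact 2x upsampling)."""
    c_out = W.shape[0]
    _, D, H, Wd = x.shape
    t = np.tensordot(W, x, axes=([1], [0]))  # (C_out, 2,2,2, D,H,W)
    y = t.transpose(0, 4, 1, 5, 2, 6, 3).reshape(c_out, 2 * D, 2 * H, 2 * Wd)
    return y + b[:, None, None, None]


def _tconv2_backward(dy, x, W):
    c_out, c_in = W.shape[:2]
    _, D, H, Wd = x.shape
    dyb = dy.reshape(c_out, D, 2, H, 2, Wd, 2).transpose(0, 2, 4, 6, 1, 3, 5)
    # dyb: (C_out, 2,2,2, D,H,W)
    dW = np.tensordot(dyb, x, axes=([4, 5, 6], [1, 2, 3]))
    dW = dW.transpose(0, 4, 1, 2, 3)
    db = dy.sum(axis=(1, 2, 3))
    dx = np.tensordot(W, dyb, axes=([0, 2, 3, 4], [0, 1, 2, 3]))
    return dx, dW, db


def _conv1_forward(x, W, b):
    """1x1x1 output convolution."""
    c_out = W.shape[0]
    y = np.tensordot(W, x, axes=([1], [0])) + b[:, None, None, None]
    return y.reshape(c_out, *x.shape[1:])


def _conv1_backward(dy, x, W):
    dW = np.tensordot(dy, x, axes=([1, 2, 3], [1, 2, 3]))
    db = dy.sum(axis=(1, 2, 3))
    dx = np.tensordot(W.T, dy, axes=([1], [0]))
    return dx, dW, db


class EDSNet:
    """Encoder–decoder network with skip connections, numpy end to end.

    Parameters live in ``self.params`` (name -> array).  ``forward``
    returns the output volume and, on request, the cache needed by
    ``backward`` to produce the parameter gradients.
    """

    def __init__(self, config: EDSConfig, rng: np.random.Generator):
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        dt = config.dtype
        S = config.n_scales

        def he(shape, fan_in):
            return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dt)

        for s in range(S):
            c_in = config.in_channels if s == 0 else config.channels(s - 1)
            c = config.channels(s)
            self.params[f"enc{s}a_W"] = he((c, c_in, 3, 3, 3), c_in * 27)
            self.params[f"enc{s}a_b"] = np.zeros(c, dtype=dt)
            self.params[f"enc{s}b_W"] = he((c, c, 3, 3, 3), c * 27)
            self.params[f"enc{s}b_b"] = np.zeros(c, dtype=dt)
        for s in range(S - 2, -1, -1):
            c_hi = config.channels(s + 1)
            c = config.channels(s)
            self.params[f"up{s}_W"] = he((c, c_hi, 2, 2, 2), c_hi * 8)
            self.params[f"up{s}_b"] = np.zeros(c, dtype=dt)
            self.params[f"dec{s}a_W"] = he((c, 2 * c, 3, 3, 3), 2 * c * 27)
            self.params[f"dec{s}a_b"] = np.zeros(c, dtype=dt)
            self.params[f"dec{s}b_W"] = he((c, c, 3, 3, 3), c * 27)
            self.params[f"dec{s}b_b"] = np.zeros(c, dtype=dt)
        c0 = config.channels(0)
        self.params["out_W"] = he((config.out_channels, c0), c0)
        self.params["out_b"] = np.zeros(config.out_channels, dtype=dt)

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray, want_cache: bool = False):
        cfg = self.config
        if x.shape[0] != cfg.in_channels:
            raise ValueError(
                f"expected {cfg.in_channels} input channels, got {x.shape[0]}"
            )
        cfg.check_shape(x.shape[1:])
        p = self.params
        x = np.asarray(x, dtype=cfg.dtype)
        cache: dict = {"x": x}
        skips = []
        h = x
        for s in range(cfg.n_scales):
            for blk in ("a", "b"):
                name = f"enc{s}{blk}"
                cache[f"{name}_in_shape"] = h.shape
                h, xp = _conv3_forward(h, p[f"{name}_W"], p[f"{name}_b"])
                if want_cache:
                    cache[f"{name}_xp"] = xp
                cache[f"{name}_pre"] = h if want_cache else None
                h = np.maximum(h, 0.0)
            if s < cfg.n_scales - 1:
                skips.append(h)
                h, mask = _pool_forward(h)
                if want_cache:
                    cache[f"pool{s}_mask"] = mask
        for s in range(cfg.n_scales - 2, -1, -1):
            cache[f"up{s}_in"] = h if want_cache else None
            cache[f"up{s}_in_shape"] = h.shape
            h = _tconv2_forward(h, p[f"up{s}_W"], p[f"up{s}_b"])
            h = np.concatenate([skips[s], h], axis=0)
            for blk in ("a", "b"):
                name = f"dec{s}{blk}"
                cache[f"{name}_in_shape"] = h.shape
                h, xp = _conv3_forward(h, p[f"{name}_W"], p[f"{name}_b"])
                if want_cache:
                    cache[f"{name}_xp"] = xp
                cache[f"{name}_pre"] = h if want_cache else None
                h = np.maximum(h, 0.0)
        cache["out_in"] = h if want_cache else None
        y = _conv1_forward(h, p["out_W"], p["out_b"])
        if want_cache:
            return y, cache
        return y

    # -- backward ----------------------------------------------------------
    def backward(self, dy: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        cfg = self.config
        p = self.params
        grads: dict[str, np.ndarray] = {}
        dy = np.asarray(dy, dtype=cfg.dtype)

        dh, grads["out_W"], grads["out_b"] = _conv1_backward(
            dy, cache["out_in"], p["out_W"]
        )
        dskips: dict[int, np.ndarray] = {}
        # unwind decoder: forward order was s = S-2 .. 0, so backward 0 .. S-2;
        # after each tconv backward, dh is the next-coarser decoder output grad
        for s in range(0, cfg.n_scales - 1):
            for blk in ("b", "a"):
                name = f"dec{s}{blk}"
                dh = dh * (cache[f"{name}_pre"] > 0)
                dh, grads[f"{name}_W"], grads[f"{name}_b"] = _conv3_backward(
                    dh, cache[f"{name}_xp"], p[f"{name}_W"],
                    cache[f"{name}_in_shape"],
                )
            c = cfg.channels(s)
            dskip = dh[:c]
            dup = dh[c:]
            dskips[s] = dskip
            dh, grads[f"up{s}_W"], grads[f"up{s}_b"] = _tconv2_backward(
                dup, cache[f"up{s}_in"], p[f"up{s}_W"]
            )
        # encoder unwind: deepest scale first
        for s in range(cfg.n_scales - 1, -1, -1):
            if s < cfg.n_scales - 1:
                dh = _pool_backward(dh, cache[f"pool{s}_mask"])
                dh = dh + dskips[s]
            for blk in ("b", "a"):
                name = f"enc{s}{blk}"
                dh = dh * (cache[f"{name}_pre"] > 0)
                dh, grads[f"{name}_W"], grads[f"{name}_b"] = _conv3_backward(
                    dh, cache[f"{name}_xp"], p[f"{name}_W"],
                    cache[f"{name}_in_shape"],
                )
        return grads

    def loss_and_grads(
        self, x: np.ndarray, target: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean-squared-error loss of one sample and its parameter grads."""
        y, cache = self.forward(x, want_cache=True)
        target = np.asarray(target, dtype=self.config.dtype)
        if target.ndim == y.ndim - 1:
            target = target[None]
        diff = y - target
        loss = float(np.mean(diff.astype(np.float64) ** 2))
        dy = (2.0 / diff.size) * diff
        return loss, self.backward(dy, cache)


def build_eds(
    config: EDSConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> EDSNet:
    """Build a freshly initialized EDS network (deterministic given seed)."""
    if config is None:
        config = EDSConfig()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    return EDSNet(config, rng)


def predict(net: EDSNet, image_set: np.ndarray) -> np.ndarray:
    """Apply the network to one normalized 4-channel volume.

    Returns the single-channel output volume (sO2 map for network A,
    soft segmentation for network B; values are not clipped here).
    """
    y = net.forward(np.asarray(image_set, dtype=net.config.dtype))
    return np.asarray(y[0], dtype=np.float64)


@dataclass
class TrainResult:
    """Best parameters plus the full per-epoch loss history."""

    params: dict[str, np.ndarray]
    train_losses: list[float]
    val_losses: list[float]
    best_epoch: int
    stopped_epoch: int

    def best_val_loss(self) -> float:
        return self.val_losses[self.best_epoch]


def train(
    net: EDSNet,
    train_set: Sequence[tuple[np.ndarray, np.ndarray]],
    val_set: Sequence[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig | None = None,
    verbose: bool = False,
) -> TrainResult:
    """Train with Adam and early stopping on the validation loss.

    ``train_set`` / ``val_set`` are sequences of (normalized input volume,
    target volume) pairs.  The network is left holding — and the result
    records — the parameters of the best validation epoch.  Training
    aborts with a diagnostic if the loss diverges to NaN.
    """
    if config is None:
        config = TrainConfig()
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    p = net.params
    m = {k: np.zeros_like(v) for k, v in p.items()}
    v = {k: np.zeros_like(val) for k, val in p.items()}
    t = 0
    best_val = np.inf
    best_params = {k: arr.copy() for k, arr in p.items()}
    best_epoch = 0
    train_losses: list[float] = []
    val_losses: list[float] = []
    since_best = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_set))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            grads_acc: dict[str, np.ndarray] | None = None
            batch_loss = 0.0
            for i in idx:
                x, target = train_set[i]
                loss, grads = net.loss_and_grads(x, target)
                batch_loss += loss
                if grads_acc is None:
                    grads_acc = grads
                else:
                    for k in grads_acc:
                        grads_acc[k] += grads[k]
            scale = 1.0 / len(idx)
            batch_loss *= scale
            epoch_loss += batch_loss * len(idx)
            if not np.isfinite(batch_loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} (loss={batch_loss})"
                )
            t += 1
            bc1 = 1.0 - config.beta1**t
            bc2 = 1.0 - config.beta2**t
            for k in p:
                gk = grads_acc[k] * scale
                m[k] = config.beta1 * m[k] + (1 - config.beta1) * gk
                v[k] = config.beta2 * v[k] + (1 - config.beta2) * gk * gk
                p[k] -= (
                    config.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + config.eps)
                ).astype(p[k].dtype)
        train_losses.append(epoch_loss / len(train_set))

        vloss = 0.0
        for x, target in val_set:
            y = net.forward(x)
            tgt = target[None] if target.ndim == y.ndim - 1 else target
            vloss += float(np.mean((y.astype(np.float64) - tgt) ** 2))
        vloss /= len(val_set)
        val_losses.append(vloss)
        if verbose:
            print(f"epoch {epoch}: train {train_losses[-1]:.3e} val {vloss:.3e}")

        if vloss < best_val:
            best_val = vloss
            best_epoch = epoch
            best_params = {k: arr.copy() for k, arr in p.items()}
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    net.params = best_params
    return TrainResult(
        params=best_params,
        train_losses=train_losses,
        val_losses=val_losses,
        best_epoch=best_epoch,
        stopped_epoch=len(train_losses) - 1,
    )
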