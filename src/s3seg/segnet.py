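"""Patch-classifying CNN with overlapping pooling before local normalization.

An AlexNet-style classifier adapted to small multi-channel image patches:
convolution -> ReLU -> overlapping max pooling (window wider than stride)
-> local response normalization after the first and second pooling stages,
then three fully connected layers with dropout on the first two and a
softmax head.  Placing the pooling *before* the divisive normalization is
the architectural modification this network carries; a structural
introspection test can assert the emitted layer order.

Segmentation uses the classifier as a sliding window: every pixel's class
probability is the mean over all windows covering it, with reflect padding
at the borders so coverage is complete.

Everything is plain numpy with analytic gradients (im2col convolutions,
argmax-routed pooling, exact LRN backward), so training is deterministic
given a seed and runs anywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .errors import DataError

__all__ = [
    "SegNetConfig",
    "SegNetParams",
    "init_params",
    "overlapping_max_pool",
    "local_response_norm",
    "relu",
    "dropout_mask",
    "apply_dropout",
    "softmax",
    "softmax_rows",
    "forward",
    "forward_batch",
    "backward_batch",
    "segment_image",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class SegNetConfig:
    """Architecture description.

    ``conv_specs`` is a sequence of (kernel size, output maps, stride);
    ``pool_after`` lists 1-based conv indices followed by a pooling stage;
    ``lrn_after_pools`` lists 1-based *pool* indices followed by local
    response normalization.  The pooling window must exceed its stride
    (overlapping pooling).  LRN constants default to (k=2, alpha=0.78,
    beta=1e-4, m=7) and are overridable.
    """

    in_channels: int = 4
    num_classes: int = 2
    patch_size: int = 16
    conv_specs: tuple = ((3, 8, 1), (3, 16, 1))
    conv_padding: str = "same"
    pool_spec: tuple = (3, 2)
    pool_after: tuple = (1, 2)
    lrn_spec: tuple = (2.0, 0.78, 1e-4, 7)
    lrn_after_pools: tuple = (1, 2)
    fc_dims: tuple = (64, 32, 2)
    dropout_p: float = 0.5
    preset: str = "custom"

    def __post_init__(self) -> None:
        w_c, stride = self.pool_spec
        if w_c <= stride:
            raise DataError(
                f"overlapping pooling requires window > stride, got {w_c} <= {stride}"
            )
        if not 0.0 <= self.dropout_p <= 1.0:
            raise DataError("dropout_p must lie in [0, 1]")
        if len(self.fc_dims) != 3:
            raise DataError("exactly three fully connected layers are required")
        if self.conv_padding not in ("same", "valid"):
            raise DataError("conv_padding must be 'same' or 'valid'")
        if self.fc_dims[-1] != self.num_classes:
            raise DataError("last fully connected dimension must equal num_classes")

    @classmethod
    def tiny(cls, in_channels: int = 4, num_classes: int = 2) -> "SegNetConfig":
        """Desk-scale preset: 2 conv layers (8/16 maps), patch 16, FC 64/32."""
        return cls(
            in_channels=in_channels,
            num_classes=num_classes,
            patch_size=16,
            conv_specs=((3, 8, 1), (3, 16, 1)),
            conv_padding="same",
            pool_spec=(3, 2),
            pool_after=(1, 2),
            lrn_after_pools=(1, 2),
            fc_dims=(64, 32, num_classes),
            preset="tiny",
        )

    @classmethod
    def paper(cls, in_channels: int = 4, num_classes: int = 2) -> "SegNetConfig":
        """Full-size preset mirroring AlexNet's 5-conv/3-FC shape at patch 64."""
        return cls(
            in_channels=in_channels,
            num_classes=num_classes,
            patch_size=64,
            conv_specs=((7, 96, 1), (5, 256, 1), (3, 384, 1), (3, 384, 1), (3, 256, 1)),
            conv_padding="valid",
            pool_spec=(3, 2),
            pool_after=(1, 2, 5),
            lrn_after_pools=(1, 2),
            fc_dims=(4096, 4096, num_classes),
            preset="paper",
        )

    def layer_sequence(self) -> list:
        """Flat, ordered list of layer names for introspection."""
        seq = []
        pool_index = 0
        for i in range(1, len(self.conv_specs) + 1):
            seq.append(f"conv{i}")
            seq.append(f"relu{i}")
            if i in self.pool_after:
                pool_index += 1
                seq.append(f"pool{pool_index}")
                if pool_index in self.lrn_after_pools:
                    seq.append(f"lrn{pool_index}")
        seq.append("flatten")
        for j in range(1, 4):
            seq.append(f"fc{j}")
            if j < 3:
                seq.append(f"relu_fc{j}")
                seq.append(f"dropout{j}")
        seq.append("softmax")
        return seq

    def spatial_dims(self) -> list:
        """Spatial size after each conv stage; raises if a window outgrows it."""
        size = self.patch_size
        dims = []
        w_c, st = self.pool_spec
        for i, (ksz, _, cstride) in enumerate(self.conv_specs, start=1):
            if self.conv_padding == "valid":
                if ksz > size:
                    raise DataError(f"conv{i}: kernel {ksz} exceeds input size {size}")
                size = (size - ksz) // cstride + 1
            else:
                size = (size - 1) // cstride + 1
            if i in self.pool_after:
                if w_c > size:
                    raise DataError(f"pool after conv{i}: window {w_c} exceeds {size}")
                size = (size - w_c) // st + 1
            dims.append(size)
        return dims


@dataclass
class SegNetParams:
    """Weight container, reproducible from (config, seed)."""

    params: dict
    seed: int
    trained: bool = False


def init_params(config: SegNetConfig, seed: int = 0) -> SegNetParams:
    """He-normal initialization of all convolution and FC weights."""
    rng = np.random.default_rng(seed)
    p: dict = {}
    cin = config.in_channels
    for i, (ksz, maps, _) in enumerate(config.conv_specs, start=1):
        fan_in = cin * ksz * ksz
        p[f"conv{i}_W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (maps, cin, ksz, ksz))
        p[f"conv{i}_b"] = np.zeros(maps)
        cin = maps
    flat = cin * config.spatial_dims()[-1] ** 2
    dims = (flat,) + tuple(config.fc_dims)
    for j in range(3):
        p[f"fc{j + 1}_W"] = rng.normal(0.0, np.sqrt(2.0 / dims[j]), (dims[j + 1], dims[j]))
        p[f"fc{j + 1}_b"] = np.zeros(dims[j + 1])
    return SegNetParams(params=p, seed=seed)


# ---------------------------------------------------------------- primitives

def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x)."""
    return np.maximum(0.0, np.asarray(x, dtype=float))


def overlapping_max_pool(x: np.ndarray, w_c: int, stride: int) -> np.ndarray:
    """Per-channel max over w_c x w_c windows anchored every ``stride`` pixels.

    Requires w_c > stride (the windows overlap) and no padding; the output
    size per axis is floor((H - w_c)/stride) + 1.
    """
    out, _ = _max_pool_forward(np.asarray(x, dtype=float)[None], w_c, stride)
    return out[0]


def _max_pool_forward(x: np.ndarray, w_c: int, stride: int):
    if w_c <= stride:
        raise DataError(
            f"overlapping pooling requires window > stride, got {w_c} <= {stride}"
        )
    B, C, H, W = x.shape
    if w_c > H or w_c > W:
        raise DataError(f"pooling window {w_c} exceeds input {H}x{W}")
    win = np.lib.stride_tricks.sliding_window_view(x, (w_c, w_c), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    Ho, Wo = win.shape[2], win.shape[3]
    flat = win.reshape(B, C, Ho, Wo, w_c * w_c)
    arg = flat.argmax(axis=-1)
    out = flat.max(axis=-1)
    cache = {"arg": arg, "shape": (H, W), "w_c": w_c, "stride": stride}
    return out, cache


def _max_pool_backward(dout: np.ndarray, cache) -> np.ndarray:
    arg, (H, W) = cache["arg"], cache["shape"]
    w_c, stride = cache["w_c"], cache["stride"]
    B, C, Ho, Wo = dout.shape
    dx = np.zeros((B, C, H, W))
    for p in range(w_c * w_c):
        u, v = divmod(p, w_c)
        mask = arg == p
        dx[:, :, u : u + Ho * stride : stride, v : v + Wo * stride : stride] += (
            dout * mask
        )
    return dx


def _channel_box_sum(x: np.ndarray, half: int) -> np.ndarray:
    """Sum over the channel window [t - half, t + half] clipped to bounds."""
    C = x.shape[1]
    cs = np.concatenate(
        [np.zeros_like(x[:, :1]), np.cumsum(x, axis=1)], axis=1
    )
    lo = np.maximum(np.arange(C) - half, 0)
    hi = np.minimum(np.arange(C) + half, C - 1) + 1
    return cs[:, hi] - cs[:, lo]


def local_response_norm(a: np.ndarray, k_lrn: float = 2.0, alpha: float = 0.78,
                        beta: float = 1e-4, m: int = 7) -> np.ndarray:
    """Divisive normalization across nearby channels.

    c_t = a_t / (k + alpha * sum_{t' in [t - m//2, t + m//2]} a_{t'}^2)^beta,
    with the channel window clipped at the tensor bounds.
    """
    out, _ = _lrn_forward(np.asarray(a, dtype=float)[None], k_lrn, alpha, beta, m)
    return out[0]


def _lrn_forward(a: np.ndarray, k_lrn, alpha, beta, m):
    if min(k_lrn, alpha, beta) <= 0 or m <= 0:
        raise DataError("LRN hyperparameters must be positive")
    S = k_lrn + alpha * _channel_box_sum(a * a, m // 2)
    out = a * S ** (-beta)
    return out, {"a": a, "S": S, "alpha": alpha, "beta": beta, "m": m}


def _lrn_backward(dout: np.ndarray, cache) -> np.ndarray:
    a, S = cache["a"], cache["S"]
    alpha, beta, m = cache["alpha"], cache["beta"], cache["m"]
    # d c_t / d a_s = delta_ts S_t^-beta - 2 alpha beta a_t a_s S_t^(-beta-1)
    # for |s - t| <= m//2; the window membership is symmetric.
    inner = dout * a * S ** (-beta - 1.0)
    return dout * S ** (-beta) - 2.0 * alpha * beta * a * _channel_box_sum(
        inner, m // 2
    )


def dropout_mask(shape, dp: float, rng_seed) -> np.ndarray:
    """I.i.d. Bernoulli(dp) keep-mask from a seeded generator."""
    if not 0.0 <= dp <= 1.0:
        raise DataError("dropout keep-probability must lie in [0, 1]")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    return (rng.random(shape) < dp).astype(float)


def apply_dropout(x: np.ndarray, dp: float, train: bool, rng=None):
    """Training: multiply by a Bernoulli(dp) keep-mask; inference: scale by dp."""
    if not 0.0 <= dp <= 1.0:
        raise DataError("dropout keep-probability must lie in [0, 1]")
    if train:
        mask = dropout_mask(x.shape, dp, rng if rng is not None else 0)
        return x * mask, mask
    return x * dp, None


def softmax(x: np.ndarray) -> np.ndarray:
    """Stable softmax of a vector (max-subtraction)."""
    x = np.asarray(x, dtype=float)
    z = np.exp(x - x.max())
    return z / z.sum()


def softmax_rows(x: np.ndarray) -> np.ndarray:
    """Stable row-wise softmax of an N x K matrix."""
    x = np.asarray(x, dtype=float)
    z = np.exp(x - x.max(axis=1, keepdims=True))
    return z / z.sum(axis=1, keepdims=True)


# ------------------------------------------------------------- conv plumbing

def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray, stride: int,
                  padding: str):
    B, C, H, Wd = x.shape
    O, Ci, kh, kw = W.shape
    if Ci != C:
        raise DataError(f"conv expects {Ci} input channels, got {C}")
    pad = kh // 2 if padding == "same" else 0
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    Hp, Wp = xp.shape[2], xp.shape[3]
    if kh > Hp or kw > Wp:
        raise DataError(f"conv kernel {kh} exceeds padded input {Hp}x{Wp}")
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    Ho, Wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho, Wo, C * kh * kw)
    out = cols @ W.reshape(O, -1).T + b
    out = out.transpose(0, 3, 1, 2)
    cache = {"cols": cols, "x_shape": x.shape, "pad": pad, "stride": stride,
             "kshape": (kh, kw)}
    return out, cache


def _conv_backward(dout: np.ndarray, W: np.ndarray, cache):
    cols = cache["cols"]
    B, C, H, Wd = cache["x_shape"]
    pad, stride = cache["pad"], cache["stride"]
    kh, kw = cache["kshape"]
    O = W.shape[0]
    d = dout.transpose(0, 2, 3, 1)  # B,Ho,Wo,O
    Ho, Wo = d.shape[1], d.shape[2]
    dW = np.einsum("bhwf,bhwo->of", cols, d).reshape(W.shape)
    db = d.sum(axis=(0, 1, 2))
    dcols = (d @ W.reshape(O, -1)).reshape(B, Ho, Wo, C, kh, kw)
    dxp = np.zeros((B, C, H + 2 * pad, Wd + 2 * pad))
    for u in range(kh):
        for v in range(kw):
            dxp[:, :, u : u + Ho * stride : stride, v : v + Wo * stride : stride] += (
                dcols[:, :, :, :, u, v].transpose(0, 3, 1, 2)
            )
    dx = dxp[:, :, pad : pad + H, pad : pad + Wd] if pad else dxp
    return dx, dW, db


# ------------------------------------------------------------ forward / back

def forward_batch(config: SegNetConfig, params: SegNetParams, x: np.ndarray,
                  train: bool = False, rng=None):
    """Forward pass over a (B, C, H, W) batch; returns (probs, caches)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 4:
        raise DataError("expected a (B, C, H, W) batch")
    if x.shape[1] != config.in_channels or x.shape[2] != config.patch_size \
            or x.shape[3] != config.patch_size:
        raise DataError(
            f"input layer: expected ({config.in_channels}, {config.patch_size}, "
            f"{config.patch_size}) patches, got {x.shape[1:]}"
        )
    p = params.params
    caches = []
    w_c, pstride = config.pool_spec
    k_lrn, alpha, beta, m = config.lrn_spec
    pool_index = 0
    for i, (_, _, cstride) in enumerate(config.conv_specs, start=1):
        x, cc = _conv_forward(x, p[f"conv{i}_W"], p[f"conv{i}_b"], cstride,
                              config.conv_padding)
        caches.append(("conv", i, cc))
        mask = x > 0
        x = x * mask
        caches.append(("relu", i, mask))
        if i in config.pool_after:
            pool_index += 1
            x, pc = _max_pool_forward(x, w_c, pstride)
            caches.append(("pool", pool_index, pc))
            if pool_index in config.lrn_after_pools:
                x, lc = _lrn_forward(x, k_lrn, alpha, beta, m)
                caches.append(("lrn", pool_index, lc))
    B = x.shape[0]
    flat_shape = x.shape
    x = x.reshape(B, -1)
    caches.append(("flatten", 0, flat_shape))
    for j in range(1, 4):
        Wm, bv = p[f"fc{j}_W"], p[f"fc{j}_b"]
        if x.shape[1] != Wm.shape[1]:
            raise DataError(f"fc{j}: expected {Wm.shape[1]} inputs, got {x.shape[1]}")
        z = x @ Wm.T + bv
        caches.append(("fc", j, x))
        if j < 3:
            mask = z > 0
            z = z * mask
            caches.append(("relu_fc", j, mask))
            z, dmask = apply_dropout(z, config.dropout_p, train, rng)
            caches.append(("dropout", j, dmask))
        x = z
    probs = softmax_rows(x)
    caches.append(("logits", 0, None))
    return probs, caches


def backward_batch(config: SegNetConfig, params: SegNetParams, caches,
                   dlogits: np.ndarray) -> dict:
    """Gradients of all parameters given d loss / d logits."""
    p = params.params
    grads: dict = {}
    g = np.asarray(dlogits, dtype=float)
    for kind, idx, cache in reversed(caches):
        if kind == "logits":
            continue
        elif kind == "fc":
            Wm = p[f"fc{idx}_W"]
            grads[f"fc{idx}_W"] = g.T @ cache
            grads[f"fc{idx}_b"] = g.sum(axis=0)
            g = g @ Wm
        elif kind == "relu_fc":
            g = g * cache
        elif kind == "dropout":
            if cache is not None:
                g = g * cache
            else:
                g = g * config.dropout_p
        elif kind == "flatten":
            g = g.reshape(cache)
        elif kind == "lrn":
            g = _lrn_backward(g, cache)
        elif kind == "pool":
            g = _max_pool_backward(g, cache)
        elif kind == "relu":
            g = g * cache
        elif kind == "conv":
            g, dW, db = _conv_backward(g, p[f"conv{idx}_W"], cache)
            grads[f"conv{idx}_W"] = dW
            grads[f"conv{idx}_b"] = db
    return grads


def forward(config: SegNetConfig, params: SegNetParams, patch: np.ndarray,
            train: bool = False, rng=None) -> np.ndarray:
    """Class-probability vector for a single (C, p, p) patch."""
    probs, _ = forward_batch(config, params, np.asarray(patch, dtype=float)[None],
                             train=train, rng=rng)
    return probs[0]


def segment_image(config: SegNetConfig, params: SegNetParams, image: np.ndarray,
                  patch_size: Optional[int] = None, stride: int = 4,
                  batch_windows: int = 512):
    """Sliding-window segmentation.

    Each pixel's class probability is the mean over all windows covering it;
    the image is reflect-padded so every pixel is covered.  The label map is
    the per-pixel argmax with ties resolved to the lower class index.
    Returns (label_map, probability_map) with the probability map shaped
    (num_classes, H, W).
    """
    if not params.trained:
        raise DataError("segment_image requires trained parameters")
    img = np.asarray(image, dtype=float)
    if img.ndim != 3:
        raise DataError("expected a (C, H, W) image")
    patch = patch_size or config.patch_size
    if patch != config.patch_size:
        raise DataError(
            f"patch size {patch} does not match network input {config.patch_size}"
        )
    C, H, W = img.shape
    if H < patch or W < patch:
        raise DataError(f"image {H}x{W} smaller than patch {patch}")
    # anchors at 0, stride, ... cover every pixel once the grid reaches the
    # bottom/right edge; reflect-pad just enough to land the last anchor there
    extra_h = (-(H - patch)) % stride
    extra_w = (-(W - patch)) % stride
    imgp = np.pad(img, ((0, 0), (0, extra_h), (0, extra_w)), mode="reflect")
    Hp, Wp = imgp.shape[1], imgp.shape[2]
    anchors = [(r, c)
               for r in range(0, Hp - patch + 1, stride)
               for c in range(0, Wp - patch + 1, stride)]
    acc = np.zeros((config.num_classes, Hp, Wp))
    cnt = np.zeros((Hp, Wp))
    for start in range(0, len(anchors), batch_windows):
        chunk = anchors[start : start + batch_windows]
        batch = np.stack([imgp[:, r : r + patch, c : c + patch] for r, c in chunk])
        probs, _ = forward_batch(config, params, batch, train=False)
        for (r, c), pr in zip(chunk, probs):
            acc[:, r : r + patch, c : c + patch] += pr[:, None, None]
            cnt[r : r + patch, c : c + patch] += 1.0
    prob_map = acc[:, :H, :W] / cnt[:H, :W]
    label_map = prob_map.argmax(axis=0)
    return label_map, prob_map


# ----------------------------------------------------------------- persistence

def save_checkpoint(path, config: SegNetConfig, params: SegNetParams,
                    extra: Optional[dict] = None) -> None:
    """Save config (JSON manifest) and weights to a single .npz archive."""
    manifest = {
        "format_version": 1,
        "config": asdict(config),
        "seed": params.seed,
        "trained": params.trained,
        "layer_shapes": {k: list(v.shape) for k, v in params.params.items()},
        "extra": extra or {},
    }
    np.savez(path, __manifest__=np.frombuffer(
        json.dumps(manifest).encode(), dtype=np.uint8), **params.params)


def load_checkpoint(path):
    """Load (config, params) from a checkpoint archive."""
    with np.load(path) as archive:
        manifest = json.loads(bytes(archive["__manifest__"]).decode())
        cfg_dict = manifest["config"]
        for key in ("conv_specs", "pool_spec", "pool_after", "lrn_spec",
                    "lrn_after_pools", "fc_dims"):
            cfg_dict[key] = tuple(
                tuple(v) if isinstance(v, list) else v for v in cfg_dict[key]
            )
        config = SegNetConfig(**cfg_dict)
        arrays = {k: archive[k] for k in archive.files if k != "__manifest__"}
    params = SegNetParams(params=arrays, seed=manifest["seed"],
                          trained=manifest["trained"])
    return config, params
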