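"""Losses, companding, and training-time schedules for the patch network.

The segmentation loss is a pixel-wise cross-entropy optionally restricted to
hard examples (true-class probability below a threshold eta) and weighted by
w_ik = 1 / ln(c + p_ik), which emphasizes low-confidence pixels.  Image
intensities are mu-law companded before entering the network, compressing
the dynamic range so an 8-bit uniform quantizer suffices downstream.
Training is plain minibatch SGD with a polynomial learning-rate decay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DataError
from . import segnet

logger = logging.getLogger(__name__)

__all__ = [
    "PixelBatch",
    "OhemWceParams",
    "LrSchedule",
    "cross_entropy",
    "pixel_weights",
    "ohem_select",
    "ohem_wce_loss",
    "mu_law_compand",
    "mu_law_expand",
    "quantize_8bit",
    "poly_lr",
    "MuLawNormalizer",
    "train",
]

_LOG_CLAMP = 1e-12


@dataclass
class PixelBatch:
    """Logits, labels, and softmax probabilities for a batch of pixels."""

    logits: np.ndarray
    true_labels: np.ndarray
    probabilities: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.logits = np.asarray(self.logits, dtype=float)
        self.true_labels = np.asarray(self.true_labels, dtype=int)
        if self.logits.ndim != 2:
            raise DataError("logits must be N x K")
        N, K = self.logits.shape
        if self.true_labels.shape != (N,):
            raise DataError("true_labels must have one entry per pixel")
        if self.true_labels.min() < 0 or self.true_labels.max() >= K:
            raise DataError(f"labels must lie in [0, {K})")
        if self.probabilities is None:
            self.probabilities = segnet.softmax_rows(self.logits)
        else:
            self.probabilities = np.asarray(self.probabilities, dtype=float)
            if np.abs(self.probabilities.sum(axis=1) - 1.0).max() > 1e-6:
                raise DataError("probability rows must sum to 1")


@dataclass
class OhemWceParams:
    """Hard-example threshold, weighting constant, and loss mode."""

    eta: float = 0.7
    c_weight: float = 1.10
    mode: str = "combined"

    def __post_init__(self) -> None:
        if not 0.0 < self.eta <= 1.0:
            raise DataError("eta must lie in (0, 1]")
        if self.c_weight <= 1.0:
            raise DataError("c_weight must exceed 1 so ln(c + p) stays positive")
        if self.mode not in ("ohem", "weighted", "combined"):
            raise DataError(f"unknown loss mode {self.mode!r}")


@dataclass
class LrSchedule:
    """Polynomial learning-rate decay init_lr * (1 - epoch/max_epoch)^power."""

    init_lr: float = 0.0005
    power: float = 0.9
    max_epoch: int = 120

    def __post_init__(self) -> None:
        if self.init_lr <= 0 or self.power <= 0 or self.max_epoch < 1:
            raise DataError("init_lr, power must be positive and max_epoch >= 1")


def cross_entropy(true_dist: np.ndarray, probs: np.ndarray) -> float:
    """-sum_k t_k log p_k with the log clamped at 1e-12."""
    t = np.asarray(true_dist, dtype=float)
    p = np.asarray(probs, dtype=float)
    if t.shape != p.shape:
        raise DataError("distribution shapes differ")
    for name, v in (("true_dist", t), ("probs", p)):
        if abs(v.sum() - 1.0) > 1e-6 or v.min() < -1e-12:
            raise DataError(f"{name} is not a probability vector")
    return float(-(t * np.log(np.maximum(p, _LOG_CLAMP))).sum())


def pixel_weights(probs: np.ndarray, c_weight: float) -> np.ndarray:
    """Per-pixel per-class weights w_ik = 1 / ln(c + p_ik)."""
    if c_weight <= 1.0:
        raise DataError("c_weight must exceed 1 so ln(c + p) stays positive")
    p = np.asarray(probs, dtype=float)
    return 1.0 / np.log(c_weight + p)


def ohem_select(batch: PixelBatch, eta: float) -> np.ndarray:
    """Boolean N x K selection: true class and probability below eta."""
    if not 0.0 < eta <= 1.0:
        raise DataError("eta must lie in (0, 1]")
    N, K = batch.logits.shape
    onehot = np.zeros((N, K), dtype=bool)
    onehot[np.arange(N), batch.true_labels] = True
    return onehot & (batch.probabilities < eta)


def ohem_wce_loss(batch: PixelBatch, params: OhemWceParams) -> float:
    """Hard-example-mined / weighted cross-entropy over a pixel batch.

    mode "ohem":      mean of -log p_ik over the selected hard pixels;
    mode "weighted":  sum of -w_ik q_ik log p_ik with one-hot q;
    mode "combined":  the weighted sum restricted to the hard selection,
                      normalized by the selection count.
    An empty selection yields loss 0 and a logged warning.
    """
    p = batch.probabilities
    logp = np.log(np.maximum(p, _LOG_CLAMP))
    N, K = p.shape
    onehot = np.zeros((N, K))
    onehot[np.arange(N), batch.true_labels] = 1.0
    if params.mode == "weighted":
        w = pixel_weights(p, params.c_weight)
        return float(-(w * onehot * logp).sum())
    sel = ohem_select(batch, params.eta)
    n_sel = int(sel.sum())
    if n_sel == 0:
        logger.warning("OHEM selected no hard examples; loss is 0")
        return 0.0
    if params.mode == "ohem":
        return float(-logp[sel].sum() / n_sel)
    w = pixel_weights(p, params.c_weight)
    return float(-(w * onehot * logp)[sel].sum() / n_sel)


def _loss_and_dlogits(probs, labels, params: OhemWceParams):
    """Loss value and gradient wrt logits; selection and weights held fixed."""
    N, K = probs.shape
    onehot = np.zeros((N, K))
    onehot[np.arange(N), labels] = 1.0
    logp = np.log(np.maximum(probs, _LOG_CLAMP))
    p_true = probs[np.arange(N), labels]
    if params.mode == "weighted":
        coeff = pixel_weights(p_true, params.c_weight)
        loss = float(-(coeff * logp[np.arange(N), labels]).sum())
        d = coeff[:, None] * (probs - onehot)
        return loss, d
    hard = p_true < params.eta
    n_sel = int(hard.sum())
    if n_sel == 0:
        return 0.0, np.zeros_like(probs)
    if params.mode == "ohem":
        coeff = hard / n_sel
    else:
        coeff = hard * pixel_weights(p_true, params.c_weight) / n_sel
    loss = float(-(coeff * logp[np.arange(N), labels]).sum())
    return loss, coeff[:, None] * (probs - onehot)


def mu_law_compand(x, mu: float = 255.0):
    """sign(x) ln(1 + mu|x|) / ln(1 + mu); odd and monotone on (-1, 1)."""
    if mu <= 0:
        raise DataError("mu must be positive")
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) >= 1.0):
        raise DataError("mu-law companding requires |x| < 1")
    out = np.sign(x) * np.log1p(mu * np.abs(x)) / np.log1p(mu)
    return float(out) if out.ndim == 0 else out


def mu_law_expand(y, mu: float = 255.0):
    """Analytic inverse of mu-law companding."""
    y = np.asarray(y, dtype=float)
    out = np.sign(y) * np.expm1(np.abs(y) * np.log1p(mu)) / mu
    return float(out) if out.ndim == 0 else out


def quantize_8bit(values) -> tuple[np.ndarray, np.ndarray]:
    """Uniform 8-bit quantization of [-1, 1].

    Returns integer codes in [0, 255] and the dequantized bin centers.
    Quantization is idempotent on the returned levels.
    """
    x = np.asarray(values, dtype=float)
    if np.any(np.abs(x) > 1.0):
        raise DataError("quantize_8bit requires inputs in [-1, 1]")
    codes = np.clip(np.floor((x + 1.0) * 128.0), 0, 255).astype(np.uint8)
    levels = -1.0 + (codes.astype(float) + 0.5) / 128.0
    return codes, levels


def poly_lr(epoch: int, sched: LrSchedule) -> float:
    """Learning rate at an epoch under polynomial decay."""
    if epoch < 0 or epoch > sched.max_epoch:
        raise DataError(f"epoch must lie in [0, {sched.max_epoch}], got {epoch}")
    return float(sched.init_lr * (1.0 - epoch / sched.max_epoch) ** sched.power)


class MuLawNormalizer:
    """Min-max scale per channel to [-0.999, 0.999], then mu-law compand.

    The scaling margin keeps values strictly inside the open companding
    domain (-1, 1).  Statistics are frozen at fit time so training and
    inference share the same transform.
    """

    def __init__(self, mu: float = 255.0, margin: float = 0.999):
        self.mu = mu
        self.margin = margin
        self.mins_: Optional[np.ndarray] = None
        self.maxs_: Optional[np.ndarray] = None

    def fit(self, patches: np.ndarray) -> "MuLawNormalizer":
        """patches: (N, C, H, W) stack of raw training patches."""
        x = np.asarray(patches, dtype=float)
        C = x.shape[1]
        flat = x.transpose(1, 0, 2, 3).reshape(C, -1)
        self.mins_ = flat.min(axis=1)
        self.maxs_ = flat.max(axis=1)
        return self

    def transform(self, images: np.ndarray) -> np.ndarray:
        """Apply to (N, C, H, W) batches or a single (C, H, W) image."""
        if self.mins_ is None:
            raise DataError("normalizer must be fitted before use")
        x = np.asarray(images, dtype=float)
        single = x.ndim == 3
        if single:
            x = x[None]
        span = np.where(self.maxs_ > self.mins_, self.maxs_ - self.mins_, 1.0)
        shape = (1, -1, 1, 1)
        unit = (x - self.mins_.reshape(shape)) / span.reshape(shape)
        scaled = (2.0 * np.clip(unit, 0.0, 1.0) - 1.0) * self.margin
        out = mu_law_compand(scaled, self.mu)
        return out[0] if single else out


def train(config, params, patches, labels, loss_params: Optional[OhemWceParams] = None,
          sched: Optional[LrSchedule] = None, seed: int = 0, epochs: Optional[int] = None,
          batch_size: int = 16, compand: bool = True):
    """Minibatch SGD training of the patch classifier.

    Inputs are mu-law companded (via a normalizer fitted on the training
    patches) before entering the network.  The learning rate follows the
    polynomial schedule per epoch.  Returns the trained parameters and a
    history dict with per-epoch loss, learning rate, and the fitted
    normalizer.  Fully reproducible from the seed.
    """
    x = np.asarray(patches, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.ndim != 4 or x.shape[0] == 0:
        raise DataError("need a nonempty (N, C, H, W) patch stack")
    if y.shape[0] != x.shape[0]:
        raise DataError("label count does not match patch count")
    loss_params = loss_params or OhemWceParams()
    if sched is None:
        sched = LrSchedule()
    if epochs is None:
        epochs = sched.max_epoch
    sched = LrSchedule(init_lr=sched.init_lr, power=sched.power, max_epoch=epochs)

    normalizer = None
    if compand:
        normalizer = MuLawNormalizer().fit(x)
        x = normalizer.transform(x)

    ss = np.random.SeedSequence(seed)
    shuffle_rng, drop_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
    N = x.shape[0]
    history = {"loss": [], "lr": [], "normalizer": normalizer}
    for epoch in range(epochs):
        lr = poly_lr(epoch, sched)
        order = shuffle_rng.permutation(N)
        epoch_losses = []
        for start in range(0, N, batch_size):
            idx = order[start : start + batch_size]
            probs, caches = segnet.forward_batch(
                config, params, x[idx], train=True, rng=drop_rng
            )
            loss, dlogits = _loss_and_dlogits(probs, y[idx], loss_params)
            grads = segnet.backward_batch(config, params, caches, dlogits)
            for key, g in grads.items():
                params.params[key] -= lr * g
            epoch_losses.append(loss)
        history["loss"].append(float(np.mean(epoch_losses)))
        history["lr"].append(lr)
    params.trained = True
    return params, history
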