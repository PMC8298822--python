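"""Synthetic study data: point clouds, brain phantoms, and stratified splits.

The phantom generator emulates co-registered multi-sequence MRI slices
(T1, T2, T1c, FLAIR): an elliptical "brain" on a dark background, one or
more tumor blobs strictly inside the brain with a channel-dependent
contrast sign (hypointense on T1, hyperintense on T2/FLAIR, strongest
enhancement on the contrast channel), a smooth multiplicative bias field
emulating MRI intensity inhomogeneity, and additive Gaussian noise — plus
the exact ground-truth tumor mask.  No physics is simulated; the images
only need channel-dependent, mask-correlated structure.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import FeatureMatrix, PartialLabels
from .errors import DataError

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterDataset",
    "PhantomSample",
    "generate_clusters",
    "generate_phantom",
    "stratified_split",
]

#: per-channel intensities: background, brain tissue, and tumor contrast
#: offsets for the (T1, T2, T1c, FLAIR) channels
_BACKGROUND = 0.05
_BRAIN = np.array([0.55, 0.45, 0.50, 0.40])
_TUMOR_DELTA = np.array([-0.25, 0.30, 0.45, 0.35])
#: channel index with the strongest (contrast-enhanced) tumor signal
CONTRAST_CHANNEL = 2


@dataclass
class ClusterDataset:
    """Two-Gaussian point cloud with a partially revealed labeling."""

    X: FeatureMatrix
    labels_full: np.ndarray
    labels_partial: PartialLabels
    meta: dict = field(default_factory=dict)


@dataclass
class PhantomSample:
    """4-channel phantom slice with its ground-truth tumor mask."""

    image: np.ndarray  # (4, H, W)
    mask: np.ndarray  # (H, W) in {0, 1}
    meta: dict = field(default_factory=dict)


def generate_clusters(n: int, d: int, separation: float, labeled_fraction: float,
                      seed: int) -> ClusterDataset:
    """Two isotropic unit-variance Gaussian clusters at +-(separation/2) e1.

    Cluster sizes are as equal as possible; a stratified random fraction of
    labels is revealed (at least one per class).
    """
    if n < 4:
        raise DataError("need n >= 4 samples")
    if not 0.0 < labeled_fraction <= 1.0:
        raise DataError("labeled_fraction must lie in (0, 1]")
    if separation <= 0:
        raise DataError("separation must be positive")
    rng = np.random.default_rng(seed)
    n_pos = n // 2
    n_neg = n - n_pos
    mu = np.zeros(d)
    mu[0] = separation / 2.0
    X = np.vstack([
        rng.normal(size=(n_pos, d)) + mu,
        rng.normal(size=(n_neg, d)) - mu,
    ])
    y = np.concatenate([np.ones(n_pos, dtype=int), -np.ones(n_neg, dtype=int)])
    perm = rng.permutation(n)
    X, y = X[perm], y[perm]

    partial = np.zeros(n, dtype=int)
    for cls in (1, -1):
        idx = np.flatnonzero(y == cls)
        n_reveal = max(1, int(round(labeled_fraction * idx.size)))
        chosen = rng.choice(idx, size=n_reveal, replace=False)
        partial[chosen] = cls
    fm = FeatureMatrix(X, [f"s{i}" for i in range(n)])
    meta = {"seed": seed, "n": n, "d": d, "separation": separation,
            "labeled_fraction": labeled_fraction}
    return ClusterDataset(X=fm, labels_full=y, labels_partial=PartialLabels(partial),
                          meta=meta)


def _ellipse_mask(H, W, cy, cx, ry, rx):
    yy, xx = np.mgrid[0:H, 0:W]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def generate_phantom(size: int = 64, tumor_count: int = 1, noise_sigma: float = 0.05,
                     bias_strength: float = 0.3, seed: int = 0) -> PhantomSample:
    """Seeded 4-channel brain phantom with exact ground truth.

    The brain is a filled ellipse covering roughly 70% of the frame; tumors
    are mildly elliptical blobs sampled to lie fully inside the brain
    (bounded resampling); the bias field is the exponential of a random
    quadratic polynomial normalized to mean 1.
    """
    if size < 32:
        raise DataError("phantom size must be >= 32")
    if tumor_count < 0:
        raise DataError("tumor_count must be >= 0")
    rng = np.random.default_rng(seed)
    H = W = size
    cy = H / 2.0 + rng.uniform(-0.02, 0.02) * H
    cx = W / 2.0 + rng.uniform(-0.02, 0.02) * W
    ry = 0.45 * H * rng.uniform(0.95, 1.05)
    rx = 0.47 * W * rng.uniform(0.95, 1.05)
    brain = _ellipse_mask(H, W, cy, cx, ry, rx)

    mask = np.zeros((H, W), dtype=bool)
    tumors = []
    for _ in range(tumor_count):
        placed = False
        for _attempt in range(100):
            # the floor keeps the smallest blob clearly larger than half a
            # 16-px patch so patch-majority labels can represent it
            r = rng.uniform(0.14, 0.20) * size
            r1 = r * rng.uniform(0.85, 1.2)
            r2 = r * r / r1
            margin = max(r1, r2) + 1.0
            if margin >= min(ry, rx):
                continue
            # sample the center inside the shrunken brain ellipse
            ty = cy + rng.uniform(-1, 1) * (ry - margin)
            tx = cx + rng.uniform(-1, 1) * (rx - margin)
            if ((ty - cy) / (ry - margin)) ** 2 + ((tx - cx) / (rx - margin)) ** 2 > 1:
                continue
            blob = _ellipse_mask(H, W, ty, tx, r1, r2)
            if blob.any() and np.all(brain[blob]):
                mask |= blob
                tumors.append({"center": (float(ty), float(tx)),
                               "radii": (float(r1), float(r2))})
                placed = True
                break
        if not placed:
            raise DataError("could not place a tumor inside the brain ellipse")

    image = np.full((4, H, W), _BACKGROUND)
    for t in range(4):
        chan = image[t]
        chan[brain] = _BRAIN[t]
        chan[mask] = _BRAIN[t] + _TUMOR_DELTA[t]

    bias_coeffs = rng.normal(0.0, 1.0, size=6)
    if bias_strength > 0:
        yy, xx = np.mgrid[0:H, 0:W]
        yn = 2.0 * yy / (H - 1) - 1.0
        xn = 2.0 * xx / (W - 1) - 1.0
        poly = (bias_coeffs[0] * yn + bias_coeffs[1] * xn + bias_coeffs[2] * yn * xn
                + bias_coeffs[3] * yn**2 + bias_coeffs[4] * xn**2)
        fieldv = np.exp(bias_strength * poly / 3.0)
        fieldv /= fieldv.mean()
        image = image * fieldv[None]
    if noise_sigma > 0:
        image = image + rng.normal(0.0, noise_sigma, size=image.shape)

    meta = {
        "seed": seed, "size": size, "tumor_count": tumor_count,
        "noise_sigma": noise_sigma, "bias_strength": bias_strength,
        "brain": {"center": (float(cy), float(cx)), "radii": (float(ry), float(rx))},
        "tumors": tumors,
        "bias_coeffs": bias_coeffs.tolist(),
    }
    return PhantomSample(image=image, mask=mask.astype(np.uint8), meta=meta)


def stratified_split(class_labels, ratio=(7, 3), seed: int = 0):
    """Disjoint, exhaustive 7:3 split with per-class largest-remainder counts.

    Returns (train_indices, test_indices).  Every class should have at least
    2 members for exact stratification; smaller classes are split best
    effort with a warning.
    """
    y = np.asarray(class_labels)
    if y.size == 0:
        raise DataError("cannot split an empty collection")
    frac = ratio[0] / (ratio[0] + ratio[1])
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < 2:
            logger.warning("class %r has %d member(s); best-effort split", cls, idx.size)
        rng.shuffle(idx)
        n_c = idx.size
        q_train, q_test = n_c * frac, n_c * (1.0 - frac)
        t, s = int(np.floor(q_train)), int(np.floor(q_test))
        if t + s < n_c:  # one leftover item: larger remainder wins, ties -> train
            if (q_train - t) >= (q_test - s):
                t += 1
            else:
                s += 1
        train.extend(idx[:t])
        test.extend(idx[t:])
    return np.array(sorted(train), dtype=int), np.array(sorted(test), dtype=int)
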