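"""Feature extraction and affinity-graph construction.

Samples are connected by a mutual k-nearest-neighbor graph weighted with an
RBF kernel; the adaptive similarity matrix used by the semi-supervised SVM
is initialized from each row's own k nearest neighbors so that every row is
a probability vector, and the shared regularization weight lambda3 = lambda4
comes from the same neighborhood distances.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .data import AffinityGraph, FeatureMatrix, Laplacian
from .errors import DataError

logger = logging.getLogger(__name__)

__all__ = [
    "featurize_patches",
    "rbf_weight",
    "build_knn_graph",
    "init_similarity",
    "laplacian",
]

#: number of histogram bins per channel in the patch feature vector
_HIST_BINS = 8
#: companding constant used for patch histograms
_MU = 255.0


def featurize_patches(image: np.ndarray, patch_size: int, stride: int) -> FeatureMatrix:
    """Summarize a multi-channel image as one feature row per patch.

    Patches are half-open windows ``[r, r + patch_size)`` taken in row-major
    order on a regular grid with the given stride.  Per channel the feature
    vector holds the patch mean, the patch standard deviation, and an 8-bin
    histogram (mass fractions) of mu-law companded intensities, where each
    channel is min-max scaled to [0, 1] over the whole image before
    companding.  The patch grid is retained in ``meta`` so patch-level labels
    can be mapped back to pixels.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = img[None]
    if img.ndim != 3:
        raise DataError(f"expected (C, H, W) or (H, W) image, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise DataError("image contains non-finite pixels")
    if patch_size < 2 or stride < 1:
        raise DataError("need patch_size >= 2 and stride >= 1")
    C, H, W = img.shape
    if patch_size > H or patch_size > W:
        raise DataError(
            f"patch size {patch_size} exceeds image size {H}x{W}"
        )

    # per-channel min-max scaling then mu-law companding for the histograms
    mins = img.reshape(C, -1).min(axis=1)[:, None, None]
    maxs = img.reshape(C, -1).max(axis=1)[:, None, None]
    span = np.where(maxs > mins, maxs - mins, 1.0)
    scaled = (img - mins) / span
    companded = np.log1p(_MU * scaled) / np.log1p(_MU)

    rows = range(0, H - patch_size + 1, stride)
    cols = range(0, W - patch_size + 1, stride)
    origins = [(r, c) for r in rows for c in cols]
    edges = np.linspace(0.0, 1.0, _HIST_BINS + 1)
    feats = []
    ids = []
    for r, c in origins:
        win = img[:, r : r + patch_size, c : c + patch_size]
        cwin = companded[:, r : r + patch_size, c : c + patch_size]
        per_channel = []
        for t in range(C):
            hist, _ = np.histogram(cwin[t], bins=edges)
            hist = hist / cwin[t].size
            per_channel.append(
                np.concatenate(([win[t].mean(), win[t].std()], hist))
            )
        feats.append(np.concatenate(per_channel))
        ids.append(f"patch_{r}_{c}")
    meta = {
        "patch_size": patch_size,
        "stride": stride,
        "image_shape": (C, H, W),
        "origins": origins,
        "n_rows": len(list(rows)),
        "n_cols": len(list(cols)),
    }
    return FeatureMatrix(np.asarray(feats), ids, meta=meta)


def rbf_weight(xi: np.ndarray, xj: np.ndarray, sigma: float) -> float:
    """RBF edge weight exp(-||xi - xj||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise DataError(f"sigma must be positive, got {sigma}")
    diff = np.asarray(xi, dtype=float) - np.asarray(xj, dtype=float)
    return float(np.exp(-np.dot(diff, diff) / (2.0 * sigma**2)))


def _neighbor_order(D: np.ndarray) -> np.ndarray:
    """Column indices of each row of D sorted by (distance, index), self last."""
    n = D.shape[0]
    D = D.copy()
    np.fill_diagonal(D, np.inf)
    return np.argsort(D, axis=1, kind="stable")


def build_knn_graph(X: FeatureMatrix, k: int, sigma="auto") -> AffinityGraph:
    """Mutual k-nearest-neighbor graph with RBF weights.

    An edge (i, j) exists iff i and j are each within the other's k nearest
    neighbors under Euclidean distance (ties broken by ascending index).
    ``sigma="auto"`` uses the median of all pairwise distances.
    """
    V = X.values
    n = V.shape[0]
    if not 1 <= k < n:
        raise DataError(f"need 1 <= k < n, got k={k}, n={n}")
    D = cdist(V, V)
    if sigma == "auto":
        sigma = float(np.median(pdist(V)))
        if sigma <= 0:  # all points coincide
            sigma = 1.0
    if sigma <= 0:
        raise DataError(f"sigma must be positive, got {sigma}")
    order = _neighbor_order(D)
    is_neighbor = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    is_neighbor[rows, order[:, :k].ravel()] = True
    mutual = is_neighbor & is_neighbor.T
    W = np.where(mutual, np.exp(-(D**2) / (2.0 * sigma**2)), 0.0)
    np.fill_diagonal(W, 0.0)
    return AffinityGraph(W, k=k, sigma=float(sigma))


def init_similarity(X: FeatureMatrix, k: int) -> tuple[np.ndarray, float]:
    """Initial adaptive similarity matrix and lambda3 = lambda4.

    With squared Euclidean distances d_ij sorted ascending for each row i,
    the k nearest neighbors j receive

        s_ij = (d_{i,k+1} - d_ij) / (k d_{i,k+1} - sum_{j<=k} d_ij)

    and all other entries are 0, so each row sums to one.  The shared
    regularizer is the mean over all rows of
    (k/2) d_{i,k+1} - (1/2) sum_{j<=k} d_ij.  If the (k+1) nearest distances
    of a row are all equal the denominator vanishes; the row then gets
    uniform mass 1/k on its k neighbors and a warning is logged.
    """
    V = X.values
    n = V.shape[0]
    if not 1 <= k <= n - 2:
        raise DataError(f"need 1 <= k <= n-2 (a (k+1)-th neighbor), got k={k}, n={n}")
    D2 = cdist(V, V, metric="sqeuclidean")
    order = _neighbor_order(D2)
    s = np.zeros((n, n))
    terms = np.empty(n)
    for i in range(n):
        nbrs = order[i, :k]
        d_k = D2[i, nbrs]
        d_next = D2[i, order[i, k]]
        denom = k * d_next - d_k.sum()
        terms[i] = 0.5 * k * d_next - 0.5 * d_k.sum()
        if denom <= 1e-12:
            logger.warning(
                "degenerate neighborhood for sample %d (k+1 equal distances); "
                "using uniform weights",
                i,
            )
            s[i, nbrs] = 1.0 / k
        else:
            s[i, nbrs] = (d_next - d_k) / denom
    lambda34 = float(terms.mean())
    return s, lambda34


def laplacian(s: np.ndarray) -> Laplacian:
    """Graph Laplacian L = D - (s + s^T)/2 of a nonnegative similarity matrix."""
    s = np.asarray(s, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise DataError("similarity matrix must be square")
    if s.min() < 0:
        raise DataError("similarity matrix has negative entries")
    sym = 0.5 * (s + s.T)
    D = np.diag(sym.sum(axis=1))
    return Laplacian(L=D - sym, D=D)
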