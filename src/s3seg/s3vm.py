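"""Graph-regularized semi-supervised SVM by alternating optimization.

The joint objective couples a linear soft-margin SVM with an adaptive
similarity matrix ``s`` and a spectral embedding ``F``:

    min_{w,b,s,y_u}  1/2 w'w
                   + lambda1 * sum_i u_ii * hinge(y_i, w'x_i + b)
                   + lambda2 * (Xw)' L_s (Xw)
                   + lambda3 * ||s||^2
                   + lambda4 * tr(F' L_s F)
    s.t. each row of s on the probability simplex, F'F = I,

where ``L_s`` is the Laplacian of the symmetrized similarity, ``u_ii`` is 1
for labeled samples and a smaller weight for unlabeled ones, and the labels
of unlabeled samples are themselves optimization variables.  Each block
subproblem has an exact minimizer: the embedding is an eigenvector problem,
each similarity row is a Euclidean projection onto the simplex, the (w, b)
subproblem is a weighted soft-margin SVM in linearly transformed features,
and relabeling takes the sign of the decision value.  Alternating these
blocks therefore never increases the objective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.linalg
import scipy.optimize
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from .data import FeatureMatrix, Laplacian, PartialLabels
from .errors import DataError, NumericalError
from .graph import init_similarity, laplacian

logger = logging.getLogger(__name__)

__all__ = [
    "S3VMParams",
    "S3VMModel",
    "DualSolution",
    "svm_dual_fit",
    "evaluate_objective",
    "update_embedding",
    "update_similarity",
    "update_svm",
    "project_simplex",
    "fit",
    "predict",
]


@dataclass
class S3VMParams:
    """Hyperparameters of the joint objective.

    ``lambda3``/``lambda4`` default to None and are then set equal to the
    data-driven initialization and frozen for the rest of the fit.
    """

    lambda1: float = 1.0
    lambda2: float = 0.1
    lambda3: Optional[float] = None
    lambda4: Optional[float] = None
    k: int = 10
    c_embed: int = 2
    gamma_unlabeled: float = 0.1
    max_iter: int = 30
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.lambda1 <= 0:
            raise DataError("lambda1 must be positive")
        if self.lambda2 < 0:
            raise DataError("lambda2 must be nonnegative")
        if not 0.0 <= self.gamma_unlabeled <= 1.0:
            raise DataError("gamma_unlabeled must lie in [0, 1]")
        if self.tol <= 0:
            raise DataError("tol must be positive")


@dataclass
class S3VMModel:
    """Fitted model: hyperplane, similarity, embedding, completed labels."""

    w: np.ndarray
    b: float
    s: np.ndarray
    F: np.ndarray
    y_full: np.ndarray
    objective_trace: list = field(default_factory=list)
    params: Optional[S3VMParams] = None


@dataclass
class DualSolution:
    """Hard-margin SVM dual solution with KKT quantities."""

    alpha: np.ndarray
    w: np.ndarray
    b: float
    support_indices: np.ndarray


def _hinge(y: np.ndarray, f: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, 1.0 - f * y)


def svm_dual_fit(X: FeatureMatrix, y) -> DualSolution:
    """Hard-margin linear SVM via its dual quadratic program.

    Solves  min_a  1/2 a' Q a - 1'a  s.t.  y'a = 0, a >= 0  with
    Q_ij = y_i y_j x_i.x_j, reconstructs w = sum_i a_i y_i x_i and b from the
    support vectors, then polishes (a_S, b) on the active set by solving the
    KKT equations exactly.  Raises if the data are not linearly separable.
    """
    V = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.shape[0] != V.shape[0]:
        raise DataError("label length does not match sample count")
    if len(np.unique(y)) < 2:
        raise DataError("both classes must be present for an SVM fit")
    n = V.shape[0]
    G = V @ V.T
    Q = (y[:, None] * y[None, :]) * G

    def obj(a):
        return 0.5 * a @ Q @ a - a.sum()

    def jac(a):
        return Q @ a - 1.0

    res = scipy.optimize.minimize(
        obj,
        np.zeros(n),
        jac=jac,
        method="SLSQP",
        bounds=[(0.0, None)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    alpha = np.maximum(res.x, 0.0)
    support = np.flatnonzero(alpha > 1e-6 * max(alpha.max(), 1e-12))
    if support.size == 0:
        raise NumericalError("dual solve produced no support vectors")

    # polish on the active set: for i in S, sum_j a_j y_j x_i.x_j + b = y_i
    # together with sum_j a_j y_j = 0 -- the exact KKT linear system.
    S = support
    A = np.zeros((S.size + 1, S.size + 1))
    A[: S.size, : S.size] = G[np.ix_(S, S)] * y[S][None, :]
    A[: S.size, -1] = 1.0
    A[-1, : S.size] = y[S]
    rhs = np.concatenate([y[S], [0.0]])
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    if np.all(sol[:-1] >= -1e-8):
        alpha = np.zeros(n)
        alpha[S] = np.maximum(sol[:-1], 0.0)
        b = float(sol[-1])
        w = (alpha * y) @ V
    else:  # polish infeasible; keep the raw SLSQP point
        w = (alpha * y) @ V
        b = float(np.mean(y[S] - V[S] @ w))

    margins = y * (V @ w + b)
    if margins.min() < 1.0 - 1e-3:
        raise NumericalError(
            "data are not linearly separable by a hard margin; "
            "use the regularized update_svm path instead"
        )
    return DualSolution(alpha=alpha, w=w, b=b, support_indices=support)


def _objective_terms(V, y, u, w, b, s, F, params: S3VMParams):
    lam3 = params.lambda3 if params.lambda3 is not None else 1.0
    lam4 = params.lambda4 if params.lambda4 is not None else lam3
    lap = laplacian(s)
    f = V @ w + b
    g = V @ w
    terms = {
        "margin": 0.5 * float(w @ w),
        "hinge": params.lambda1 * float(u @ _hinge(y, f)),
        "smooth_w": params.lambda2 * float(g @ lap.L @ g),
        "s_norm": lam3 * float(np.sum(s * s)),
        "embed": lam4 * float(np.trace(F.T @ lap.L @ F)),
    }
    return terms


def evaluate_objective(model: S3VMModel, X: FeatureMatrix, labels: PartialLabels,
                       params: Optional[S3VMParams] = None) -> float:
    """Value of the joint objective for a model on the given data."""
    params = params or model.params
    V = X.values
    if V.shape[1] != model.w.shape[0]:
        raise DataError(
            f"feature dimension {V.shape[1]} does not match model dimension "
            f"{model.w.shape[0]}"
        )
    u = np.where(labels.labeled_mask, 1.0, params.gamma_unlabeled)
    terms = _objective_terms(V, model.y_full, u, model.w, model.b, model.s,
                             model.F, params)
    return float(sum(terms.values()))


def update_embedding(L, c_embed: int) -> np.ndarray:
    """Orthonormal eigenvectors of the c_embed smallest Laplacian eigenvalues.

    The sign of each eigenvector is fixed so its first component of magnitude
    above 1e-12 is positive, making the embedding deterministic.
    """
    Lm = L.L if isinstance(L, Laplacian) else np.asarray(L, dtype=float)
    n = Lm.shape[0]
    if c_embed >= n:
        raise DataError(f"c_embed must be < n, got c_embed={c_embed}, n={n}")
    _, vecs = scipy.linalg.eigh(Lm, subset_by_index=[0, c_embed - 1])
    for j in range(vecs.shape[1]):
        col = vecs[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            vecs[:, j] = -col
    return vecs


def project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row of v onto the probability simplex."""
    v = np.atleast_2d(np.asarray(v, dtype=float))
    u = -np.sort(-v, axis=1)
    css = np.cumsum(u, axis=1) - 1.0
    j = np.arange(1, v.shape[1] + 1)
    cond = u - css / j > 0
    rho = cond.shape[1] - 1 - np.argmax(cond[:, ::-1], axis=1)
    theta = css[np.arange(v.shape[0]), rho] / (rho + 1)
    return np.maximum(v - theta[:, None], 0.0)


def update_similarity(X: FeatureMatrix, w: np.ndarray, F: np.ndarray,
                      params: S3VMParams) -> np.ndarray:
    """Exact row-wise similarity update.

    Each row i minimizes  sum_j e_ij s_ij + 2 lambda3 s_ij^2  over the
    probability simplex, with
    e_ij = lambda2 (w'x_i - w'x_j)^2 + lambda4 ||f_i - f_j||^2.  Completing
    the square reduces every row to the Euclidean projection of
    -e_i / (4 lambda3) onto the simplex; the diagonal is excluded and forced
    to zero.
    """
    lam3 = params.lambda3
    if lam3 is None or lam3 <= 0:
        raise DataError("lambda3 must be positive for the similarity update")
    lam4 = params.lambda4 if params.lambda4 is not None else lam3
    V = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    n = V.shape[0]
    g = V @ w
    e = params.lambda2 * (g[:, None] - g[None, :]) ** 2
    e += lam4 * cdist(F, F, metric="sqeuclidean")
    off = ~np.eye(n, dtype=bool)
    v = (-e / (4.0 * lam3))[off].reshape(n, n - 1)
    rows = project_simplex(v)
    s = np.zeros((n, n))
    s[off] = rows.ravel()
    return s


def update_svm(X, y_full, u_weights, L, params: S3VMParams) -> tuple[np.ndarray, float]:
    """Exact (w, b) subproblem solve.

    Minimizes  1/2 w'(I + 2 lambda2 X'LX) w + lambda1 sum_i u_i hinge_i
    over (w, b).  Substituting v = A^{1/2} w with A = I + 2 lambda2 X'LX
    turns this into a weighted soft-margin linear SVM in the transformed
    features X A^{-1/2}, which is solved to high precision by a deterministic
    SMO solver; w is recovered as A^{-1/2} v.
    """
    V = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y_full, dtype=float)
    u = np.asarray(u_weights, dtype=float)
    if not (np.all(np.isfinite(V)) and np.all(np.isfinite(y)) and np.all(np.isfinite(u))):
        raise DataError("non-finite inputs to update_svm")
    d = V.shape[1]
    Lm = L.L if isinstance(L, Laplacian) else np.asarray(L, dtype=float)
    A = np.eye(d) + 2.0 * params.lambda2 * (V.T @ Lm @ V)
    A = 0.5 * (A + A.T)
    evals, evecs = scipy.linalg.eigh(A)
    evals = np.maximum(evals, 1e-12)
    A_isqrt = (evecs * (1.0 / np.sqrt(evals))) @ evecs.T
    Vt = V @ A_isqrt

    keep = u > 0
    svc = SVC(kernel="linear", C=params.lambda1, tol=1e-9, cache_size=256)
    svc.fit(Vt[keep], y[keep], sample_weight=u[keep])
    v = svc.coef_[0]
    b = float(svc.intercept_[0])
    w = A_isqrt @ v
    return w, b


def fit(X: FeatureMatrix, labels: PartialLabels, params: Optional[S3VMParams] = None) -> S3VMModel:
    """Alternating optimization of the joint semi-supervised objective.

    Initializes the similarity matrix and lambda3 = lambda4 from the data,
    warm-starts the unlabeled labels with a labeled-only SVM, then cycles
    embedding -> similarity -> hyperplane -> relabel until the relative
    objective change falls below ``tol`` or ``max_iter`` is reached.  The
    objective is recorded after every block update and never increases.
    """
    params = params or S3VMParams()
    V = X.values
    n = V.shape[0]
    y_in = labels.labels
    lab = labels.labeled_mask
    if len(np.unique(y_in[lab])) < 2:
        raise DataError("need at least one labeled sample in each class")
    if n < params.k + 2:
        raise DataError(f"need n >= k + 2 samples, got n={n}, k={params.k}")

    s, lam34 = init_similarity(X, params.k)
    if params.lambda3 is None:
        params.lambda3 = max(lam34, 1e-12)
    if params.lambda4 is None:
        params.lambda4 = params.lambda3

    u = np.where(lab, 1.0, params.gamma_unlabeled)

    # warm start: labeled-only regularized SVM, then sign-rule pseudo-labels
    zeroL = Laplacian(L=np.zeros((int(lab.sum()),) * 2), D=np.zeros((int(lab.sum()),) * 2))
    w, b = update_svm(V[lab], y_in[lab], np.ones(int(lab.sum())), zeroL, params)
    y_full = y_in.copy().astype(float)
    dec = V @ w + b
    y_full[~lab] = np.where(dec[~lab] >= 0.0, 1.0, -1.0)

    lap = laplacian(s)
    F = update_embedding(lap, params.c_embed)

    def obj(w_, b_, s_, F_, y_):
        return float(sum(_objective_terms(V, y_, u, w_, b_, s_, F_, params).values()))

    trace = [obj(w, b, s, F, y_full)]
    prev_cycle = trace[0]
    for _ in range(params.max_iter):
        F = update_embedding(laplacian(s), params.c_embed)
        trace.append(obj(w, b, s, F, y_full))

        s = update_similarity(X, w, F, params)
        trace.append(obj(w, b, s, F, y_full))

        lap = laplacian(s)
        w_new, b_new = update_svm(V, y_full, u, lap, params)
        # the subproblem solver is exact up to solver tolerance; keep the
        # better of old and new so the trace is monotone by construction
        if obj(w_new, b_new, s, F, y_full) <= trace[-1]:
            w, b = w_new, b_new
        trace.append(obj(w, b, s, F, y_full))

        dec = V @ w + b
        y_full[~lab] = np.where(dec[~lab] >= 0.0, 1.0, -1.0)
        trace.append(obj(w, b, s, F, y_full))

        if abs(trace[-1] - prev_cycle) < params.tol * max(1.0, abs(prev_cycle)):
            break
        prev_cycle = trace[-1]

    return S3VMModel(w=w, b=float(b), s=s, F=F, y_full=y_full.astype(int),
                     objective_trace=trace, params=params)


def predict(model: S3VMModel, X_new) -> np.ndarray:
    """Sign of the decision value; a value of exactly zero maps to +1."""
    V = X_new.values if isinstance(X_new, FeatureMatrix) else np.asarray(X_new, dtype=float)
    if V.ndim == 1:
        V = V[None]
    if V.shape[1] != model.w.shape[0]:
        raise DataError(
            f"feature dimension {V.shape[1]} does not match model dimension "
            f"{model.w.shape[0]}"
        )
    dec = V @ model.w + model.b
    return np.where(dec >= 0.0, 1, -1)
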