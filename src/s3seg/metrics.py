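"""Segmentation-overlap and regression-error metrics.

For a binary expert mask T and predicted mask P:

    Jaccard     = |T and P| / |T or P|
    DSC         = 2 |T and P| / (|T| + |P|)
    PPV         = |T and P| / |P|        (precision on predicted tumor)
    Sensitivity = |T and P| / |T|        (recall of true tumor)

Empty-denominator conventions: if both masks are empty every metric is 1
(a perfect all-background prediction); if exactly one is empty the affected
ratios are 0.  Both situations are logged when they occur.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DataError

logger = logging.getLogger(__name__)

__all__ = ["MetricsReport", "overlap_metrics", "rmse", "mae", "aggregate_reports"]


@dataclass
class MetricsReport:
    """Overlap ratios in [0, 1] plus the raw counts behind them."""

    jaccard: float
    dsc: float
    ppv: float
    sensitivity: float
    intersection: int
    union: int
    size_T: int
    size_P: int
    rmse: Optional[float] = None
    mae: Optional[float] = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _check_binary(mask: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(mask)
    if m.dtype == bool:
        return m.astype(np.uint8)
    if not np.all(np.isin(m, (0, 1))):
        raise DataError(f"{name} mask must be binary (entries in {{0, 1}})")
    return m.astype(np.uint8)


def overlap_metrics(truth: np.ndarray, pred: np.ndarray) -> MetricsReport:
    """Jaccard, DSC, PPV, and Sensitivity for a truth/prediction mask pair."""
    T = _check_binary(truth, "truth")
    P = _check_binary(pred, "prediction")
    if T.shape != P.shape:
        raise DataError(f"mask shapes differ: {T.shape} vs {P.shape}")
    inter = int(np.sum((T == 1) & (P == 1)))
    union = int(np.sum((T == 1) | (P == 1)))
    size_T = int(T.sum())
    size_P = int(P.sum())
    if size_T == 0 and size_P == 0:
        logger.info("both masks empty; scoring all metrics as 1")
        j = d = ppv = sens = 1.0
    else:
        if size_T == 0 or size_P == 0:
            logger.info("one mask empty; affected ratios score 0")
        j = inter / union if union else 0.0
        d = 2.0 * inter / (size_T + size_P)
        ppv = inter / size_P if size_P else 0.0
        sens = inter / size_T if size_T else 0.0
    return MetricsReport(jaccard=j, dsc=d, ppv=ppv, sensitivity=sens,
                         intersection=inter, union=union,
                         size_T=size_T, size_P=size_P)


def rmse(pred: Sequence[float], truth: Sequence[float]) -> float:
    """Root mean squared difference."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise DataError("rmse needs two equal-length nonempty sequences")
    return float(np.sqrt(np.mean((p - t) ** 2)))


def mae(pred: Sequence[float], truth: Sequence[float]) -> float:
    """Mean absolute difference."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise DataError("mae needs two equal-length nonempty sequences")
    return float(np.mean(np.abs(p - t)))


def aggregate_reports(reports: Sequence[MetricsReport]) -> dict:
    """Macro-average of per-image overlap metrics."""
    if not reports:
        raise DataError("no reports to aggregate")
    keys = ("jaccard", "dsc", "ppv", "sensitivity")
    return {k: float(np.mean([getattr(r, k) for r in reports])) for k in keys}
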