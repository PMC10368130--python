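"""Score-regression accuracy metrics: MAD, RMSE, MAPE."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["QualityMetrics", "metrics"]


@dataclass(frozen=True)
class QualityMetrics:
    """Mean absolute deviation, root-mean-square error and mean
    absolute percentage error of a prediction/label pairing."""

    mad: float
    rmse: float
    mape: float


def metrics(pred, truth) -> QualityMetrics:
    """MAD = mean|e|, RMSE = sqrt(mean e^2), MAPE = 100 mean|e/truth|.

    All three are computed from the same residuals e = pred - truth.
    MAPE requires every truth entry to be nonzero; the offending index
    is named otherwise.
    """
    pred = np.asarray(pred, float).reshape(-1)
    truth = np.asarray(truth, float).reshape(-1)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("prediction and truth must be equal, non-empty")
    zero = np.flatnonzero(truth == 0)
    if zero.size:
        raise ValueError(
            f"MAPE undefined: truth entry at index {int(zero[0])} is zero")
    e = pred - truth
    return QualityMetrics(
        mad=float(np.mean(np.abs(e))),
        rmse=float(np.sqrt(np.mean(e**2))),
        mape=float(100.0 * np.mean(np.abs(e) / np.abs(truth))),
    )
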