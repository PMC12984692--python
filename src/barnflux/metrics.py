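"""Regression evaluation metrics.

Six metrics summarise one model on one data partition: the Pearson
correlation R, the coefficient of determination R² (the squared correlation
between targets and predictions, matching the regression-analysis usage of
the modelling environment the settings mirror), MSE, RMSE, MAE, and SD, the
population standard deviation of the residuals.  SD equals RMSE exactly when
the mean residual is zero, which is why the two track each other closely for
well-trained networks.  An alternative 1 - SSE/SST definition of R² is also
computed (``R2_ss``) but the correlation-based value is the headline.

A model is conventionally deemed satisfactory when R > 0.80 and R² > 0.70.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["MetricsReport", "compute_metrics", "is_satisfactory",
           "R_THRESHOLD", "R2_THRESHOLD"]

R_THRESHOLD = 0.80
R2_THRESHOLD = 0.70


@dataclass(frozen=True)
class MetricsReport:
    """Evaluation metrics for one model on one partition."""

    R: float
    R2: float
    MSE: float
    RMSE: float
    MAE: float
    SD: float
    n: int
    partition: str = "test"
    R2_ss: float = float("nan")

    @property
    def satisfied(self) -> bool:
        return is_satisfactory(self.R, self.R2)

    def as_dict(self) -> dict:
        return {
            "R": self.R, "R2": self.R2, "MSE": self.MSE, "RMSE": self.RMSE,
            "MAE": self.MAE, "SD": self.SD, "n": self.n, "partition": self.partition,
        }


def is_satisfactory(r: float, r2: float) -> bool:
    """Model-quality rule: R above 0.80 and R² above 0.70 (strict)."""
    return bool(r > R_THRESHOLD and r2 > R2_THRESHOLD)


def compute_metrics(targets, predictions, partition: str = "test") -> MetricsReport:
    """Compute R, R², MSE, RMSE, MAE and SD on de-normalized values.

    With constant predictions (or constant targets) the correlation is
    undefined; R and R² are reported as NaN with a warning while the error
    metrics are still returned.
    """
    t = np.asarray(targets, dtype=float).ravel()
    p = np.asarray(predictions, dtype=float).ravel()
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if t.size < 2:
        raise ValueError("need at least 2 points to evaluate")

    resid = p - t
    mse = float(np.mean(resid**2))
    rmse = math.sqrt(mse)
    mae = float(np.mean(np.abs(resid)))
    sd = float(np.std(resid))

    sst = float(np.sum((t - t.mean()) ** 2))
    if np.std(t) == 0.0 or np.std(p) == 0.0:
        warnings.warn("constant series: correlation undefined", stacklevel=2)
        r = float("nan")
        r2 = float("nan")
    else:
        r = float(np.corrcoef(t, p)[0, 1])
        r2 = r * r
    r2_ss = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else float("nan")
    return MetricsReport(R=r, R2=r2, MSE=mse, RMSE=rmse, MAE=mae, SD=sd,
                         n=t.size, partition=partition, R2_ss=r2_ss)
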