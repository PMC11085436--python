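"""Goodness-of-fit and validation statistics shared by model fitting and validation.

The six assessment statistics used throughout the package are the adjusted
coefficient of determination (R2a), root mean square error (RMSE), Akaike
information criterion (AIC) for the fitting stage, and the mean error (ME),
mean absolute error (MAE) and fit index (FI) for the validation stage, plus
the Pearson product-moment correlation used in the covariate screen.

Conventions (deliberately mixed, matching common forestry practice):

* ``rmse`` uses the degrees-of-freedom divisor ``n - p``.
* ``me`` and ``mae`` use the plain divisor ``n``.
* ``aic = n * ln(SSE / n) + 2p``, the standard least-squares AIC up to an
  additive constant; only AIC *differences* between models fitted to the
  same response are meaningful.
* ``fi`` (fit index) is ``1 - SSE/SST``; computed on the fitting set it is
  identical to the unadjusted R2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

__all__ = ["FitReport", "fit_report", "pearson", "adjusted_r2_from_rmse_sd"]


@dataclass
class FitReport:
    """Statistics for one model on one data set (fitting or held-out)."""

    n: Optional[int] = None
    p: Optional[int] = None
    r2: Optional[float] = None
    r2_adjusted: Optional[float] = None
    rmse: Optional[float] = None
    aic: Optional[float] = None
    me: Optional[float] = None
    mae: Optional[float] = None
    fi: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)


def fit_report(y, yhat, p: int) -> FitReport:
    """Compute the full statistics block for predictions ``yhat`` of ``y``.

    Parameters
    ----------
    y, yhat : array-like, same length
        Observed and predicted response (LMA, g/m^2).
    p : int
        Number of fitted parameters; must satisfy ``n > p``.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError("y and yhat must be 1-d arrays of equal length")
    n = y.size
    p = int(p)
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")

    resid = y - yhat
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))

    if sst == 0.0:
        warnings.warn("zero-variance response: R2 and FI are undefined", stacklevel=2)
        r2 = r2a = fi = float("nan")
    else:
        r2 = 1.0 - sse / sst
        r2a = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
        fi = r2

    rmse = float(np.sqrt(sse / (n - p)))
    # log(0) -> -inf for a perfect fit; that is the honest limit of this AIC.
    with np.errstate(divide="ignore"):
        aic = float(n * np.log(sse / n) + 2 * p) if sse > 0 else float("-inf")

    return FitReport(
        n=n,
        p=p,
        r2=r2,
        r2_adjusted=r2a,
        rmse=rmse,
        aic=aic,
        me=float(resid.mean()),
        mae=float(np.abs(resid).mean()),
        fi=fi,
    )


def pearson(x, y) -> float:
    """Pearson product-moment correlation of two samples.

    Requires length >= 3 and non-constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(np.corrcoef(x, y)[0, 1])


def adjusted_r2_from_rmse_sd(rmse: float, sd: float, n: int, p: int) -> float:
    """Reconstruct R2a from a reported RMSE and the response standard deviation.

    Uses SSE = rmse^2 (n - p) (RMSE with the n-p divisor) and
    SST = sd^2 (n - 1) (sample SD), then the usual adjustment.
    Useful as an internal-consistency check on published fit tables.
    """
    sse = rmse**2 * (n - p)
    sst = sd**2 * (n - 1)
    r2 = 1.0 - sse / sst
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p)
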