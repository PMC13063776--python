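"""Curve estimation: power, linear and exponential fits with R² and p.

Power laws ``y = a * x**b`` relate both the bone properties to the
Hounsfield unit and the lattice properties to the strut ratio t/L;
linear and exponential forms are used for the screw pull-out force.
Power and exponential models are fitted by ordinary least squares on
the log-transformed data (the classic curve-estimation convention), so
R² and the p-value of the slope refer to the transformed space.  An
iterative nonlinear least-squares mode is available for sensitivity
checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CurveFit",
    "fit_power",
    "fit_linear",
    "fit_exponential",
    "predict",
    "read_xy_csv",
    "write_fit_json",
]


@dataclass(frozen=True)
class CurveFit:
    """A fitted two-parameter curve.

    model      one of ``power`` (y = a·x^b), ``linear`` (y = a·x + b),
               ``exponential`` (y = a·e^(b·x))
    constant   a (multiplier for power/exponential, slope for linear)
    exponent   b (exponent, intercept, or rate depending on model)
    r_squared  coefficient of determination (log space for power/exponential)
    p_value    significance of the single regressor (F-test == two-sided t)
    """

    model: str
    constant: float
    exponent: float
    r_squared: float
    p_value: float

    def __post_init__(self) -> None:
        if self.model not in ("power", "linear", "exponential"):
            raise ValueError(f"unknown model {self.model!r}")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Slope, intercept, R² and slope p-value of simple OLS.

    For a single regressor the F-test of the regression equals the
    two-sided t-test of the slope.  A constant response is returned as
    slope 0, R² 0, p 1 rather than NaN.
    """
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope is unidentifiable")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0, 1.0
    res = stats.linregress(x, y)
    r2 = min(float(res.rvalue) ** 2, 1.0)
    return float(res.slope), float(res.intercept), r2, float(res.pvalue)


def _check_positive(arr: np.ndarray, name: str) -> None:
    if np.any(arr <= 0):
        raise ValueError(f"{name} must be strictly positive for this model")


def fit_power(x, y, nonlinear: bool = False) -> CurveFit:
    """Fit ``y = a * x**b`` by OLS on (ln x, ln y).

    With ``nonlinear=True`` the log-space estimate is refined by
    Levenberg-Marquardt least squares in linear space (R²/p still
    reported from log space for comparability).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_positive(x, "x")
    _check_positive(y, "y")
    slope, intercept, r2, p = _ols(np.log(x), np.log(y))
    a, b = float(np.exp(intercept)), slope
    if nonlinear:
        (a, b), _ = optimize.curve_fit(
            lambda t, a_, b_: a_ * t**b_, x, y, p0=(a, b), maxfev=10000
        )
    return CurveFit("power", float(a), float(b), r2, p)


def fit_linear(x, y) -> CurveFit:
    """Fit ``y = a*x + b`` by OLS; constant = slope a, exponent = intercept b."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    slope, intercept, r2, p = _ols(x, y)
    return CurveFit("linear", slope, intercept, r2, p)


def fit_exponential(x, y, nonlinear: bool = False) -> CurveFit:
    """Fit ``y = a * exp(b*x)`` by OLS on (x, ln y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_positive(y, "y")
    slope, intercept, r2, p = _ols(x, np.log(y))
    a, b = float(np.exp(intercept)), slope
    if nonlinear:
        (a, b), _ = optimize.curve_fit(
            lambda t, a_, b_: a_ * np.exp(b_ * t), x, y, p0=(a, b), maxfev=10000
        )
    return CurveFit("exponential", float(a), float(b), r2, p)


def predict(fit: CurveFit, x) -> np.ndarray:
    """Evaluate a fitted model at ``x`` (scalar or array)."""
    x = np.asarray(x, dtype=float)
    if fit.model == "power":
        if np.any(x <= 0):
            raise ValueError("power model is defined for x > 0 only")
        out = fit.constant * x**fit.exponent
    elif fit.model == "linear":
        out = fit.constant * x + fit.exponent
    elif fit.model == "exponential":
        out = fit.constant * np.exp(fit.exponent * x)
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(fit.model)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# I/O helpers


def read_xy_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read ``x,y`` pairs from a headed CSV."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"x", "y"} <= set(df.columns):
        raise ValueError("CSV must have columns x,y")
    return df["x"].to_numpy(float), df["y"].to_numpy(float)


def write_fit_json(path, fit: CurveFit) -> None:
    with open(path, "w") as fh:
        json.dump(fit.to_dict(), fh, indent=2)
        fh.write("\n")
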