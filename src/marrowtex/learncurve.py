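"""Inverse-power-law learning curves and sample-size estimation.

Classifier performance as a function of training-set size x is modeled
as ``y = (1 - a) - b * x**c`` where ``a`` is the minimum achievable
error (so ``1 - a`` is the asymptote), ``b`` the learning rate and
``c`` the decay rate; a well-behaved curve has ``b > 0`` and ``c < 0``
(monotone increasing, saturating).  Coefficients are estimated by
weighted nonlinear least squares with the Levenberg-Marquardt
algorithm.  Goodness of fit is summarized by
``SSE = sum_i w_i (y_i - yhat_i)^2`` and
``RMSE = sqrt(SSE / (n - m))`` with ``m = 3`` fitted coefficients.
The fitted curve is inverted in closed form to give the smallest
training size whose predicted performance exceeds a target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import t as t_dist

__all__ = [
    "CurvePoint",
    "LearningCurveFit",
    "GoodnessOfFit",
    "evaluate_curve",
    "fit_inverse_power",
    "required_sample_size",
    "prediction_bounds",
    "save_points_csv",
    "load_points_csv",
]

_M_COEFFS = 3


@dataclass(frozen=True)
class CurvePoint:
    """One observation: performance ``y`` at training size ``x``."""

    x: float
    y: float
    w: float = 1.0

    def __post_init__(self) -> None:
        if self.x < 0:
            raise ValueError("x must be >= 0")
        if not 0.0 <= self.y <= 1.0:
            raise ValueError("y must be a proportion in [0, 1]")
        if self.w <= 0:
            raise ValueError("weight must be > 0")


@dataclass
class LearningCurveFit:
    """Fitted coefficients of the inverse power law."""

    a: float
    b: float
    c: float
    covariance: np.ndarray
    points: list[CurvePoint] = field(default_factory=list)
    residual_variance: float = 0.0

    @property
    def asymptote(self) -> float:
        return 1.0 - self.a

    @property
    def well_behaved(self) -> bool:
        """True when the curve is monotone increasing (b > 0, c < 0)."""
        return self.b > 0 and self.c < 0


@dataclass
class GoodnessOfFit:
    SSE: float
    RMSE: float
    n: int
    m: int = _M_COEFFS


def _model(x, a, b, c):
    return (1.0 - a) - b * np.power(x, c)


def evaluate_curve(fit: LearningCurveFit, x) -> np.ndarray | float:
    """Predicted performance at training size ``x`` (> 0 when c < 0)."""
    x_arr = np.asarray(x, dtype=float)
    if fit.c < 0 and np.any(x_arr <= 0):
        raise ValueError("x must be > 0 when the decay rate c is negative")
    y = _model(x_arr, fit.a, fit.b, fit.c)
    return float(y) if np.isscalar(x) or x_arr.ndim == 0 else y


def fit_inverse_power(
    points: Sequence[CurvePoint],
    x0: tuple[float, float, float] | None = None,
    max_iters: int = 10_000,
    tol: float = 1e-10,
) -> tuple[LearningCurveFit, GoodnessOfFit]:
    """Weighted Levenberg-Marquardt fit of ``y = (1 - a) - b x^c``.

    Points at x = 0 (chance-level anchors) are excluded from the fit
    because the model is undefined there for c < 0.  Requires at least
    4 usable points so the residual degrees of freedom are positive.
    Initialization: ``a0 = 1 - max(y)``, ``b0 = 1``, ``c0 = -0.5``.
    """
    usable = [p for p in points if p.x > 0]
    n = len(usable)
    if n <= _M_COEFFS:
        raise ValueError(
            f"need more than {_M_COEFFS} points with x > 0, got {n}"
        )
    x = np.array([p.x for p in usable])
    y = np.array([p.y for p in usable])
    sw = np.sqrt(np.array([p.w for p in usable]))
    if x0 is None:
        x0 = (1.0 - y.max(), 1.0, -0.5)

    def residuals(theta):
        a, b, c = theta
        return sw * (y - _model(x, a, b, c))

    def jac(theta):
        a, b, c = theta
        xc = np.power(x, c)
        # dr/dtheta = -df/dtheta, weighted
        return np.column_stack(
            [sw * np.ones_like(x), sw * xc, sw * b * xc * np.log(x)]
        )

    sol = least_squares(
        residuals,
        x0=np.asarray(x0, dtype=float),
        jac=jac,
        method="lm",
        xtol=tol,
        ftol=tol,
        gtol=tol,
        max_nfev=max_iters,
    )
    if not sol.success:
        raise RuntimeError(
            f"Levenberg-Marquardt did not converge: {sol.message}; "
            f"last iterate {sol.x}"
        )
    a, b, c = sol.x
    resid = residuals(sol.x)
    sse = float(np.sum(resid**2))
    rmse = math.sqrt(sse / (n - _M_COEFFS))
    s2 = sse / (n - _M_COEFFS)
    J = jac(sol.x)
    JtJ = J.T @ J
    try:
        cov = s2 * np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(JtJ)
    fit = LearningCurveFit(
        a=float(a),
        b=float(b),
        c=float(c),
        covariance=cov,
        points=list(points),
        residual_variance=s2,
    )
    gof = GoodnessOfFit(SSE=sse, RMSE=rmse, n=n)
    return fit, gof


def required_sample_size(fit: LearningCurveFit, target: float) -> int:
    """Smallest integer training size exceeding the curve's inverse at
    ``target``: ``x* = ((1 - a - target) / b) ** (1 / c)``.

    Requires a monotone increasing curve (b > 0, c < 0) and a target
    below the asymptote ``1 - a``.
    """
    if not fit.well_behaved:
        raise ValueError("curve must have b > 0 and c < 0 to be inverted")
    gap = (1.0 - fit.a) - target
    if gap <= 0:
        raise ValueError(
            f"target {target} exceeds the asymptote {1.0 - fit.a:.6g}"
        )
    x_star = (gap / fit.b) ** (1.0 / fit.c)
    # strictly-greater integer, robust to float round-off near integers
    return int(math.floor(x_star * (1 + 1e-12) + 1e-9)) + 1


def prediction_bounds(
    fit: LearningCurveFit,
    x_grid,
    level: float = 0.95,
    include_observation_noise: bool = True,
):
    """Delta-method 95% bounds around the fitted curve.

    Returns ``(yhat, lower, upper)`` on ``x_grid``.  With
    ``include_observation_noise`` the bounds are prediction bounds for
    a new observation (parameter uncertainty plus residual variance);
    without it they are confidence bounds for the mean curve.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    if fit.c < 0 and np.any(x_grid <= 0):
        raise ValueError("x_grid must be > 0")
    if fit.covariance is None or not np.all(np.isfinite(fit.covariance)):
        raise ValueError("fit has no usable covariance")
    n = len([p for p in fit.points if p.x > 0])
    dof = n - _M_COEFFS
    if dof < 1:
        raise ValueError("no residual degrees of freedom")
    yhat = _model(x_grid, fit.a, fit.b, fit.c)
    xc = np.power(x_grid, fit.c)
    G = np.column_stack([-np.ones_like(x_grid), -xc, -fit.b * xc * np.log(x_grid)])
    var_mean = np.einsum("ij,jk,ik->i", G, fit.covariance, G)
    var = var_mean + (fit.residual_variance if include_observation_noise else 0.0)
    half = t_dist.ppf((1 + level) / 2, dof) * np.sqrt(np.maximum(var, 0.0))
    return yhat, yhat - half, yhat + half


def save_points_csv(points: Sequence[CurvePoint], path) -> None:
    """Columns: size, performance, weight."""
    import pandas as pd

    pd.DataFrame(
        [{"size": p.x, "performance": p.y, "weight": p.w} for p in points]
    ).to_csv(path, index=False)


def load_points_csv(path) -> list[CurvePoint]:
    import pandas as pd

    df = pd.read_csv(path)
    return [
        CurvePoint(x=float(r["size"]), y=float(r["performance"]),
                   w=float(r.get("weight", 1.0)))
        for _, r in df.iterrows()
    ]
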