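"""Egg-production response surfaces: tricube LOESS and the 3D Lorentzian model.

Daily cohort means of (age ``x``, corrected intake ``y``, eggs per female
``z``) are modelled two ways:

* non-parametrically, by locally weighted degree-1 regression (LOESS) with the
  tricube kernel over a fraction ``q`` of nearest points;
* parametrically, by a product-Lorentzian peak

  .. math:: f(x, y) = \\frac{\\alpha}{\\bigl[1 + ((x-x_0)/\\beta)^2\\bigr]
                             \\bigl[1 + ((y-y_0)/\\gamma)^2\\bigr]}

  whose five parameters are the peak location ``(x0, y0)`` (age at peak,
  intake at peak), the peak amplitude ``alpha`` (eggs/day) and the half-widths
  ``beta`` (age, days) and ``gamma`` (intake units).  ``f`` equals ``alpha``
  at the peak and ``alpha/2`` one half-width away along either axis.

The nonlinear fit minimises the unweighted residual sum of squares by
Levenberg-Marquardt, with positivity of ``alpha, beta, gamma`` enforced by
optimising their logarithms.  Inference follows the classical nonlinear-
regression ANOVA "corrected for the mean": the regression sum of squares is
defined by subtraction from the total about the mean, on 4 regression degrees
of freedom (5 parameters minus 1 for the mean correction), and Wald standard
errors come from ``ms_res * inv(J'J)`` with the analytic Jacobian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

PARAM_NAMES = ("x0", "y0", "alpha", "beta", "gamma")


class FitError(RuntimeError):
    """The nonlinear fit could not be run on these data."""


class ConvergenceError(FitError):
    """Levenberg-Marquardt did not converge; carries the last iterate."""

    def __init__(self, message: str, last_params: "LorentzianParams"):
        super().__init__(message)
        self.last_params = last_params


class InferenceError(RuntimeError):
    """Singular J'J: standard errors are not available."""


class LoessError(RuntimeError):
    """Singular local design at a LOESS query point."""


@dataclass(frozen=True)
class SurfacePoint:
    """One (age, mean daily intake, mean daily eggs) observation."""

    x: float
    y: float
    z: float


@dataclass(frozen=True)
class LorentzianParams:
    """Peak location (x0, y0), amplitude alpha, half-widths beta (age) and gamma (intake)."""

    x0: float
    y0: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0 and self.gamma > 0):
            raise ValueError("alpha, beta and gamma must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.x0, self.y0, self.alpha, self.beta, self.gamma])


@dataclass(frozen=True)
class LoessConfig:
    """Smoothing fraction q in ((degree+1)/n, 1); degree fixed at 1; tricube weights.

    ``weights="uniform"`` replaces the tricube kernel by constant weights,
    which at q -> 1 reduces the fit to the global least-squares plane.
    """

    q: float
    degree: int = 1
    weights: str = "tricube"

    def validate_for(self, n: int) -> None:
        low = (self.degree + 1) / n
        if not (low < self.q < 1):
            raise ValueError(f"q={self.q} outside admissible ({low:.4g}, 1) for n={n}")
        if self.degree != 1:
            raise ValueError("only local degree 1 is supported")
        if self.weights not in ("tricube", "uniform"):
            raise ValueError(f"unknown weight kind {self.weights!r}")


def points_to_arrays(points) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = np.array([p.x for p in points], dtype=float)
    y = np.array([p.y for p in points], dtype=float)
    z = np.array([p.z for p in points], dtype=float)
    return x, y, z


def tricube_weight(u):
    """Tricube kernel ``(1 - |u|^3)^3`` on ``|u| < 1``, else 0."""
    u = np.abs(np.asarray(u, dtype=float))
    w = np.where(u < 1, (1 - u**3) ** 3, 0.0)
    return w if w.ndim else float(w)


def lorentzian_eval(params: LorentzianParams, x, y):
    """Expected eggs/day at age ``x`` and intake ``y`` under the Lorentzian surface."""
    u = (np.asarray(x, dtype=float) - params.x0) / params.beta
    v = (np.asarray(y, dtype=float) - params.y0) / params.gamma
    out = params.alpha / ((1 + u**2) * (1 + v**2))
    return out if out.ndim else float(out)


def lorentzian_jacobian(params: LorentzianParams, x, y) -> np.ndarray:
    """Analytic Jacobian of the surface w.r.t. (x0, y0, alpha, beta, gamma), shape (n, 5)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    u = (x - params.x0) / params.beta
    v = (y - params.y0) / params.gamma
    A = 1 + u**2
    B = 1 + v**2
    f = params.alpha / (A * B)
    d_x0 = f * 2 * u / (params.beta * A)
    d_y0 = f * 2 * v / (params.gamma * B)
    d_alpha = 1.0 / (A * B)
    d_beta = f * 2 * u**2 / (params.beta * A)
    d_gamma = f * 2 * v**2 / (params.gamma * B)
    return np.column_stack([d_x0, d_y0, d_alpha, d_beta, d_gamma])


# ---------------------------------------------------------------------------
# LOESS


def loess_fit_predict(points, config: LoessConfig, queries) -> np.ndarray:
    """Predict the response at each query by tricube-weighted local planes.

    For each query the ``ceil(q*n)`` nearest points in standardised predictor
    space are selected, weighted by the tricube of distance scaled to the
    neighbourhood's maximum distance, and a weighted least-squares plane is
    fitted and evaluated at the query.
    """
    x, y, z = points_to_arrays(points)
    n = x.size
    config.validate_for(n)
    q_arr = np.atleast_2d(np.asarray(queries, dtype=float))
    sx = x.std(ddof=1) or 1.0
    sy = y.std(ddof=1) or 1.0
    X = np.column_stack([x / sx, y / sy])
    k = math.ceil(config.q * n)
    k = max(k, config.degree + 2)  # need more points than plane coefficients
    preds = np.empty(q_arr.shape[0])
    for i, (qx, qy) in enumerate(q_arr):
        d = np.hypot(X[:, 0] - qx / sx, X[:, 1] - qy / sy)
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        if config.weights == "uniform":
            w = np.ones(k)
        elif dmax == 0:
            w = np.ones(k)
        else:
            w = tricube_weight(d[idx] / dmax)
            # boundary point of the neighbourhood gets weight 0; keep the
            # design overdetermined by never letting all weight collapse
            if np.count_nonzero(w) < 3:
                raise LoessError(f"fewer than 3 weighted points at query ({qx}, {qy})")
        A = np.column_stack([np.ones(k), x[idx] - qx, y[idx] - qy])
        sw = np.sqrt(w)
        coef, _, rank, _ = np.linalg.lstsq(A * sw[:, None], z[idx] * sw, rcond=None)
        if rank < 3:
            raise LoessError(f"singular (collinear) local design at query ({qx}, {qy})")
        preds[i] = coef[0]
    return preds


# ---------------------------------------------------------------------------
# Aggregation


def aggregate_daily_means(table, max_age: int = 60) -> list[SurfacePoint]:
    """Cohort daily means: one point per age day with x = day, y = mean
    corrected intake and z = mean eggs among flies alive (observed) that day.

    Days past ``max_age`` or with no living fly are omitted.  Requires a
    female cohort with egg counts.
    """
    from .records import Sex, intake_series

    if not any(r.eggs is not None and r.sex is Sex.F for r in table.records):
        raise ValueError("aggregate_daily_means needs a female cohort with egg counts")
    eggs_by_day: dict[int, list[float]] = {}
    intake_by_day: dict[int, list[float]] = {}
    for fid in table.fly_ids():
        for day, val in intake_series(table, fid):
            if day <= max_age:
                intake_by_day.setdefault(day, []).append(val)
    for r in table.records:
        if r.eggs is not None and r.age_day <= max_age and r.age_day <= table.death_day[r.fly_id]:
            eggs_by_day.setdefault(r.age_day, []).append(float(r.eggs))
    points = []
    for day in sorted(intake_by_day):
        if day not in eggs_by_day:
            continue
        points.append(
            SurfacePoint(
                x=float(day),
                y=float(np.mean(intake_by_day[day])),
                z=float(np.mean(eggs_by_day[day])),
            )
        )
    return points


# ---------------------------------------------------------------------------
# Nonlinear fit and inference


@dataclass(frozen=True)
class FitInference:
    """Coefficient table and ANOVA (corrected for the mean) of a Lorentzian fit."""

    estimates: LorentzianParams
    se: dict[str, float]
    t: dict[str, float]
    p: dict[str, float]
    ss_reg: float
    ss_res: float
    ss_total: float
    df_reg: int
    df_res: int
    df_total: int
    ms_reg: float
    ms_res: float
    F: float
    F_p: float
    r: float
    r2: float
    adj_r2: float
    se_estimate: float


def anova_from_sums(ss_res: float, n: int, ss_total: float | None = None,
                    ss_reg: float | None = None) -> dict[str, float]:
    """ANOVA-corrected-for-the-mean scalars from sums of squares.

    Exactly one of ``ss_total`` / ``ss_reg`` may be omitted; the third is
    recovered from ``ss_total = ss_reg + ss_res``.  Degrees of freedom follow
    the 5-parameter model: regression 4, residual n-5, total n-1.
    """
    if ss_total is None and ss_reg is None:
        raise ValueError("provide ss_total or ss_reg")
    if ss_total is None:
        ss_total = ss_reg + ss_res
    if ss_reg is None:
        ss_reg = ss_total - ss_res
    df_reg, df_res, df_total = 4, n - 5, n - 1
    ms_reg = ss_reg / df_reg
    ms_res = ss_res / df_res
    F = ms_reg / ms_res if ms_res > 0 else math.inf
    F_p = float(stats.f.sf(F, df_reg, df_res)) if math.isfinite(F) else 0.0
    r2 = ss_reg / ss_total
    adj_r2 = 1 - ms_res / (ss_total / df_total)
    return {
        "ss_reg": ss_reg, "ss_res": ss_res, "ss_total": ss_total,
        "df_reg": df_reg, "df_res": df_res, "df_total": df_total,
        "ms_reg": ms_reg, "ms_res": ms_res, "F": F, "F_p": F_p,
        "r": math.sqrt(max(r2, 0.0)), "r2": r2, "adj_r2": adj_r2,
        "se_estimate": math.sqrt(ms_res),
    }


def compute_inference(points, params: LorentzianParams) -> FitInference:
    """Wald coefficient table and ANOVA block for a converged Lorentzian fit.

    Parameter covariance is ``ms_res * inv(J'J)`` with the analytic Jacobian
    at the estimates; t = estimate/SE with two-sided p on n-5 df.
    """
    x, y, z = points_to_arrays(points)
    n = x.size
    resid = z - lorentzian_eval(params, x, y)
    ss_res = float(resid @ resid)
    ss_total = float(np.sum((z - z.mean()) ** 2))
    block = anova_from_sums(ss_res=ss_res, n=n, ss_total=ss_total)
    J = lorentzian_jacobian(params, x, y)
    JtJ = J.T @ J
    try:
        cov = block["ms_res"] * np.linalg.inv(JtJ)
    except np.linalg.LinAlgError as exc:
        raise InferenceError("singular J'J: standard errors unavailable") from exc
    se_arr = np.sqrt(np.diag(cov))
    est = params.as_array()
    with np.errstate(divide="ignore", invalid="ignore"):
        t_arr = est / se_arr
    p_arr = 2 * stats.t.sf(np.abs(t_arr), block["df_res"])
    return FitInference(
        estimates=params,
        se=dict(zip(PARAM_NAMES, se_arr.tolist())),
        t=dict(zip(PARAM_NAMES, t_arr.tolist())),
        p=dict(zip(PARAM_NAMES, p_arr.tolist())),
        **block,
    )


def _default_init(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> LorentzianParams:
    i = int(np.argmax(z))
    return LorentzianParams(
        x0=float(x[i]),
        y0=float(y[i]),
        alpha=float(max(z.max(), 1e-6)),
        beta=float(max(np.ptp(x) / 2, 1e-6)),
        gamma=float(max(np.ptp(y) / 2, 1e-6)),
    )


def fit_lorentzian(
    points,
    init: LorentzianParams | None = None,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> tuple[LorentzianParams, FitInference]:
    """Least-squares Lorentzian surface fit with Wald inference.

    Minimises the residual sum of squares by Levenberg-Marquardt on
    ``(x0, y0, log alpha, log beta, log gamma)``; convergence when the
    relative SS change drops below ``tol``.  Default start: peak location at
    the arg-max point, amplitude at max z, half-widths at half the predictor
    ranges.
    """
    x, y, z = points_to_arrays(points)
    n = x.size
    if n < 6:
        raise FitError(f"need at least 6 points to fit 5 parameters, got {n}")
    if np.ptp(z) == 0:
        raise FitError("degenerate data: constant response")
    p0 = init if init is not None else _default_init(x, y, z)
    theta0 = np.array([p0.x0, p0.y0, math.log(p0.alpha), math.log(p0.beta), math.log(p0.gamma)])

    def unpack(theta: np.ndarray) -> LorentzianParams:
        return LorentzianParams(
            x0=float(theta[0]), y0=float(theta[1]),
            alpha=float(math.exp(theta[2])), beta=float(math.exp(theta[3])),
            gamma=float(math.exp(theta[4])),
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        return lorentzian_eval(unpack(theta), x, y) - z

    def jac(theta: np.ndarray) -> np.ndarray:
        p = unpack(theta)
        J = lorentzian_jacobian(p, x, y)
        # chain rule for the log-scale parameters
        J[:, 2] *= p.alpha
        J[:, 3] *= p.beta
        J[:, 4] *= p.gamma
        return J

    res = optimize.least_squares(
        residuals, theta0, jac=jac, method="lm",
        ftol=tol, xtol=1e-14, gtol=1e-14, max_nfev=max_iter * 6,
    )
    params = unpack(res.x)
    if res.status <= 0:
        raise ConvergenceError(
            f"Levenberg-Marquardt did not converge within {max_iter} iterations", params
        )
    return params, compute_inference(points, params)
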