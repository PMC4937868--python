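"""Elimination-half-life estimation from CSTD plus an intake time series.

Given a declining cross-sectional trend and a reconstruction of the
population intake trend, the static PPK model links the two: each sampled
individual's concentration is the static forward solution of first-order
uptake and elimination over their lifetime, driven by the (log-linearly
interpolated) intake series.  The intrinsic elimination half-life is the
value whose forward predictions best match the observed concentrations in
least squares on the log scale, found by 1-D bounded minimization.

The absolute scale of reconstructed intake and of the assumed body constants
is uncertain, so by default a multiplicative intake scale factor is profiled
out analytically (the optimal log-scale is the mean log-residual); the
estimate then depends only on the *shapes* of the two series.

The estimator inherits the static model's assumptions — no mother-to-child
transfer, constant body and lipid weight.  For slowly eliminated chemicals
(elimination half-life above the intake halving time, or roughly >= 10
years) those assumptions fail and the tool systematically underestimates the
elimination half-life; the recommender flags such results as invalid, and the
age–concentration diagnostic provides an empirical cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import FitError, PeriodError
from .exposure import LN2, ChemicalParams
from .ppk_static import StaticBody, concentration_static_from_intake
from .series import CSTDSeries, IntakeSeries
from .trend_analysis import TrendFit, fit_loglinear

__all__ = ["IntakeSeries", "ToolResult", "estimate_elim_halflife"]

DEFAULT_BOUNDS = (0.05, 100.0)  # years, search range for the elimination half-life


@dataclass
class ToolResult:
    """Output of the elimination-half-life estimator.

    ``t_half_cstd`` is the apparent halving time fitted to the input CSTD;
    ``t_half_elim_est`` the inverse-estimated intrinsic elimination
    half-life.  ``converged`` is False when the optimum sits at a search
    bound.  ``intake_scale`` is the profiled multiplicative intake factor
    (1.0 when scale co-estimation is off).
    """

    t_half_cstd: float
    cstd_fit: TrendFit
    t_half_elim_est: float
    objective: float
    intake_scale: float
    converged: bool
    body: StaticBody
    sampling_age: float | None
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "t_half_cstd_years": float(self.t_half_cstd),
            "t_half_elim_est_years": float(self.t_half_elim_est),
            "objective": float(self.objective),
            "intake_scale": float(self.intake_scale),
            "converged": bool(self.converged),
            "body_weight_kg": float(self.body.body_weight),
            "lipid_fraction": float(self.body.lipid_fraction),
            "warnings": list(self.warnings),
        }


def _log_residuals(
    k_half: float,
    cstd: CSTDSeries,
    ages: np.ndarray,
    intake: IntakeSeries,
    body: StaticBody,
) -> np.ndarray:
    chem = ChemicalParams(t_half_elim=k_half)
    model = np.array(
        [
            concentration_static_from_intake(body, chem, intake, y - a, y)
            for y, a in zip(cstd.year, ages)
        ]
    )
    return np.log(cstd.concentration) - np.log(model)


def estimate_elim_halflife(
    cstd: CSTDSeries,
    intake: IntakeSeries,
    body: StaticBody | None = None,
    sampling_age: float | None = None,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    co_estimate_scale: bool = True,
    ban_year: float | None = None,
) -> ToolResult:
    """Estimate the intrinsic elimination half-life by inverting the static
    model.

    ``sampling_age`` overrides the per-record ages (useful when a table
    reports a nominal cohort age only).  With ``ban_year`` given, a CSTD
    window lying entirely before the ban is refused — the estimator is
    undefined there (pre-ban trends carry no elimination information beyond
    the intake doubling time).
    """
    body = body or StaticBody()
    notes: list[str] = []
    if len(cstd) < 3:
        raise FitError("need at least 3 CSTD records to estimate an elimination half-life")
    if np.any(cstd.concentration <= 0):
        raise ValueError("CSTD concentrations must be positive")
    if ban_year is not None and np.max(cstd.year) < ban_year:
        raise PeriodError(
            "CSTD window lies entirely before the ban year; the estimator is "
            "undefined for pre-ban data"
        )
    ages = (
        np.full(len(cstd), float(sampling_age)) if sampling_age is not None else cstd.age.copy()
    )
    if np.any(~np.isfinite(ages)) or np.any(ages <= 0):
        raise ValueError("each CSTD record needs a positive sampling age")

    fit = fit_loglinear(cstd)
    if fit.kind != "halving":
        notes.append(
            "CSTD trend is not declining over the input window; the fitted "
            "apparent half-life is not meaningful"
        )
    t_half_cstd = fit.half_life_or_doubling if fit.kind == "halving" else float("inf")

    def objective(log_thalf: float) -> float:
        r = _log_residuals(float(np.exp(log_thalf)), cstd, ages, intake, body)
        if co_estimate_scale:
            r = r - r.mean()
        return float(r @ r)

    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    # coarse log-grid scan first: the profiled objective can be flat or
    # multimodal when the data barely constrain the elimination rate
    grid = np.linspace(lo, hi, 41)
    grid_obj = np.array([objective(x) for x in grid])
    i = int(np.argmin(grid_obj))
    blo, bhi = grid[max(0, i - 1)], grid[min(grid.size - 1, i + 1)]
    opt = minimize_scalar(
        objective, bounds=(blo, bhi), method="bounded", options={"xatol": 1e-8}
    )
    log_t = float(opt.x)
    t_elim = float(np.exp(log_t))
    converged = bool(opt.success and (log_t - lo > 1e-3) and (hi - log_t > 1e-3))
    if not converged:
        notes.append(
            f"optimum at or near a search bound [{bounds[0]:g}, {bounds[1]:g}] y; "
            "estimate flagged non-convergent"
        )
    scale = 1.0
    if co_estimate_scale:
        scale = float(np.exp(_log_residuals(t_elim, cstd, ages, intake, body).mean()))
    return ToolResult(
        t_half_cstd=t_half_cstd,
        cstd_fit=fit,
        t_half_elim_est=t_elim,
        objective=float(opt.fun),
        intake_scale=scale,
        converged=converged,
        body=body,
        sampling_age=sampling_age,
        warnings=notes,
    )


def intake_series_from_scenario(scenario, years) -> IntakeSeries:
    """Tabulate a parametric exposure scenario as an intake series.

    On a yearly grid containing the ban year, log-linear interpolation of the
    table reproduces the piecewise-exponential trend exactly.
    """
    from .exposure import exposure_multiplier

    years = np.asarray(years, dtype=float)
    return IntakeSeries(years, scenario.peak_intake * exposure_multiplier(scenario, years))
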