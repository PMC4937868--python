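"""Static population-pharmacokinetic model (closed form).

A "static" individual has a fixed body weight and lipid fraction and receives
no chemical from their mother (no in-utero transfer, no breastfeeding).  The
lipid-normalized concentration C (ng/g lipid) then obeys the linear balance

    dC/dt = u * I(t) - k_elim * C,      u = f_abs * 365.25 * bw / lipid_mass,

with I(t) the population intake trend in ng/kg bw/day and k_elim = ln2 /
t_half_elim (1/year).  When I is piecewise exponential — the parametric
ban-year scenario, or any tabulated intake series under log-linear
interpolation — the equation solves segment by segment in closed form:

    over a segment of length d with I(t) = I0 * exp(r t):
        C(d) = C0 * exp(-k d) + u * I0 * d * exp(-k d) * phi((k + r) d),
    phi(x) = (exp(x) - 1) / x,  phi(0) = 1.

phi handles the degenerate resonance k_elim = -r (elimination rate equal to
the intake decline rate) without division by zero.

The closed form makes the cross-sectional slope theorem exact: for a fixed
sampling age A with the whole life in the post-ban period, C is proportional
to I(sampling year), so the fitted halving time of the cross-sectional trend
equals the intake halving time for *any* elimination half-life.  This model
is the forward engine of the elimination-half-life estimation tool and the
analytic oracle for the dynamic model's static limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exposure import DAYS_PER_YEAR, ChemicalParams, ExposureScenario, exposure_multiplier
from .series import CSTDSeries, IntakeSeries


@dataclass(frozen=True)
class StaticBody:
    """Fixed adult body used by the static model (defaults: 60 kg, 30% lipid)."""

    body_weight: float = 60.0  # kg
    lipid_fraction: float = 0.30

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValueError("body_weight must be positive")
        if not 0 < self.lipid_fraction < 1:
            raise ValueError("lipid_fraction must be in (0, 1)")

    @property
    def lipid_mass(self) -> float:
        """Body lipid mass in grams."""
        return 1000.0 * self.body_weight * self.lipid_fraction


def _phi(x: float) -> float:
    """(exp(x) - 1)/x, continuous at 0 (series for small |x|)."""
    if abs(x) < 1e-10:
        return 1.0 + 0.5 * x
    return float(np.expm1(x) / x)


def _segment_step(c0: float, k: float, u: float, i0: float, r: float, d: float) -> float:
    """Propagate C across one exponential-intake segment of length d."""
    if d == 0.0:
        return c0
    ekd = float(np.exp(-k * d))
    return c0 * ekd + u * i0 * d * ekd * _phi((k + r) * d)


def _uptake_coefficient(body: StaticBody, chem: ChemicalParams) -> float:
    """u in (ng/g lipid/year) per (ng/kg bw/day) of intake."""
    return chem.absorbed_fraction * DAYS_PER_YEAR * body.body_weight / body.lipid_mass


def concentration_static(
    body: StaticBody,
    chem: ChemicalParams,
    scenario: ExposureScenario,
    birth_year: float,
    sampling_year: float,
    c_birth: float = 0.0,
) -> float:
    """Closed-form lipid-normalized concentration (ng/g lipid) at sampling.

    The life from ``birth_year`` to ``sampling_year`` is split at the ban year
    and each segment is propagated exactly.  ``c_birth`` defaults to 0 (the
    static model has no mother-to-child transfer); a non-zero value gives the
    pure-decay-plus-uptake solution from that initial condition.
    """
    if sampling_year < birth_year:
        raise ValueError("sampling_year must not precede birth_year")
    k = chem.k_elim
    u = _uptake_coefficient(body, chem)
    c = c_birth
    t = birth_year
    if birth_year < scenario.ban_year:
        t1 = min(scenario.ban_year, sampling_year)
        c = _segment_step(
            c, k, u, scenario.peak_intake * exposure_multiplier(scenario, t), scenario.k_rise, t1 - t
        )
        t = t1
    if sampling_year > t:
        c = _segment_step(
            c, k, u, scenario.peak_intake * exposure_multiplier(scenario, t), -scenario.k_fall,
            sampling_year - t,
        )
    return c


def concentration_static_from_intake(
    body: StaticBody,
    chem: ChemicalParams,
    intake: IntakeSeries,
    birth_year: float,
    sampling_year: float,
    c_birth: float = 0.0,
    intake_scale: float = 1.0,
) -> float:
    """Static-model concentration forced by a tabulated intake series.

    Log-linear interpolation makes the intake piecewise exponential, so each
    inter-record interval is propagated with the exact segment solution.
    Years outside the table reuse the terminal log-slopes (the series warns).
    """
    if sampling_year < birth_year:
        raise ValueError("sampling_year must not precede birth_year")
    k = chem.k_elim
    u = _uptake_coefficient(body, chem) * intake_scale
    # segment breakpoints: birth, interior record years, sampling
    interior = intake.year[(intake.year > birth_year) & (intake.year < sampling_year)]
    knots = np.concatenate(([birth_year], interior, [sampling_year]))
    c = c_birth
    for t0, t1 in zip(knots[:-1], knots[1:]):
        d = float(t1 - t0)
        if d <= 0:
            continue
        i0 = float(intake.interp(t0))
        i1 = float(intake.interp(t1))
        r = float(np.log(i1 / i0) / d)
        c = _segment_step(c, k, u, i0, r, d)
    return c


def static_cstd(
    body: StaticBody,
    chem: ChemicalParams,
    scenario: ExposureScenario,
    target_age: float,
    sampling_years,
) -> CSTDSeries:
    """Cross-sectional trend data under the static model.

    Each record is its own static individual born ``target_age`` years before
    its sampling year.  Once sampling_year - target_age >= ban_year (lives
    entirely post-ban) the log-slope of the series equals -ln2/t1/2in exactly,
    for any elimination half-life.
    """
    years = np.asarray(sampling_years, dtype=float)
    conc = np.array(
        [concentration_static(body, chem, scenario, y - target_age, y) for y in years]
    )
    return CSTDSeries(years, np.full_like(years, float(target_age)), conc)
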