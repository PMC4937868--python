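"""Population exposure: piecewise-exponential intake trends.

The population intake of a persistent organic pollutant is modeled as an
exponential increase up to the year the chemical was banned (or phased out)
and an exponential decline thereafter, characterized by an intake doubling
time t2in and an intake halving time t1/2in.  The multiplier equals 1 at the
ban year, where the per-kg intake peaks.  Individual intake scales with body
weight and, optionally, with a smooth age factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

LN2 = float(np.log(2.0))
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class ChemicalParams:
    """Intrinsic toxicokinetic properties of one POP.

    ``t_half_elim`` is the intrinsic elimination half-life (years): how fast
    the chemical is metabolized and excreted from the human body.  It is a
    property of chemical and physiology — distinct from any apparent half-life
    fitted to population time trends.
    """

    t_half_elim: float  # years
    absorbed_fraction: float = 1.0  # dimensionless, (0, 1]

    def __post_init__(self) -> None:
        if self.t_half_elim <= 0:
            raise ValueError("t_half_elim must be positive")
        if not 0 < self.absorbed_fraction <= 1:
            raise ValueError("absorbed_fraction must be in (0, 1]")

    @property
    def k_elim(self) -> float:
        """First-order elimination rate constant, ln2 / t_half_elim (1/year)."""
        return LN2 / self.t_half_elim


@dataclass(frozen=True)
class ExposureScenario:
    """Piecewise-exponential population intake trend peaking at a ban year.

    ``peak_intake`` is the per-body-weight intake rate at the ban year in
    ng/kg body weight/day.  ``age_factor`` is an optional smooth multiplier
    on the per-kg rate as a function of age (default: 1 at all ages); infant
    breast-milk intake is handled mechanistically by the dynamic model, not
    through this factor.
    """

    ban_year: float
    t_double_in: float  # years, pre-ban intake doubling time (t2in)
    t_half_in: float  # years, post-ban intake halving time (t1/2in)
    peak_intake: float = 1.0  # ng / kg bw / day at ban_year
    age_factor: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if self.t_double_in <= 0 or self.t_half_in <= 0:
            raise ValueError("intake doubling and halving times must be positive")
        if self.peak_intake < 0:
            raise ValueError("peak_intake must be non-negative")

    @property
    def k_rise(self) -> float:
        """Pre-ban intake growth rate, ln2 / t2in (1/year)."""
        return LN2 / self.t_double_in

    @property
    def k_fall(self) -> float:
        """Post-ban intake decline rate, ln2 / t1/2in (1/year)."""
        return LN2 / self.t_half_in


def exposure_multiplier(scenario: ExposureScenario, year):
    """Dimensionless intake multiplier at ``year`` (vectorized).

    2**((year - ban)/t2in) before the ban, 2**(-(year - ban)/t1/2in) after;
    exactly 1 at the ban year and strictly positive everywhere.
    """
    year = np.asarray(year, dtype=float)
    dt = year - scenario.ban_year
    log2m = np.where(dt <= 0, dt / scenario.t_double_in, -dt / scenario.t_half_in)
    out = np.exp2(log2m)
    return out if out.ndim else float(out)


def intake_rate(
    scenario: ExposureScenario,
    chem: ChemicalParams | None,
    year,
    age,
    bw,
):
    """Gross dietary intake in ng/day for a person of ``age`` and body weight
    ``bw`` (kg) in ``year``.

    ``chem`` is accepted for interface symmetry but unused: absorption is
    applied in the pharmacokinetic modules, on the absorbed dose.
    """
    bw = np.asarray(bw, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(bw <= 0):
        raise ValueError("body weight must be positive")
    if np.any(age < 0):
        raise ValueError("age must be non-negative")
    af = 1.0 if scenario.age_factor is None else np.asarray(scenario.age_factor(age), dtype=float)
    out = scenario.peak_intake * np.asarray(exposure_multiplier(scenario, year)) * af * bw
    return out if np.ndim(out) else float(out)
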