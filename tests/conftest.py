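"""Shared fixtures: the reference two-chemical simulation scenario.

Two hypothetical chemicals share one intake trend (doubling and halving time
7 years, ban in 1970) and differ only in elimination half-life: 3 years
(rapid) vs 14 years (slow).  CSTD of 30-year-old mothers are read from the
dynamic transgenerational model; cross-sections over ages 20-45 are taken in
2030 (deep post-ban).  Simulations are session-scoped — they are deterministic
and several tests share them.
"""

import numpy as np
import pytest

from cstdkit import (
    ChemicalParams,
    ExposureScenario,
    simulate_cross_section,
    simulate_cstd,
)

PRE_BAN_YEARS = np.arange(1950.0, 1969.0, 2.0)
POST_BAN_YEARS = np.arange(2040.0, 2081.0, 2.0)
CROSS_SECTION_AGES = (20.0, 25.0, 30.0, 35.0, 40.0, 45.0)
CROSS_SECTION_YEAR = 2030.0


@pytest.fixture(scope="session")
def scenario() -> ExposureScenario:
    return ExposureScenario(ban_year=1970.0, t_double_in=7.0, t_half_in=7.0, peak_intake=1.0)


@pytest.fixture(scope="session")
def fast_chem() -> ChemicalParams:
    return ChemicalParams(t_half_elim=3.0)


@pytest.fixture(scope="session")
def slow_chem() -> ChemicalParams:
    return ChemicalParams(t_half_elim=14.0)


@pytest.fixture(scope="session")
def cstd_fast_pre(fast_chem, scenario):
    return simulate_cstd(fast_chem, scenario, 30.0, PRE_BAN_YEARS)


@pytest.fixture(scope="session")
def cstd_slow_pre(slow_chem, scenario):
    return simulate_cstd(slow_chem, scenario, 30.0, PRE_BAN_YEARS)


@pytest.fixture(scope="session")
def cstd_fast_post(fast_chem, scenario):
    return simulate_cstd(fast_chem, scenario, 30.0, POST_BAN_YEARS)


@pytest.fixture(scope="session")
def cstd_slow_post(slow_chem, scenario):
    return simulate_cstd(slow_chem, scenario, 30.0, POST_BAN_YEARS)


@pytest.fixture(scope="session")
def cross_section_fast(fast_chem, scenario):
    return simulate_cross_section(fast_chem, scenario, CROSS_SECTION_AGES, CROSS_SECTION_YEAR)


@pytest.fixture(scope="session")
def cross_section_slow(slow_chem, scenario):
    return simulate_cross_section(slow_chem, scenario, CROSS_SECTION_AGES, CROSS_SECTION_YEAR)
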