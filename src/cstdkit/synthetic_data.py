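"""Synthetic CSTD generation and packaged data fixtures.

Real breast-milk monitoring programs pool samples from tens of donors of
similar age each year; the scatter of the resulting yearly values around the
population mean is well described as multiplicative lognormal.  The
generator reproduces that structure: a dynamic- or static-model mean curve
with per-year geometric means of lognormal draws.  With ``sigma_log = 0`` the
output is exactly the model curve, so every downstream stage can be tested
noise-free as well.

``load_fixture`` serves transcriptions of published Swedish CSTD/intake
tables for BDE-47, DDT, PCB-153 and HCB when they are present under
``data/fixtures``; absent fixtures raise a clear error naming the
supplementary source to transcribe.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import FixtureNotFoundError
from .exposure import ChemicalParams, ExposureScenario
from .life_history import GrowthModel, ReproductionSchedule
from .ppk_dynamic import SimulationFeatures, simulate_cstd
from .ppk_static import StaticBody, static_cstd
from .series import CSTDSeries, IntakeSeries

#: Known fixture names -> (CSTD filename, intake filename or None, provenance)
FIXTURES = {
    "S1_BDE47": ("S1_bde47_cstd.csv", "S1_bde47_intake.csv", "Swedish BDE-47 CSTD and intake"),
    "S2_DDT": ("S2_ddt_cstd.csv", "S2_ddt_intake.csv", "Swedish DDT CSTD and intake"),
    "S3_PCB153": ("S3_pcb153_cstd.csv", "S3_pcb153_intake.csv", "Swedish PCB-153 CSTD and intake"),
    "S4_HCB": ("S4_hcb_cstd.csv", "S4_hcb_intake.csv", "Swedish HCB CSTD and intake"),
}


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal sampling noise.

    ``sigma_log`` is the standard deviation of the natural-log concentration
    of a single pooled sample (default 0.2, typical pooled-milk scatter);
    ``n_per_year`` the number of draws pooled into each yearly geometric
    mean.  Generation is reproducible given ``seed``.
    """

    sigma_log: float = 0.2
    n_per_year: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be non-negative")
        if self.n_per_year < 1:
            raise ValueError("n_per_year must be at least 1")


def generate_cstd(
    model: str,
    chem: ChemicalParams,
    scenario: ExposureScenario,
    target_age: float,
    sampling_years,
    noise: NoiseModel | None = None,
    body: StaticBody | None = None,
    schedule: ReproductionSchedule | None = None,
    growth: GrowthModel | None = None,
    features: SimulationFeatures | None = None,
    **sim_kwargs,
) -> CSTDSeries:
    """Generate a CSTD series from the chosen model with sampling noise.

    ``model`` is ``"dynamic"`` (transgenerational lineage simulation) or
    ``"static"`` (closed form).  Per sampling year, the record is the
    geometric mean of ``n_per_year`` lognormal draws around the model mean;
    ``sigma_log = 0`` reproduces the model exactly.
    """
    if model == "dynamic":
        base = simulate_cstd(
            chem, scenario, target_age, sampling_years,
            schedule=schedule, growth=growth, features=features, **sim_kwargs,
        )
    elif model == "static":
        base = static_cstd(body or StaticBody(), chem, scenario, target_age, sampling_years)
    else:
        raise ValueError(f"model must be 'dynamic' or 'static', got {model!r}")
    noise = noise or NoiseModel()
    if noise.sigma_log == 0:
        return CSTDSeries(
            base.year, base.age, base.concentration,
            np.full(len(base), float(noise.n_per_year)),
        )
    rng = np.random.default_rng(noise.seed)
    draws = rng.normal(0.0, noise.sigma_log, size=(len(base), noise.n_per_year))
    conc = base.concentration * np.exp(draws.mean(axis=1))  # geometric mean of draws
    return CSTDSeries(base.year, base.age, conc, np.full(len(base), float(noise.n_per_year)))


def load_fixture(name: str) -> tuple[CSTDSeries, IntakeSeries | None]:
    """Load a packaged CSTD (+ intake) fixture by name.

    Valid names: ``S1_BDE47``, ``S2_DDT``, ``S3_PCB153``, ``S4_HCB``.  Units
    are validated on read: concentrations in ng/g lipid, intakes in ng/kg
    body weight/day.
    """
    if name not in FIXTURES:
        raise ValueError(
            f"unknown fixture {name!r}; valid names: {sorted(FIXTURES)}"
        )
    cstd_file, intake_file, provenance = FIXTURES[name]
    root = resources.files("cstdkit").joinpath("data/fixtures")
    cstd_path = root.joinpath(cstd_file)
    if not cstd_path.is_file():
        raise FixtureNotFoundError(
            f"fixture {name!r} ({provenance}) is not shipped with this "
            f"installation: transcribe the published supplementary table to "
            f"data/fixtures/{cstd_file} (columns: year, age, "
            f"conc_ng_per_g_lipid, n)"
        )
    with resources.as_file(cstd_path) as p:
        cstd = CSTDSeries.read_csv(p)
    if np.any(cstd.concentration <= 0):
        raise ValueError(f"fixture {name!r}: concentrations must be positive ng/g lipid")
    intake = None
    if intake_file is not None:
        intake_path = root.joinpath(intake_file)
        if intake_path.is_file():
            with resources.as_file(intake_path) as p:
                intake = IntakeSeries.read_csv(p)
    return cstd, intake
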