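"""Life histories: growth curves, reproduction schedules and lineages.

The dynamic population-pharmacokinetic model follows chemical through chains
of mother->child life histories.  This module supplies the physiology those
simulations need: age-dependent body weight and body-lipid fraction
(piecewise linear between anchor ages, constant beyond the last anchor), a
reproduction schedule (age at childbirth, breastfeeding duration, milk lipid
output), and machinery to build multi-generation lineages so that a person of
a target age exists in any requested sampling year.

Ages and calendar years are continuous decimal years throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .errors import CoverageError

#: Female reference growth anchors: representative body weight (kg) and body
#: lipid fraction by age.  Configurable; the model only requires that both
#: change with age.
DEFAULT_ANCHOR_AGES = (0.0, 1.0, 5.0, 10.0, 15.0, 20.0)
DEFAULT_BODY_WEIGHTS = (3.5, 10.0, 20.0, 35.0, 55.0, 60.0)
DEFAULT_LIPID_FRACTIONS = (0.25, 0.20, 0.18, 0.22, 0.27, 0.30)


@dataclass(frozen=True)
class GrowthModel:
    """Age-dependent body weight and lipid fraction.

    Piecewise-linear between ``anchor_ages``; constant after the last anchor.
    Body weight must be positive and lipid fraction in (0, 1) at every anchor,
    which (by linearity) guarantees the same at every age.
    """

    anchor_ages: tuple = DEFAULT_ANCHOR_AGES
    body_weight_at_anchor: tuple = DEFAULT_BODY_WEIGHTS
    lipid_fraction_at_anchor: tuple = DEFAULT_LIPID_FRACTIONS

    def __post_init__(self) -> None:
        ages = np.asarray(self.anchor_ages, dtype=float)
        bw = np.asarray(self.body_weight_at_anchor, dtype=float)
        lf = np.asarray(self.lipid_fraction_at_anchor, dtype=float)
        if not (ages.size == bw.size == lf.size and ages.size >= 1):
            raise ValueError("anchor arrays must be non-empty and of equal length")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("anchor ages must be strictly ascending")
        if ages[0] < 0:
            raise ValueError("anchor ages must be non-negative")
        if np.any(bw <= 0):
            raise ValueError("body weight must be positive at every anchor")
        if np.any((lf <= 0) | (lf >= 1)):
            raise ValueError("lipid fraction must lie in (0, 1) at every anchor")

    def _check_age(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        if np.any(age < 0):
            raise ValueError("age must be non-negative")
        return age

    def body_weight(self, age):
        """Body weight (kg) at ``age`` (years); vectorized."""
        age = self._check_age(age)
        out = np.interp(age, self.anchor_ages, self.body_weight_at_anchor)
        return out if out.ndim else float(out)

    def lipid_fraction(self, age):
        """Body lipid fraction (dimensionless) at ``age``; vectorized."""
        age = self._check_age(age)
        out = np.interp(age, self.anchor_ages, self.lipid_fraction_at_anchor)
        return out if out.ndim else float(out)

    def lipid_mass(self, age):
        """Body lipid mass (g) at ``age``: 1000 * bw[kg] * lipid fraction."""
        return 1000.0 * np.asarray(self.body_weight(age)) * np.asarray(self.lipid_fraction(age))

    @property
    def adult_body_weight(self) -> float:
        return float(self.body_weight_at_anchor[-1])

    @property
    def adult_lipid_fraction(self) -> float:
        return float(self.lipid_fraction_at_anchor[-1])


@dataclass(frozen=True)
class ReproductionSchedule:
    """One child per individual; lactation transfers milk lipid to the child.

    ``milk_lipid_output`` is grams of milk lipid per day during lactation
    (default 25 g/day, roughly 700 g milk/day at 3.5% lipid).
    """

    age_at_childbirth: float = 30.0  # years
    breastfeeding_duration: float = 0.5  # years
    milk_lipid_output: float = 25.0  # g lipid / day

    def __post_init__(self) -> None:
        if self.age_at_childbirth <= 0:
            raise ValueError("age_at_childbirth must be positive")
        if self.breastfeeding_duration < 0:
            raise ValueError("breastfeeding_duration must be non-negative")
        if self.milk_lipid_output < 0:
            raise ValueError("milk_lipid_output must be non-negative")


@dataclass(frozen=True)
class Individual:
    """One lineage member. ``mother_index`` is None for the founder."""

    birth_year: float
    mother_index: int | None
    growth: GrowthModel
    schedule: ReproductionSchedule

    def age_at(self, year: float) -> float:
        return year - self.birth_year


@dataclass
class Lineage:
    """An ordered mother->child chain; birth years strictly increase."""

    members: list = field(default_factory=list)

    def __post_init__(self) -> None:
        births = [m.birth_year for m in self.members]
        if any(b1 <= b0 for b0, b1 in zip(births, births[1:])):
            raise ValueError("birth years must be strictly increasing along the chain")
        for i, m in enumerate(self.members):
            if i == 0 and m.mother_index is not None:
                raise ValueError("founder must have no mother")
            if i > 0 and m.mother_index != i - 1:
                raise ValueError("each member's mother must be the previous member")

    def __len__(self) -> int:
        return len(self.members)

    def birth_years(self) -> np.ndarray:
        return np.array([m.birth_year for m in self.members])


class IndividualMatch(NamedTuple):
    """Result of an age-targeted lineage query."""

    index: int
    individual: Individual
    actual_age: float
    exact: bool


def build_lineage(
    founder_birth_year: float,
    n_generations: int,
    schedule: ReproductionSchedule | None = None,
    growth: GrowthModel | None = None,
) -> Lineage:
    """Chain ``n_generations`` individuals, each born ``age_at_childbirth``
    years after their mother."""
    if n_generations < 1:
        raise ValueError("n_generations must be at least 1")
    schedule = schedule or ReproductionSchedule()
    growth = growth or GrowthModel()
    members = [
        Individual(
            birth_year=founder_birth_year + k * schedule.age_at_childbirth,
            mother_index=None if k == 0 else k - 1,
            growth=growth,
            schedule=schedule,
        )
        for k in range(n_generations)
    ]
    return Lineage(members)


def individual_at(lineage: Lineage, sampling_year: float, target_age: float) -> IndividualMatch:
    """The lineage member whose age at ``sampling_year`` is closest to
    ``target_age``.

    Ties are broken toward the older candidate; the actual age is always
    reported so callers can detect (and refuse) non-exact matches.
    """
    if len(lineage) == 0:
        raise ValueError("lineage is empty")
    ages = sampling_year - lineage.birth_years()
    dist = np.abs(ages - target_age)
    # stable argmin scans in birth order, i.e. oldest first -> ties go older
    idx = int(np.argmin(dist))
    actual = float(ages[idx])
    return IndividualMatch(idx, lineage.members[idx], actual, bool(abs(actual - target_age) < 1e-9))


def lineages_for_sampling(
    sampling_years: Sequence[float],
    target_age: float,
    schedule: ReproductionSchedule | None = None,
    growth: GrowthModel | None = None,
    buffer_generations: int = 3,
) -> list[Lineage]:
    """Build the smallest set of lineages such that every sampling year has an
    exact ``target_age``-year-old member.

    Required birth years are ``year - target_age``; birth years within one
    lineage are spaced ``age_at_childbirth`` apart, so one lineage is built per
    residue of the required birth years modulo that spacing.
    ``buffer_generations`` extra ancestors are prepended so that sampled
    individuals carry an equilibrated transgenerational burden (the founder
    herself starts life with none), and one trailing generation is appended so
    that every sampled adult has her own child and lactation history.
    """
    schedule = schedule or ReproductionSchedule()
    growth = growth or GrowthModel()
    g = schedule.age_at_childbirth
    births = np.asarray([y - target_age for y in sampling_years], dtype=float)
    if births.size == 0:
        raise CoverageError("no sampling years requested")
    lineages = []
    # group required births by residue mod the generation time
    residues: dict[float, list] = {}
    for b in births:
        r = round(float(np.mod(b, g)), 9)
        residues.setdefault(r, []).append(float(b))
    for needed in residues.values():
        first, last = min(needed), max(needed)
        founder = first - buffer_generations * g
        n_gen = buffer_generations + 1 + int(round((last - first) / g)) + 1
        lineages.append(build_lineage(founder, n_gen, schedule, growth))
    return lineages


def check_coverage(
    lineages: Sequence[Lineage], sampling_years: Sequence[float], target_age: float
) -> None:
    """Raise :class:`CoverageError` listing every sampling year with no
    exact-age individual in any lineage."""
    gaps = []
    for y in sampling_years:
        if not any(individual_at(lin, y, target_age).exact for lin in lineages):
            gaps.append(y)
    if gaps:
        raise CoverageError(
            f"no individual of age {target_age:g} exists for sampling years {gaps}"
        )
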