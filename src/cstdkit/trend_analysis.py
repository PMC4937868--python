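"""Log-linear trend extraction from cross-sectional trend data.

Fitted slopes of ln(concentration) against sampling year are converted into
halving times (negative slope, symbol t1/2CSTD) or doubling times (positive
slope, t2CSTD).  These are *apparent*, population-specific quantities: how
they relate to the intake trend and to the intrinsic elimination half-life
depends on the calendar period (pre-ban, transition, post-ban) and on whether
the chemical is rapidly or slowly eliminated — the decision logic lives in
:mod:`cstdkit.recommender`.

Also provided: the calendar-period classifier and the age–concentration
diagnostic, which flags slow eliminators (elimination half-life exceeding the
intake halving time) from a rising age profile within a single post-ban
sampling year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import FitError, PeriodError
from .exposure import LN2
from .series import CSTDSeries

PRE_BAN = "pre-ban"
TRANSITION = "transition"
POST_BAN = "post-ban"


@dataclass
class TrendFit:
    """A log-linear fit of CSTD against calendar year.

    ``slope`` is on the natural-log scale (1/year).  ``half_life_or_doubling``
    is ln2/|slope| in years — a halving time when the slope is negative
    (``kind == 'halving'``), a doubling time when positive; infinite when the
    slope is below ``slope_epsilon`` in magnitude (``kind == 'flat'``).
    """

    window: tuple[float, float]
    slope: float
    intercept: float
    half_life_or_doubling: float
    kind: str  # 'halving' | 'doubling' | 'flat'
    r_squared: float
    n_points: int
    slope_se: float
    warnings: list = field(default_factory=list)

    @property
    def t_half_cstd(self) -> float | None:
        """The apparent CSTD halving time, if the trend is declining."""
        return self.half_life_or_doubling if self.kind == "halving" else None

    @property
    def t_double_cstd(self) -> float | None:
        """The apparent CSTD doubling time, if the trend is rising."""
        return self.half_life_or_doubling if self.kind == "doubling" else None


@dataclass
class PeriodLabels:
    """Per-record calendar-period labels and the transition window."""

    year: np.ndarray
    labels: np.ndarray  # strings in {pre-ban, transition, post-ban}
    transition_window: tuple[float, float]
    elimination_halflife_unknown: bool = False


def fit_loglinear(
    series: CSTDSeries,
    window: tuple[float, float] | None = None,
    weight_by_n: bool = False,
    pool_replicate_years: bool = True,
    slope_epsilon: float = 1e-10,
) -> TrendFit:
    """Ordinary least squares of ln(concentration) on sampling year.

    Replicate records sharing a year are first reduced to their geometric mean
    (matching pooled-sample fitting practice); set ``pool_replicate_years``
    False to fit all records individually.  With ``weight_by_n`` records are
    weighted by their sample size (WLS).  Non-positive concentrations are
    rejected with a warning.
    """
    if window is not None:
        series = series.window(*window)
    notes: list[str] = []
    year = series.year
    conc = series.concentration
    n = series.n
    bad = ~(conc > 0)
    if np.any(bad):
        notes.append(f"rejected {int(bad.sum())} non-positive concentration record(s)")
        warnings.warn(notes[-1], stacklevel=2)
        year, conc = year[~bad], conc[~bad]
        n = None if n is None else n[~bad]
    if year.size < 2:
        raise FitError("need at least 2 positive-concentration records to fit")
    logc = np.log(conc)
    if pool_replicate_years and np.unique(year).size < year.size:
        df = pd.DataFrame({"year": year, "logc": logc, "w": 1.0 if n is None else n})
        grouped = df.groupby("year").agg(
            logc=("logc", "mean"), w=("w", "sum")
        )  # mean of logs == log geometric mean
        year = grouped.index.to_numpy()
        logc = grouped["logc"].to_numpy()
        n = grouped["w"].to_numpy() if n is not None else None
        if year.size < 2:
            raise FitError("fewer than 2 distinct years after pooling replicates")
    X = sm.add_constant(year)
    if weight_by_n:
        if n is None:
            notes.append("weight_by_n requested but no sample sizes given; unweighted fit")
        model = sm.WLS(logc, X, weights=n if n is not None else 1.0)
    else:
        model = sm.OLS(logc, X)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = model.fit()
        slope = float(res.params[1])
        se = float(res.bse[1]) if year.size > 2 else float("nan")
    if abs(slope) < slope_epsilon:
        kind, t = "flat", float("inf")
    elif slope < 0:
        kind, t = "halving", LN2 / -slope
    else:
        kind, t = "doubling", LN2 / slope
    win = window if window is not None else (float(year.min()), float(year.max()))
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = float(res.rsquared) if year.size > 2 else 1.0
    return TrendFit(
        window=win,
        slope=slope,
        intercept=float(res.params[0]),
        half_life_or_doubling=t,
        kind=kind,
        r_squared=r2,
        n_points=int(year.size),
        slope_se=se,
        warnings=notes,
    )


def classify_periods(
    series: CSTDSeries,
    ban_year: float,
    t_half_elim: float | None = None,
    min_transition_years: float = 10.0,
    transition_multiplier: float = 2.0,
) -> PeriodLabels:
    """Label each record pre-ban / transition / post-ban.

    The transition lasts ``max(min_transition_years, transition_multiplier *
    t_half_elim)`` years after the ban: roughly a decade suffices for rapidly
    eliminated chemicals, while slow eliminators flatten the trend for much
    longer.  With the elimination half-life unknown the 10-year default is
    used and flagged as a caveat.
    """
    unknown = t_half_elim is None
    delta = (
        min_transition_years
        if unknown
        else max(min_transition_years, transition_multiplier * t_half_elim)
    )
    end = ban_year + delta
    labels = np.where(
        series.year < ban_year,
        PRE_BAN,
        np.where(series.year < end, TRANSITION, POST_BAN),
    )
    return PeriodLabels(
        year=series.year.copy(),
        labels=labels,
        transition_window=(ban_year, end),
        elimination_halflife_unknown=unknown,
    )


@dataclass
class AgeTrendDiagnostic:
    """Outcome of the age–concentration cross-check."""

    flag: bool  # True -> "t1/2elim > t1/2in indicated"
    slope: float  # d ln C / d age (1/year)
    p_value: float  # one-sided, H1: slope > 0
    message: str


def age_trend_check(
    cross_section: CSTDSeries,
    period: str,
    alpha: float = 0.05,
    min_slope: float | None = None,
) -> AgeTrendDiagnostic:
    """Test whether concentration rises with age within one sampling year.

    In the post-ban period, a *pronounced* rising age profile is possible
    only when the elimination half-life exceeds the intake halving time, so a
    positive slope of ln C on age flags a slow eliminator.  During the
    pre-ban and transition periods age–concentration trends do not separate
    slowly from rapidly eliminated chemicals, so the check refuses to run.

    Rapid eliminators are not perfectly flat: whole-life-post-ban uptake
    still leaves a residual saturating rise with age.  At the boundary case
    (elimination half-life equal to the intake halving time) the profile
    rises like ln(age), i.e. with local slope 1/age, and slow eliminators
    rise faster than that.  The flag therefore requires the slope both to be
    statistically positive (one-sided level ``alpha``) and to exceed
    ``min_slope``, which defaults to 1/max(age) — just below the
    boundary-case slope across the sampled ages.
    """
    if period != POST_BAN:
        raise PeriodError(
            "the age–concentration cross-check is defined only for post-ban "
            f"cross-sections (got period {period!r}): before that, age trends "
            "do not differ between slowly and rapidly eliminated chemicals"
        )
    if np.unique(cross_section.year).size != 1:
        raise ValueError("cross-section must come from a single sampling year")
    if np.unique(cross_section.age).size < 3:
        raise ValueError("need at least 3 distinct ages")
    if np.any(cross_section.concentration <= 0):
        raise ValueError("concentrations must be positive")
    if min_slope is None:
        min_slope = 1.0 / float(np.max(cross_section.age))
    X = sm.add_constant(cross_section.age)
    res = sm.OLS(np.log(cross_section.concentration), X).fit()
    slope = float(res.params[1])
    # one-sided p-value for a positive slope
    p = float(res.pvalues[1]) / 2 if slope > 0 else 1 - float(res.pvalues[1]) / 2
    flag = bool(slope > min_slope and p < alpha)
    msg = (
        "concentration increases with age: elimination half-life exceeding the "
        "intake halving time indicated"
        if flag
        else "no significant increase of concentration with age"
    )
    return AgeTrendDiagnostic(flag=flag, slope=slope, p_value=p, message=msg)
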