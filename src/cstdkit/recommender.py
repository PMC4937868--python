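"""Decision rules for interpreting CSTD fits and tool results.

Fitted halving/doubling times of cross-sectional trend data mean different
things in different calendar periods, and the elimination-half-life estimator
is only trustworthy for rapidly eliminated chemicals.  This module encodes
those constraints as five explicit rules (R1–R5) and annotates every fit with
verdicts and rationales:

R1  Pre-ban: the rising CSTD slope gives the intake doubling time directly
    (t2CSTD = t2in), independent of the elimination half-life.
R2  Transition: an apparent halving time fitted to transition-period data is
    not meaningful, even though it is technically computable.
R3  Late transition: once the elimination half-life is known to be shorter
    than the intake halving time, t1/2CSTD = t1/2in holds from roughly 10
    years after the ban onward.
R4  The elimination-half-life estimator applies in the later transition
    period as well as post-ban, provided the chemical is rapidly eliminated
    (elimination half-life below the intake halving time).
R5  If the elimination half-life exceeds the intake halving time, or is long
    in general (roughly >= 10 years), or concentrations rise with age in a
    post-ban cross-section, the estimator must not be applied; the apparent
    CSTD halving time is then only an upper limit of the intake halving time.

A hard output constraint applies throughout: the apparent CSTD halving time
is never presented as an elimination half-life — the two are distinct
quantities and never coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .trend_analysis import (
    POST_BAN,
    PRE_BAN,
    TRANSITION,
    AgeTrendDiagnostic,
    PeriodLabels,
    TrendFit,
)

VALID = "valid"
INVALID = "invalid"
CAUTION = "caution"

#: How the apparent fitted quantity must be labeled in any report.  It is an
#: exposure-trend summary of the sampled population, never a property of the
#: chemical's metabolism.
APPARENT_LABEL = "apparent CSTD halving/doubling time"

RULE_TEXT = {
    "R1": (
        "Pre-ban period: the intake doubling time can be derived directly from "
        "the slope of the exponential increase in CSTD (t2CSTD = t2in), "
        "completely independently of the elimination half-life."
    ),
    "R2": (
        "Transition period: estimating an apparent halving time from "
        "transition-period CSTD is not meaningful, even though it is "
        "technically possible."
    ),
    "R3": (
        "If there are indications that the elimination half-life is shorter "
        "than the intake halving time, CSTD identify the intake halving time "
        "(t1/2CSTD = t1/2in) already from about 10 years into the transition "
        "period."
    ),
    "R4": (
        "The elimination-half-life estimator is applicable not only to the "
        "post-ban period but also to the later transition period, provided the "
        "elimination half-life is shorter than the intake halving time."
    ),
    "R5": (
        "If there are indications that the elimination half-life exceeds the "
        "intake halving time, or that it is long in general (roughly 10 years "
        "or more), the elimination-half-life estimator must not be applied; "
        "the apparent CSTD halving time is then only an upper limit of the "
        "intake halving time."
    ),
}


@dataclass
class Recommendation:
    """One rule's verdict on a fit/tool result."""

    rule_id: str  # R1..R5
    verdict: str  # valid | invalid | caution
    rationale: str
    triggers: dict = field(default_factory=dict)


def _window_composition(
    fit: TrendFit, periods: PeriodLabels, transition_early_years: float
) -> set[str]:
    ban = periods.transition_window[0]
    lo, hi = fit.window
    mask = (periods.year >= lo) & (periods.year <= hi)
    comps: set[str] = set()
    for y, lab in zip(periods.year[mask], periods.labels[mask]):
        if lab == TRANSITION:
            comps.add(
                "transition-early" if y < ban + transition_early_years else "transition-late"
            )
        else:
            comps.add(str(lab))
    return comps


def evaluate(
    fit: TrendFit,
    periods: PeriodLabels,
    t_half_elim_known: float | None = None,
    t_half_in_est: float | None = None,
    age_flag: AgeTrendDiagnostic | bool | None = None,
    long_elim_threshold: float = 10.0,
    transition_early_years: float = 10.0,
) -> list[Recommendation]:
    """Annotate a trend fit with every applicable rule's verdict.

    ``t_half_elim_known`` is prior knowledge of the elimination half-life
    (years), ``t_half_in_est`` an independent estimate of the intake halving
    time.  When the latter is missing, a declining post-ban fit provides its
    own upper-limit proxy and all ordering-dependent verdicts are downgraded
    to "caution".  ``age_flag`` carries the age–concentration diagnostic
    (truthy means a rising age profile was detected).
    """
    comps = _window_composition(fit, periods, transition_early_years)
    mixed = len(comps) > 1
    ban = periods.transition_window[0]

    proxy_used = False
    t_in = t_half_in_est
    if t_in is None and POST_BAN in comps and fit.kind == "halving":
        t_in = fit.half_life_or_doubling  # upper limit of the intake halving time
        proxy_used = True

    ordering: str | None = None
    if t_half_elim_known is not None and t_in is not None and np.isfinite(t_in):
        ordering = "<" if t_half_elim_known < t_in else ">"

    age_raised = bool(getattr(age_flag, "flag", age_flag))
    long_elim = t_half_elim_known is not None and t_half_elim_known >= long_elim_threshold
    tool_barred = ordering == ">" or long_elim or age_raised

    triggers = {
        "periods_in_window": sorted(comps),
        "mixed_window": mixed,
        "t_half_elim_known": t_half_elim_known,
        "t_half_in_used": t_in,
        "t_half_in_proxy_from_cstd": proxy_used,
        "age_flag_raised": age_raised,
        "years_since_ban": float(fit.window[1] - ban),
        "fit_kind": fit.kind,
    }
    split_note = (
        " The fit window mixes calendar periods; split it and fit each period "
        "separately."
        if mixed
        else ""
    )

    def rec(rule: str, verdict: str, note: str = "") -> Recommendation:
        return Recommendation(rule, verdict, RULE_TEXT[rule] + note + split_note, dict(triggers))

    out: list[Recommendation] = []

    if PRE_BAN in comps:
        if mixed:
            out.append(rec("R1", CAUTION, " Applies to the pre-ban records only."))
        elif fit.kind == "doubling":
            out.append(
                rec("R1", VALID, " The fitted doubling time estimates the intake doubling time.")
            )
        else:
            out.append(
                rec("R1", CAUTION, " Pre-ban window but no rising trend was fitted.")
            )

    in_transition = "transition-early" in comps or "transition-late" in comps
    late_only = comps == {"transition-late"}
    if in_transition:
        if late_only and ordering == "<":
            out.append(
                rec(
                    "R2",
                    CAUTION,
                    " Overridden here: the window lies in the later transition "
                    "period and the chemical is rapidly eliminated (see R3).",
                )
            )
        else:
            out.append(rec("R2", INVALID, " Do not interpret this apparent halving time."))

    if "transition-late" in comps or POST_BAN in comps:
        if ordering == "<":
            verdict = CAUTION if (proxy_used or mixed) else VALID
            out.append(
                rec(
                    "R3",
                    verdict,
                    " The fitted halving time estimates the intake halving time."
                    + (" (Intake halving time proxied by the fit itself.)" if proxy_used else ""),
                )
            )
        elif ordering == ">":
            out.append(
                rec(
                    "R3",
                    INVALID,
                    " The elimination half-life exceeds the intake halving time, so "
                    "the fitted halving time overstates the intake halving time.",
                )
            )
        else:
            out.append(
                rec(
                    "R3",
                    CAUTION,
                    " Elimination half-life unknown; the equality with the intake "
                    "halving time cannot be confirmed.",
                )
            )

        if tool_barred:
            out.append(rec("R4", INVALID, " Superseded by R5."))
        elif ordering == "<":
            out.append(
                rec("R4", CAUTION if (proxy_used or mixed) else VALID, " The estimator may be applied.")
            )
        else:
            out.append(
                rec("R4", CAUTION, " Rapid elimination not established; apply with caution.")
            )

    if tool_barred:
        reasons = []
        if ordering == ">":
            reasons.append("elimination half-life exceeds the intake halving time")
        if long_elim:
            reasons.append(
                f"elimination half-life >= {long_elim_threshold:g} years"
            )
        if age_raised:
            reasons.append("concentration rises with age in a post-ban cross-section")
        out.append(
            rec(
                "R5",
                INVALID,
                " Triggered because: " + "; ".join(reasons) + ". Report the fitted "
                "halving time only as an upper limit of the intake halving time.",
            )
        )
    elif POST_BAN in comps and ordering is None:
        out.append(
            rec(
                "R5",
                CAUTION,
                " Elimination half-life unknown; rule out a slow eliminator (e.g. "
                "via the age–concentration cross-check) before applying the "
                "estimator.",
            )
        )
    return out


def render_report(
    fit: TrendFit,
    recommendations: Sequence[Recommendation],
    tool_result=None,
) -> dict:
    """JSON-ready report of a fit plus its verdicts.

    The fitted quantity is labeled as the apparent CSTD halving/doubling
    time; by construction it is never presented as an elimination half-life.
    """
    report = {
        "fit": {
            "window": list(fit.window),
            "slope_per_year": fit.slope,
            "quantity": APPARENT_LABEL,
            "kind": fit.kind,
            "value_years": fit.half_life_or_doubling,
            "r_squared": fit.r_squared,
            "n_points": fit.n_points,
            "slope_se": fit.slope_se,
            "warnings": list(fit.warnings),
        },
        "recommendations": [
            {
                "rule": r.rule_id,
                "verdict": r.verdict,
                "rationale": r.rationale,
                "triggers": r.triggers,
            }
            for r in recommendations
        ],
    }
    if tool_result is not None:
        report["halflife_tool"] = tool_result.to_dict()
    return report
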