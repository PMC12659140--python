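"""Event counting, person-time rates, exact rate ratios and 5-year risks.

Rates are unadjusted events per person-year.  Rate-ratio confidence
intervals and p-values use the classical exact conditional construction:
given the total count ``c1 + c0``, the exposed count is binomial with
success probability ``RR·pt1 / (RR·pt1 + pt0)``; a Clopper–Pearson
interval for that proportion, mapped back through the odds transform,
yields the exact interval for the rate ratio, and the exact two-sided
binomial test at ``RR = 1`` yields the p-value.

Five-year risks are simple first-event proportions of the cohort
denominators, expressed in percent, with the risk ratio and risk
difference computed on the unrounded risks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import DAYS_PER_YEAR

__all__ = [
    "GroupCounts",
    "RateResult",
    "RiskResult",
    "UtilisationSummary",
    "count_events",
    "rate_ratio_exact",
    "risk_and_ratio",
    "summarize_utilisation",
    "utilisation_table",
]


@dataclass(frozen=True)
class GroupCounts:
    """Event counts and person-years for the exposed (1) and comparator (0)
    groups, for one event kind and setting filter."""

    c1: int
    pt1: float
    c0: int
    pt0: float
    kind: str = "all"
    settings: Optional[tuple[str, ...]] = None


@dataclass(frozen=True)
class RateResult:
    c1: int
    pt1: float
    c0: int
    pt0: float
    rate1: float
    rate0: float
    rate_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    confidence_level: float
    kind: str = "all"
    settings: Optional[tuple[str, ...]] = None


@dataclass(frozen=True)
class RiskResult:
    c1: int
    n1: int
    c0: int
    n0: int
    risk1: float  # percent over five years
    risk0: float
    risk_ratio: Optional[float]  # None when not estimable (c0 == 0)
    risk_difference: float


@dataclass(frozen=True)
class UtilisationSummary:
    median: float
    q1: float
    q3: float
    zero_percent: float
    n: int


def count_events(
    events: pd.DataFrame,
    children: pd.DataFrame,
    kind: str = "all",
    settings: Optional[Sequence[str]] = None,
) -> GroupCounts:
    """Count events and person-time per exposure group.

    ``children`` must carry ``child_id``, ``exposure``, ``birth_date``,
    ``followup_end`` and ``person_years`` (see
    :func:`regiscan.cohort.add_followup`).  ``kind='all'`` counts every
    event over full person-time; ``kind='incident'`` counts at most one
    event per child and truncates that child's person-time at the first
    event of the filtered settings.  Events outside a child's follow-up
    window are an upstream bug and raise ``AssertionError``.
    """
    if kind not in ("all", "incident"):
        raise ValueError(f"kind must be 'all' or 'incident', got {kind!r}")
    ev = events
    if settings is not None:
        ev = ev[ev["setting"].isin(settings)]
    cols = ["child_id", "exposure", "birth_date", "followup_end", "person_years"]
    kids = children[cols].set_index("child_id")
    ev = ev[ev["child_id"].isin(kids.index)]
    if len(ev):
        birth = kids["birth_date"].reindex(ev["child_id"]).to_numpy()
        end = kids["followup_end"].reindex(ev["child_id"]).to_numpy()
        dates = ev["event_date"].to_numpy()
        assert (dates >= birth).all() and (dates <= end).all(), (
            "events outside follow-up window"
        )
    exposed = kids["exposure"].astype(bool)
    if kind == "all":
        per_child = ev.groupby("child_id").size().reindex(kids.index, fill_value=0)
        c1 = int(per_child[exposed].sum())
        c0 = int(per_child[~exposed].sum())
        pt1 = float(kids.loc[exposed, "person_years"].sum())
        pt0 = float(kids.loc[~exposed, "person_years"].sum())
    else:
        first = ev.groupby("child_id")["event_date"].min()
        has_event = kids.index.isin(first.index)
        time_to_first = pd.Series(np.nan, index=kids.index)
        time_to_first[first.index] = (
            (first - kids.loc[first.index, "birth_date"]).dt.days / DAYS_PER_YEAR
        )
        pt = np.where(has_event, time_to_first, kids["person_years"])
        c1 = int((has_event & exposed).sum())
        c0 = int((has_event & ~exposed).sum())
        pt1 = float(pt[exposed].sum())
        pt0 = float(pt[~exposed].sum())
    return GroupCounts(
        c1, pt1, c0, pt0, kind=kind,
        settings=tuple(settings) if settings is not None else None,
    )


def rate_ratio_exact(
    c1: int,
    pt1: float,
    c0: int,
    pt0: float,
    confidence_level: float = 0.95,
    kind: str = "all",
    settings: Optional[Sequence[str]] = None,
) -> RateResult:
    """Exact conditional rate ratio for two Poisson counts.

    Conditioning on ``m = c1 + c0``, ``c1`` is Binomial(m, pi) with
    ``pi = RR·pt1/(RR·pt1 + pt0)``; the Clopper–Pearson interval for pi
    maps to ``RR = pi/(1-pi) · pt0/pt1``.  With ``c0 = 0`` the upper
    bound is infinite.
    """
    if pt1 <= 0 or pt0 <= 0:
        raise ValueError("person-time must be positive in both groups")
    m = c1 + c0
    if m < 1:
        raise ValueError("need at least one event for an exact interval")
    alpha = 1.0 - confidence_level
    # Clopper–Pearson for pi = P(event is from group 1 | event occurred)
    pi_low = 0.0 if c1 == 0 else stats.beta.ppf(alpha / 2, c1, c0 + 1)
    pi_high = 1.0 if c0 == 0 else stats.beta.ppf(1 - alpha / 2, c1 + 1, c0)
    ratio_pt = pt0 / pt1
    ci_low = (pi_low / (1 - pi_low)) * ratio_pt if pi_low < 1 else math.inf
    ci_high = (pi_high / (1 - pi_high)) * ratio_pt if pi_high < 1 else math.inf
    pi_null = pt1 / (pt1 + pt0)
    p_value = float(stats.binomtest(c1, m, pi_null).pvalue)
    rate1, rate0 = c1 / pt1, c0 / pt0
    rr = rate1 / rate0 if c0 > 0 else math.inf
    return RateResult(
        c1=c1, pt1=pt1, c0=c0, pt0=pt0, rate1=rate1, rate0=rate0,
        rate_ratio=rr, ci_low=ci_low, ci_high=ci_high, p_value=p_value,
        confidence_level=confidence_level, kind=kind,
        settings=tuple(settings) if settings is not None else None,
    )


def risk_and_ratio(c1: int, n1: int, c0: int, n0: int) -> RiskResult:
    """Five-year risks (percent), risk ratio and risk difference."""
    for c, n in ((c1, n1), (c0, n0)):
        if n < 1:
            raise ValueError("denominators must be >= 1")
        if not 0 <= c <= n:
            raise ValueError("counts must satisfy 0 <= c <= n")
    risk1 = 100.0 * c1 / n1
    risk0 = 100.0 * c0 / n0
    rr = risk1 / risk0 if c0 > 0 else None
    return RiskResult(
        c1=c1, n1=n1, c0=c0, n0=n0, risk1=risk1, risk0=risk0,
        risk_ratio=rr, risk_difference=risk1 - risk0,
    )


def summarize_utilisation(totals: Sequence[float]) -> UtilisationSummary:
    """Median, IQR (linear-interpolation quantiles) and percent with zero
    events, over per-child event totals (zeros included)."""
    arr = np.asarray(totals, float)
    if arr.size == 0:
        raise ValueError("empty cohort")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return UtilisationSummary(
        median=float(med), q1=float(q1), q3=float(q3),
        zero_percent=100.0 * float(np.mean(arr == 0)), n=int(arr.size),
    )


_TABLE2_ROWS: tuple[tuple[str, Optional[tuple[str, ...]]], ...] = (
    ("Hospital visits combined", ("inpatient", "outpatient")),
    ("Outpatient visits", ("outpatient",)),
    ("Inpatient admissions", ("inpatient",)),
    ("Drug dispensations", ("dispensation",)),
)


def utilisation_table(
    events: pd.DataFrame,
    children: pd.DataFrame,
    drug_children: Optional[pd.DataFrame] = None,
    confidence_level: float = 0.95,
) -> pd.DataFrame:
    """Incident and all-event rates with exact rate ratios, one row per
    event definition and setting filter (the study's utilisation table).

    ``drug_children`` optionally restricts dispensation rows to the drug
    sub-cohort.
    """
    rows = []
    for kind in ("incident", "all"):
        for name, settings in _TABLE2_ROWS:
            kids = children
            if settings == ("dispensation",) and drug_children is not None:
                kids = drug_children
            gc = count_events(events, kids, kind=kind, settings=settings)
            if gc.c1 + gc.c0 == 0:
                continue
            r = rate_ratio_exact(
                gc.c1, gc.pt1, gc.c0, gc.pt0,
                confidence_level=confidence_level, kind=kind, settings=settings,
            )
            rows.append(
                {
                    "event": name,
                    "kind": kind,
                    "exposed_events": r.c1,
                    "exposed_rate": r.rate1,
                    "comparator_events": r.c0,
                    "comparator_rate": r.rate0,
                    "rate_ratio": r.rate_ratio,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p_value": r.p_value,
                }
            )
    return pd.DataFrame(rows)
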