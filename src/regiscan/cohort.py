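"""Analysis-cohort construction.

Comparator parents enter the source platform by being sampled as matches
for lymphoma patients, so their demographic mix is not representative of
the population.  Representativeness is restored with Kaplan–Meier-type
inverse-probability-of-sampling weights: within each stratum (sex ×
birth year by default), the probability of being sampled in year *u* is
``p_u = sampled_u / population_u``, and an individual first eligible in
year *e* and sampled in year *t* receives

    w = 1 / ( prod_{e <= u < t} (1 - p_u) * p_t ),

the inverse of the product-limit probability of their sampling history.
Summed over sampled individuals these weights recover the population
counts when the supplied populations are the not-yet-sampled totals.

The weighted 1:*ratio* matching then draws, for each exposed child,
``ratio`` comparator children without replacement with probability
proportional to their sampling weight, among those whose maternal age
matches (exact integer age, widening to ±1 year when the pool runs
short).  Follow-up runs from birth to the earliest of death, emigration
or the fifth birthday (1,826 days).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import DAYS_PER_YEAR, FIVE_YEARS_DAYS

__all__ = [
    "MatchedCohort",
    "MatchingError",
    "DataError",
    "compute_sampling_weights",
    "match_children",
    "define_followup",
    "add_followup",
    "build_drug_subcohort",
    "DRUG_REGISTER_START",
]

logger = logging.getLogger(__name__)

DRUG_REGISTER_START = pd.Timestamp("2005-07-01")


class MatchingError(RuntimeError):
    """Raised when an exposed child cannot be given enough comparators."""


class DataError(ValueError):
    """Raised for impossible dates (e.g. death before birth)."""


# ---------------------------------------------------------------------------
# Sampling weights
# ---------------------------------------------------------------------------

def compute_sampling_weights(
    comparators: pd.DataFrame,
    population_counts: pd.DataFrame,
    strata: Sequence[str] = ("sex", "birth_year"),
) -> pd.DataFrame:
    """Kaplan–Meier-type inverse-probability-of-sampling weights.

    Parameters
    ----------
    comparators:
        One row per sampled comparator with the stratum columns plus
        ``first_eligible_year`` and ``sampled_year``.
    population_counts:
        Rows ``(year, *strata, count)`` giving the eligible population
        of each stratum in each sampling year.
    strata:
        Stratification columns; only those present in *both* tables are
        used.

    Returns
    -------
    A copy of ``comparators`` with columns ``sampling_probability`` (the
    per-year probability of their sampling year) and ``sampling_weight``.
    The per-stratum-year probability table is attached as the attribute
    ``.attrs["stratum_weight_table"]`` for audit.
    """
    strata = [
        s for s in strata if s in comparators.columns and s in population_counts.columns
    ]
    key_cols = strata + ["year"]
    sampled = (
        comparators.assign(year=comparators["sampled_year"])
        .groupby(key_cols, as_index=False)
        .size()
        .rename(columns={"size": "sampled"})
    )
    table = sampled.merge(population_counts, on=key_cols, how="left", validate="1:1")
    if table["count"].isna().any() or (table["count"] <= 0).any():
        bad = table.loc[table["count"].isna() | (table["count"] <= 0), key_cols]
        raise ValueError(f"missing or zero population for strata-years:\n{bad}")
    if (table["sampled"] > table["count"]).any():
        raise ValueError("more sampled than population in some stratum-year")
    table["probability"] = table["sampled"] / table["count"]

    prob_lookup = {
        tuple(row[c] for c in key_cols): row["probability"]
        for _, row in table.iterrows()
    }

    def _weight(row) -> tuple[float, float]:
        key = tuple(row[c] for c in strata)
        t = int(row["sampled_year"])
        e = int(row["first_eligible_year"])
        if e > t:
            raise ValueError(
                f"first_eligible_year {e} after sampled_year {t} for {key}"
            )
        surv = 1.0
        for u in range(e, t):
            surv *= 1.0 - prob_lookup.get(key + (u,), 0.0)
        p_t = prob_lookup.get(key + (t,), 0.0)
        if p_t <= 0:
            raise ValueError(f"no sampling probability for stratum {key} year {t}")
        return p_t, 1.0 / (surv * p_t)

    out = comparators.copy()
    probs_weights = out.apply(_weight, axis=1, result_type="expand")
    out["sampling_probability"] = probs_weights[0]
    out["sampling_weight"] = probs_weights[1]
    out.attrs["stratum_weight_table"] = table
    return out


# ---------------------------------------------------------------------------
# Weighted matching
# ---------------------------------------------------------------------------

@dataclass
class MatchedCohort:
    """A pooled matched cohort: one exposed child plus ``ratio`` comparators
    per matched set, flagged by the ``set_id`` and ``role`` columns."""

    children: pd.DataFrame
    ratio: int

    @property
    def exposed(self) -> pd.DataFrame:
        return self.children[self.children["role"] == "exposed"]

    @property
    def comparators(self) -> pd.DataFrame:
        return self.children[self.children["role"] == "comparator"]

    @property
    def n_sets(self) -> int:
        return len(self.exposed)

    def __len__(self) -> int:
        return len(self.children)


def match_children(
    exposed: pd.DataFrame,
    comparator_pool: pd.DataFrame,
    ratio: int = 5,
    caliper_years: int = 1,
    weights: Optional[pd.Series] = None,
    seed: Optional[int] = None,
) -> MatchedCohort:
    """Weighted 1:``ratio`` matching on maternal age, without replacement.

    Matching is greedy in a seed-randomised exposed order.  For each
    exposed child, comparators at the exact integer maternal age are
    eligible; when fewer than ``ratio`` remain, the caliper widens one
    year at a time up to ``caliper_years`` (logged).  Selection within
    the eligible set is probability-proportional-to-weight.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    rng = np.random.default_rng(seed)
    pool = comparator_pool.reset_index(drop=True)
    if weights is None:
        w_all = pool.get(
            "sampling_weight", pd.Series(1.0, index=pool.index)
        ).to_numpy(float)
    else:
        w_all = np.asarray(weights, float)
    if np.any(w_all <= 0):
        raise ValueError("weights must be positive")
    pool_age = np.rint(pool["maternal_age_years"].to_numpy(float)).astype(int)
    by_age: dict[int, list[int]] = {}
    for idx, age in enumerate(pool_age):
        by_age.setdefault(age, []).append(idx)
    used = np.zeros(len(pool), dtype=bool)

    exp = exposed.reset_index(drop=True)
    order = rng.permutation(len(exp))
    rows: list[pd.DataFrame] = []
    n_widened = 0
    for set_id, i in enumerate(order):
        target_age = int(np.rint(exp["maternal_age_years"].iloc[i]))
        chosen: Optional[np.ndarray] = None
        for width in range(0, caliper_years + 1):
            cand = [
                j
                for a in range(target_age - width, target_age + width + 1)
                for j in by_age.get(a, [])
                if not used[j]
            ]
            if len(cand) >= ratio:
                cand = np.asarray(cand)
                p = w_all[cand] / w_all[cand].sum()
                chosen = rng.choice(cand, size=ratio, replace=False, p=p)
                if width > 0:
                    n_widened += 1
                break
        if chosen is None:
            raise MatchingError(
                f"exposed child {exp['child_id'].iloc[i]!r}: fewer than "
                f"{ratio} unused comparators within ±{caliper_years}y of "
                f"maternal age {target_age}"
            )
        used[chosen] = True
        e_row = exp.iloc[[i]].assign(set_id=set_id, role="exposed")
        c_rows = pool.iloc[chosen].assign(set_id=set_id, role="comparator")
        rows.append(e_row)
        rows.append(c_rows)
    if n_widened:
        logger.info("caliper widened beyond exact age for %d matched sets", n_widened)
    children = pd.concat(rows, ignore_index=True)
    return MatchedCohort(children=children, ratio=ratio)


# ---------------------------------------------------------------------------
# Follow-up
# ---------------------------------------------------------------------------

def define_followup(
    birth_date: pd.Timestamp,
    death_date: Optional[pd.Timestamp] = None,
    emigration_date: Optional[pd.Timestamp] = None,
) -> tuple[pd.Timestamp, float]:
    """Follow-up end and person-years for one child.

    End of follow-up is the earliest of death, emigration and the fifth
    birthday (1,826 days); person-time is reported in years of 365.25
    days.
    """
    birth = pd.Timestamp(birth_date)
    end = birth + pd.Timedelta(days=FIVE_YEARS_DAYS)
    for d in (death_date, emigration_date):
        if d is not None and not pd.isna(d):
            d = pd.Timestamp(d)
            if d < birth:
                raise DataError(f"event date {d} before birth {birth}")
            end = min(end, d)
    return end, (end - birth).days / DAYS_PER_YEAR


def add_followup(children: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`define_followup` over a cohort table.

    Adds ``followup_end`` and ``person_years`` columns.
    """
    birth = children["birth_date"]
    end = birth + pd.Timedelta(days=FIVE_YEARS_DAYS)
    for col in ("death_date", "emigration_date"):
        if col in children.columns:
            d = pd.to_datetime(children[col])
            if (d < birth).any():
                raise DataError(f"{col} before birth for some children")
            end = end.where(d.isna() | (end <= d), d)
    out = children.copy()
    out["followup_end"] = end
    out["person_years"] = (end - birth).dt.days / DAYS_PER_YEAR
    if (out["person_years"] < 0).any():
        raise DataError("negative person-time")
    return out


def build_drug_subcohort(
    cohort: MatchedCohort, register_start: pd.Timestamp = DRUG_REGISTER_START
) -> MatchedCohort:
    """Restrict to matched sets whose exposed child was born after the
    start of the prescribed-drug register (July 2005 by default)."""
    exposed = cohort.exposed
    keep_sets = set(exposed.loc[exposed["birth_date"] >= register_start, "set_id"])
    children = cohort.children[cohort.children["set_id"].isin(keep_sets)].reset_index(
        drop=True
    )
    if not keep_sets:
        logger.warning("drug sub-cohort is empty: no exposed child born after %s",
                       register_start.date())
    else:
        logger.info(
            "drug sub-cohort: %d of %d matched sets retained",
            len(keep_sets),
            cohort.n_sets,
        )
    return MatchedCohort(children=children, ratio=cohort.ratio)
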