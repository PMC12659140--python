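"""Synthetic registry generator.

The real study data live in confidential Swedish national registers, so
this module fabricates cohorts and event streams with the statistical
structure the downstream analysis assumes:

* an exposed group (children with a parent diagnosed with lymphoma
  before their birth) and a larger comparator pool, with overlapping
  maternal-age distributions and per-child sampling weights;
* recurrent coded healthcare events per child and tree leaf, drawn from
  Poisson processes with a child-level gamma frailty shared across all
  codes (one "sickness propensity" per child, which induces the
  within-child correlation the scan's child-level randomisation must
  respect);
* a global exposure rate multiplier (default 1.08, the overall excess
  utilisation rate of the exposed group) modelling uniform
  health-seeking behaviour, plus optional injected code clusters with a
  cut-specific risk ratio;
* death and emigration as independent exponentials truncating follow-up
  at whichever of death, emigration or the fifth birthday comes first.

Dates are day-resolved; five years is counted as 1,826 days.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .trees import ClassificationSystem, ClassificationTree

__all__ = [
    "HazardConfig",
    "ConfigurationError",
    "simulate_cohort",
    "simulate_events",
    "write_cohort_table",
    "write_event_table",
    "FIVE_YEARS_DAYS",
    "DAYS_PER_YEAR",
]

FIVE_YEARS_DAYS = 1826
DAYS_PER_YEAR = 365.25


class ConfigurationError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass(frozen=True)
class HazardConfig:
    """Event-process parameters of the synthetic registry.

    Parameters
    ----------
    baseline_rate:
        Annual event rate per tree leaf for a frailty-1 comparator
        child.  A scalar applies to every leaf; a mapping overrides
        individual leaves.  The default 0.02/leaf/year yields roughly
        0.8 events per child-year on the bundled ~40-leaf toy ICD tree,
        matching the all-events hospital-visit rate scale of a Swedish
        early-childhood cohort.
    frailty_variance:
        Variance of the gamma-distributed, mean-one child-level frailty
        shared across all leaves.  0 disables overdispersion.
    exposure_multiplier:
        Rate multiplier applied to every leaf for exposed children
        (uniform health-seeking excess; default 1.08).
    clusters:
        Sequence of ``(cut_code, risk_ratio)`` pairs; exposed children's
        rates on leaves under each cut are additionally multiplied by
        the risk ratio.
    death_rate, emigration_rate:
        Annual exponential hazards for the competing/censoring events.
    """

    baseline_rate: Union[float, Mapping[str, float]] = 0.02
    frailty_variance: float = 0.5
    exposure_multiplier: float = 1.08
    clusters: tuple[tuple[str, float], ...] = ()
    death_rate: float = 0.0005
    emigration_rate: float = 0.005

    def __post_init__(self):
        rates = (
            self.baseline_rate.values()
            if isinstance(self.baseline_rate, Mapping)
            else [self.baseline_rate]
        )
        if any(r < 0 for r in rates):
            raise ConfigurationError("baseline rates must be >= 0")
        if self.frailty_variance < 0:
            raise ConfigurationError("frailty variance must be >= 0")
        if self.exposure_multiplier < 0:
            raise ConfigurationError("exposure multiplier must be >= 0")
        if any(rr <= 0 for _, rr in self.clusters):
            raise ConfigurationError("injected risk ratios must be > 0")
        if self.death_rate < 0 or self.emigration_rate < 0:
            raise ConfigurationError("death/emigration rates must be >= 0")

    def with_(self, **kwargs) -> "HazardConfig":
        return replace(self, **kwargs)


_STUDY_START = pd.Timestamp("2000-01-01")
_STUDY_END = pd.Timestamp("2018-12-31")


def _children_frame(
    rng: np.random.Generator,
    n: int,
    exposed: bool,
    config: HazardConfig,
    id_offset: int,
) -> pd.DataFrame:
    span = (_STUDY_END - _STUDY_START).days
    birth_days = rng.integers(0, span + 1, size=n)
    birth = _STUDY_START + pd.to_timedelta(birth_days, unit="D")
    maternal_age = np.clip(rng.normal(31.0, 4.5, size=n), 18.0, 45.0)
    # competing / censoring processes (exponential, in years)
    with np.errstate(divide="ignore"):
        t_death = (
            rng.exponential(1.0 / config.death_rate, size=n)
            if config.death_rate > 0
            else np.full(n, np.inf)
        )
        t_emig = (
            rng.exponential(1.0 / config.emigration_rate, size=n)
            if config.emigration_rate > 0
            else np.full(n, np.inf)
        )

    def _date(t_years: np.ndarray) -> pd.Series:
        # dates beyond ten years post-birth can never affect 5-year follow-up
        days = np.where(t_years <= 10.0, np.round(t_years * DAYS_PER_YEAR), np.nan)
        out = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
        ok = np.isfinite(days)
        out[ok] = birth[ok] + pd.to_timedelta(days[ok], unit="D")
        return out

    prefix = "E" if exposed else "C"
    birth_year = birth.year
    if exposed:
        # parent diagnosed before birth, within the registry window
        diagnosis_year = np.minimum(
            birth_year, 2000 + rng.integers(0, 19, size=n)
        )
        subtype = np.where(rng.random(n) < 0.563, "HL", "NHL")
        parent_sex = np.where(rng.random(n) < 0.457, "F", "M")
        weight = np.ones(n)
    else:
        diagnosis_year = np.full(n, np.nan)
        subtype = np.full(n, "none")
        parent_sex = np.full(n, "")
        # emulated KM-type inverse-probability-of-sampling weights (>= 1)
        weight = 1.0 / rng.uniform(0.5, 1.0, size=n)
    return pd.DataFrame(
        {
            "child_id": [f"{prefix}{id_offset + i:06d}" for i in range(n)],
            "parent_id": [f"P{prefix}{id_offset + i:06d}" for i in range(n)],
            "birth_date": birth,
            "exposure": exposed,
            "exposed_parent_sex": parent_sex,
            "lymphoma_subtype": subtype,
            "parent_diagnosis_year": diagnosis_year,
            "maternal_age_years": maternal_age,
            "death_date": _date(t_death).values,
            "emigration_date": _date(t_emig).values,
            "sampling_weight": weight,
        }
    )


def simulate_cohort(
    n_exposed: int,
    ratio: int,
    config: Optional[HazardConfig] = None,
    seed: Optional[int] = None,
    pool_factor: float = 3.0,
) -> pd.DataFrame:
    """Simulate exposed children plus a comparator pool.

    The pool holds ``pool_factor * ratio * n_exposed`` comparator-origin
    children so that 1:``ratio`` matching on maternal age is feasible.
    Reproducible under a fixed ``seed``.
    """
    if n_exposed < 1 or ratio < 1:
        raise ConfigurationError("need n_exposed >= 1 and ratio >= 1")
    if pool_factor < 1:
        raise ConfigurationError("pool_factor must be >= 1")
    config = config or HazardConfig()
    rng = np.random.default_rng(seed)
    exposed = _children_frame(rng, n_exposed, True, config, 0)
    n_pool = int(np.ceil(pool_factor * ratio * n_exposed))
    pool = _children_frame(rng, n_pool, False, config, 0)
    return pd.concat([exposed, pool], ignore_index=True)


def _followup_days(children: pd.DataFrame) -> np.ndarray:
    birth = children["birth_date"]
    end_death = (children["death_date"] - birth).dt.days.to_numpy(float)
    end_emig = (children["emigration_date"] - birth).dt.days.to_numpy(float)
    days = np.fmin(np.fmin(end_death, end_emig), FIVE_YEARS_DAYS)
    return np.where(np.isnan(days), FIVE_YEARS_DAYS, days)


def simulate_events(
    children: pd.DataFrame,
    tree: ClassificationTree,
    config: Optional[HazardConfig] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Draw recurrent coded events for every child on ``tree``'s leaves.

    Per child ``i`` and leaf ``j`` the number of events over follow-up
    ``T_i`` (years) is Poisson with mean ``rate_j * g_i * m_i * T_i``,
    where ``g_i`` is the shared gamma frailty and ``m_i`` combines the
    global exposure multiplier with any injected cluster risk ratios.
    Event dates are uniform over the follow-up window.  Settings are
    dispensations for an ATC tree, in-/outpatient (1:9) for ICD.
    """
    config = config or HazardConfig()
    rng = np.random.default_rng(seed)
    leaves = tree.leaf_codes
    n_children, n_leaves = len(children), len(leaves)
    if isinstance(config.baseline_rate, Mapping):
        base = np.array([config.baseline_rate.get(l, 0.0) for l in leaves])
    else:
        base = np.full(n_leaves, float(config.baseline_rate))

    exposed = children["exposure"].to_numpy(bool)
    if config.frailty_variance > 0:
        shape = 1.0 / config.frailty_variance
        frailty = rng.gamma(shape, config.frailty_variance, size=n_children)
    else:
        frailty = np.ones(n_children)
    t_years = _followup_days(children) / DAYS_PER_YEAR

    lam = np.outer(frailty * t_years, base)
    lam[exposed] *= config.exposure_multiplier
    leaf_index = {l: j for j, l in enumerate(leaves)}
    for cut_code, rr in config.clusters:
        cols = [leaf_index[l] for l in tree.leaves_under(cut_code) if l in leaf_index]
        lam[np.ix_(exposed, cols)] *= rr

    counts = rng.poisson(lam)
    child_idx, leaf_idx = np.nonzero(counts)
    reps = counts[child_idx, leaf_idx]
    child_idx = np.repeat(child_idx, reps)
    leaf_idx = np.repeat(leaf_idx, reps)
    n_events = len(child_idx)
    age_days = np.floor(
        rng.random(n_events) * t_years[child_idx] * DAYS_PER_YEAR
    ).astype(int)

    births = children["birth_date"].to_numpy()
    ids = children["child_id"].to_numpy()
    if tree.system is ClassificationSystem.ATC:
        setting = np.full(n_events, "dispensation")
        position = np.full(n_events, "")
    else:
        setting = np.where(rng.random(n_events) < 0.1, "inpatient", "outpatient")
        position = np.where(rng.random(n_events) < 0.8, "main", "secondary")
    events = pd.DataFrame(
        {
            "child_id": ids[child_idx],
            "event_date": births[child_idx] + age_days.astype("timedelta64[D]"),
            "code": np.array(leaves, dtype=object)[leaf_idx],
            "setting": setting,
            "diagnosis_position": position,
        }
    )
    return events.sort_values(["child_id", "event_date"], kind="stable").reset_index(
        drop=True
    )


def _write_tsv(frame: pd.DataFrame, path, seed: Optional[int]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# regiscan synthetic registry; seed={seed}\n")
        frame.to_csv(fh, sep="\t", index=False)


def write_cohort_table(children: pd.DataFrame, path, seed: Optional[int] = None) -> None:
    """Write the child cohort as TSV with the seed recorded in a header comment."""
    _write_tsv(children, path, seed)


def write_event_table(events: pd.DataFrame, path, seed: Optional[int] = None) -> None:
    """Write the event stream as TSV with the seed recorded in a header comment."""
    _write_tsv(events, path, seed)
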