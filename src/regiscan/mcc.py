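"""Mean cumulative count (MCC) of recurrent events with death as a
competing risk.

The estimator is the nonparametric

    MCC(t) = sum_{u <= t}  S_D(u-) * d(u) / n(u)

where ``d(u)`` is the number of recurrent events at age ``u``, ``n(u)``
the number of children still under observation at ``u`` (follow-up end =
min(death, censoring)), and ``S_D(u-)`` the left-continuous Kaplan–Meier
survivor function for death, censored by emigration/age five only.  With
no deaths this reduces to the cumulative sum of ``d(u)/n(u)``; with no
censoring either, MCC at the horizon is exactly total events divided by
the number of children.

Ties between an event and a death or censoring at the same age are
resolved event-first: the child still contributes to the risk set and
``S_D(u-)`` excludes deaths at ``u`` itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["MCCCurve", "mean_cumulative_count"]


class DataError(ValueError):
    pass


@dataclass(frozen=True)
class MCCCurve:
    """A non-decreasing step function: MCC value at each distinct event age."""

    ages: np.ndarray
    values: np.ndarray
    n_at_risk: np.ndarray

    def __call__(self, t: float) -> float:
        """MCC at age ``t`` (step-function evaluation)."""
        idx = np.searchsorted(self.ages, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.values[idx])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"age": self.ages, "mcc": self.values, "n_at_risk": self.n_at_risk}
        )


def mean_cumulative_count(
    event_ages: Sequence[Sequence[float]],
    death_ages: Sequence[float],
    censor_ages: Sequence[float],
) -> MCCCurve:
    """Estimate the MCC curve for one group of children.

    Parameters
    ----------
    event_ages:
        Per child, the ages (years) of their recurrent events.
    death_ages:
        Per child, age at death or NaN.
    censor_ages:
        Per child, age at administrative censoring
        (min(emigration, five years)); must be finite.

    Events after a child's end of follow-up raise :class:`DataError`
    (events *at* death/censoring age are allowed, event-first).
    """
    death = np.asarray(death_ages, float)
    censor = np.asarray(censor_ages, float)
    n_children = len(censor)
    if len(death) != n_children or len(event_ages) != n_children:
        raise ValueError("event_ages, death_ages, censor_ages must align")
    if not np.isfinite(censor).all():
        raise ValueError("censor ages must be finite")
    end = np.fmin(death, censor)  # NaN deaths ignored
    died = ~np.isnan(death) & (death <= censor)

    ev_child = []
    ev_age = []
    for i, ages in enumerate(event_ages):
        for a in ages:
            if a > end[i]:
                raise DataError(
                    f"child {i}: event at age {a} after follow-up end {end[i]}"
                )
            ev_child.append(i)
            ev_age.append(float(a))
    ev_age_arr = np.asarray(ev_age, float)

    # Process distinct ages ascending.  At each age: events first (using the
    # current left-limit of S_D and the risk set including children ending
    # here), then the death factor updates S_D.
    event_times = np.unique(ev_age_arr) if ev_age_arr.size else np.array([])
    death_times = np.unique(end[died]) if died.any() else np.array([])
    all_times = np.unique(np.concatenate([event_times, death_times]))

    end_sorted = np.sort(end)
    deaths_at = {}
    for t in death_times:
        deaths_at[t] = int(np.sum(died & (end == t)))
    d_events = {}
    if ev_age_arr.size:
        vals, counts = np.unique(ev_age_arr, return_counts=True)
        d_events = dict(zip(vals, counts))

    surv = 1.0
    mcc = 0.0
    out_ages, out_vals, out_risk = [], [], []
    for t in all_times:
        n_at_risk = n_children - int(np.searchsorted(end_sorted, t, side="left"))
        d = d_events.get(t, 0)
        if d and n_at_risk > 0:
            mcc += surv * d / n_at_risk
            out_ages.append(t)
            out_vals.append(mcc)
            out_risk.append(n_at_risk)
        dd = deaths_at.get(t, 0)
        if dd and n_at_risk > 0:
            surv *= 1.0 - dd / n_at_risk
    return MCCCurve(
        ages=np.asarray(out_ages),
        values=np.asarray(out_vals),
        n_at_risk=np.asarray(out_risk, int),
    )
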