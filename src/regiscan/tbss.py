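"""Unconditional Bernoulli tree-based scan statistic (TBSS).

Every node of a classification tree (chapter, block, category,
subcategory for ICD-10; the five ATC levels) is a candidate *cut*.  For
each cut, ``n`` is the number of cohort children with at least one
(first) event whose code falls at or below the cut and ``c`` of them are
exposed.  Under the null, each affected child is exposed with the design
probability ``p = n_exposed / (n_exposed + n_comparators)`` (1/6 under
1:5 matching), so ``c ~ Binomial(n, p)`` for every cut.  Each cut is
scored with the one-sided Bernoulli log-likelihood ratio

    LLR(c, n) = c·ln(c/(p·n)) + (n−c)·ln((n−c)/((1−p)·n))   if c/n > p,
    0 otherwise,

and the family-wise multiplicity over all cuts is absorbed by Monte
Carlo: replicates relabel every child independently as exposed with
probability ``p`` — all of a child's cut memberships move together,
preserving the within-child correlation across codes — and record the
maximum LLR over cuts.  The adjusted p-value of a cut is its LLR's rank
within the ``R`` null maxima, ``(1 + #{max >= LLR}) / (R + 1)``.

The counting unit is the distinct child per cut (consistent with 5-year
risks equal to affected children over cohort size); event-level
relabelling, where each child-code first event is randomised
independently, is available via ``ScanConfig(relabel="event")`` for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .rates import risk_and_ratio
from .trees import ClassificationTree

__all__ = [
    "ScanConfig",
    "ScanData",
    "aggregate_cut_counts",
    "bernoulli_llr",
    "monte_carlo_null",
    "adjusted_pvalue",
    "rank_and_report",
    "scan",
]


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters: case probability ``p``, Monte-Carlo replicates,
    seed, report size and relabelling unit."""

    p: float
    n_replicates: int = 9999
    seed: Optional[int] = None
    k: int = 10
    relabel: str = "child"

    def __post_init__(self):
        if not 0 < self.p < 1:
            raise ValueError("p must be in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("need at least one Monte-Carlo replicate")
        if self.relabel not in ("child", "event"):
            raise ValueError("relabel must be 'child' or 'event'")


@dataclass
class ScanData:
    """Aggregated per-cut counts plus the unit-by-cut membership matrix
    used for Monte-Carlo relabelling.

    ``membership`` rows are relabelling units (children, or child-code
    pairs under event-level relabelling) with at least one event;
    ``unit_exposed`` flags the observed labels.  ``c``/``n`` are the
    exposed/total affected units per cut, aligned with ``cut_codes``.
    """

    cut_codes: list[str]
    c: np.ndarray
    n: np.ndarray
    membership: sparse.csr_matrix
    unit_exposed: np.ndarray
    labels: dict[str, str] = field(default_factory=dict)
    n_unknown_codes: int = 0


def aggregate_cut_counts(
    events: pd.DataFrame,
    children: pd.DataFrame,
    tree: ClassificationTree,
    relabel: str = "child",
) -> ScanData:
    """Count, per cut, the distinct children with a first event in the cut.

    ``events`` must already be masked onto tree nodes, chapter-excluded
    and restricted to follow-up.  Codes not on the tree are counted and
    dropped.  A child appears at most once per cut but may appear in
    many cuts (its own code's node plus every ancestor below the root).
    """
    cut_codes = list(tree.iter_preorder())
    cut_index = {code: i for i, code in enumerate(cut_codes)}
    path_cache: dict[str, Optional[list[int]]] = {}

    def _path(code: str) -> Optional[list[int]]:
        if code not in path_cache:
            if code in tree:
                path_cache[code] = [cut_index[a] for a in tree.ancestors(code)]
            else:
                path_cache[code] = None
        return path_cache[code]

    pairs = events[["child_id", "code"]].drop_duplicates()
    known = pairs["code"].map(lambda c: _path(c) is not None)
    n_unknown = int((~known).sum())
    pairs = pairs[known]

    exposure = children.set_index("child_id")["exposure"].astype(bool)

    unit_rows: list[int] = []
    unit_cols: list[int] = []
    unit_exposed: list[bool] = []
    if relabel == "child":
        unit_of_child: dict[str, int] = {}
        seen: set[tuple[int, int]] = set()
        for child_id, code in pairs.itertuples(index=False):
            u = unit_of_child.get(child_id)
            if u is None:
                u = unit_of_child[child_id] = len(unit_exposed)
                unit_exposed.append(bool(exposure[child_id]))
            for ci in _path(code):
                if (u, ci) not in seen:
                    seen.add((u, ci))
                    unit_rows.append(u)
                    unit_cols.append(ci)
    elif relabel == "event":
        for child_id, code in pairs.itertuples(index=False):
            u = len(unit_exposed)
            unit_exposed.append(bool(exposure[child_id]))
            for ci in _path(code):
                unit_rows.append(u)
                unit_cols.append(ci)
    else:
        raise ValueError("relabel must be 'child' or 'event'")

    n_units = len(unit_exposed)
    membership = sparse.csr_matrix(
        (np.ones(len(unit_rows), dtype=np.float32), (unit_rows, unit_cols)),
        shape=(n_units, len(cut_codes)),
    )
    exposed_vec = np.asarray(unit_exposed, bool)
    n = np.asarray(membership.sum(axis=0)).ravel().astype(np.int64)
    c = (
        np.asarray(membership[exposed_vec].sum(axis=0)).ravel().astype(np.int64)
        if exposed_vec.any()
        else np.zeros(len(cut_codes), np.int64)
    )
    labels = {code: tree.node(code).label for code in cut_codes}
    return ScanData(
        cut_codes=cut_codes, c=c, n=n, membership=membership,
        unit_exposed=exposed_vec, labels=labels, n_unknown_codes=n_unknown,
    )


def bernoulli_llr(c, n, p: float):
    """One-sided Bernoulli log-likelihood ratio (vectorised).

    Zero when the cut is not enriched (``c/n <= p``) or empty; terms
    with zero counts contribute zero.
    """
    c = np.asarray(c, float)
    n = np.asarray(n, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(c > 0, c * np.log(c / (p * n)), 0.0)
        t2 = np.where(n - c > 0, (n - c) * np.log((n - c) / ((1 - p) * n)), 0.0)
        llr = np.where((n > 0) & (c > p * n), t1 + t2, 0.0)
    if llr.ndim == 0:
        return float(llr)
    return llr


def monte_carlo_null(
    scan_data: ScanData,
    config: ScanConfig,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Sorted null distribution of the maximum LLR over cuts.

    Each replicate relabels every unit independently as exposed with
    probability ``p``, recomputes all cut LLRs from the membership
    matrix, and records the maximum.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    R = config.n_replicates
    n_units = scan_data.membership.shape[0]
    n = scan_data.n
    active = n > 0
    M = scan_data.membership[:, active] if not active.all() else scan_data.membership
    n_act = n[active]
    maxima = np.empty(R)
    if n_units == 0 or not active.any():
        maxima[:] = 0.0
        return maxima
    # chunked so the replicate-by-unit label matrix stays small
    chunk = max(1, min(R, int(2e7 // max(n_units, 1))))
    done = 0
    while done < R:
        b = min(chunk, R - done)
        labels = (
            rng.random((b, n_units), dtype=np.float32) < config.p
        ).astype(np.float32)
        counts = labels @ M  # dense (b, cuts)
        counts = np.asarray(counts)
        llr = bernoulli_llr(counts, n_act[None, :], config.p)
        maxima[done : done + b] = llr.max(axis=1)
        done += b
    maxima.sort()
    return maxima


def adjusted_pvalue(llr, null_maxima: np.ndarray, n_replicates: Optional[int] = None):
    """Monte-Carlo adjusted p: ``(1 + #{null max >= llr}) / (R + 1)``."""
    null_sorted = np.sort(np.asarray(null_maxima, float))
    R = len(null_sorted) if n_replicates is None else n_replicates
    n_ge = len(null_sorted) - np.searchsorted(null_sorted, np.asarray(llr, float),
                                              side="left")
    p = (1.0 + n_ge) / (R + 1.0)
    if np.ndim(llr) == 0:
        return float(p)
    return p


def rank_and_report(
    scan_data: ScanData,
    llr: np.ndarray,
    pvalues: np.ndarray,
    n_exposed: int,
    n_comparators: int,
    k: int = 10,
) -> pd.DataFrame:
    """Top-``k`` cuts by LLR (ties code-lexicographic), with 5-year risks,
    risk ratio and risk difference against the cohort denominators."""
    active = scan_data.n > 0
    order = sorted(
        np.flatnonzero(active),
        key=lambda i: (-llr[i], scan_data.cut_codes[i]),
    )[: max(k, 0) if k is not None else None]
    rows = []
    for rank, i in enumerate(order, start=1):
        code = scan_data.cut_codes[i]
        c, n = int(scan_data.c[i]), int(scan_data.n[i])
        rr = risk_and_ratio(c, n_exposed, n - c, n_comparators)
        rows.append(
            {
                "rank": rank,
                "cut": code,
                "label": scan_data.labels.get(code, ""),
                "exposed_events": c,
                "exposed_risk_pct": rr.risk1,
                "comparator_events": n - c,
                "comparator_risk_pct": rr.risk0,
                "risk_ratio": rr.risk_ratio,
                "risk_difference": rr.risk_difference,
                "llr": float(llr[i]),
                "p_value": float(pvalues[i]),
            }
        )
    return pd.DataFrame(rows)


def scan(
    events: pd.DataFrame,
    children: pd.DataFrame,
    tree: ClassificationTree,
    config: ScanConfig,
) -> pd.DataFrame:
    """Full scan: aggregate counts, score cuts, build the Monte-Carlo
    null, adjust p-values and return the ranked top-``k`` table."""
    data = aggregate_cut_counts(events, children, tree, relabel=config.relabel)
    llr = bernoulli_llr(data.c, data.n, config.p)
    null = monte_carlo_null(data, config)
    pvals = adjusted_pvalue(llr, null, config.n_replicates)
    n_exposed = int(children["exposure"].astype(bool).sum())
    n_comp = int((~children["exposure"].astype(bool)).sum())
    return rank_and_report(data, llr, pvals, n_exposed, n_comp, k=config.k)
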