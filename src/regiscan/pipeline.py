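"""End-to-end orchestration of the synthetic-registry analysis.

One :class:`RunConfig` (loadable from YAML) drives the whole chain:
simulate cohort and events → weighted matching → follow-up → chapter
exclusion and masking → utilisation rates → mean cumulative counts →
tree scans (ICD on the full cohort, ATC on the drug sub-cohort) →
optional power curve.  A single master seed spawns per-stage substreams,
so any stage re-run in isolation reproduces its output; every emitted
TSV carries a header comment with the package version, master seed and a
hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import MatchedCohort, add_followup, build_drug_subcohort, match_children
from .dictionaries import load_toy_tree
from .mcc import mean_cumulative_count
from .rates import rate_ratio_exact, summarize_utilisation, utilisation_table
from .simulate import (
    DAYS_PER_YEAR,
    HazardConfig,
    simulate_cohort,
    simulate_events,
)
from .tbss import ScanConfig, scan
from .trees import (
    ClassificationSystem,
    build_tree,
    default_atc_mask_rules,
    default_icd10_mask_rules,
    exclude_chapters,
    mask_events,
    read_dictionary,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "stratified_rates"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Pipeline parameters; defaults run a small but complete analysis."""

    seed: int = 0
    n_exposed: int = 1424
    ratio: int = 5
    caliper_years: int = 1
    icd_dictionary: Optional[str] = None  # paths; None -> bundled toy trees
    atc_dictionary: Optional[str] = None
    n_replicates: int = 9999
    top_k: int = 10
    hazard: HazardConfig = field(default_factory=HazardConfig)
    run_rates: bool = True
    run_mcc: bool = True
    run_scan_icd: bool = True
    run_scan_atc: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        hazard = HazardConfig(**{
            k: (tuple(map(tuple, v)) if k == "clusters" else v)
            for k, v in (raw.pop("hazard", {}) or {}).items()
        })
        known = {f.name for f in dataclasses.fields(cls)} - {"hazard"}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        return cls(hazard=hazard, **raw)

    def validate(self) -> None:
        for path in (self.icd_dictionary, self.atc_dictionary):
            if path is not None and not Path(path).exists():
                raise PipelineError("config", f"dictionary path {path!r} not found")
        if self.n_exposed < 1 or self.ratio < 1:
            raise PipelineError("config", "n_exposed and ratio must be >= 1")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _write(frame: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# regiscan {__version__}; seed={config.seed}; "
            f"config={config.config_hash()}\n"
        )
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _load_tree(path: Optional[str], system: ClassificationSystem):
    if path is None:
        return load_toy_tree(system)
    return build_tree(read_dictionary(path), system)


def _group_mcc(events: pd.DataFrame, children: pd.DataFrame) -> pd.DataFrame:
    frames = []
    for exposed, name in ((True, "exposed"), (False, "comparator")):
        grp = children[children["exposure"] == exposed]
        ev = events[events["child_id"].isin(grp["child_id"])]
        birth = grp.set_index("child_id")["birth_date"]
        ages = (
            (ev["event_date"].to_numpy() - birth.reindex(ev["child_id"]).to_numpy())
            .astype("timedelta64[D]").astype(float) / DAYS_PER_YEAR
        )
        per_child = {cid: [] for cid in grp["child_id"]}
        for cid, age in zip(ev["child_id"], ages):
            per_child[cid].append(age)
        death = (
            (grp["death_date"] - grp["birth_date"]).dt.days / DAYS_PER_YEAR
        ).to_numpy()
        censor = np.where(
            grp["emigration_date"].notna(),
            (grp["emigration_date"] - grp["birth_date"]).dt.days / DAYS_PER_YEAR,
            np.inf,
        )
        censor = np.fmin(censor, 5.0)
        # deaths after censoring are unobserved
        curve = mean_cumulative_count(
            [per_child[cid] for cid in grp["child_id"]], death, censor
        )
        frame = curve.to_frame()
        frame.insert(0, "group", name)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Run every enabled stage; returns the output directory.

    Writes ``cohort.tsv``, ``events_*.tsv``, ``table2.tsv``,
    ``utilisation_summary.tsv``, ``mcc.tsv``, ``table3_icd.tsv`` and
    ``table3_atc.tsv`` (as enabled), each with a seed/config header.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(config.seed).spawn(6)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in streams]

    def stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        stage("simulate")
        icd_tree = _load_tree(config.icd_dictionary, ClassificationSystem.ICD10)
        atc_tree = _load_tree(config.atc_dictionary, ClassificationSystem.ATC)
        pool = simulate_cohort(config.n_exposed, config.ratio, config.hazard,
                               seed=seeds[0])
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", str(exc)) from exc

    try:
        stage("cohort")
        cohort = match_children(
            pool[pool["exposure"]], pool[~pool["exposure"]],
            ratio=config.ratio, caliper_years=config.caliper_years, seed=seeds[1],
        )
        children = add_followup(cohort.children)
        cohort = MatchedCohort(children=children, ratio=config.ratio)
        _write(children, out / "cohort.tsv", config)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("cohort", str(exc)) from exc

    try:
        stage("events")
        icd_events = simulate_events(children, icd_tree, config.hazard, seed=seeds[2])
        atc_events = simulate_events(children, atc_tree, config.hazard, seed=seeds[3])
        icd_events, n_excluded = exclude_chapters(icd_events)
        icd_events, n_dropped_icd = mask_events(
            icd_events, ClassificationSystem.ICD10, default_icd10_mask_rules(),
            icd_tree,
        )
        atc_events, n_dropped_atc = mask_events(
            atc_events, ClassificationSystem.ATC, default_atc_mask_rules(), atc_tree
        )
        logger.info(
            "events: %d ICD (excluded %d, unknown %d), %d ATC (unknown %d)",
            len(icd_events), n_excluded, n_dropped_icd, len(atc_events),
            n_dropped_atc,
        )
        _write(icd_events, out / "events_icd.tsv", config)
        _write(atc_events, out / "events_atc.tsv", config)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("events", str(exc)) from exc

    drug_cohort = build_drug_subcohort(cohort)
    all_events = pd.concat([icd_events, atc_events], ignore_index=True)

    if config.run_rates:
        try:
            stage("rates")
            table2 = utilisation_table(
                all_events, children, drug_children=drug_cohort.children
            )
            _write(table2, out / "table2.tsv", config)
            hosp = icd_events.groupby("child_id").size()
            totals = hosp.reindex(children["child_id"], fill_value=0)
            rows = []
            for exposed, name in ((True, "exposed"), (False, "comparator")):
                s = summarize_utilisation(
                    totals[children["exposure"].to_numpy() == exposed]
                )
                rows.append({"group": name, **dataclasses.asdict(s)})
            _write(pd.DataFrame(rows), out / "utilisation_summary.tsv", config)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("rates", str(exc)) from exc

    if config.run_mcc:
        try:
            stage("mcc")
            _write(_group_mcc(icd_events, children), out / "mcc.tsv", config)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("mcc", str(exc)) from exc

    for enabled, name, tree, events_df, kids in (
        (config.run_scan_icd, "icd", icd_tree, icd_events, children),
        (config.run_scan_atc, "atc", atc_tree, atc_events, drug_cohort.children),
    ):
        if not enabled or kids.empty:
            continue
        try:
            stage(f"scan_{name}")
            n1 = int(kids["exposure"].sum())
            n0 = len(kids) - n1
            cfg = ScanConfig(
                p=n1 / (n1 + n0), n_replicates=config.n_replicates,
                seed=seeds[4 if name == "icd" else 5], k=config.top_k,
            )
            ev = events_df[events_df["child_id"].isin(kids["child_id"])]
            _write(scan(ev, kids, tree, cfg), out / f"table3_{name}.tsv", config)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"scan_{name}", str(exc)) from exc
    return out


def stratified_rates(
    events: pd.DataFrame,
    children: pd.DataFrame,
    key: str,
    settings=None,
    kind: str = "all",
) -> pd.DataFrame:
    """Re-run the rate analysis within strata of an exposed-side variable.

    ``key`` is ``exposed_parent_sex`` or ``lymphoma_subtype``; each
    stratum keeps its exposed children plus their matched comparators
    (via ``set_id``), and the final row compares the exposed rates of
    the two largest strata directly.
    """
    if key not in ("exposed_parent_sex", "lymphoma_subtype"):
        raise ValueError(f"unknown stratification key {key!r}")
    from .rates import count_events

    exposed = children[children["exposure"]]
    rows = []
    stratum_counts = {}
    for value, grp in exposed.groupby(key):
        sets = set(grp["set_id"])
        kids = children[children["set_id"].isin(sets)]
        ev = events[events["child_id"].isin(kids["child_id"])]
        gc = count_events(ev, kids, kind=kind, settings=settings)
        if gc.c1 + gc.c0 == 0:
            logger.warning("stratum %s=%r empty, skipped", key, value)
            continue
        r = rate_ratio_exact(gc.c1, gc.pt1, gc.c0, gc.pt0, kind=kind)
        stratum_counts[value] = (gc.c1, gc.pt1)
        rows.append(
            {
                "stratum": value,
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
    if len(stratum_counts) >= 2:
        (va, (ca, pa)), (vb, (cb, pb)) = sorted(
            stratum_counts.items(), key=lambda kv: -kv[1][0]
        )[:2]
        between = rate_ratio_exact(ca, pa, cb, pb)
        rows.append(
            {
                "stratum": f"{va} vs {vb} (exposed only)",
                "exposed_events": ca,
                "exposed_rate": ca / pa,
                "comparator_events": cb,
                "comparator_rate": cb / pb,
                "rate_ratio": between.rate_ratio,
                "ci_low": between.ci_low,
                "ci_high": between.ci_high,
                "p_value": between.p_value,
            }
        )
    return pd.DataFrame(rows)
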