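"""Sampling weights, weighted matching, follow-up, drug sub-cohort."""

import numpy as np
import pandas as pd
import pytest

import regiscan as rs
from regiscan.cohort import (
    DataError,
    MatchingError,
    add_followup,
    build_drug_subcohort,
)


def _comparators(rows):
    return pd.DataFrame(
        rows, columns=["parent_id", "sex", "first_eligible_year", "sampled_year"]
    )


class TestSamplingWeights:
    def test_single_year_simple_inverse(self):
        """10 sampled from 100 in one year -> weight 10 each."""
        comp = _comparators([(f"p{i}", "M", 2000, 2000) for i in range(10)])
        popn = pd.DataFrame({"year": [2000], "sex": ["M"], "count": [100]})
        out = rs.compute_sampling_weights(comp, popn, strata=("sex",))
        assert np.allclose(out["sampling_weight"], 10.0)

    def test_two_year_product_limit(self):
        """Eligible two years, sampled in year 2 with per-year probabilities
        0.1 then 0.2 -> weight 1/(0.9 * 0.2)."""
        rows = [(f"a{i}", "M", 2000, 2000) for i in range(10)]
        rows += [(f"b{i}", "M", 2000, 2001) for i in range(18)]
        comp = _comparators(rows)
        popn = pd.DataFrame(
            {"year": [2000, 2001], "sex": ["M", "M"], "count": [100, 90]}
        )
        out = rs.compute_sampling_weights(comp, popn, strata=("sex",))
        year2 = out[out["sampled_year"] == 2001]
        assert np.allclose(year2["sampling_weight"], 1 / (0.9 * 0.2))
        assert np.allclose(year2["sampling_probability"], 0.2)

    def test_everyone_sampled_gives_unit_weights(self):
        comp = _comparators([(f"p{i}", "F", 2005, 2005) for i in range(5)])
        popn = pd.DataFrame({"year": [2005], "sex": ["F"], "count": [5]})
        out = rs.compute_sampling_weights(comp, popn, strata=("sex",))
        assert np.allclose(out["sampling_weight"], 1.0)

    def test_zero_population_rejected(self):
        comp = _comparators([("p0", "M", 2000, 2000)])
        popn = pd.DataFrame({"year": [2000], "sex": ["M"], "count": [0]})
        with pytest.raises(ValueError, match="population"):
            rs.compute_sampling_weights(comp, popn, strata=("sex",))

    def test_weighted_margins_restore_population(self, rng):
        """Each sampling year's weighted comparators re-inflate to the full
        stratum population (within 2% at n ~ 1e4), restoring the stratum
        margins the matched sampling distorted."""
        populations = {"M": 200_000, "F": 120_000}
        hazards = [0.015, 0.02, 0.03]
        rows, counts = [], []
        for sex, population in populations.items():
            alive = np.ones(population, bool)
            for year, h in zip((2000, 2001, 2002), hazards):
                counts.append((year, sex, int(alive.sum())))
                pick = alive & (rng.random(population) < h)
                for idx in np.flatnonzero(pick):
                    rows.append((f"{sex}{idx}", sex, 2000, year))
                alive &= ~pick
        comp = _comparators(rows)
        assert len(comp) > 10_000
        popn = pd.DataFrame(counts, columns=["year", "sex", "count"])
        out = rs.compute_sampling_weights(comp, popn, strata=("sex",))
        margins = out.groupby(["sex", "sampled_year"])["sampling_weight"].sum()
        for (sex, _), total in margins.items():
            assert abs(total / populations[sex] - 1) < 0.02


class TestMatching:
    def test_matching_ratio_exact(self):
        pool = rs.simulate_cohort(200, 5, seed=1)
        m = rs.match_children(
            pool[pool["exposure"]], pool[~pool["exposure"]], ratio=5, seed=2
        )
        assert m.n_sets == 200
        assert len(m.comparators) == 1000
        per_set = m.children.groupby("set_id")["role"].value_counts().unstack()
        assert (per_set["exposed"] == 1).all()
        assert (per_set["comparator"] == 5).all()

    def test_single_candidate_chosen(self):
        exposed = pd.DataFrame(
            {"child_id": ["e"], "maternal_age_years": [30.0]}
        )
        pool = pd.DataFrame(
            {"child_id": ["c"], "maternal_age_years": [30.0],
             "sampling_weight": [2.0]}
        )
        m = rs.match_children(exposed, pool, ratio=1, seed=0)
        assert m.comparators["child_id"].tolist() == ["c"]

    def test_insufficient_pool_raises_with_child_named(self):
        exposed = pd.DataFrame(
            {"child_id": ["e1"], "maternal_age_years": [30.0]}
        )
        pool = pd.DataFrame(
            {"child_id": ["c1"], "maternal_age_years": [44.0],
             "sampling_weight": [1.0]}
        )
        with pytest.raises(MatchingError, match="e1"):
            rs.match_children(exposed, pool, ratio=1, caliper_years=1, seed=0)

    def test_caliper_respected(self):
        pool = rs.simulate_cohort(100, 5, seed=3)
        m = rs.match_children(
            pool[pool["exposure"]], pool[~pool["exposure"]], ratio=5,
            caliper_years=1, seed=4,
        )
        ages = m.children.pivot_table(
            index="set_id", columns="role", values="maternal_age_years",
            aggfunc=list,
        )
        for _, row in ages.iterrows():
            target = round(row["exposed"][0])
            assert all(abs(round(a) - target) <= 1 for a in row["comparator"])

    def test_comparators_not_reused(self):
        pool = rs.simulate_cohort(150, 5, seed=5)
        m = rs.match_children(
            pool[pool["exposure"]], pool[~pool["exposure"]], ratio=5, seed=6
        )
        ids = m.comparators["child_id"]
        assert ids.is_unique

    def test_deterministic_under_seed(self):
        pool = rs.simulate_cohort(50, 5, seed=7)
        args = (pool[pool["exposure"]], pool[~pool["exposure"]])
        a = rs.match_children(*args, ratio=5, seed=8).children
        b = rs.match_children(*args, ratio=5, seed=8).children
        pd.testing.assert_frame_equal(a, b)

    def test_matched_age_distributions_overlap(self):
        """With uniform weights and a large pool, comparator maternal ages
        track the exposed distribution."""
        pool = rs.simulate_cohort(400, 5, seed=9, pool_factor=4)
        comp = pool[~pool["exposure"]].assign(sampling_weight=1.0)
        m = rs.match_children(pool[pool["exposure"]], comp, ratio=5, seed=10)
        diff = (
            m.exposed["maternal_age_years"].mean()
            - m.comparators["maternal_age_years"].mean()
        )
        assert abs(diff) < 0.5


class TestFollowup:
    def test_full_followup_is_five_years(self):
        end, py = rs.define_followup(pd.Timestamp("2010-01-01"))
        assert end == pd.Timestamp("2010-01-01") + pd.Timedelta(days=1826)
        assert py == pytest.approx(5.0, abs=0.01)

    def test_death_truncates(self):
        birth = pd.Timestamp("2010-01-01")
        end, py = rs.define_followup(birth, death_date=birth + pd.Timedelta(days=730))
        assert py == pytest.approx(2.0, abs=0.01)

    def test_late_emigration_capped_at_five_years(self):
        birth = pd.Timestamp("2010-01-01")
        end, py = rs.define_followup(
            birth, emigration_date=birth + pd.Timedelta(days=6 * 365)
        )
        assert py == pytest.approx(5.0, abs=0.01)

    def test_death_before_birth_is_data_error(self):
        with pytest.raises(DataError):
            rs.define_followup(
                pd.Timestamp("2010-01-01"), death_date=pd.Timestamp("2009-01-01")
            )

    def test_person_time_bounds(self, small_cohort):
        assert (small_cohort["person_years"] >= 0).all()
        assert (small_cohort["person_years"] <= 5.01).all()


class TestDrugSubcohort:
    def _cohort(self, years):
        rows = []
        for i, y in enumerate(years):
            rows.append(
                {"child_id": f"e{i}", "set_id": i, "role": "exposed",
                 "exposure": True, "birth_date": pd.Timestamp(f"{y}-06-01")}
            )
            rows.append(
                {"child_id": f"c{i}", "set_id": i, "role": "comparator",
                 "exposure": False, "birth_date": pd.Timestamp(f"{y}-06-01")}
            )
        return rs.MatchedCohort(children=pd.DataFrame(rows), ratio=1)

    def test_pre_register_births_excluded(self):
        sub = build_drug_subcohort(self._cohort([2004, 2010]))
        assert set(sub.children["set_id"]) == {1}

    def test_comparators_follow_their_set(self):
        sub = build_drug_subcohort(self._cohort([2010]))
        assert len(sub.children) == 2

    def test_all_pre_register_gives_empty_subcohort(self, caplog):
        sub = build_drug_subcohort(self._cohort([2001, 2003]))
        assert sub.children.empty
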