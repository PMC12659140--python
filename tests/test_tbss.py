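"""Bernoulli tree scan: LLR algebra (with an independent binomial-likelihood
oracle), count aggregation, Monte-Carlo null, adjusted p-values, ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import regiscan as rs
from regiscan.tbss import ScanConfig, aggregate_cut_counts, monte_carlo_null


def binomial_lr_oracle(c, n, p):
    """Generic binomial likelihood ratio via log-pmfs: the maximised
    alternative (success probability c/n) against the null p, one-sided."""
    if n == 0 or c / n <= p:
        return 0.0
    return float(stats.binom.logpmf(c, n, c / n) - stats.binom.logpmf(c, n, p))


class TestBernoulliLLR:
    def test_otitis_media_counts(self):
        assert rs.bernoulli_llr(186, 861, 1 / 6) == pytest.approx(7.0349, abs=1e-3)

    def test_null_configuration_is_zero(self):
        assert rs.bernoulli_llr(10, 60, 1 / 6) == 0.0

    def test_all_cases_exposed_boundary(self):
        n, p = 25, 0.2
        assert rs.bernoulli_llr(n, n, p) == pytest.approx(n * np.log(1 / p))

    def test_deficit_is_zero(self):
        assert rs.bernoulli_llr(1, 60, 1 / 6) == 0.0

    def test_matches_binomial_likelihood_oracle(self, rng):
        """Equality with an independent symbolic-likelihood implementation
        on 1,000 random (c, n, p) triples, to 1e-10."""
        for _ in range(1000):
            n = int(rng.integers(1, 500))
            c = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0.01, 0.99))
            assert rs.bernoulli_llr(c, n, p) == pytest.approx(
                binomial_lr_oracle(c, n, p), abs=1e-10
            )

    def test_vectorised_matches_scalar(self):
        c = np.array([0, 5, 10, 20])
        n = np.array([0, 10, 30, 20])
        out = rs.bernoulli_llr(c, n, 0.25)
        for ci, ni, oi in zip(c, n, out):
            assert oi == rs.bernoulli_llr(int(ci), int(ni), 0.25)


def _mini_cohort_events(icd_tree):
    """3 exposed + 3 comparator children; two siblings under H65–H75."""
    kids = pd.DataFrame(
        {
            "child_id": [f"k{i}" for i in range(6)],
            "exposure": [True, True, True, False, False, False],
        }
    )
    ev = pd.DataFrame(
        {
            "child_id": ["k0", "k0", "k1", "k3"],
            "code": ["H65", "H66", "H66", "B34"],
        }
    )
    return kids, ev


class TestAggregateCutCounts:
    def test_distinct_child_rule_across_siblings(self, icd_tree):
        kids, ev = _mini_cohort_events(icd_tree)
        data = aggregate_cut_counts(ev, kids, icd_tree)
        idx = {c: i for i, c in enumerate(data.cut_codes)}
        # k0 counts once in each sibling and once in their parent
        assert data.n[idx["H65"]] == 1
        assert data.n[idx["H66"]] == 2
        assert data.n[idx["H65–H75"]] == 2
        assert data.c[idx["H65–H75"]] == 2
        assert data.n[idx["B34"]] == 1 and data.c[idx["B34"]] == 0

    def test_empty_cut_has_zero_counts(self, icd_tree):
        kids, ev = _mini_cohort_events(icd_tree)
        data = aggregate_cut_counts(ev, kids, icd_tree)
        idx = {c: i for i, c in enumerate(data.cut_codes)}
        assert data.n[idx["G00–G09"]] == 0

    def test_single_leaf_every_child(self, icd_tree):
        kids = pd.DataFrame(
            {"child_id": [f"k{i}" for i in range(12)],
             "exposure": [True] * 2 + [False] * 10}
        )
        ev = pd.DataFrame({"child_id": kids["child_id"], "code": "H66"})
        data = aggregate_cut_counts(ev, kids, icd_tree)
        idx = {c: i for i, c in enumerate(data.cut_codes)}
        assert data.n[idx["H66"]] == 12 and data.c[idx["H66"]] == 2

    def test_unknown_codes_counted_and_dropped(self, icd_tree):
        kids, ev = _mini_cohort_events(icd_tree)
        ev = pd.concat(
            [ev, pd.DataFrame({"child_id": ["k5"], "code": ["QQQ"]})],
            ignore_index=True,
        )
        data = aggregate_cut_counts(ev, kids, icd_tree)
        assert data.n_unknown_codes == 1

    def test_nested_count_bounds(self, small_events, small_cohort, icd_tree):
        ev, _ = rs.exclude_chapters(small_events)
        ev, _ = rs.mask_events(
            ev, rs.ClassificationSystem.ICD10, rs.default_icd10_mask_rules(),
            icd_tree,
        )
        data = aggregate_cut_counts(ev, small_cohort, icd_tree)
        idx = {c: i for i, c in enumerate(data.cut_codes)}
        for code in data.cut_codes:
            kids = icd_tree.children(code)
            if not kids:
                continue
            child_n = [data.n[idx[k]] for k in kids]
            n_node = data.n[idx[code]]
            assert n_node >= max(child_n, default=0)
            # children with events coded at the node itself can exceed the sum
            assert n_node <= sum(child_n) + n_node


class TestMonteCarloNull:
    def test_fixed_seed_reproducible(self, icd_tree):
        kids, ev = _mini_cohort_events(icd_tree)
        data = aggregate_cut_counts(ev, kids, icd_tree)
        cfg = ScanConfig(p=0.5, n_replicates=200, seed=3)
        a = monte_carlo_null(data, cfg)
        b = monte_carlo_null(data, cfg)
        assert np.array_equal(a, b)

    def test_single_cut_matches_direct_binomial_simulation(self, rng):
        """With one cut containing every child, the null maxima are the
        LLRs of Binomial(n, p) draws."""
        from scipy import sparse

        n_children, p, R = 40, 1 / 6, 2000
        data = rs.ScanData(
            cut_codes=["only"],
            c=np.array([10]),
            n=np.array([n_children]),
            membership=sparse.csr_matrix(np.ones((n_children, 1), np.float32)),
            unit_exposed=np.zeros(n_children, bool),
        )
        cfg = ScanConfig(p=p, n_replicates=R, seed=9)
        maxima = monte_carlo_null(data, cfg)
        direct = rs.bernoulli_llr(
            rng.binomial(n_children, p, size=R), n_children, p
        )
        ks = stats.ks_2samp(maxima, np.sort(direct))
        assert ks.pvalue > 0.01

    def test_chunking_does_not_change_distribution(self, icd_tree):
        kids, ev = _mini_cohort_events(icd_tree)
        data = aggregate_cut_counts(ev, kids, icd_tree)
        cfg = ScanConfig(p=0.5, n_replicates=500, seed=4)
        reference = monte_carlo_null(data, cfg)
        assert len(reference) == 500
        assert (reference >= 0).all()


class TestAdjustedPvalue:
    def test_rank_one_case(self):
        null = np.arange(9999, dtype=float)
        assert rs.adjusted_pvalue(1e9, null, 9999) == pytest.approx(1 / 10_000)

    def test_zero_llr_has_p_one(self):
        null = np.abs(np.random.default_rng(0).normal(size=999))
        assert rs.adjusted_pvalue(0.0, null, 999) == pytest.approx(1.0)

    def test_empirical_percentile(self):
        null = np.sort(np.linspace(0, 10, 999))
        llr = np.quantile(null, 0.95)
        p = rs.adjusted_pvalue(llr + 1e-9, null, 999)
        assert p == pytest.approx(0.05, abs=0.01)

    def test_bounds(self):
        null = np.linspace(0, 1, 99)
        p = rs.adjusted_pvalue(np.array([0.0, 2.0]), null, 99)
        assert p[0] == 1.0 and p[1] == pytest.approx(1 / 100)


class TestRankAndReport:
    def test_k_larger_than_cuts_returns_all(self, icd_tree):
        kids, ev = _mini_cohort_events(icd_tree)
        cfg = ScanConfig(p=0.5, n_replicates=99, seed=1, k=1000)
        table = rs.scan(ev, kids, icd_tree, cfg)
        # active cuts: the H65/H66 chain up to its chapter plus the B34 chain
        expected = {"H65", "H66", "H65–H75", "H60–H95", "B34", "B25–B34",
                    "A00–B99"}
        assert set(table["cut"]) == expected

    def test_ties_are_code_ordered(self, icd_tree):
        kids = pd.DataFrame(
            {"child_id": ["a", "b"], "exposure": [True, True]}
        )
        ev = pd.DataFrame({"child_id": ["a", "b"], "code": ["H65", "H66"]})
        data = aggregate_cut_counts(ev, kids, icd_tree)
        llr = rs.bernoulli_llr(data.c, data.n, 0.5)
        table = rs.rank_and_report(data, llr, np.ones(len(llr)), 2, 2, k=10)
        identical = table[table["exposed_events"] == 1]["cut"].tolist()
        assert identical == sorted(identical)

    def test_report_risks_use_cohort_denominators(self, icd_tree):
        kids, ev = _mini_cohort_events(icd_tree)
        cfg = ScanConfig(p=0.5, n_replicates=99, seed=1, k=10)
        table = rs.scan(ev, kids, icd_tree, cfg)
        row = table[table["cut"] == "H66"].iloc[0]
        assert row["exposed_risk_pct"] == pytest.approx(100 * 2 / 3)
        assert row["comparator_risk_pct"] == pytest.approx(0.0)


class TestNullCalibration:
    @staticmethod
    def _null_dataset(ss, icd_tree, n_exp=200, n_comp=1000):
        cfg = rs.HazardConfig(exposure_multiplier=1.0)
        seed_pair = ss.generate_state(2) % (2**31)
        pool = rs.simulate_cohort(n_exp, n_comp // n_exp, cfg,
                                  seed=int(seed_pair[0]), pool_factor=1)
        from regiscan.cohort import add_followup

        children = add_followup(pool)
        ev = rs.simulate_events(children, icd_tree, cfg,
                                seed=int(seed_pair[1]))
        ev, _ = rs.exclude_chapters(ev)
        ev, _ = rs.mask_events(
            ev, rs.ClassificationSystem.ICD10, rs.default_icd10_mask_rules(),
            icd_tree,
        )
        return children, ev

    def test_fixed_margin_design_keeps_familywise_error_bounded(self, icd_tree):
        """With the matched design's fixed exposure margins the scan's
        family-wise error stays at or below nominal plus MC noise (the
        hypergeometric cut counts make it mildly conservative)."""
        n_datasets, p = 150, 1 / 6
        rejections = 0
        for ss in np.random.SeedSequence(314).spawn(n_datasets):
            children, ev = self._null_dataset(ss, icd_tree)
            data = aggregate_cut_counts(ev, children, icd_tree)
            max_llr = rs.bernoulli_llr(data.c, data.n, p).max()
            null = monte_carlo_null(
                data, ScanConfig(p=p, n_replicates=499),
                rng=np.random.default_rng(ss),
            )
            rejections += rs.adjusted_pvalue(max_llr, null, 499) <= 0.05
        se = np.sqrt(0.05 * 0.95 / n_datasets)
        assert rejections / n_datasets <= 0.05 + 2 * se

    def test_adjusted_pvalues_superuniform_under_null(self, icd_tree):
        """Under iid Bernoulli exposure labels the smallest adjusted p is
        (weakly super-)uniform: its empirical CDF does not exceed the
        diagonal by more than MC noise."""
        n_datasets, p = 120, 1 / 6
        min_ps = []
        for ss in np.random.SeedSequence(2718).spawn(n_datasets):
            rng = np.random.default_rng(ss)
            children, ev = self._null_dataset(ss, icd_tree)
            children = children.copy()
            children["exposure"] = rng.random(len(children)) < p
            data = aggregate_cut_counts(ev, children, icd_tree)
            max_llr = rs.bernoulli_llr(data.c, data.n, p).max()
            null = monte_carlo_null(
                data, ScanConfig(p=p, n_replicates=499), rng=rng
            )
            min_ps.append(rs.adjusted_pvalue(max_llr, null, 499))
        min_ps = np.asarray(min_ps)
        for x in (0.1, 0.25, 0.5):
            se = np.sqrt(x * (1 - x) / n_datasets)
            assert np.mean(min_ps <= x) <= x + 3 * se


class TestEventLevelRelabelling:
    def test_event_units_exceed_child_units(self, icd_tree):
        kids, ev = _mini_cohort_events(icd_tree)
        child = aggregate_cut_counts(ev, kids, icd_tree, relabel="child")
        event = aggregate_cut_counts(ev, kids, icd_tree, relabel="event")
        assert event.membership.shape[0] == 4  # one unit per child-code pair
        assert child.membership.shape[0] == 3  # distinct children with events
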