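"""Pooling, order inference, distances, bounds, coincidence, map summary."""

import math
import random

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from trilink import datasets
from trilink.errors import DataError
from trilink.genetics import CrossoverCategory
from trilink.simulate import SimConfig, simulate_cross, simulate_gamete_counts
from trilink.threepoint import (
    Convention,
    CrossRecord,
    ThreePointCross,
    coincidence,
    exceptional_class_distance,
    haldane_cm,
    infer_order,
    interval_distance,
    kosambi_cm,
    marker_cosegregation_summary,
    pool_by_parent,
    records_from_progeny,
    zero_recombinant_bound,
)


class TestIntervalDistance:
    @pytest.mark.parametrize(
        "count, total, cm",
        [
            (8, 1291, 0.62),
            (20, 784, 2.55),
            (12, 784, 1.53),
            (1, 146, 0.68),
            (5, 299, 1.67),
            (2, 299, 0.67),
            (1, 95, 1.05),
            (1, 61, 1.64),
            (2, 146, 1.37),
            (0, 500, 0.0),
        ],
    )
    def test_percent_recombinants(self, count, total, cm):
        assert interval_distance(count, total).printed_cm == cm

    def test_monotone_in_count(self):
        d = [interval_distance(k, 1000).distance_cm for k in range(0, 50)]
        assert d == sorted(d)

    def test_zero_total_rejected(self):
        with pytest.raises(DataError):
            interval_distance(0, 0)

    @given(st.integers(min_value=1, max_value=10**6))
    def test_bound_equals_one_recombinant_distance(self, total):
        assert math.isclose(
            zero_recombinant_bound(total).distance_cm,
            interval_distance(1, total).distance_cm,
        )

    @pytest.mark.parametrize(
        "total, bound", [(191, 0.52), (174, 0.57), (157, 0.64), (1, 100.0)]
    )
    def test_zero_recombinant_bounds(self, total, bound):
        est = zero_recombinant_bound(total)
        assert est.is_bound
        assert est.printed_cm == bound
        assert est.printed.startswith("<")

    @pytest.mark.parametrize(
        "count, total, cm", [(1, 784, 0.13), (1, 2075, 0.05), (0, 1291, 0.0)]
    )
    def test_exceptional_class_distance(self, count, total, cm):
        est = exceptional_class_distance(count, total)
        assert est.printed_cm == cm
        # the homostyle column prints a plain 0.00, not a bound
        if count == 0:
            assert est.printed == "0.00"


class TestCoincidence:
    def test_interference_is_one_minus_c(self):
        est1 = interval_distance(8, 1291)
        est2 = interval_distance(5, 1291)
        res = coincidence(4, est1, est2)
        assert math.isclose(res.interference, 1.0 - res.c)

    @given(
        st.integers(min_value=0, max_value=50),
        st.integers(min_value=1, max_value=500),
        st.integers(min_value=1, max_value=500),
    )
    def test_interference_identity_holds_for_all_inputs(self, d, k1, k2):
        n = 10000
        res = coincidence(d, interval_distance(k1, n), interval_distance(k2, n))
        assert res.interference == 1.0 - res.c

    def test_direct_arithmetic_oracle(self):
        """observed=1, r1=5/299, r2=2/299, N=299 -> c = 299/10 = 29.9."""
        res = coincidence(1, interval_distance(5, 299), interval_distance(2, 299))
        assert math.isclose(res.c, 29.9)

    def test_no_interference_when_observed_matches_expectation(self):
        n = 10000
        est1 = interval_distance(1000, n)  # r = 0.1
        est2 = interval_distance(500, n)   # r = 0.05
        res = coincidence(int(0.1 * 0.05 * n), est1, est2)
        assert math.isclose(res.c, 1.0)
        assert math.isclose(res.interference, 0.0, abs_tol=1e-12)

    def test_printed_values_imply_printed_interference(self):
        # the published coefficients and interference values are consistent
        # with I = 1 - c even though the underlying double counts are not
        # restated in the tabulated data
        for c, interference in [(103.8, -102.8), (8.6, -7.6), (50.1, -49.1)]:
            assert math.isclose(1.0 - c, interference)

    def test_zero_expectation_is_undefined_not_an_exception(self):
        res = coincidence(0, interval_distance(0, 100), interval_distance(5, 100))
        assert not res.defined
        assert math.isnan(res.c)

    def test_mismatched_totals_rejected(self):
        with pytest.raises(DataError):
            coincidence(1, interval_distance(1, 100), interval_distance(1, 200))


class TestMapFunctions:
    def test_transforms_exceed_raw_percentage(self):
        # optional transforms only; both expand distances for r > 0
        assert haldane_cm(0.1) > 10.0
        assert kosambi_cm(0.1) > 10.0
        assert haldane_cm(0.1) > kosambi_cm(0.1)


class TestPooling:
    def test_pools_by_informative_parent(self, hih_design):
        design, parents = hih_design
        records = ThreePointCross.from_interval_counts(
            datasets.okl_s_hih_interval_counts(), design).records
        pools = {p.informative_parent: p for p in pool_by_parent(records)}
        assert pools["thrum-1"].total == 1291
        assert pools["thrum-2"].total == 784
        assert pools["thrum-1"].cross_ids == ("cross_1", "cross_2", "cross_3")
        # the informative parent pools together whether it served as male or
        # female (cross_3 and cross_6 had the thrum as the seed parent)
        assert "cross_6" in pools["thrum-2"].cross_ids

    def test_single_cross_pool_equals_cross(self):
        rec = CrossRecord("c1", "t1", 100, interval_counts={
            "interval_1": 2, "interval_2": 1, "intra_s": 0})
        (pool,) = pool_by_parent([rec])
        assert pool.total == 100
        assert pool.interval_counts == rec.interval_counts

    def test_counts_must_sum_to_total(self):
        with pytest.raises(DataError, match="sum"):
            CrossRecord("c1", "t1", 10, category_counts={
                CrossoverCategory.PARENTAL: 5})


class TestInferOrder:
    def test_pooled_pair_counts_give_middle_s(self, sep_design):
        design, parents = sep_design
        model = ThreePointCross.from_pair_counts(
            datasets.okl_s_sep_pair_counts(), design, parents)
        res = model.fit()
        assert res.order_result.order == ("OKL", "S", "SEP")
        assert res.order_result.middle == "S"
        assert res.order_result.double_pair_count == 1
        assert not res.order_result.ambiguous

    def test_order_from_classified_simulation(self, hih_design):
        design, parents = hih_design
        cfg = SimConfig(design=design, informative=parents["thrum-1"],
                        tester=parents["pin-1"], r1=0.05, r2=0.03, n=20000, seed=5)
        table = simulate_cross(cfg)
        df = table.individuals.assign(cross_id="sim", informative_parent="thrum-1")
        model = ThreePointCross.from_progeny(df, design, parents)
        res = model.fit()
        assert res.order_result.middle == "S"
        assert res.order_result.inferred

    def test_order_invariant_under_locus_relabelling(self, sep_design):
        """Permuting the declared locus order leaves the inferred middle
        locus unchanged (canonical up to reversal)."""
        import yaml
        from trilink.io import design_from_dict
        from trilink.datasets import _read_yaml

        base = _read_yaml("design_okl_s_sep.yaml")
        perms = [[0, 1, 2], [2, 1, 0], [1, 0, 2], [0, 2, 1]]
        middles = set()
        for perm in perms:
            cfg = dict(base)
            cfg["loci"] = [base["loci"][i] for i in perm]
            cfg["parents"] = [
                {**p, "haplotypes": [
                    ",".join(h.split(",")[i] for i in perm) for h in p["haplotypes"]
                ]} for p in base["parents"]
            ]
            design, parents = design_from_dict(cfg)
            df = datasets.okl_s_sep_pair_counts()
            model = ThreePointCross.from_pair_counts(df, design, parents)
            res = model.fit()
            middles.add(res.order_result.middle)
            assert res.order_result.canonical() in {("OKL", "S", "SEP"), ("SEP", "S", "OKL")}
        assert middles == {"S"}

    def test_all_nonparental_empty_is_indeterminate(self, sep_design):
        design, parents = sep_design
        df = pd.DataFrame([
            {"cross_id": "c", "informative_parent": "thrum-1",
             "class_a": "OKL=mutant;S=thrum;SEP=wild_type",
             "class_b": "OKL=wild_type;S=pin;SEP=mutant", "count": 100},
        ])
        model = ThreePointCross.from_pair_counts(df, design, parents)
        res = model.fit()
        assert res.order_result.indeterminate

    def test_tie_for_rarest_sets_ambiguity(self, sep_design):
        design, parents = sep_design
        df = datasets.okl_s_sep_pair_counts().copy()
        df.loc[df["count"] == 2, "count"] = 1  # two pairs now tie at 1
        model = ThreePointCross.from_pair_counts(df, design, parents)
        res = model.fit()
        assert res.order_result.ambiguous


class TestOracleEquivalence:
    def test_classified_counts_equal_truth_counts(self, hih_design):
        """With h=0, classification recovers the generating category of
        every individual exactly."""
        design, parents = hih_design
        cfg = SimConfig(design=design, informative=parents["thrum-1"],
                        tester=parents["pin-1"], r1=0.03, r2=0.02, n=10000, seed=17)
        table = simulate_cross(cfg)
        df = table.individuals.assign(cross_id="sim", informative_parent="thrum-1")
        (rec,) = records_from_progeny(df, design, parents)
        assert rec.category_counts == {
            k: v for k, v in table.category_counts().items() if v
        }
        assert rec.n_unclassified == 0


class TestParameterRecovery:
    def test_estimates_within_three_binomial_se(self, hih_design):
        """r1=0.01, r2=0.005, c=1, N=1e5: singles-plus-doubles estimates of
        both fractions within 3 binomial SE of truth in >= 99% of 200 seeds."""
        design, parents = hih_design
        r1, r2, n = 0.01, 0.005, 10**5
        se1 = (r1 * (1 - r1) / n) ** 0.5
        se2 = (r2 * (1 - r2) / n) ** 0.5
        ok = 0
        for seed in range(200):
            cfg = SimConfig(design=design, informative=parents["thrum-1"],
                            tester=parents["pin-1"], r1=r1, r2=r2, n=n, seed=seed)
            counts = simulate_gamete_counts(cfg)
            rec = CrossRecord("sim", "thrum-1", n, category_counts=counts)
            model = ThreePointCross([rec], design, parents=parents,
                                    convention=Convention.SINGLES_PLUS_DOUBLES)
            est = model.fit().pools[0]
            r1_hat = est.est1.distance_cm / 100
            r2_hat = est.est2.distance_cm / 100
            if abs(r1_hat - r1) <= 3 * se1 and abs(r2_hat - r2) <= 3 * se2:
                ok += 1
        assert ok >= 198

    def test_coincidence_estimator_unbiased_at_c_one(self, hih_design):
        """Mean fitted c over 200 seeds within 10% of 1 (N=1e5, r1=r2=0.05)."""
        design, parents = hih_design
        n = 10**5
        cs = []
        for seed in range(200):
            cfg = SimConfig(design=design, informative=parents["thrum-1"],
                            tester=parents["pin-1"], r1=0.05, r2=0.05, c=1.0,
                            n=n, seed=seed)
            counts = simulate_gamete_counts(cfg)
            rec = CrossRecord("sim", "thrum-1", n, category_counts=counts)
            model = ThreePointCross([rec], design, parents=parents,
                                    convention=Convention.SINGLES_PLUS_DOUBLES)
            cs.append(model.fit().pools[0].coincidence.c)
        mean_c = sum(cs) / len(cs)
        assert abs(mean_c - 1.0) <= 0.1


class TestPublishedReconciliation:
    def test_inconsistent_cell_is_flagged_not_matched(self, hih_design):
        design, parents = hih_design
        model = ThreePointCross.from_interval_counts(
            datasets.okl_s_hih_interval_counts(), design, parents=parents,
            published=datasets.okl_s_hih_published())
        res = model.fit()
        locs = [a.location for a in res.annotations]
        assert locs == ["thrum-1:S-HIH", "thrum-1:S-HIH"]
        messages = " | ".join(a.message for a in res.annotations)
        assert "6" in messages and "5" in messages and "0.46" in messages

    def test_fully_consistent_table_has_no_annotations(self, sep_design):
        design, parents = sep_design
        model = ThreePointCross.from_interval_counts(
            datasets.okl_s_sep_interval_counts(), design, parents=parents,
            published=datasets.okl_s_sep_published())
        assert model.fit().annotations == []


class TestSummary:
    def test_summary_contains_order_table_and_notes(self, hih_design):
        design, parents = hih_design
        model = ThreePointCross.from_interval_counts(
            datasets.okl_s_hih_interval_counts(), design, parents=parents,
            published=datasets.okl_s_hih_published())
        text = model.fit().summary()
        for token in ("OKL-S-HIH", "1291", "0.62", "2.55", "1.53", "0.13",
                      "0.62-2.55", "0.39-1.53", "NOTE"):
            assert token in text

    def test_conflicting_orders_across_pools_rejected(self, hih_design):
        from trilink.threepoint import (
            IntervalEstimate, OrderResult, ParentPool, PoolEstimate, summarize_map,
        )

        def pe(order):
            pool = ParentPool("p" + order[1], ("c",), 100)
            return PoolEstimate(
                pool=pool,
                est1=interval_distance(1, 100),
                est2=interval_distance(1, 100),
                intra=exceptional_class_distance(0, 100),
                order=OrderResult(order=order, middle=order[1]),
            )

        with pytest.raises(DataError, match="conflicting"):
            summarize_map([pe(("A", "B", "C")), pe(("A", "C", "B"))],
                          ("A", "B", "C"), ("A-B", "B-C"))


class TestMarkerCosegregationSummary:
    def test_bounds_and_estimates(self):
        df = marker_cosegregation_summary(datasets.single_marker_cosegregation())
        by = df.set_index("marker")
        assert by.loc["PvSLP1", "printed"] == "< 0.52"
        assert by.loc["PvSLL1", "printed"] == "< 0.57"
        assert by.loc["PvGlo", "printed"] == "< 0.64"
        assert by.loc["PvSLL2", "printed"] == "1.37"
        assert not by.loc["PvSLL2", "is_bound"]
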