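"""Variant-call evaluation, t-tests, matched regions and enrichment."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mcrkit.evalstats import (
    chi_squared_2x2,
    classify_calls,
    compare_strategies_ttest,
    compute_rates,
    enrichment_test,
    evaluate_calls,
    sample_matched_regions,
)
from mcrkit.genomeio import Genome, Interval, VariantRecord
from mcrkit.synthgenome import generate_background


def mk(chrom, pos, alt="C", gt="het", ref="A"):
    if ref == alt:
        ref = "G"
    return VariantRecord(chrom, pos, ref, alt, gt)


class TestClassify:
    def test_identity(self):
        vs = [mk("c", i) for i in range(10)]
        cls = classify_calls(vs, vs)
        assert (len(cls["TP"]), len(cls["FP"]), len(cls["FN"])) == (10, 0, 0)

    def test_partial_overlap(self):
        truth = [mk("c", i) for i in range(10)]
        called = [mk("c", i) for i in range(7)] + [mk("c", i) for i in range(50, 53)]
        cls = classify_calls(truth, called)
        assert (len(cls["TP"]), len(cls["FP"]), len(cls["FN"])) == (7, 3, 3)

    def test_same_position_different_alt_is_fp_plus_fn(self):
        truth = [mk("c", 5, alt="C")]
        called = [mk("c", 5, alt="T")]
        cls = classify_calls(truth, called)
        assert (len(cls["TP"]), len(cls["FP"]), len(cls["FN"])) == (0, 1, 1)

    def test_genotype_matching_optional(self):
        truth = [mk("c", 5, gt="hom")]
        called = [mk("c", 5, gt="het")]
        assert len(classify_calls(truth, called)["TP"]) == 1
        assert classify_calls(truth, called)["genotype_concordant"] == 0
        strict = classify_calls(truth, called, match_on_genotype=True)
        assert len(strict["TP"]) == 0

    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            classify_calls([mk("c", 5), mk("c", 5, alt="T")], [])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
    def test_partition_identities_on_random_sets(self, n_shared, n_fp, n_fn):
        truth = [mk("c", i) for i in range(n_shared + n_fn)]
        called = [mk("c", i) for i in range(n_shared)] + [
            mk("c", 10_000 + i) for i in range(n_fp)
        ]
        cls = classify_calls(truth, called)
        assert len(cls["TP"]) + len(cls["FP"]) == len(called)
        assert len(cls["TP"]) + len(cls["FN"]) == len(truth)


class TestRates:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected",
        [
            ((7), 3, 3, (0.7, 0.3, 0.3)),
            (10, 0, 0, (1.0, 0.0, 0.0)),
            (0, 5, 10, (0.0, 1.0, 1.0)),
        ],
    )
    def test_examples(self, tp, fp, fn, expected):
        assert compute_rates(tp, fp, fn) == pytest.approx(expected)

    def test_empty_called_set_reported_missing_not_zero(self):
        acc, fpr, fnr = compute_rates(0, 0, 5)
        assert np.isnan(acc) and np.isnan(fpr) and fnr == 1.0
        acc, fpr, fnr = compute_rates(0, 0, 0)
        assert np.isnan(acc) and np.isnan(fpr) and np.isnan(fnr)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 1000), st.integers(0, 1000), st.integers(0, 1000))
    def test_accuracy_plus_fp_rate_is_one(self, tp, fp, fn):
        acc, fpr, fnr = compute_rates(tp, fp, fn)
        if tp + fp > 0:
            assert acc + fpr == pytest.approx(1.0)
        for r in (acc, fpr, fnr):
            assert np.isnan(r) or 0 <= r <= 1


class TestTtest:
    def test_pooled_t_frozen_example(self):
        df = pd.DataFrame(
            {
                "strategy": ["a"] * 3 + ["b"] * 3,
                "stratum": "MCR",
                "accuracy": [0.5, 0.6, 0.7, 0.9, 1.0, 1.1],
            }
        )
        out = compare_strategies_ttest(df, "accuracy")
        assert out["t"].loc["a", "b"] == pytest.approx(-4.899, abs=1e-3)
        assert out["p"].loc["a", "b"] == pytest.approx(0.00806, abs=1e-4)

    def test_identical_groups_p_one(self):
        df = pd.DataFrame(
            {
                "strategy": ["a"] * 3 + ["b"] * 3,
                "stratum": "MCR",
                "accuracy": [0.5, 0.5, 0.5] * 2,
            }
        )
        out = compare_strategies_ttest(df, "accuracy")
        assert out["p"].loc["a", "b"] == 1.0

    def test_eight_strategies_give_28_pairs(self, rng):
        rows = []
        for s in range(8):
            for r in range(3):
                rows.append(
                    {"strategy": f"s{s}", "stratum": "MCR",
                     "accuracy": float(rng.random())}
                )
        out = compare_strategies_ttest(pd.DataFrame(rows), "accuracy")
        p = out["p"].to_numpy()
        n_pairs = (p.shape[0] * (p.shape[0] - 1)) // 2
        assert n_pairs == 28
        assert np.allclose(p, p.T)


class TestMatchedRegions:
    def test_length_multiset_preserved(self, small_genome, rng):
        template = [
            Interval("c1", 100, 600),
            Interval("c1", 1000, 1100),
            Interval("c2", 0, 2000),
        ]
        out = sample_matched_regions(template, small_genome, seed=1)
        assert sorted(len(i) for i in out) == sorted(len(i) for i in template)
        # non-overlapping
        by_c = {}
        for iv in out:
            by_c.setdefault(iv.chrom, []).append(iv)
        for ivs in by_c.values():
            ivs.sort(key=lambda i: i.start)
            for a, b in zip(ivs, ivs[1:]):
                assert a.end <= b.start

    def test_full_chromosome_template_forced_to_origin(self):
        g = Genome([("c", "ACGT" * 1000)])
        out = sample_matched_regions([Interval("c", 0, 4000)], g, seed=2)
        assert out == [Interval("c", 0, 4000)]

    def test_start_positions_uniform_by_ks(self):
        g = Genome([("c", "A" * 100_000)])
        rng = np.random.default_rng(3)
        starts = [
            sample_matched_regions([Interval("c", 0, 1000)], g, rng)[0].start
            for _ in range(10_000)
        ]
        d = stats.kstest(np.array(starts) / 99_000, "uniform")
        assert d.pvalue > 0.01

    def test_oversized_template_rejected(self):
        with pytest.raises(RuntimeError, match="host"):
            sample_matched_regions(
                [Interval("c1", 0, 29_000)], Genome([("x", "A" * 1000)]), seed=1
            )


class TestEnrichment:
    def test_hand_computed_2x2(self):
        chi2, p = chi_squared_2x2(90, 10, 50, 50)
        assert chi2 == pytest.approx(38.0952, abs=1e-4)
        # cross-check against scipy's uncorrected contingency test
        s = stats.chi2_contingency([[90, 10], [50, 50]], correction=False)
        assert chi2 == pytest.approx(s.statistic)
        assert p == pytest.approx(s.pvalue)

    def test_degenerate_margin(self):
        assert chi_squared_2x2(0, 0, 0, 0) == (0.0, 1.0)

    def test_saturated_features_give_p_one(self):
        g = Genome([("c", "A" * 50_000)])
        query = [Interval("c", i * 1000, i * 1000 + 200) for i in range(10)]
        features = [Interval("c", 0, 50_000)]
        res = enrichment_test(query, features, g, n_sims=200, seed=4)
        assert res.observed == 10
        assert (res.shuffled == 10).all()
        assert res.empirical_p == 1.0
        assert res.direction == "none"

    def test_overrepresentation_detected(self):
        g = generate_background({"c1": 200_000}, seed=45)
        # features placed exactly on the query: maximal overlap
        query = [Interval("c1", 10_000 + i * 5000, 10_200 + i * 5000) for i in range(20)]
        res = enrichment_test(query, query, g, n_sims=200, seed=5)
        assert res.observed == 20
        assert res.direction == "over"
        assert res.empirical_p < 0.05

    def test_few_sims_warn(self):
        g = Genome([("c", "A" * 10_000)])
        with pytest.warns(UserWarning, match="unstable"):
            enrichment_test(
                [Interval("c", 0, 100)], [Interval("c", 500, 600)], g, n_sims=10, seed=6
            )

    def test_shuffle_vector_length_matches_n_sims(self):
        g = Genome([("c", "A" * 20_000)])
        res = enrichment_test(
            [Interval("c", 0, 100)], [Interval("c", 500, 600)], g, n_sims=150, seed=7
        )
        assert res.shuffled.shape == (150,)
        assert res.p_per_sim.shape == (150,)


class TestEvaluateCalls:
    def test_strata_assignment_and_other(self, small_genome):
        strata = {
            "MCR": [Interval("c1", 0, 1000)],
            "flank": [Interval("c1", 1000, 2000)],
        }
        seq = small_genome.seq("c1")

        def v(pos, alt_shift=1):
            ref = seq[pos]
            alt = "ACGT"[("ACGT".index(ref) + alt_shift) % 4]
            return VariantRecord("c1", pos, ref, alt)

        truth = [v(100), v(1500)]
        called = [v(100), v(5000)]  # one TP, one FP outside both strata
        df = evaluate_calls(truth, called, strata, strategy="s", replicate=0)
        row = df.set_index("stratum")
        assert row.loc["MCR", "TP"] == 1 and row.loc["MCR", "FP"] == 0
        assert row.loc["flank", "FN"] == 1
        assert row.loc["other", "FP"] == 1
        assert row.loc["MCR", "accuracy"] == 1.0
        # accuracy + fp_rate = 1 on all rows with calls
        sub = df.dropna(subset=["accuracy"])
        assert np.allclose(sub["accuracy"] + sub["fp_rate"], 1.0)
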