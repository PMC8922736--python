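import itertools

import numpy as np
import pytest

from degbench.core_data import ConditionLabels, CountMatrix
from degbench.de_methods import DEResult, benjamini_hochberg, discoveries, run_wilcoxon_pipeline
from degbench.evaluation import (
    compare_poorness_groups,
    empirical_power,
    evaluate_methods,
    fdp,
    foldchange_frequency_profile,
    nb_gof_poorness,
    permutation_summary,
    power_at_actual_fdr,
)
from tests.oracles import nb_gof_pearson_naive


def result_from_q(universe, qvals, method="m"):
    q = np.asarray(qvals, dtype=float)
    return DEResult(list(universe), np.zeros(q.size), np.zeros(q.size),
                    q.copy(), q.copy(), method)


class TestFdpAndPower:
    def test_half_false(self):
        assert fdp({"g1", "g2", "g3", "g4"}, {"g1", "g2"}) == 0.5

    def test_subset_of_truth_is_zero(self):
        assert fdp({"g1"}, {"g1", "g2"}) == 0.0

    def test_empty_discoveries_zero_by_convention(self):
        assert fdp(set(), {"g1"}) == 0.0

    def test_power_examples(self):
        assert empirical_power({"g1", "g2", "g3", "g4"}, {"g1", "g2"}) == 1.0
        assert empirical_power({"g3"}, {"g1", "g2"}) == 0.0
        assert empirical_power({"g1", "g2", "g3"}, {"g1", "g2", "g3"}) == 1.0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            empirical_power({"g1"}, set())


class TestEvaluateMethods:
    def test_single_replicate_composition(self):
        res = result_from_q(["g1", "g2", "g3", "g4", "g5"],
                            [0.001, 0.001, 0.001, 0.001, 0.9])
        summary = evaluate_methods({"m": [res]}, [{"g1", "g2"}], thresholds=[0.05])
        assert summary.actual_fdr("m")[0] == pytest.approx(0.5)
        assert summary.power("m")[0] == pytest.approx(1.0)

    def test_mean_over_replicates(self):
        r1 = result_from_q(["g1", "g2"], [0.001, 0.001])  # disc both, fdp 0.5
        r2 = result_from_q(["g1", "g2"], [0.001, 0.9])    # disc g1 only, fdp 0.0
        summary = evaluate_methods({"m": [r1, r2]}, [{"g1"}, {"g1"}], [0.05])
        assert summary.actual_fdr("m")[0] == pytest.approx(0.25)
        assert summary.R == 2

    def test_means_equal_per_replicate_means(self):
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(30)]
        results = []
        truths = []
        for _ in range(4):
            p = rng.uniform(size=30) ** 2
            results.append(DEResult(universe, np.zeros(30), np.zeros(30),
                                    p, benjamini_hochberg(p), "m"))
            truths.append(set(rng.choice(universe, size=8, replace=False)))
        summary = evaluate_methods({"m": results}, truths, [0.05, 0.2])
        for i, t in enumerate(summary.thresholds):
            hand_fdp = np.mean([
                fdp(discoveries(r, t), tr) for r, tr in zip(results, truths)
            ])
            assert summary.actual_fdr("m")[i] == pytest.approx(hand_fdp)

    def test_discoveries_nondecreasing_in_threshold(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=50) ** 3
        res = DEResult([f"g{i}" for i in range(50)], np.zeros(50), np.zeros(50),
                       p, benjamini_hochberg(p), "m")
        sizes = [len(discoveries(res, t)) for t in (0.001, 0.01, 0.05, 0.2, 0.9)]
        assert sizes == sorted(sizes)

    def test_replicate_count_mismatch_rejected(self):
        res = result_from_q(["g1", "g2"], [0.5, 0.5])
        with pytest.raises(ValueError, match="truth sets"):
            evaluate_methods({"m": [res]}, [{"g1"}, {"g2"}], [0.05])


class TestPowerAtActualFdr:
    def make_summary(self, pairs_by_method):
        methods = list(pairs_by_method)
        thresholds = np.arange(len(next(iter(pairs_by_method.values()))))
        fdps = {
            m: np.array([[f] for f, _ in pairs])
            for m, pairs in pairs_by_method.items()
        }
        powers = {
            m: np.array([[p] for _, p in pairs])
            for m, pairs in pairs_by_method.items()
        }
        from degbench.evaluation import EvaluationSummary

        return EvaluationSummary(methods, thresholds.astype(float), 1, fdps, powers)

    def test_hand_interpolation(self):
        summary = self.make_summary({"m": [(0.01, 0.2), (0.05, 0.6)]})
        out = power_at_actual_fdr(summary, [0.03])
        assert out["power"].iloc[0] == pytest.approx(0.4)

    def test_identical_methods_identical_curves(self):
        pairs = [(0.01, 0.2), (0.02, 0.5), (0.05, 0.9)]
        summary = self.make_summary({"a": pairs, "b": pairs})
        out = power_at_actual_fdr(summary, [0.015, 0.03])
        a = out[out.method == "a"]["power"].to_numpy()
        b = out[out.method == "b"]["power"].to_numpy()
        np.testing.assert_allclose(a, b)

    def test_query_outside_range_missing(self):
        summary = self.make_summary({"m": [(0.01, 0.2), (0.05, 0.6)]})
        out = power_at_actual_fdr(summary, [0.001, 0.5])
        assert out["power"].isna().all()

    def test_isotonic_hull_enforces_monotonicity(self):
        # a dip in power is lifted by the running maximum
        summary = self.make_summary({"m": [(0.01, 0.5), (0.02, 0.3), (0.05, 0.9)]})
        out = power_at_actual_fdr(summary, [0.02])
        assert out["power"].iloc[0] == pytest.approx(0.5)


class TestPermutationSummary:
    def test_exceed_fraction_direct_count(self):
        universe = [f"g{i}" for i in range(12)]
        original = result_from_q(universe, [0.001] * 4 + [0.9] * 8)
        counts = (0, 5, 5, 9)
        permuted = [
            result_from_q(universe, [0.001] * c + [0.9] * (12 - c))
            for c in counts
        ]
        s = permutation_summary(original, permuted, 0.05)
        assert s.original_count == 4
        assert list(s.permutation_counts) == [0, 5, 5, 9]
        assert s.exceed_fraction == pytest.approx(0.75)

    def test_gene_frequency(self):
        universe = ["a", "b"]
        original = result_from_q(universe, [0.9, 0.9])
        permuted = [
            result_from_q(universe, [0.001, 0.9]),
            result_from_q(universe, [0.001, 0.9]),
            result_from_q(universe, [0.9, 0.9]),
            result_from_q(universe, [0.9, 0.9]),
        ]
        s = permutation_summary(original, permuted, 0.05)
        assert dict(zip(s.gene_ids, s.identification_frequency)) == {"a": 0.5, "b": 0.0}

    def test_no_discoveries_anywhere(self):
        universe = ["a", "b"]
        res = result_from_q(universe, [0.9, 0.9])
        s = permutation_summary(res, [res, res], 0.05)
        assert s.exceed_fraction == 0.0
        assert np.all(s.identification_frequency == 0.0)

    def test_matches_brute_force_enumeration_on_toy(self):
        """All distinct label assignments of a 5-sample design, checked
        against direct recomputation from the discovery sets."""
        rng = np.random.default_rng(1234)
        counts = rng.negative_binomial(2, 0.002, size=(30, 5)) + 5
        m = CountMatrix([f"g{i}" for i in range(30)],
                        [f"s{j}" for j in range(5)], counts)
        assignments = [
            c for c in itertools.permutations(["A", "A", "A", "B", "B"])
        ]
        distinct = sorted(set(assignments))
        labels0 = ConditionLabels(m.sample_ids, ["A", "A", "A", "B", "B"])
        original = run_wilcoxon_pipeline(m, labels0)
        permuted = [
            run_wilcoxon_pipeline(m, ConditionLabels(m.sample_ids, list(a)))
            for a in distinct
        ]
        s = permutation_summary(original, permuted, 0.5)
        expected_counts = [len(discoveries(r, 0.5)) for r in permuted]
        assert list(s.permutation_counts) == expected_counts
        for i, g in enumerate(s.gene_ids):
            freq = np.mean([g in discoveries(r, 0.5) for r in permuted])
            assert s.identification_frequency[i] == pytest.approx(freq)
        assert s.exceed_fraction == pytest.approx(
            np.mean([c > s.original_count for c in expected_counts])
        )


class TestFoldchangeFrequencyProfile:
    def make_summary(self, universe, orig, freqs):
        from degbench.evaluation import PermutationSummary

        return PermutationSummary(
            list(universe), set(orig), len(orig),
            np.array([0]), np.asarray(freqs, dtype=float), 0.05,
        )

    def test_rank_by_abs_log2fc(self):
        s = self.make_summary(["a", "b"], ["a", "b"], [0.3, 0.7])
        out = foldchange_frequency_profile(s, {"a": 0.5, "b": -2.0})
        assert list(out["gene_id"]) == ["b", "a"]
        assert list(out["rank"]) == [1, 2]
        np.testing.assert_allclose(out["frequency"], [0.7, 0.3])

    def test_empty_original_set(self):
        s = self.make_summary(["a"], [], [0.2])
        assert foldchange_frequency_profile(s, {"a": 1.0}).empty


class TestNBGofPoorness:
    def test_constant_vector_degenerate(self):
        row = nb_gof_poorness([7.0] * 20, 0.2)
        assert row.degenerate and np.isnan(row.poorness)

    def test_too_few_observations_degenerate(self):
        assert nb_gof_poorness([1, 2, 3], 0.2).degenerate

    def test_matches_naive_table_oracle(self):
        """The closed-form X^2 shortcut equals the literal frequency-table
        computation on random inputs."""
        rng = np.random.default_rng(31)
        for _ in range(30):
            phi = float(rng.uniform(0.05, 0.5))
            mean = float(rng.uniform(2, 40))
            size = 1 / phi
            vals = rng.negative_binomial(size, size / (size + mean), 60)
            if np.unique(vals).size == 1:
                continue
            row = nb_gof_poorness(vals, phi)
            p_naive, df = nb_gof_pearson_naive(vals, phi)
            assert row.p_value == pytest.approx(p_naive, rel=1e-9, abs=1e-12)

    def test_median_poorness_under_true_law(self):
        """Data drawn from the fitted law itself: the typical p-value sits
        near the center of (0,1), i.e. median poorness near -log10(0.5)."""
        medians = []
        for s in range(50):
            rng = np.random.default_rng(9000 + s)
            mean, phi = 5.0, 0.1
            size = 1 / phi
            vals = rng.negative_binomial(size, size / (size + mean), 500)
            row = nb_gof_poorness(vals, phi)
            medians.append(row.poorness)
        assert 0.15 <= np.median(medians) <= 0.55

    def test_single_extreme_outlier_detected(self):
        rng = np.random.default_rng(7)
        size = 1 / 0.2
        vals = rng.negative_binomial(size, size / (size + 25.0), 500).astype(float)
        clean = nb_gof_poorness(vals, 0.2).poorness
        vals[0] = np.rint(50 * vals.mean())
        contaminated = nb_gof_poorness(vals, 0.2).poorness
        assert contaminated > 2.0
        assert contaminated > clean


class TestComparePoornessGroups:
    def test_identical_groups_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        assert compare_poorness_groups(a, list(a)) == pytest.approx(1.0)

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(2)
        b = rng.gamma(2, 1, size=50)
        a = b + 10
        assert compare_poorness_groups(a, b) < 0.01

    def test_symmetric(self):
        rng = np.random.default_rng(3)
        a, b = rng.gamma(2, 1, 20), rng.gamma(3, 1, 25)
        assert compare_poorness_groups(a, b) == pytest.approx(
            compare_poorness_groups(b, a)
        )

    def test_nan_dropped_and_empty_rejected(self):
        with pytest.raises(ValueError):
            compare_poorness_groups([np.nan], [1.0, 2.0])
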