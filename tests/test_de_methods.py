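import math

import numpy as np
import pytest
import scipy.stats

from degbench.core_data import ConditionLabels, CountMatrix
from degbench.de_methods import (
    DEResult,
    benjamini_hochberg,
    discoveries,
    load_external_result,
    nb_wald_pipeline,
    read_de_result,
    run_wilcoxon_pipeline,
    wilcoxon_p,
    write_de_result,
)
from degbench.resampling import permute_labels
from degbench.synthetic_data import SimulationConfig, simulate_dataset
from tests.oracles import bh_rejections_stepup, exact_wilcoxon_two_sided


class TestWilcoxonP:
    def test_separated_triples_exact(self):
        # all 3 smallest ranks in one group: 1 split per tail out of C(6,3)=20
        assert wilcoxon_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_multisets_give_one(self):
        assert wilcoxon_p([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=8), rng.normal(size=5)
        assert wilcoxon_p(x, y) == pytest.approx(wilcoxon_p(y, x))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=10), rng.normal(size=7)
        assert wilcoxon_p(x, y) == pytest.approx(wilcoxon_p(np.exp(x), np.exp(y)))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_p([], [1.0])

    def test_exact_mode_matches_full_enumeration(self):
        """200 random tie-free cases over all group sizes <= 6."""
        rng = np.random.default_rng(12345)
        cases = 0
        while cases < 200:
            n1 = int(rng.integers(1, 7))
            n2 = int(rng.integers(1, 7))
            pooled = rng.normal(size=n1 + n2)
            if np.unique(pooled).size < n1 + n2:
                continue
            x, y = pooled[:n1], pooled[n1:]
            assert wilcoxon_p(x, y) == pytest.approx(
                exact_wilcoxon_two_sided(x, y), abs=1e-12
            )
            cases += 1

    def test_large_samples_use_tie_corrected_normal(self):
        # heavy ties; mode must fall back to the corrected approximation
        x = [1.0] * 30 + [2.0] * 10
        y = [1.0] * 10 + [2.0] * 30
        p = wilcoxon_p(x, y)
        assert 0 < p < 1


class TestBenjaminiHochberg:
    def test_hand_evaluated_example(self):
        q = benjamini_hochberg([0.002, 0.01, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.008, 0.02, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_passthrough(self):
        np.testing.assert_allclose(benjamini_hochberg([0.2]), [0.2])

    def test_missing_pass_through(self):
        q = benjamini_hochberg([0.01, np.nan, 0.5])
        assert np.isnan(q[1])
        assert not np.isnan(q[0]) and not np.isnan(q[2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    def test_equals_stepup_rejection_rule(self):
        """q_value < q iff rejected by the naive step-up rule (1000 vectors)."""
        rng = np.random.default_rng(777)
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3)
            q_level = float(rng.uniform(0.01, 0.3))
            qvals = benjamini_hochberg(p)
            rejected = set(np.flatnonzero(qvals <= q_level).tolist())
            expected = bh_rejections_stepup(p, q_level)
            assert rejected == expected

    def test_monotone_in_pvalues(self):
        """Lowering any p-value never removes a discovery at fixed threshold."""
        rng = np.random.default_rng(42)
        p = rng.uniform(size=30)
        base = set(np.flatnonzero(benjamini_hochberg(p) < 0.1).tolist())
        for _ in range(20):
            i = int(rng.integers(30))
            p2 = p.copy()
            p2[i] *= rng.uniform()
            after = set(np.flatnonzero(benjamini_hochberg(p2) < 0.1).tolist())
            assert base - {i} <= after


class TestDiscoveries:
    def make_result(self, q):
        q = np.asarray(q, dtype=float)
        n = q.size
        return DEResult([f"g{i}" for i in range(n)], np.zeros(n), np.zeros(n),
                        q.copy(), q, "m")

    def test_strict_inequality(self):
        res = self.make_result([0.04, 0.05, 0.9])
        assert discoveries(res, 0.05) == {"g0"}

    def test_missing_q_gives_empty(self):
        res = DEResult(["g0"], [np.nan], [np.nan], [np.nan], [np.nan], "m")
        assert discoveries(res, 0.05) == set()

    def test_threshold_one_returns_all_tested(self):
        res = self.make_result([0.2, 0.99, 0.5])
        assert discoveries(res, 1.0) == {"g0", "g1", "g2"}


class TestWilcoxonPipeline:
    def test_type_one_error_on_permuted_null(self, small_null_parent):
        """Exchangeable groups: fraction of p < 0.05 in [0.01, 0.06].

        Ties can only make the rank-sum test conservative, never
        anticonservative, hence the asymmetric band.
        """
        sim = small_null_parent
        perms = permute_labels(sim.labels, 20, seed=5)
        fractions = []
        for plabels in perms:
            res = run_wilcoxon_pipeline(sim.matrix, plabels)
            p = res.p_value[~np.isnan(res.p_value)]
            fractions.append(float((p < 0.05).mean()))
        assert 0.01 <= np.mean(fractions) <= 0.06

    def test_minimal_p_at_n7_is_exact_floor(self):
        """With 7 vs 7 tie-free values the smallest achievable p is 2/C(14,7)."""
        x = list(range(1, 8))
        y = list(range(101, 108))
        assert wilcoxon_p(x, y) == pytest.approx(2 / math.comb(14, 7))
        cfg = SimulationConfig(G=300, n1=7, n2=7, pi=0.1, seed=31,
                               log2fc_min=2.0, log2fc_max=4.0)
        sim = simulate_dataset(cfg)
        res = run_wilcoxon_pipeline(sim.matrix, sim.labels)
        p = res.p_value[~np.isnan(res.p_value)]
        assert p.min() >= 2 / math.comb(14, 7) - 1e-12
        assert np.any(np.isclose(p, 2 / math.comb(14, 7)))

    def test_all_genes_filtered_gives_all_missing(self):
        counts = np.ones((3, 4), dtype=int)  # every total is 4 < 15
        m = CountMatrix(["g1", "g2", "g3"], ["s1", "s2", "s3", "s4"], counts)
        lab = ConditionLabels(m.sample_ids, ["A", "A", "B", "B"])
        res = run_wilcoxon_pipeline(m, lab)
        assert np.all(np.isnan(res.p_value))
        assert discoveries(res, 0.05) == set()

    def test_statistic_is_rank_sum_of_second_group(self, small_null_parent):
        sim = small_null_parent
        res = run_wilcoxon_pipeline(sim.matrix, sim.labels)
        i = int(np.flatnonzero(~np.isnan(res.p_value))[0])
        n = sim.labels.n_samples
        n2 = sim.labels.group_sizes()[1]
        # a rank sum of n2 values among n pooled ranks lies in a known range
        assert n2 * (n2 + 1) / 2 <= res.statistic[i] <= n2 * (2 * n - n2 + 1) / 2


class TestNBWaldPipeline:
    def test_null_pvalues_near_uniform_at_large_n(self):
        """Same NB law in both groups: p approximately U(0,1), KS < 0.05."""
        cfg = SimulationConfig(G=2000, n1=100, n2=100, pi=0.0, epsilon=0.0,
                               seed=2024)
        sim = simulate_dataset(cfg)
        res = nb_wald_pipeline(sim.matrix, sim.labels)
        p = res.p_value[~np.isnan(res.p_value)]
        assert p.size > 1500
        ks = scipy.stats.kstest(p, "uniform").statistic
        assert ks < 0.05

    def test_log2fc_zero_for_mirrored_groups(self):
        rng = np.random.default_rng(2)
        block = rng.negative_binomial(5, 0.005, size=(40, 3))
        counts = np.concatenate([block, block], axis=1)  # identical columns
        m = CountMatrix([f"g{i}" for i in range(40)],
                        [f"s{j}" for j in range(6)], counts)
        lab = ConditionLabels(m.sample_ids, ["A"] * 3 + ["B"] * 3)
        res = nb_wald_pipeline(m, lab)
        tested = ~np.isnan(res.p_value)
        np.testing.assert_allclose(res.log2fc[tested], 0.0, atol=1e-6)

    def test_poisson_limit_matches_likelihood_ratio_oracle(self):
        """On Poisson data the NB Wald p tracks an independent Poisson LR test."""
        rng = np.random.default_rng(8)
        G, n = 20, 100
        base = rng.uniform(50, 500, G)
        Y = rng.poisson(base[:, None] * np.ones(2 * n))
        ids = [f"s{j}" for j in range(2 * n)]
        m = CountMatrix([f"g{i}" for i in range(G)], ids, Y)
        lab = ConditionLabels(ids, ["A"] * n + ["B"] * n)
        res = nb_wald_pipeline(m, lab, min_total_count=0, use_effective_sizes=False)
        lib = Y.sum(axis=0).astype(float)

        def pois_lr_p(y, o):  # offsets: per-sample library sizes
            y1, y2, o1, o2 = y[:n], y[n:], o[:n], o[n:]
            m1, m2 = y1.sum() / o1.sum(), y2.sum() / o2.sum()
            m0 = y.sum() / o.sum()
            ll = lambda yy, mu: np.sum(scipy.stats.poisson.logpmf(yy, mu))
            lr = 2 * (ll(y1, m1 * o1) + ll(y2, m2 * o2)
                      - ll(y1, m0 * o1) - ll(y2, m0 * o2))
            return scipy.stats.chi2.sf(lr, 1)

        for i in range(G):
            p_oracle = pois_lr_p(Y[i].astype(float), lib)
            assert res.p_value[i] == pytest.approx(p_oracle, rel=0.10)


class TestExternalResults:
    def test_load_recomputes_bh(self, tmp_path):
        path = tmp_path / "ext.tsv"
        path.write_text(
            "gene_id\tp_value\tlog2fc\nga\t0.002\t1.0\ngb\t0.01\t-2.0\ngc\t0.03\t0.5\n"
        )
        res = load_external_result(path)
        np.testing.assert_allclose(res.q_value, [0.006, 0.015, 0.03])

    def test_q_only_table_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene_id\tq_value\nga\t0.01\n")
        with pytest.raises(Exception, match="p_value"):
            load_external_result(path)

    def test_round_trip_preserves_discoveries(self, tmp_path):
        rng = np.random.default_rng(4)
        n = 25
        p = rng.uniform(size=n)
        res = DEResult([f"g{i}" for i in range(n)], rng.normal(size=n),
                       rng.normal(size=n), p, benjamini_hochberg(p), "m")
        path = tmp_path / "res.tsv"
        write_de_result(res, path, fdr_threshold=0.1)
        back = read_de_result(path, "m")
        for t in (0.01, 0.05, 0.1, 0.5, 1.0):
            assert discoveries(back, t) == discoveries(res, t)
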