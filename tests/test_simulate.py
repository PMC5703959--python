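import numpy as np
import pandas as pd
import pytest
from scipy import stats

from condfdr.simulate import (
    SimConfig,
    evaluate_detection,
    negative_control_config,
    simulate_reference_panel,
    simulate_two_trait_stats,
)


class TestSummaryStatsGenerator:
    def test_all_null_pvalues_uniform(self):
        """With pi_null = 1 both traits' p-values follow Uniform(0,1)."""
        cfg = SimConfig(seed=5, m_snps=10_000, pi_null=1.0, pi_a=0.0,
                        pi_b=0.0, pi_ab=0.0)
        a, b, _ = simulate_two_trait_stats(cfg)
        for df in (a, b):
            ks = stats.kstest(df["pvalue"], "uniform").statistic
            assert ks < 0.02

    def test_zero_effect_trait_indistinguishable_from_null(self):
        cfg = SimConfig(seed=6, m_snps=10_000, mu_a=0.0)
        a, _, _ = simulate_two_trait_stats(cfg)
        assert stats.kstest(a["pvalue"], "uniform").statistic < 0.02

    def test_same_seed_bit_identical_different_seed_differs(self):
        cfg = SimConfig(seed=42, m_snps=500)
        a1, b1, t1 = simulate_two_trait_stats(cfg)
        a2, b2, t2 = simulate_two_trait_stats(cfg)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)
        pd.testing.assert_frame_equal(t1, t2)
        _, _, t3 = simulate_two_trait_stats(SimConfig(seed=43, m_snps=500))
        assert not np.array_equal(t1["z_a"], t3["z_a"])

    def test_mixture_proportions_multinomial(self):
        """Component counts fit Multinomial(m, pi): chi-square p > 0.001."""
        cfg = SimConfig(seed=9, m_snps=10_000)
        _, _, truth = simulate_two_trait_stats(cfg)
        counts = truth["component"].value_counts()
        observed = [counts.get(c, 0) for c in ("null", "a_only", "b_only", "pleiotropic")]
        expected = np.array([0.90, 0.04, 0.04, 0.02]) * cfg.m_snps
        p = stats.chisquare(observed, expected).pvalue
        assert p > 0.001

    def test_pvalues_strictly_positive_and_at_most_one(self):
        cfg = SimConfig(seed=10, m_snps=5_000, mu_a=8.0, mu_b=8.0)
        a, b, _ = simulate_two_trait_stats(cfg)
        for df in (a, b):
            p = df["pvalue"].to_numpy()
            assert (p > 0).all() and (p <= 1).all()

    def test_layout_covers_22_chromosomes_sorted(self):
        a, _, _ = simulate_two_trait_stats(SimConfig(seed=1, m_snps=2200))
        assert set(a["chrom"]) == {str(c) for c in range(1, 23)}
        for _, sub in a.groupby("chrom"):
            assert sub["pos"].is_monotonic_increasing

    def test_invalid_proportions_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(seed=1, pi_null=0.5, pi_a=0.1, pi_b=0.1, pi_ab=0.1)

    def test_negative_control_keeps_marginal_causal_fractions(self):
        cfg = negative_control_config(SimConfig(seed=12, m_snps=20_000))
        _, _, truth = simulate_two_trait_stats(cfg)
        frac_a = truth["component"].isin(["a_only", "pleiotropic"]).mean()
        frac_b = truth["component"].isin(["b_only", "pleiotropic"]).mean()
        assert abs(frac_a - 0.06) < 0.01
        assert abs(frac_b - 0.06) < 0.01
        # designed overlap removed: only chance-level joint causality remains
        frac_ab = (truth["component"] == "pleiotropic").mean()
        assert frac_ab < 0.01


class TestReferencePanelGenerator:
    @staticmethod
    def _pair_r2(dosages, i, j):
        return np.corrcoef(dosages[i], dosages[j])[0, 1] ** 2

    def test_rho_zero_gives_independent_snps(self):
        cfg = SimConfig(seed=21, m_snps=200, n_samples=500, rho=0.0)
        panel = simulate_reference_panel(cfg)
        r2s = [self._pair_r2(panel.dosages, i, j)
               for b in range(0, 200, 10)
               for i in range(b, b + 10) for j in range(i + 1, b + 10)]
        assert np.mean(r2s) <= 0.05

    def test_high_rho_blocks_are_strongly_linked(self):
        cfg = SimConfig(seed=22, m_snps=200, n_samples=500, rho=0.95)
        panel = simulate_reference_panel(cfg)
        adjacent = [self._pair_r2(panel.dosages, i, i + 1)
                    for i in range(199) if (i % 10) != 9]
        assert np.median(adjacent) > 0.2

    def test_cross_block_pairs_independent(self):
        cfg = SimConfig(seed=23, m_snps=200, n_samples=500, rho=0.95)
        panel = simulate_reference_panel(cfg)
        rng = np.random.default_rng(0)
        r2s = []
        for _ in range(300):
            i, j = rng.integers(0, 200, 2)
            if i // 10 != j // 10:
                r2s.append(self._pair_r2(panel.dosages, i, j))
        assert np.mean(r2s) <= 0.05

    def test_recovered_maf_within_range(self):
        cfg = SimConfig(seed=24, m_snps=500, n_samples=500,
                        maf_range=(0.1, 0.4))
        panel = simulate_reference_panel(cfg)
        # binomial sampling error on 1000 haplotypes: ~3.5 sd slack
        tol = 3.5 * np.sqrt(0.4 * 0.6 / (2 * cfg.n_samples))
        assert (panel.maf > 0.1 - tol).all()
        assert (panel.maf < 0.4 + tol).all()

    def test_panel_matches_stats_layout(self):
        cfg = SimConfig(seed=25, m_snps=300)
        a, _, _ = simulate_two_trait_stats(cfg)
        panel = simulate_reference_panel(cfg)
        merged_ids = a.sort_values(["chrom", "pos"])  # same id universe
        assert set(panel.snp_id) == set(merged_ids["snp_id"])


class TestEvaluateDetection:
    @pytest.fixture
    def truth(self):
        comp = ["pleiotropic"] * 10 + ["null"] * 20 + ["a_only"] * 5
        return pd.DataFrame(
            {"snp_id": [f"rs{i}" for i in range(35)], "component": comp,
             "z_a": 0.0, "z_b": 0.0}
        )

    def test_empty_call_set_convention(self, truth):
        assert evaluate_detection(truth, set(), "conjunction") == (0.0, 0.0)

    def test_perfect_recovery(self, truth):
        called = {f"rs{i}" for i in range(10)}
        assert evaluate_detection(truth, called, "conjunction") == (0.0, 1.0)

    def test_half_false_calls(self, truth):
        called = {f"rs{i}" for i in range(10)} | {f"rs{i}" for i in range(10, 20)}
        fdr, power = evaluate_detection(truth, called, "conjunction")
        assert fdr == 0.5 and power == 1.0

    def test_direction_specific_truth(self, truth):
        called = {"rs30", "rs31"}  # a_only SNPs
        fdr_a, _ = evaluate_detection(truth, called, "A|B")
        fdr_c, _ = evaluate_detection(truth, called, "conjunction")
        assert fdr_a == 0.0 and fdr_c == 1.0

    def test_unknown_id_rejected(self, truth):
        with pytest.raises(ValueError):
            evaluate_detection(truth, {"rs999"}, "conjunction")
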