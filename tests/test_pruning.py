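import numpy as np
import pandas as pd
import pytest

from condfdr.io import merge_common_snps
from condfdr.pruning import (
    ConstantGenotypeError,
    PruneParams,
    compute_r2,
    ld_prune,
    verify_pruned,
)
from condfdr.simulate import SimConfig, simulate_reference_panel, simulate_two_trait_stats

from conftest import make_merged, random_panel


# ---------------------------------------------------------------------------
# brute-force oracle: same greedy convention, written naively


def oracle_prune(merged, panel, params):
    """Naive re-implementation: explicit pair loops and removal list."""
    idx = panel.row_index()
    removed = set()
    for chrom, sub in merged.groupby("chrom", sort=False):
        rows = list(sub.itertuples())
        while True:
            changed = False
            alive = [r for r in rows if r.snp_id not in removed]
            start = 0
            while start < len(alive):
                window = [r for r in alive[start:start + params.window]
                          if r.snp_id not in removed]
                for i in range(len(window)):
                    for j in range(i + 1, len(window)):
                        ri, rj = window[i], window[j]
                        if ri.snp_id in removed:
                            break
                        if rj.snp_id in removed:
                            continue
                        if ri.snp_id not in idx or rj.snp_id not in idx:
                            continue
                        try:
                            r2 = compute_r2(panel.dosages[idx[ri.snp_id]],
                                            panel.dosages[idx[rj.snp_id]])
                        except ConstantGenotypeError:
                            continue
                        if r2 <= params.r2_threshold:
                            continue
                        mi = panel.maf[idx[ri.snp_id]]
                        mj = panel.maf[idx[rj.snp_id]]
                        if mi < mj:
                            removed.add(ri.snp_id)
                        elif mj < mi:
                            removed.add(rj.snp_id)
                        else:
                            removed.add(rj.snp_id if rj.pos > ri.pos else ri.snp_id)
                        changed = True
                start += params.step
            if not changed:
                break
    return merged[~merged["snp_id"].isin(removed)].reset_index(drop=True)


# ---------------------------------------------------------------------------


class TestComputeR2:
    def test_identical_vectors(self):
        assert compute_r2([0, 1, 2, 0, 1], [0, 1, 2, 0, 1]) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert compute_r2([0, 1, 2, 0], [2, 1, 0, 2]) == pytest.approx(1.0)

    def test_orthogonal_contrast(self):
        assert compute_r2([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)

    def test_constant_vector_raises(self):
        with pytest.raises(ConstantGenotypeError):
            compute_r2([1, 1, 1, 1], [0, 1, 2, 0])


def _block_fixture(seed, m=60, rho=0.9, n=400):
    cfg = SimConfig(seed=seed, m_snps=m, n_samples=n, rho=rho)
    a, b, _ = simulate_two_trait_stats(cfg)
    merged = merge_common_snps(a, b)
    panel = simulate_reference_panel(cfg)
    return merged, panel


class TestLdPrune:
    def test_smaller_maf_member_removed(self, ):
        # two correlated SNPs with known MAFs: keep the common one
        rng = np.random.default_rng(0)
        g1 = rng.binomial(2, 0.4, 200)
        flip = rng.random(200) < 0.1
        g2 = np.where(flip, rng.binomial(2, 0.1, 200), g1)
        g2 = np.where(g1 > 0, g2, 0)  # depress MAF of SNP 2
        from condfdr.io import ReferencePanel

        panel = ReferencePanel(snp_id=["rs0", "rs1"], chrom=["1", "1"],
                               pos=[1000, 2000], dosages=np.stack([g1, g2]))
        assert panel.maf[1] < panel.maf[0]
        assert compute_r2(g1, g2) > 0.2
        merged = make_merged([0.5, 0.5], [0.5, 0.5])
        pruned = ld_prune(merged, panel, PruneParams())
        assert list(pruned["snp_id"]) == ["rs0"]

    def test_no_high_ld_input_unchanged(self):
        rng = np.random.default_rng(1)
        panel = random_panel(rng, 40, n_samples=400)
        merged = make_merged(rng.uniform(size=40), rng.uniform(size=40))
        # independent Binomial dosages at n=400: all pairwise r2 ~ 1/n << 0.2
        pruned = ld_prune(merged, panel, PruneParams())
        pd.testing.assert_frame_equal(pruned, merged)

    def test_tight_block_keeps_single_highest_maf_snp(self):
        """A rho=0.99 block collapses to its highest-MAF member."""
        # similar MAFs keep the copula's dosage correlation uniformly high
        cfg = SimConfig(seed=33, m_snps=10, n_samples=500, rho=0.99,
                        block_size=10, maf_range=(0.2, 0.5))
        sim_panel = simulate_reference_panel(cfg)
        from condfdr.io import ReferencePanel

        # place the whole block on one chromosome
        panel = ReferencePanel(
            snp_id=sim_panel.snp_id, chrom=np.array(["1"] * 10, dtype=object),
            pos=np.arange(1000, 11000, 1000), dosages=sim_panel.dosages,
        )
        merged = make_merged([0.5] * 10, [0.5] * 10)
        merged["snp_id"] = panel.snp_id
        # precondition: every pair within the block exceeds the threshold
        r2 = np.array([[compute_r2(panel.dosages[i], panel.dosages[j])
                        for j in range(10)] for i in range(10)])
        assert (r2[np.triu_indices(10, 1)] > 0.2).all()
        pruned = ld_prune(merged, panel, PruneParams())
        assert len(pruned) == 1
        assert pruned["snp_id"].iloc[0] == panel.snp_id[np.argmax(panel.maf)]

    @pytest.mark.parametrize("seed,m", [(41, 60), (42, 120), (43, 250)])
    def test_matches_bruteforce_oracle(self, seed, m):
        merged, panel = _block_fixture(seed, m=m)
        params = PruneParams(window=20, step=5, r2_threshold=0.2)
        expected = oracle_prune(merged, panel, params)
        got = ld_prune(merged, panel, params)
        assert list(got["snp_id"]) == list(expected["snp_id"])

    def test_snps_absent_from_panel_retained(self):
        merged, panel = _block_fixture(44, m=30)
        extra = pd.DataFrame(
            {"snp_id": ["rsX"], "chrom": ["1"], "pos": [5], "p1": [0.5], "p2": [0.5]}
        )
        merged2 = pd.concat([extra, merged]).reset_index(drop=True)
        pruned = ld_prune(merged2, panel, PruneParams())
        assert "rsX" in set(pruned["snp_id"])

    def test_output_subset_order_preserved_and_idempotent(self):
        merged, panel = _block_fixture(45, m=100)
        params = PruneParams()
        pruned = ld_prune(merged, panel, params)
        assert set(pruned["snp_id"]) <= set(merged["snp_id"])
        sub = merged[merged["snp_id"].isin(set(pruned["snp_id"]))]
        assert list(sub["snp_id"]) == list(pruned["snp_id"])
        again = ld_prune(pruned, panel, params)
        pd.testing.assert_frame_equal(again, pruned)

    def test_deterministic(self):
        merged, panel = _block_fixture(46, m=80)
        p1 = ld_prune(merged, panel, PruneParams())
        p2 = ld_prune(merged, panel, PruneParams())
        pd.testing.assert_frame_equal(p1, p2)

    def test_removal_log_names_culprit_pairs(self):
        merged, panel = _block_fixture(47, m=50)
        pruned, log_df = ld_prune(merged, panel, PruneParams(), return_log=True)
        assert len(pruned) + len(log_df) == len(merged)
        assert set(log_df["removed"]).isdisjoint(set(pruned["snp_id"]))
        assert (log_df["r2"] > 0.2).all()


class TestVerifyPruned:
    def test_true_on_prune_output(self):
        merged, panel = _block_fixture(51, m=120)
        pruned = ld_prune(merged, panel, PruneParams())
        assert verify_pruned(pruned, panel, PruneParams())

    def test_false_on_unpruned_ld_blocks(self):
        merged, panel = _block_fixture(52, m=60, rho=0.9)
        assert not verify_pruned(merged, panel, PruneParams())

    def test_true_on_single_snp(self):
        merged, panel = _block_fixture(53, m=60)
        assert verify_pruned(merged.iloc[[0]], panel, PruneParams())


def test_prune_params_validation():
    with pytest.raises(ValueError):
        PruneParams(window=1)
    with pytest.raises(ValueError):
        PruneParams(step=0)
    with pytest.raises(ValueError):
        PruneParams(r2_threshold=1.0)
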