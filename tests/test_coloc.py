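import numpy as np
import pandas as pd
import pytest

from picara.blocks import LinkageBlock
from picara.coloc import (
    DistanceEcdf,
    build_ecdf,
    coloc_prob,
    permutation_test,
    rank_weights,
    weighted_posterior,
)
from picara.io import CandidateGene
from tests.conftest import matrix_from_calls


def assoc_frame(rows):
    """rows: (snp_id, chromosome, position, significance, is_significant)"""
    df = pd.DataFrame(
        rows, columns=["snp_id", "chromosome", "position", "significance", "is_significant"]
    )
    df["effect"] = 0.0
    return df


def block_over(chrom, lo, hi, gene_id="g"):
    return LinkageBlock(
        gene_id=gene_id,
        chromosome=chrom,
        upstream_bound=lo,
        downstream_bound=hi,
        source="local",
        anchor_snps=(),
        r2_threshold=1.0,
    )


class TestEcdf:
    def test_distances_from_gene_center(self):
        m = matrix_from_calls(np.zeros((3, 4), np.int8) , positions=[400, 500, 700])
        m.calls[:, 0] = 1  # keep loci polymorphic
        gene = CandidateGene("g", "chr1", 400, 600)  # center 500
        ecdf = build_ecdf(gene, m)
        np.testing.assert_array_equal(ecdf.sorted_distances, [0, 100, 200])
        assert ecdf.n == 3

    def test_single_snp_chromosome(self):
        m = matrix_from_calls([[0, 1, 0, 1]], positions=[1234])
        ecdf = build_ecdf(CandidateGene("g", "chr1", 1000, 1100), m)
        assert ecdf.n == 1

    def test_empty_chromosome_raises(self):
        m = matrix_from_calls([[0, 1, 0, 1]])
        with pytest.raises(KeyError):
            build_ecdf(CandidateGene("g", "chrX", 1, 10), m)


class TestColocProb:
    ecdf = DistanceEcdf("g", np.array([0.0, 100.0, 200.0]), 3)

    def test_zero_distance_gives_probability_one(self):
        assert coloc_prob(self.ecdf, 0) == 1.0

    def test_interior_value_counts_distances_at_least_d(self):
        assert coloc_prob(self.ecdf, 100) == pytest.approx(2 / 3)

    def test_beyond_farthest_snp_gives_zero(self):
        assert coloc_prob(self.ecdf, 200.0001) == 0.0
        assert coloc_prob(self.ecdf, 200) == pytest.approx(1 / 3)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            coloc_prob(self.ecdf, -1)

    def test_non_increasing_in_distance(self):
        d = np.linspace(0, 300, 301)
        p = coloc_prob(self.ecdf, d)
        assert (np.diff(p) <= 0).all()
        assert ((p >= 0) & (p <= 1)).all()


class TestRankWeights:
    def test_reverse_rank_normalisation(self):
        df = assoc_frame(
            [("a", "1", 10, 15, True), ("b", "1", 20, 12, True), ("c", "1", 30, 3, True)]
        )
        w = rank_weights(df).set_index("snp_id")["weight"]
        assert w["a"] == pytest.approx(3 / 6)
        assert w["b"] == pytest.approx(2 / 6)
        assert w["c"] == pytest.approx(1 / 6)

    def test_single_significant_signal_takes_all_weight(self):
        df = assoc_frame([("a", "1", 10, 7, True), ("b", "1", 20, 1, False)])
        w = rank_weights(df).set_index("snp_id")["weight"]
        assert w["a"] == pytest.approx(1.0)
        assert w["b"] == 0.0

    def test_tied_rimps_share_weight(self):
        df = assoc_frame([("a", "1", 10, 5, True), ("b", "1", 20, 5, True)])
        w = rank_weights(df)["weight"]
        assert list(w) == pytest.approx([0.5, 0.5])

    def test_weights_sum_to_one_and_are_order_invariant(self):
        rng = np.random.default_rng(1)
        rows = [
            (f"s{i}", "1", 10 * i, int(r), bool(r >= 2))
            for i, r in enumerate(rng.integers(1, 16, 40))
        ]
        w1 = rank_weights(assoc_frame(rows))
        w2 = rank_weights(assoc_frame(rows[::-1]))
        assert w1["weight"].sum() == pytest.approx(1.0, abs=1e-9)
        merged = w1.set_index("snp_id")["weight"] - w2.set_index("snp_id")["weight"]
        assert np.allclose(merged, 0)

    def test_pvalue_mode_ranks_ascending(self):
        df = assoc_frame(
            [("a", "1", 10, 0.001, True), ("b", "1", 20, 0.04, True)]
        )
        w = rank_weights(df, mode="pvalue").set_index("snp_id")["weight"]
        assert w["a"] > w["b"]

    def test_improving_significance_never_lowers_weight(self):
        base = [("a", "1", 10, 4, True), ("b", "1", 20, 8, True), ("c", "1", 30, 2, True)]
        w_before = rank_weights(assoc_frame(base)).set_index("snp_id")["weight"]["a"]
        boosted = [("a", "1", 10, 9, True)] + base[1:]
        w_after = rank_weights(assoc_frame(boosted)).set_index("snp_id")["weight"]["a"]
        assert w_after >= w_before


class TestWeightedPosterior:
    gene = CandidateGene("g", "chr1", 450, 550)  # center 500

    def _matrix(self, positions):
        rng = np.random.default_rng(0)
        calls = (rng.random((len(positions), 20)) < 0.5).astype(np.int8)
        return matrix_from_calls(calls, positions=positions)

    def test_no_significant_signal_in_block_gives_zero(self):
        m = self._matrix([100, 500, 900])
        ecdf = build_ecdf(self.gene, m)
        signals = rank_weights(assoc_frame([("x", "chr1", 5_000, 9, True)]))
        assert weighted_posterior(self.gene, block_over("chr1", 400, 600), signals, ecdf) == 0.0

    def test_signal_at_gene_center_with_full_weight_gives_one(self):
        m = self._matrix([100, 500, 900])
        ecdf = build_ecdf(self.gene, m)
        signals = rank_weights(assoc_frame([("x", "chr1", 500, 9, True)]))
        post = weighted_posterior(self.gene, block_over("chr1", 400, 600), signals, ecdf)
        assert post == pytest.approx(1.0)

    def test_hand_computed_weighted_sum(self):
        # weights .5/.5 (tied), coloc probs 1.0 and 0.4 → posterior 0.7
        positions = [500, 600, 700, 800, 900]  # distances 0,100,200,300,400
        m = self._matrix(positions)
        ecdf = build_ecdf(self.gene, m)
        signals = rank_weights(
            assoc_frame([("x", "chr1", 500, 6, True), ("y", "chr1", 800, 6, True)])
        )
        assert coloc_prob(ecdf, 0) == 1.0
        assert coloc_prob(ecdf, 300) == pytest.approx(0.4)
        post = weighted_posterior(self.gene, block_over("chr1", 400, 900), signals, ecdf)
        assert post == pytest.approx(0.7)

    def test_out_of_block_association_contributes_nothing(self):
        positions = [500, 600, 700, 800, 900]
        m = self._matrix(positions)
        ecdf = build_ecdf(self.gene, m)
        base = rank_weights(assoc_frame([("x", "chr1", 500, 6, True)]))
        with_far = rank_weights(
            assoc_frame([("x", "chr1", 500, 6, True), ("far", "chr1", 900, 6, True)])
        )
        blk = block_over("chr1", 400, 850)
        p_base = weighted_posterior(self.gene, blk, base, ecdf)
        p_far = weighted_posterior(self.gene, blk, with_far, ecdf)
        # the far signal is outside the block: it contributes 0, though it
        # still takes half the chromosome's weight mass
        assert p_far == pytest.approx(p_base / 2)


class TestPermutationTest:
    gene = CandidateGene("g", "chr1", 4_500, 5_500)

    def _inputs(self, n_snps=200, n_assoc=12, seed=0):
        rng = np.random.default_rng(seed)
        calls = (rng.random((n_snps, 30)) < 0.5).astype(np.int8)
        positions = np.sort(rng.choice(np.arange(1, 100_000), n_snps, replace=False))
        m = matrix_from_calls(calls, positions=positions)
        idx = rng.choice(n_snps, n_assoc, replace=False)
        assoc = assoc_frame(
            [
                (f"q{k}", "chr1", int(positions[i]), int(rng.integers(2, 16)), True)
                for k, i in enumerate(idx)
            ]
        )
        return m, assoc

    def test_zero_posterior_gives_p_one(self):
        m, assoc = self._inputs()
        empty_block = block_over("chr1", -10, -5)  # contains nothing
        res = permutation_test(self.gene, empty_block, assoc, m, n_perm=200, seed=1)
        assert res.posterior == 0.0
        assert res.perm_p == 1.0

    def test_identical_seed_reproduces_bitwise(self):
        m, assoc = self._inputs()
        blk = block_over("chr1", 2_000, 8_000)
        r1 = permutation_test(self.gene, blk, assoc, m, n_perm=300, seed=9, keep_null=True)
        r2 = permutation_test(self.gene, blk, assoc, m, n_perm=300, seed=9, keep_null=True)
        assert r1.posterior == r2.posterior
        assert r1.perm_p == r2.perm_p
        np.testing.assert_array_equal(r1.null_posteriors, r2.null_posteriors)

    def test_perm_p_in_unit_interval_and_never_zero(self):
        m, assoc = self._inputs()
        blk = block_over("chr1", 1, 100_000)  # whole chromosome
        res = permutation_test(self.gene, blk, assoc, m, n_perm=150, seed=2)
        assert 0 < res.perm_p <= 1

    def test_more_associations_than_snps_rejected(self):
        m, _ = self._inputs(n_snps=10, n_assoc=5)
        assoc = assoc_frame(
            [(f"q{k}", "chr1", 100 + k, 3, True) for k in range(11)]
        )
        with pytest.raises(ValueError, match="without replacement"):
            permutation_test(self.gene, block_over("chr1", 1, 1000), assoc, m, n_perm=100, seed=0)

    def test_too_few_permutations_rejected(self):
        m, assoc = self._inputs()
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(self.gene, block_over("chr1", 1, 10), assoc, m, n_perm=10, seed=0)

    def test_null_calibration_on_uniform_signals(self):
        # observed associations drawn from the same uniform law as the
        # permutation null → perm_p approximately Uniform(0, 1)
        n_genes = 200
        reject = 0
        rng = np.random.default_rng(7)
        calls = (rng.random((400, 30)) < 0.5).astype(np.int8)
        positions = np.sort(rng.choice(np.arange(1, 1_000_000), 400, replace=False))
        m = matrix_from_calls(calls, positions=positions)
        for i in range(n_genes):
            center = int(rng.integers(10_000, 990_000))
            gene = CandidateGene(f"g{i}", "chr1", center - 500, center + 500)
            blk = block_over("chr1", center - 40_000, center + 40_000, gene_id=gene.gene_id)
            idx = rng.choice(400, 15, replace=False)
            assoc = assoc_frame(
                [
                    (f"q{k}", "chr1", int(positions[j]), int(rng.integers(2, 16)), True)
                    for k, j in enumerate(idx)
                ]
            )
            res = permutation_test(gene, blk, assoc, m, n_perm=400, seed=i)
            reject += res.perm_p <= 0.05
        rate = reject / n_genes
        mc_se = np.sqrt(0.05 * 0.95 / n_genes)
        assert abs(rate - 0.05) <= 2 * mc_se + 1e-12
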