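import numpy as np
import pandas as pd
import pytest
import scipy.stats

from picara.blocks import LinkageBlock
from picara.enrich import (
    candidate_set_mean_lod,
    enrichment_null,
    enrichment_pvalue_exact,
    enrichment_score,
    run_enrichment,
)
from picara.io import CandidateGene
from tests.conftest import matrix_from_calls


def block_over(lo, hi, gene_id="g", chrom="chr1"):
    return LinkageBlock(
        gene_id=gene_id,
        chromosome=chrom,
        upstream_bound=lo,
        downstream_bound=hi,
        source="local",
        anchor_snps=(),
        r2_threshold=1.0,
    )


def uniform_matrix(n_snps, length, seed=0, chrom="chr1"):
    rng = np.random.default_rng(seed)
    calls = (rng.random((n_snps, 10)) < 0.5).astype(np.int8)
    positions = np.sort(rng.choice(np.arange(1, length), n_snps, replace=False))
    return matrix_from_calls(calls, positions=positions, chromosome=chrom)


class TestEnrichmentScore:
    def test_zero_when_block_rate_equals_chromosome_rate(self):
        assert enrichment_score(100, 2, 1000, 20, continuity=0) == pytest.approx(0.0)

    def test_depletion_is_negative(self):
        assert enrichment_score(100, 0, 10_000, 10) < 0

    def test_hand_computed_lod(self):
        # 6 of 100 block loci associated vs 229 of 1e6 chromosome-wide
        e = enrichment_score(100, 6, 1_000_000, 229, continuity=0)
        assert e == pytest.approx(np.log10((6 / 100) / (229 / 1_000_000)), abs=1e-12)
        assert e == pytest.approx(2.418, abs=5e-4)
        # the g >= 1 branch is continuity-independent
        assert enrichment_score(100, 6, 1_000_000, 229) == pytest.approx(e)

    def test_empty_block_scores_zero(self):
        assert enrichment_score(0, 0, 1000, 10) == 0.0

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValueError, match="impossible"):
            enrichment_score(0, 1, 1000, 10)
        with pytest.raises(ValueError, match="exceed"):
            enrichment_score(5, 6, 1000, 10)

    def test_zero_continuity_gives_minus_inf_at_zero_count(self):
        assert enrichment_score(100, 0, 1000, 10, continuity=0) == float("-inf")

    def test_strictly_increasing_in_g_and_decreasing_in_x(self):
        S, G = 50_000, 40
        for x in (10, 100, 1000):
            scores = [enrichment_score(x, g, S, G) for g in range(0, x // 2)]
            assert all(a < b for a, b in zip(scores, scores[1:]))
        for g in (0, 3):
            scores = [enrichment_score(x, g, S, G) for x in (10, 50, 250, 1000)]
            assert all(a > b for a, b in zip(scores, scores[1:]))


class TestExactPvalue:
    def test_matches_scipy_survival_function(self):
        assert enrichment_pvalue_exact(50, 6, 100_000, 20) == pytest.approx(
            scipy.stats.hypergeom.sf(5, 100_000, 20, 50)
        )

    def test_zero_count_has_p_one(self):
        assert enrichment_pvalue_exact(50, 0, 1000, 10) == 1.0


class TestEnrichmentNull:
    def test_block_covering_all_snps_gives_point_mass(self):
        m = uniform_matrix(80, 10_000)
        gene = CandidateGene("g", "chr1", 100, 200)
        null, _ = enrichment_null(gene, block_over(0, 10_001), m, G_t=7, n_rand=200, seed=0)
        assert len(np.unique(null)) == 1  # every draw lands g = G_t

    def test_null_mean_matches_hypergeometric_expectation(self):
        m = uniform_matrix(500, 1_000_000, seed=4)
        positions = m.positions("chr1")
        blk = block_over(positions[100] - 1, positions[199] + 1)  # x_i = 100
        gene = CandidateGene("g", "chr1", int(positions[150]), int(positions[150]) + 10)
        G_t = 30
        null, _ = enrichment_null(gene, blk, m, G_t=G_t, n_rand=3000, seed=1)
        # back out the null g from the score to compare with Hypergeom mean
        mu = 100 * G_t / 500
        g_vals = np.where(np.isfinite(null), np.round(mu * 10**null), 0.0)
        expected = scipy.stats.hypergeom.mean(500, G_t, 100)
        sd = np.sqrt(scipy.stats.hypergeom.var(500, G_t, 100))
        assert abs(g_vals.mean() - expected) <= 2 * sd / np.sqrt(3000)

    def test_more_associations_than_snps_rejected(self):
        m = uniform_matrix(10, 10_000)
        gene = CandidateGene("g", "chr1", 100, 200)
        with pytest.raises(ValueError, match="exceeds"):
            enrichment_null(gene, block_over(0, 10_001), m, G_t=11, n_rand=100, seed=0)

    def test_same_seed_same_null_vector(self):
        m = uniform_matrix(100, 50_000)
        gene = CandidateGene("g", "chr1", 100, 200)
        blk = block_over(1, 25_000)
        n1, _ = enrichment_null(gene, blk, m, G_t=9, n_rand=300, seed=5)
        n2, _ = enrichment_null(gene, blk, m, G_t=9, n_rand=300, seed=5)
        np.testing.assert_array_equal(n1, n2)


class TestRunEnrichment:
    def _setup(self, pass_coloc: bool):
        from picara.coloc import ColocResult

        m = uniform_matrix(20_000, 20_000_000, seed=2)
        positions = m.positions("chr1")
        blk = block_over(positions[0] - 1, positions[49] + 1)  # x_i = 50
        gene = CandidateGene("g", "chr1", int(positions[10]), int(positions[12]))
        sig_pos = positions[[2, 5, 8, 11, 20, 30]]
        far_pos = positions[np.arange(200, 214)]
        assoc = pd.DataFrame(
            {
                "snp_id": [f"q{i}" for i in range(20)],
                "chromosome": "chr1",
                "position": np.concatenate([sig_pos, far_pos]),
                "significance": 5.0,
                "effect": 0.0,
                "is_significant": True,
            }
        )
        cres = ColocResult(
            gene_id="g",
            posterior=0.5,
            contributing=pd.DataFrame(),
            perm_p=0.01 if pass_coloc else 0.8,
            perm_threshold=0.3,
            n_perm=100,
            seed=0,
        )
        return m, gene, blk, assoc, cres

    def test_g_counts_only_when_coloc_passes(self):
        m, gene, blk, assoc, cres = self._setup(pass_coloc=True)
        out = run_enrichment([gene], {"g": blk}, {"g": cres}, assoc, m, n_rand=500, seed=0)
        row = out.iloc[0]
        assert row["g_i"] == 6 and row["x_i"] == 50
        assert row["significant"] and row["E_i"] >= 2

        m, gene, blk, assoc, cres = self._setup(pass_coloc=False)
        out = run_enrichment([gene], {"g": blk}, {"g": cres}, assoc, m, n_rand=500, seed=0)
        row = out.iloc[0]
        assert row["g_i"] == 0 and not row["significant"]

    def test_exact_mode_agrees_with_sampler_within_mc_error(self):
        m, gene, blk, assoc, cres = self._setup(pass_coloc=True)
        samp = run_enrichment([gene], {"g": blk}, {"g": cres}, assoc, m, n_rand=2000, seed=3)
        exact = run_enrichment([gene], {"g": blk}, {"g": cres}, assoc, m, method="exact")
        p_ex = exact.iloc[0]["empirical_p"]
        mc = 2 * np.sqrt(p_ex * (1 - p_ex) / 2000) + 1 / 2000
        assert abs(samp.iloc[0]["empirical_p"] - p_ex) <= mc + 1e-9

    def test_missing_upstream_result_reported_as_skipped(self):
        m, gene, blk, assoc, cres = self._setup(pass_coloc=True)
        other = CandidateGene("orphan", "chr1", 5, 10)
        out = run_enrichment([gene, other], {"g": blk}, {"g": cres}, assoc, m, n_rand=200, seed=0)
        st = out.set_index("gene_id")["status"]
        assert st["orphan"] == "skipped" and st["g"] == "ok"

    def test_results_sorted_by_score_descending(self, small_fixture):
        from picara.pipeline import PipelineConfig, run_pipeline

        res = run_pipeline(
            small_fixture.matrix,
            small_fixture.associations,
            small_fixture.genes,
            PipelineConfig(n_perm=150, n_rand=150, seed=0),
        )
        e = res.enrichment["E_i"].to_numpy()
        assert (np.diff(e[np.isfinite(e)]) <= 1e-12).all()


class TestMeanLod:
    def _frame(self, scores):
        return pd.DataFrame({"E_i": scores, "status": "ok"})

    def test_mean_of_floored_scores(self):
        assert candidate_set_mean_lod(self._frame([2.0, 0.0])) == 1.0
        assert candidate_set_mean_lod(self._frame([0.0, 0.0])) == 0.0
        assert candidate_set_mean_lod(self._frame([-1.0, 1.0])) == 0.5

    def test_raw_mean_flag(self):
        assert candidate_set_mean_lod(self._frame([-1.0, 1.0]), floor=False) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            candidate_set_mean_lod(pd.DataFrame({"E_i": [], "status": []}))
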