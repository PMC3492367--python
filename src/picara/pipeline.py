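"""End-to-end orchestration: MAF filter → LD → blocks → coloc → enrichment.

All thresholds live in :class:`PipelineConfig`; one root seed drives every
permutation, with per-gene streams derived deterministically from (seed,
gene_id) so results do not depend on gene processing order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from picara.io import CandidateGene, GenotypeMatrix, match_associations
from picara.ld import filter_maf, pairwise_r2
from picara.blocks import (
    BlockSizeEstimate,
    LinkageBlock,
    blocks_table,
    chromosome_block_median,
    gene_linkage_block,
)
from picara.coloc import (
    ColocResult,
    build_ecdf,
    coloc_table,
    permutation_test,
    rank_weights,
)
from picara.enrich import run_enrichment

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of a `picara run`, with the study defaults."""

    maf_threshold: float = 0.05
    r2_threshold: float = 1.0  # perfect LD defines blocks
    max_pair_distance: Optional[int] = None  # bp cap on LD pair enumeration
    min_informative: int = 4
    n_flank: int = 1
    significance_mode: str = "rimp"  # "rimp" | "pvalue"
    significance_cutoff: Optional[float] = None  # None → 2 (rimp) / 0.05 (pvalue)
    n_perm: int = 1000
    n_rand: int = 1000
    lod_cutoff: float = 2.0
    alpha: float = 0.05
    coloc_alpha: float = 0.05
    fallback_scope: str = "chromosome"  # or "genome": whole-genome median
    default_fallback: Optional[float] = None  # used when no r²=1 pair exists
    enrichment_method: str = "randomization"  # or "exact"
    seed: int = 0


@dataclass
class PipelineResult:
    matrix: GenotypeMatrix  # MAF-filtered
    block_medians: dict[str, Optional[BlockSizeEstimate]]
    blocks: dict[str, LinkageBlock]
    coloc: dict[str, ColocResult]
    enrichment: pd.DataFrame
    config: PipelineConfig

    @property
    def blocks_frame(self) -> pd.DataFrame:
        return blocks_table([self.blocks[g] for g in sorted(self.blocks)])

    @property
    def coloc_frame(self) -> pd.DataFrame:
        return coloc_table([self.coloc[g] for g in sorted(self.coloc)])


def run_pipeline(
    matrix: GenotypeMatrix,
    associations: pd.DataFrame,
    genes: Sequence[CandidateGene],
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run every stage on every gene.

    ``associations`` must already carry ``is_significant`` (as produced by
    :func:`picara.io.read_associations`) and must reference genotyped loci.
    """
    filtered = filter_maf(matrix, config.maf_threshold)
    match_associations(associations, filtered)

    gene_chroms = sorted({g.chromosome for g in genes})
    pair_cache: dict[str, pd.DataFrame] = {}
    median_cache: dict[str, Optional[BlockSizeEstimate]] = {}

    def pairs_for(chrom: str) -> pd.DataFrame:
        if chrom not in pair_cache:
            pair_cache[chrom] = pairwise_r2(
                filtered,
                chrom,
                max_distance=config.max_pair_distance,
                min_r2=config.r2_threshold,
                min_informative=config.min_informative,
            )
            logger.info(
                "%s: %d pairs at r2 >= %.3g",
                chrom,
                len(pair_cache[chrom]),
                config.r2_threshold,
            )
        return pair_cache[chrom]

    def median_for(chrom: str) -> Optional[BlockSizeEstimate]:
        if chrom not in median_cache:
            median_cache[chrom] = chromosome_block_median(
                pairs_for(chrom), config.r2_threshold
            )
        return median_cache[chrom]

    def fallback_width(chrom: str) -> float:
        if config.fallback_scope == "genome":
            dists = []
            for c in filtered.chromosomes():
                est = median_for(c)
                if est is not None:
                    dists.append(est.median)
            width = float(np.median(dists)) if dists else None
        else:
            est = median_for(chrom)
            width = est.median if est is not None else None
        if width is None:
            width = config.default_fallback
        if width is None:
            raise ValueError(
                f"no r2 >= {config.r2_threshold} pair on {chrom} and no "
                "default_fallback configured"
            )
        return width

    # significance weights are a per-chromosome property of the associations
    weighted = {
        chrom: rank_weights(
            associations.loc[associations["chromosome"] == chrom],
            mode=config.significance_mode,
        )
        for chrom in associations["chromosome"].unique()
    }
    empty = associations.iloc[0:0].assign(rank=np.nan, weight=0.0)

    blocks: dict[str, LinkageBlock] = {}
    coloc: dict[str, ColocResult] = {}
    for gene in sorted(genes, key=lambda g: g.gene_id):
        if gene.chromosome not in filtered.chromosomes():
            logger.warning(
                "gene %s: chromosome %s has no SNPs after filtering — skipped",
                gene.gene_id,
                gene.chromosome,
            )
            continue
        block = gene_linkage_block(
            gene,
            filtered,
            pairs_for(gene.chromosome),
            r2_threshold=config.r2_threshold,
            fallback=fallback_width(gene.chromosome),
            n_flank=config.n_flank,
        )
        blocks[gene.gene_id] = block
        signals = weighted.get(gene.chromosome, empty)
        coloc[gene.gene_id] = permutation_test(
            gene,
            block,
            signals,
            filtered,
            n_perm=config.n_perm,
            seed=config.seed,
            ecdf=build_ecdf(gene, filtered),
            signals=signals,
            mode=config.significance_mode,
        )

    enrichment = run_enrichment(
        [g for g in genes if g.gene_id in blocks],
        blocks,
        coloc,
        associations,
        filtered,
        n_rand=config.n_rand,
        seed=config.seed,
        lod_cutoff=config.lod_cutoff,
        alpha=config.alpha,
        coloc_alpha=config.coloc_alpha,
        method=config.enrichment_method,
    )
    medians = {c: median_cache.get(c) for c in gene_chroms if c in median_cache}
    return PipelineResult(
        matrix=filtered,
        block_medians=medians,
        blocks=blocks,
        coloc=coloc,
        enrichment=enrichment,
        config=config,
    )
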