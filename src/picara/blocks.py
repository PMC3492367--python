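"""Linkage-block estimation, global and per candidate gene.

A chromosome's global block scale is the median distance between SNP pairs
in perfect LD (r² = 1).  Each candidate gene additionally gets a *dynamic*
local block: starting from an anchor set S_k (the SNPs inside the gene plus
its nearest flanking SNPs), the block is the hull of the gene interval and
every chromosome SNP in perfect LD with an anchor, upstream and downstream.
Genes in SNP-poor regions, whose anchors have no perfect-LD partner, fall
back to a block of the global median width centred on the gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from picara.io import CandidateGene, GenotypeMatrix
from picara.ld import R2_TOL

__all__ = [
    "BlockSizeEstimate",
    "LinkageBlock",
    "chromosome_block_median",
    "build_anchor_set",
    "gene_linkage_block",
]


@dataclass(frozen=True)
class BlockSizeEstimate:
    """Global linkage-block scale of a chromosome."""

    median: float
    q90: float
    n_pairs: int


@dataclass(frozen=True)
class LinkageBlock:
    """Per-gene linkage block, [upstream_bound, downstream_bound] in bp.

    ``source`` is "local" when the bounds come from observed perfect-LD
    partners of the gene's anchor SNPs, "genome-wide-fallback" when the
    gene sits in a SNP-poor region and the global median width was used.
    """

    gene_id: str
    chromosome: str
    upstream_bound: float
    downstream_bound: float
    source: str  # "local" | "genome-wide-fallback"
    anchor_snps: tuple[str, ...]
    r2_threshold: float

    @property
    def size(self) -> float:
        return self.downstream_bound - self.upstream_bound

    def contains(self, position: np.ndarray | float) -> np.ndarray | bool:
        return (np.asarray(position) >= self.upstream_bound) & (
            np.asarray(position) <= self.downstream_bound
        )


def chromosome_block_median(
    pairs: pd.DataFrame, r2_threshold: float = 1.0
) -> Optional[BlockSizeEstimate]:
    """Median (and 90% quantile) distance among pairs with r² >= threshold.

    ``pairs`` must come from a single chromosome.  Returns None when no
    pair qualifies; the caller must then supply its own default width.
    """
    if len(pairs) == 0:
        return None
    qual = pairs.loc[pairs["r2"] >= r2_threshold - R2_TOL, "distance"]
    if len(qual) == 0:
        return None
    d = qual.to_numpy(dtype=float)
    return BlockSizeEstimate(
        median=float(np.median(d)),
        q90=float(np.quantile(d, 0.9)),
        n_pairs=len(d),
    )


def build_anchor_set(
    gene: CandidateGene, matrix: GenotypeMatrix, n_flank: int = 1
) -> list[str]:
    """The anchor SNP set S_k: in-gene SNPs plus nearest flanking SNPs.

    All SNPs with gene.start <= position <= gene.end, plus the ``n_flank``
    nearest SNPs strictly upstream and strictly downstream when they exist.
    Returns an empty list when the gene's chromosome carries no SNPs.
    """
    try:
        positions = matrix.positions(gene.chromosome)
        ids = matrix.snp_ids(gene.chromosome)
    except KeyError:
        return []
    lo = int(np.searchsorted(positions, gene.start, "left"))
    hi = int(np.searchsorted(positions, gene.end, "right"))
    take = list(range(max(0, lo - n_flank), min(len(ids), hi + n_flank)))
    return [str(ids[i]) for i in take]


def gene_linkage_block(
    gene: CandidateGene,
    matrix: GenotypeMatrix,
    pairs: pd.DataFrame,
    r2_threshold: float = 1.0,
    fallback: Optional[float] = None,
    n_flank: int = 1,
) -> LinkageBlock:
    """Dynamic linkage block for one candidate gene.

    A chromosome SNP qualifies when it forms a pair with r² >=
    ``r2_threshold`` with any anchor.  With at least one qualifying
    partner, the block is the hull of the gene interval, the anchors and
    all partners (so blocks are asymmetric where LD is asymmetric).  With
    no partner — or no anchors at all — the block falls back to
    ``center ± fallback/2``.

    ``pairs`` must cover the gene's chromosome and include every pair at
    the threshold that involves an anchor (a ``min_r2`` pre-filter at or
    below ``r2_threshold`` is fine; a ``max_distance`` cap bounds how far a
    local block can reach).
    """
    anchors = build_anchor_set(gene, matrix, n_flank=n_flank)
    partner_pos: np.ndarray = np.array([], dtype=np.int64)
    if anchors and len(pairs):
        anchor_set = set(anchors)
        a_in = pairs["snp_a"].isin(anchor_set).to_numpy()
        b_in = pairs["snp_b"].isin(anchor_set).to_numpy()
        strong = (pairs["r2"].to_numpy() >= r2_threshold - R2_TOL) & (a_in | b_in)
        if strong.any():
            partner_ids = np.concatenate(
                [
                    pairs.loc[strong & b_in, "snp_a"].to_numpy(),
                    pairs.loc[strong & a_in, "snp_b"].to_numpy(),
                ]
            )
            chrom_ids = matrix.snp_ids(gene.chromosome)
            chrom_pos = matrix.positions(gene.chromosome)
            pos_of = pd.Series(chrom_pos, index=chrom_ids)
            # same-chromosome partners only; inter-chromosomal r²=1 pairs
            # (possible in small synthetic panels) are ignored
            partner_ids = [p for p in partner_ids if p in pos_of.index]
            partner_pos = pos_of.loc[partner_ids].to_numpy(dtype=np.int64)

    if partner_pos.size:
        chrom_ids = matrix.snp_ids(gene.chromosome)
        chrom_pos = matrix.positions(gene.chromosome)
        anchor_pos = pd.Series(chrom_pos, index=chrom_ids).loc[anchors].to_numpy()
        lo = float(min(gene.start, anchor_pos.min(), partner_pos.min()))
        hi = float(max(gene.end, anchor_pos.max(), partner_pos.max()))
        return LinkageBlock(
            gene_id=gene.gene_id,
            chromosome=gene.chromosome,
            upstream_bound=lo,
            downstream_bound=hi,
            source="local",
            anchor_snps=tuple(anchors),
            r2_threshold=r2_threshold,
        )

    if fallback is None:
        raise ValueError(
            f"gene {gene.gene_id}: no perfect-LD partner for any anchor and "
            "no fallback width given — supply the chromosome_block_median "
            "estimate as `fallback`"
        )
    half = float(fallback) / 2.0
    return LinkageBlock(
        gene_id=gene.gene_id,
        chromosome=gene.chromosome,
        upstream_bound=gene.center - half,
        downstream_bound=gene.center + half,
        source="genome-wide-fallback",
        anchor_snps=tuple(anchors),
        r2_threshold=r2_threshold,
    )


def blocks_table(blocks: Sequence[LinkageBlock]) -> pd.DataFrame:
    """BED-like export: one row per gene block."""
    return pd.DataFrame(
        {
            "gene_id": [b.gene_id for b in blocks],
            "chromosome": [b.chromosome for b in blocks],
            "upstream_bound": [b.upstream_bound for b in blocks],
            "downstream_bound": [b.downstream_bound for b in blocks],
            "size": [b.size for b in blocks],
            "source": [b.source for b in blocks],
        }
    )
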