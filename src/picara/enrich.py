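"""LOD-scaled enrichment of linkage blocks for GWAS association signals.

With S_t SNP loci and G_t significant associations on a chromosome, a gene
whose block holds x_i loci expects mu_i = x_i * G_t / S_t associations by
chance.  The enrichment score compares the g_i associations observed in the
block (counted only when the gene also passes its co-localization
permutation) with that expectation on a log10 (LOD) scale:

    E_i = log10(g_i / mu_i)                    for g_i >= 1
    E_i = log10(c / (mu_i + c)),  c = 0.5      for g_i = 0   (finite, <= 0)
    E_i = 0                                    for x_i = 0   (empty block)

E_i is 0 when the block's association rate equals the chromosome-wide
rate, positive under enrichment, strictly increasing in g_i and strictly
decreasing in x_i.  The null is position randomization: association
positions are re-drawn uniformly without replacement over the chromosome's
SNP loci (the in-block count is then exactly hypergeometric, and an exact
scipy-based p-value is available as a cross-check / fast path).  A gene is
called significant when E_i >= the LOD cutoff (default 2) and the
randomization p-value is <= 0.05.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from picara.blocks import LinkageBlock
from picara.io import CandidateGene, GenotypeMatrix
from picara.coloc import ColocResult, gene_rng
from picara._sampling import sample_without_replacement

__all__ = [
    "enrichment_score",
    "enrichment_pvalue_exact",
    "enrichment_null",
    "run_enrichment",
    "candidate_set_mean_lod",
]

DEFAULT_CONTINUITY = 0.5


def enrichment_score(
    x_i: int,
    g_i: int,
    S_t: int,
    G_t: int,
    continuity: float = DEFAULT_CONTINUITY,
) -> float:
    """LOD-scale enrichment of a block's association count over expectation.

    ``continuity`` only matters at g_i = 0, where the raw log ratio is
    −inf; the default 0.5 keeps the score finite and non-positive there
    (``continuity=0`` restores the raw ratio, −inf at g_i = 0).
    """
    if S_t < 1 or G_t < 1:
        raise ValueError("S_t and G_t must be >= 1")
    if not 0 <= g_i:
        raise ValueError("g_i must be >= 0")
    if x_i == 0:
        if g_i > 0:
            raise ValueError("g_i > 0 with x_i = 0 is impossible")
        return 0.0
    if g_i > x_i:
        raise ValueError(f"g_i ({g_i}) cannot exceed x_i ({x_i})")
    mu = x_i * G_t / S_t
    if g_i >= 1:
        return float(np.log10(g_i / mu))
    if continuity <= 0:
        return float("-inf")
    return float(np.log10(continuity / (mu + continuity)))


def enrichment_pvalue_exact(x_i: int, g_i: int, S_t: int, G_t: int) -> float:
    """Exact tail probability P(g >= g_i) under position randomization.

    Drawing G_t association positions without replacement from S_t loci
    makes the in-block count hypergeometric; since the score is strictly
    increasing in g at fixed (x_i, S_t, G_t), this is the exact version of
    the randomization p-value.
    """
    return float(scipy.stats.hypergeom.sf(g_i - 1, S_t, G_t, x_i))


def enrichment_null(
    gene: CandidateGene,
    block: LinkageBlock,
    matrix: GenotypeMatrix,
    G_t: int,
    n_rand: int = 1000,
    seed: int = 0,
    observed_e: Optional[float] = None,
    continuity: float = DEFAULT_CONTINUITY,
) -> tuple[np.ndarray, Optional[float]]:
    """Position-randomization null of the enrichment score.

    Each round draws G_t association positions without replacement from
    the chromosome's SNP loci and scores the in-block count.  Returns the
    null score vector and, when ``observed_e`` is given, the add-one
    empirical p-value (1 + #{null >= observed}) / (n_rand + 1).
    """
    positions = matrix.positions(gene.chromosome)
    S_t = len(positions)
    if G_t > S_t:
        raise ValueError(
            f"gene {gene.gene_id}: G_t ({G_t}) exceeds S_t ({S_t})"
        )
    in_block = np.asarray(block.contains(positions), dtype=bool)
    x_i = int(in_block.sum())
    rng = gene_rng(seed, gene.gene_id + "/enrich")
    if G_t == 0:
        null_g = np.zeros(n_rand, dtype=np.int64)
    else:
        idx = sample_without_replacement(rng, S_t, G_t, n_rand)
        null_g = in_block[idx].sum(axis=1)
    uniq, inverse = np.unique(null_g, return_inverse=True)
    scores = np.array(
        [enrichment_score(x_i, int(g), S_t, max(G_t, 1), continuity) for g in uniq]
    )
    null_e = scores[inverse]
    p = None
    if observed_e is not None:
        p = float((1 + np.count_nonzero(null_e >= observed_e - 1e-12)) / (n_rand + 1))
    return null_e, p


def run_enrichment(
    genes: Sequence[CandidateGene],
    blocks: dict[str, LinkageBlock],
    coloc_results: dict[str, ColocResult],
    associations: pd.DataFrame,
    matrix: GenotypeMatrix,
    n_rand: int = 1000,
    seed: int = 0,
    lod_cutoff: float = 2.0,
    alpha: float = 0.05,
    coloc_alpha: float = 0.05,
    continuity: float = DEFAULT_CONTINUITY,
    method: str = "randomization",
) -> pd.DataFrame:
    """Score every gene; returns a table sorted by E_i descending.

    g_i counts the significant in-block associations only when the gene's
    co-localization permutation p-value is <= ``coloc_alpha`` ("also
    significantly co-locating"); otherwise g_i = 0.  A gene with a missing
    upstream block or co-localization result is reported with status
    "skipped", never dropped.  ``method="exact"`` replaces the sampled
    randomization p-value with the closed-form hypergeometric tail.
    """
    if method not in ("randomization", "exact"):
        raise ValueError(f"unknown method {method!r}")
    sig = associations.loc[associations["is_significant"]]
    rows = []
    for gene in genes:
        block = blocks.get(gene.gene_id)
        cres = coloc_results.get(gene.gene_id)
        if block is None or cres is None:
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "chromosome": gene.chromosome,
                    "S_t": 0,
                    "G_t": 0,
                    "x_i": 0,
                    "g_i": 0,
                    "E_i": np.nan,
                    "empirical_p": np.nan,
                    "significant": False,
                    "status": "skipped",
                }
            )
            continue
        positions = matrix.positions(gene.chromosome)
        S_t = len(positions)
        chrom_sig = sig.loc[sig["chromosome"] == gene.chromosome]
        G_t = len(chrom_sig)
        x_i = int(np.count_nonzero(block.contains(positions)))
        in_block = block.contains(chrom_sig["position"].to_numpy())
        g_i = int(np.count_nonzero(in_block)) if cres.perm_p <= coloc_alpha else 0
        g_i = min(g_i, x_i)  # a significant association sits on a block SNP
        if G_t == 0:
            e_i, emp_p = 0.0, 1.0
        else:
            e_i = enrichment_score(x_i, g_i, S_t, G_t, continuity)
            if method == "exact":
                emp_p = enrichment_pvalue_exact(x_i, g_i, S_t, G_t)
            else:
                _, emp_p = enrichment_null(
                    gene,
                    block,
                    matrix,
                    G_t,
                    n_rand=n_rand,
                    seed=seed,
                    observed_e=e_i,
                    continuity=continuity,
                )
        rows.append(
            {
                "gene_id": gene.gene_id,
                "chromosome": gene.chromosome,
                "S_t": S_t,
                "G_t": G_t,
                "x_i": x_i,
                "g_i": g_i,
                "E_i": e_i,
                "empirical_p": emp_p,
                "significant": bool(e_i >= lod_cutoff and emp_p <= alpha),
                "status": "ok",
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(
        "E_i", ascending=False, kind="stable", na_position="last"
    ).reset_index(drop=True)


def candidate_set_mean_lod(results: pd.DataFrame, floor: bool = True) -> float:
    """Mean LOD over a candidate set (the pseudo-candidate control).

    With ``floor=True`` (default) negative scores are floored at 0 so that
    depletion cannot mask enrichment; ``floor=False`` gives the raw mean.
    """
    e = results.loc[results["status"] == "ok", "E_i"].to_numpy(dtype=float)
    if e.size == 0:
        raise ValueError("no scored genes in results")
    if floor:
        e = np.maximum(e, 0.0)
    return float(np.mean(e))
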