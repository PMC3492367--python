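"""Synthetic NAM-like fixtures: genotypes, candidate genes, associations.

The generator emulates the input roles of the real study — a dense
biallelic SNP panel scored on homozygous recombinant inbred lines, an
association table whose significance currency is a RIMP count, and a list
of a priori candidate intervals — at desk scale and with known truth:

* Perfect-LD blocks are planted by column duplication: every SNP inside a
  planted block shares one genotype column (up to random allele
  relabeling), which is exactly the structure the r² = 1 block estimator
  assumes.  Background SNP columns are drawn independently, so background
  r² concentrates near 1/n_lines and r² = 1 background pairs are
  (probability ~2**-n_lines) never observed.
* Candidate genes are planted either anchored strictly inside a block's
  realized SNP span (their local linkage block is then the span itself) or
  in background regions (they must fall back to the chromosome median).
* Associations sit on SNP loci.  "Enriched" genes get a stated number of
  significant associations planted on their block's SNPs; the rest are
  placed uniformly without replacement — the same law the permutation
  nulls assume, which is what makes the calibration tests meaningful.
* RIMP counts follow a truncated geometric on {2..15} (the observed range
  of strong maize signals) with an insignificant class at RIMP 1; allelic
  effects are small and sign-symmetric, N(0, 0.1 days).

Every draw flows from the single config seed; fixtures are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from picara.io import (
    CALL_MISSING,
    CandidateGene,
    GenotypeMatrix,
    write_associations,
    write_genes,
    write_genotypes,
)

__all__ = [
    "ChromosomeSpec",
    "BlockSpec",
    "SimConfig",
    "Fixture",
    "simulate_genotypes",
    "simulate_associations",
    "simulate_fixture",
    "write_fixture",
    "small_config",
    "null_calibration_config",
    "power_config",
    "make_pseudo_genes",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ChromosomeSpec:
    name: str
    length: int  # bp
    n_background_snps: int


@dataclass(frozen=True)
class BlockSpec:
    chromosome: str
    start: int
    end: int
    n_snps: int


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of a synthetic fixture."""

    n_lines: int = 200
    chromosomes: tuple[ChromosomeSpec, ...] = ()
    blocks: tuple[BlockSpec, ...] = ()
    n_genes_in_blocks: int = 0  # per chromosome, each in its own block
    n_background_genes: int = 0  # per chromosome
    n_enriched: int = 0  # per chromosome, among the in-block genes
    gene_length: int = 3000  # background genes, bp
    n_associations: int = 0  # per chromosome
    n_planted_per_gene: int = 6  # significant associations per enriched gene
    rimp_insig_prob: float = 0.35  # P(RIMP = 1): insignificant class
    rimp_geom_p: float = 0.35  # decay of the {2..15} truncated geometric
    rimp_max: int = 15
    effect_sd: float = 0.1  # days; "many small effects" regime
    maf_low: float = 0.05
    maf_high: float = 0.5
    block_maf_low: float = 0.1  # blocks stay safely above the MAF filter
    block_maf_high: float = 0.45
    maf_threshold: float = 0.05  # filter the association table respects
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        names = {c.name for c in self.chromosomes}
        per_chrom: dict[str, list[BlockSpec]] = {n: [] for n in names}
        for b in self.blocks:
            if b.chromosome not in names:
                raise ValueError(f"block on unknown chromosome {b.chromosome!r}")
            per_chrom[b.chromosome].append(b)
        for c in self.chromosomes:
            blocks = sorted(per_chrom[c.name], key=lambda b: b.start)
            for b in blocks:
                if not (1 <= b.start <= b.end <= c.length):
                    raise ValueError(f"block {b} outside chromosome {c.name}")
                if b.n_snps > b.end - b.start + 1:
                    raise ValueError(f"block {b}: n_snps exceeds span at 1 bp spacing")
            for left, right in zip(blocks, blocks[1:]):
                if left.end >= right.start:
                    raise ValueError(
                        f"overlapping planted blocks on {c.name}: {left}, {right}"
                    )
            if self.n_genes_in_blocks > len(blocks):
                raise ValueError(
                    f"{self.n_genes_in_blocks} in-block genes requested on "
                    f"{c.name} but only {len(blocks)} blocks planted"
                )
            if c.n_background_snps > c.length:
                raise ValueError(f"{c.name}: more background SNPs than positions")
        if self.n_enriched > self.n_genes_in_blocks:
            raise ValueError("n_enriched exceeds n_genes_in_blocks")


@dataclass
class Fixture:
    """A simulated data set plus its ground truth."""

    config: SimConfig
    matrix: GenotypeMatrix
    associations: pd.DataFrame
    genes: list[CandidateGene]
    truth: pd.DataFrame  # gene_id, chromosome, enriched, in_block, span_lo, span_hi


# ---------------------------------------------------------------------------
# genotypes


def _draw_distinct_ints(
    rng: np.random.Generator,
    low: int,
    high: int,
    n: int,
    spans: Sequence[tuple[int, int]],
) -> np.ndarray:
    """n distinct ints in [low, high] avoiding the closed intervals ``spans``."""
    starts = np.array(sorted(s for s, _ in spans), dtype=np.int64)
    ends = np.array([e for _, e in sorted(spans)], dtype=np.int64)
    have: np.ndarray = np.empty(0, dtype=np.int64)
    while len(have) < n:
        draw = rng.integers(low, high + 1, size=2 * (n - len(have)) + 8)
        if len(starts):
            i = np.searchsorted(starts, draw, "right") - 1
            in_span = (i >= 0) & (draw <= ends[np.maximum(i, 0)])
            draw = draw[~in_span]
        have = np.unique(np.concatenate([have, draw]))
    # keep a uniform subset of the accumulated distinct values
    return np.sort(rng.choice(have, size=n, replace=False))


def _column(rng: np.random.Generator, n_lines: int, p: float) -> np.ndarray:
    return (rng.random(n_lines) < p).astype(np.int8)


def _realized_maf(col: np.ndarray) -> float:
    obs = col[col != CALL_MISSING]
    if len(obs) == 0:
        return float("nan")
    f = obs.mean()
    return float(min(f, 1.0 - f))


def _sprinkle_missing(
    rng: np.random.Generator, col: np.ndarray, rate: float
) -> np.ndarray:
    out = col.copy()
    if rate > 0:
        out[rng.random(len(col)) < rate] = CALL_MISSING
    return out


def simulate_genotypes(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw the genotype matrix; also returns the realized planted blocks.

    The second return value has one row per planted block with the realized
    SNP span (``span_lo``/``span_hi`` = first/last block SNP position) and
    the block's SNP count — the ground truth the block estimator should
    recover.
    """
    rng = rng or np.random.default_rng(config.seed)
    n_lines = config.n_lines
    recs: list[dict] = []
    calls_rows: list[np.ndarray] = []
    block_rows: list[dict] = []
    blocks_by_chrom: dict[str, list[BlockSpec]] = {}
    for b in config.blocks:
        blocks_by_chrom.setdefault(b.chromosome, []).append(b)

    for chrom in config.chromosomes:
        blocks = sorted(blocks_by_chrom.get(chrom.name, []), key=lambda b: b.start)
        forbidden_spans = [(b.start, b.end) for b in blocks]

        snp_counter = 0
        chrom_recs: list[tuple[int, dict, np.ndarray]] = []

        for bi, b in enumerate(blocks):
            pos = np.sort(
                rng.choice(np.arange(b.start, b.end + 1), size=b.n_snps, replace=False)
            )
            # one shared haplotype column for the whole block
            while True:
                p = rng.uniform(config.block_maf_low, config.block_maf_high)
                shared = _column(rng, n_lines, p)
                if config.maf_threshold <= _realized_maf(shared) :
                    break
            for pp in pos:
                flip = rng.random() < 0.5  # allele relabeling
                col = (1 - shared) if flip else shared.copy()
                while True:
                    noisy = _sprinkle_missing(rng, col, config.missing_rate)
                    if _realized_maf(noisy) >= config.maf_threshold:
                        break
                alleles = rng.choice(4, size=2, replace=False)
                chrom_recs.append(
                    (
                        int(pp),
                        {
                            "snp_id": f"{chrom.name}_s{snp_counter}",
                            "chromosome": chrom.name,
                            "position": int(pp),
                            "allele_a": _BASES[alleles[0]],
                            "allele_b": _BASES[alleles[1]],
                        },
                        noisy,
                    )
                )
                snp_counter += 1
            block_rows.append(
                {
                    "chromosome": chrom.name,
                    "block_index": bi,
                    "start": b.start,
                    "end": b.end,
                    "n_snps": b.n_snps,
                    "span_lo": int(pos[0]),
                    "span_hi": int(pos[-1]),
                }
            )

        bg_pos = _draw_distinct_ints(
            rng, 1, chrom.length, chrom.n_background_snps, forbidden_spans
        )
        if chrom.n_background_snps:
            probs = rng.uniform(config.maf_low, config.maf_high, size=len(bg_pos))
            cols = (
                rng.random((len(bg_pos), n_lines)) < probs[:, None]
            ).astype(np.int8)
            if config.missing_rate > 0:
                cols[rng.random(cols.shape) < config.missing_rate] = CALL_MISSING
            first = rng.integers(0, 4, size=len(bg_pos))
            second = (first + rng.integers(1, 4, size=len(bg_pos))) % 4
            pairs = np.column_stack([first, second])
            for i, pp in enumerate(bg_pos):
                chrom_recs.append(
                    (
                        int(pp),
                        {
                            "snp_id": f"{chrom.name}_s{snp_counter}",
                            "chromosome": chrom.name,
                            "position": int(pp),
                            "allele_a": _BASES[pairs[i, 0]],
                            "allele_b": _BASES[pairs[i, 1]],
                        },
                        cols[i],
                    )
                )
                snp_counter += 1

        chrom_recs.sort(key=lambda t: t[0])
        for _, rec, col in chrom_recs:
            recs.append(rec)
            calls_rows.append(col)

    loci = pd.DataFrame(recs)
    calls = np.vstack(calls_rows) if calls_rows else np.empty((0, n_lines), np.int8)
    matrix = GenotypeMatrix(
        loci=loci,
        lines=[f"line{i:03d}" for i in range(n_lines)],
        calls=calls,
    )
    return matrix, pd.DataFrame(block_rows)


# ---------------------------------------------------------------------------
# genes


def _plant_genes(
    config: SimConfig,
    matrix: GenotypeMatrix,
    realized_blocks: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[list[CandidateGene], pd.DataFrame]:
    genes: list[CandidateGene] = []
    truth_rows: list[dict] = []
    for chrom in config.chromosomes:
        cblocks = realized_blocks.loc[
            realized_blocks["chromosome"] == chrom.name
        ].reset_index(drop=True)
        chosen = (
            rng.choice(len(cblocks), size=config.n_genes_in_blocks, replace=False)
            if config.n_genes_in_blocks
            else np.array([], dtype=int)
        )
        enriched_flags = np.zeros(len(chosen), dtype=bool)
        enriched_flags[: config.n_enriched] = True

        positions = matrix.positions(chrom.name)
        ids = matrix.snp_ids(chrom.name)

        for gi, (bidx, enr) in enumerate(zip(chosen, enriched_flags)):
            blk = cblocks.iloc[int(bidx)]
            in_span = (positions >= blk["span_lo"]) & (positions <= blk["span_hi"])
            p = positions[in_span]
            if len(p) < 4:
                raise ValueError("planted block too sparse to anchor a gene")
            # interior placement: block SNPs inside the gene AND as both
            # nearest flanks, so the anchor hull recovers the span exactly
            lo_i = max(1, len(p) // 4)
            hi_i = min(len(p) - 2, 3 * len(p) // 4)
            start, end = int(p[lo_i]), int(p[hi_i])
            gid = f"gene_{chrom.name}_b{gi}"
            genes.append(
                CandidateGene(gene_id=gid, chromosome=chrom.name, start=start, end=end)
            )
            truth_rows.append(
                {
                    "gene_id": gid,
                    "chromosome": chrom.name,
                    "enriched": bool(enr),
                    "in_block": True,
                    "block_index": int(blk["block_index"]),
                    "span_lo": int(blk["span_lo"]),
                    "span_hi": int(blk["span_hi"]),
                }
            )

        block_spans = list(
            zip(cblocks["start"].to_numpy(), cblocks["end"].to_numpy())
        )
        for gi in range(config.n_background_genes):
            gid = f"gene_{chrom.name}_g{gi}"
            start, end = _background_interval(
                rng, chrom, config.gene_length, positions, block_spans
            )
            genes.append(
                CandidateGene(gene_id=gid, chromosome=chrom.name, start=start, end=end)
            )
            truth_rows.append(
                {
                    "gene_id": gid,
                    "chromosome": chrom.name,
                    "enriched": False,
                    "in_block": False,
                    "block_index": -1,
                    "span_lo": -1,
                    "span_hi": -1,
                }
            )
    truth = pd.DataFrame(truth_rows)
    return genes, truth


def _background_interval(
    rng: np.random.Generator,
    chrom: ChromosomeSpec,
    length: int,
    positions: np.ndarray,
    block_spans: list[tuple[int, int]],
) -> tuple[int, int]:
    """A gene interval whose anchors are guaranteed background SNPs."""
    for _ in range(10_000):
        start = int(rng.integers(1, max(2, chrom.length - length)))
        end = start + length - 1
        lo = int(np.searchsorted(positions, start, "left"))
        hi = int(np.searchsorted(positions, end, "right"))
        if hi - lo < 1:  # want at least one in-gene SNP
            continue
        # anchors = in-gene SNPs + one flank either side; none may sit in a
        # planted block, or the gene would inherit the block's perfect LD
        a_lo = positions[max(0, lo - 1)]
        a_hi = positions[min(len(positions) - 1, hi)]
        if any(s <= a_hi and a_lo <= e for s, e in block_spans):
            continue
        return start, end
    raise RuntimeError(f"could not place a background gene on {chrom.name}")


# ---------------------------------------------------------------------------
# associations


def _draw_rimp(
    rng: np.random.Generator, n: int, config: SimConfig, significant_only: bool
) -> np.ndarray:
    geo = 2 + (rng.geometric(config.rimp_geom_p, size=n) - 1)
    geo = np.minimum(geo, config.rimp_max)
    if significant_only:
        return geo
    insig = rng.random(n) < config.rimp_insig_prob
    return np.where(insig, 1, geo)


def simulate_associations(
    config: SimConfig,
    matrix: GenotypeMatrix,
    truth: Optional[pd.DataFrame] = None,
    rng: Optional[np.random.Generator] = None,
    maf: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Place associations on SNP loci; plant signals in enriched genes.

    Enriched genes (rows of ``truth`` with ``enriched``) receive
    ``n_planted_per_gene`` significant associations on SNPs of their
    planted block; the remaining associations are placed uniformly without
    replacement over the chromosome's MAF-passing loci — the uniform law
    the permutation nulls assume.  Returns the standard association table
    with ``is_significant`` set in RIMP mode (cutoff 2).
    """
    from picara.ld import compute_maf
    from picara.io import flag_significance

    rng = rng or np.random.default_rng(config.seed + 1)
    if maf is None:
        maf = compute_maf(matrix)
    rows: list[pd.DataFrame] = []
    for chrom in config.chromosomes:
        sl = matrix.chromosome_slice(chrom.name)
        passing = np.flatnonzero(maf[sl.start : sl.stop] >= config.maf_threshold)
        ids = matrix.snp_ids(chrom.name)
        positions = matrix.positions(chrom.name)

        planted_idx: list[int] = []
        if truth is not None:
            enriched = truth.loc[
                (truth["chromosome"] == chrom.name) & truth["enriched"]
            ]
            for t in enriched.itertuples(index=False):
                in_span = np.flatnonzero(
                    (positions >= t.span_lo) & (positions <= t.span_hi)
                )
                in_span = in_span[np.isin(in_span, passing)]
                if len(in_span) < config.n_planted_per_gene:
                    raise ValueError(
                        f"block of {t.gene_id} has {len(in_span)} usable SNPs, "
                        f"cannot plant {config.n_planted_per_gene} associations"
                    )
                planted_idx.extend(
                    rng.choice(in_span, size=config.n_planted_per_gene, replace=False)
                )
        n_rest = config.n_associations - len(planted_idx)
        if n_rest < 0:
            raise ValueError(
                f"{chrom.name}: planted associations ({len(planted_idx)}) exceed "
                f"n_associations ({config.n_associations})"
            )
        pool = passing[~np.isin(passing, planted_idx)]
        if n_rest > len(pool):
            raise ValueError(f"{chrom.name}: not enough loci for associations")
        rest_idx = rng.choice(pool, size=n_rest, replace=False)
        idx = np.concatenate([np.array(planted_idx, dtype=int), rest_idx]).astype(int)
        rimp = np.concatenate(
            [
                _draw_rimp(rng, len(planted_idx), config, significant_only=True),
                _draw_rimp(rng, n_rest, config, significant_only=False),
            ]
        )
        rows.append(
            pd.DataFrame(
                {
                    "snp_id": ids[idx],
                    "chromosome": chrom.name,
                    "position": positions[idx],
                    "significance": rimp.astype(float),
                    "effect": rng.normal(0.0, config.effect_sd, size=len(idx)),
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    return flag_significance(table, mode="rimp", cutoff=2, source="simulated")


def simulate_fixture(config: SimConfig) -> Fixture:
    """Full fixture from one seed: genotypes, genes, associations, truth."""
    rng = np.random.default_rng(config.seed)
    matrix, realized = simulate_genotypes(config, rng)
    genes, truth = _plant_genes(config, matrix, realized, rng)
    associations = simulate_associations(config, matrix, truth, rng)
    return Fixture(
        config=config,
        matrix=matrix,
        associations=associations,
        genes=genes,
        truth=truth,
    )


def write_fixture(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate and write the three input files plus the truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fx = simulate_fixture(config)
    paths = {
        "genotypes": out / "genotypes.hapmap.txt",
        "associations": out / "associations.tsv",
        "genes": out / "genes.tsv",
        "truth": out / "truth.tsv",
        "config": out / "sim_config.yaml",
    }
    write_genotypes(fx.matrix, paths["genotypes"])
    write_associations(fx.associations, paths["associations"])
    write_genes(fx.genes, paths["genes"])
    fx.truth.to_csv(paths["truth"], sep="\t", index=False)
    cfg = asdict(config)  # recurses into the nested specs
    cfg["chromosomes"] = [dict(c) for c in cfg["chromosomes"]]
    cfg["blocks"] = [dict(b) for b in cfg["blocks"]]
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=False))
    return paths


def make_pseudo_genes(
    config: SimConfig,
    matrix: GenotypeMatrix,
    n: int,
    rng: np.random.Generator,
    length: int = 2000,
) -> list[CandidateGene]:
    """Random background intervals — the pseudo-candidate control set."""
    genes = []
    chroms = {c.name: c for c in config.chromosomes}
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for b in config.blocks:
        spans[b.chromosome].append((b.start, b.end))
    names = list(chroms)
    for i in range(n):
        cname = names[int(rng.integers(len(names)))]
        start, end = _background_interval(
            rng, chroms[cname], length, matrix.positions(cname), spans[cname]
        )
        genes.append(
            CandidateGene(
                gene_id=f"pseudo_{i:03d}", chromosome=cname, start=start, end=end
            )
        )
    return genes


# ---------------------------------------------------------------------------
# standard study designs


def _spread_blocks(
    name: str, length: int, n_blocks: int, span: int, n_snps: int
) -> list[BlockSpec]:
    """Evenly spaced non-overlapping blocks along one chromosome."""
    step = length // (n_blocks + 1)
    if step <= span:
        raise ValueError("blocks would overlap")
    return [
        BlockSpec(name, start=(i + 1) * step, end=(i + 1) * step + span - 1, n_snps=n_snps)
        for i in range(n_blocks)
    ]


def small_config(seed: int = 0, n_lines: int = 60) -> SimConfig:
    """Two small chromosomes for unit and recovery tests."""
    chroms = (
        ChromosomeSpec("chr01", 1_000_000, 180),
        ChromosomeSpec("chr02", 1_000_000, 180),
    )
    blocks = tuple(
        b
        for c in chroms
        for b in _spread_blocks(c.name, c.length, n_blocks=3, span=30_000, n_snps=12)
    )
    return SimConfig(
        n_lines=n_lines,
        chromosomes=chroms,
        blocks=blocks,
        n_genes_in_blocks=2,
        n_background_genes=3,
        n_enriched=1,
        n_associations=30,
        n_planted_per_gene=4,
        seed=seed,
    )


def null_calibration_config(seed: int = 0) -> SimConfig:
    """Null study conditions: no planted enrichment, uniform associations.

    Ten 50-Mb chromosomes of 5,000 SNPs (4,375 background + 25 planted
    perfect-LD blocks of 25 SNPs over 150 kb), 50 candidate genes per
    chromosome (half anchored in blocks, half background), 150 uniformly
    placed associations per chromosome.
    """
    chroms = tuple(
        ChromosomeSpec(f"chr{i:02d}", 50_000_000, 4_375) for i in range(1, 11)
    )
    blocks = tuple(
        b
        for c in chroms
        for b in _spread_blocks(c.name, c.length, n_blocks=25, span=150_000, n_snps=25)
    )
    return SimConfig(
        n_lines=200,
        chromosomes=chroms,
        blocks=blocks,
        n_genes_in_blocks=25,
        n_background_genes=25,
        n_enriched=0,
        n_associations=150,
        seed=seed,
    )


def power_config(seed: int = 0) -> SimConfig:
    """Planted-enrichment study conditions.

    Ten 250-Mb chromosomes of 100,000 SNPs; one 50-SNP perfect-LD block of
    ~2.5 kb per chromosome hosting one enriched gene with 6 planted
    significant associations; 20 associations per chromosome in total.
    """
    chroms = tuple(
        ChromosomeSpec(f"chr{i:02d}", 250_000_000, 99_950) for i in range(1, 11)
    )
    blocks = tuple(
        b
        for c in chroms
        for b in _spread_blocks(c.name, c.length, n_blocks=1, span=2_500, n_snps=50)
    )
    return SimConfig(
        n_lines=200,
        chromosomes=chroms,
        blocks=blocks,
        n_genes_in_blocks=1,
        n_background_genes=0,
        n_enriched=1,
        n_associations=20,
        n_planted_per_gene=6,
        seed=seed,
    )
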