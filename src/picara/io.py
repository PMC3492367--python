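"""Readers and writers for the pipeline's tabular formats.

Three text formats are handled, all tab-delimited with a header row:

* HapMap-dialect genotypes: columns ``rs#  alleles  chrom  pos`` followed by
  one column per inbred line; calls are single IUPAC characters, ``N`` for
  missing.  Lines are treated as homozygous, so each call is one observed
  haplotype.
* Association tables: ``snp_id  chromosome  position  significance  effect``
  where significance is a RIMP count (resampling model inclusion
  probability, integer mode) or a p-value.
* Candidate-gene tables: ``gene_id  chromosome  start  end  annotation
  homology_class``.

Coordinates are 1-based inclusive throughout; distances are absolute bp
differences of point coordinates.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CALL_A",
    "CALL_B",
    "CALL_MISSING",
    "HOMOLOGY_CLASSES",
    "CandidateGene",
    "GenotypeMatrix",
    "read_genotypes",
    "read_associations",
    "read_genes",
    "write_genotypes",
    "write_associations",
    "write_genes",
    "match_associations",
]

# Internal genotype codes: calls[i, j] for locus i, line j.
CALL_A = 0  # first allele of the locus' allele pair
CALL_B = 1  # second allele
CALL_MISSING = -1

# IUPAC ambiguity codes (heterozygous in a diploid reading).
_HET_CODES = frozenset("RYSWKM")

HOMOLOGY_CLASSES = frozenset(
    {
        "one-to-one",
        "one-to-many",
        "many-to-many",
        "between-species-paralog",
        "apparent-one-to-one",
        "unknown",
    }
)


@dataclass(frozen=True)
class CandidateGene:
    """An a priori candidate interval (1-based, inclusive ends).

    ``center`` is the integer midpoint of [start, end]; all gene-to-SNP
    distances in the pipeline are measured from it.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    annotation: str = ""
    homology_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start must be >= 1")
        if self.homology_class not in HOMOLOGY_CLASSES:
            raise ValueError(
                f"gene {self.gene_id}: unknown homology class "
                f"{self.homology_class!r}"
            )

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenotypeMatrix:
    """Biallelic SNP calls for a panel of inbred lines.

    Attributes
    ----------
    loci : pandas.DataFrame
        One row per SNP with columns ``snp_id, chromosome, position,
        allele_a, allele_b``, sorted by (chromosome, position).  The index
        is the row number into ``calls``.
    lines : list of str
        Line (taxon) identifiers, one per column of ``calls``.
    calls : numpy.ndarray of int8, shape (n_loci, n_lines)
        ``CALL_A`` / ``CALL_B`` / ``CALL_MISSING``.
    """

    loci: pd.DataFrame
    lines: list[str]
    calls: np.ndarray
    _chrom_slices: dict[str, slice] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.loci), len(self.lines)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.loci)} loci x {len(self.lines)} lines"
            )
        if len(self.lines) < 2:
            raise ValueError("a genotype matrix needs at least 2 lines")
        if self.calls.size and not (
            (self.calls >= CALL_MISSING) & (self.calls <= CALL_B)
        ).all():
            raise ValueError("calls contain codes other than {0, 1, -1}")
        self._validate_loci()
        self._index_chromosomes()

    def _validate_loci(self) -> None:
        loci = self.loci
        dup = loci["snp_id"][loci["snp_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate snp_id: {dup.iloc[0]!r}")
        # canonical order: lexicographic chromosome, then position
        order = np.lexsort((loci["position"].to_numpy(), loci["chromosome"].to_numpy()))
        if not np.array_equal(order, np.arange(len(loci))):
            self.loci = loci.iloc[order].reset_index(drop=True)
            self.calls = self.calls[order]
        if (self.loci["position"] < 1).any():
            bad = self.loci.loc[self.loci["position"] < 1, "snp_id"].iloc[0]
            raise ValueError(f"SNP {bad!r}: position must be >= 1")
        same = self.loci.duplicated(subset=["chromosome", "position"])
        if same.any():
            bad = self.loci.loc[same].iloc[0]
            raise ValueError(
                f"two SNPs at {bad['chromosome']}:{bad['position']} "
                "(per-chromosome positions must be strictly increasing)"
            )

    def _index_chromosomes(self) -> None:
        self._chrom_slices = {}
        chroms = self.loci["chromosome"].to_numpy()
        if len(chroms) == 0:
            return
        starts = np.flatnonzero(np.r_[True, chroms[1:] != chroms[:-1]])
        bounds = np.r_[starts, len(chroms)]
        for s, e in zip(bounds[:-1], bounds[1:]):
            self._chrom_slices[chroms[s]] = slice(int(s), int(e))

    # -- accessors ---------------------------------------------------------

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def chromosomes(self) -> list[str]:
        return list(self._chrom_slices)

    def chromosome_slice(self, chromosome: str) -> slice:
        """Row slice of ``loci``/``calls`` covering one chromosome."""
        try:
            return self._chrom_slices[chromosome]
        except KeyError:
            raise KeyError(f"no SNPs on chromosome {chromosome!r}") from None

    def positions(self, chromosome: str) -> np.ndarray:
        sl = self.chromosome_slice(chromosome)
        return self.loci["position"].to_numpy()[sl]

    def snp_ids(self, chromosome: str) -> np.ndarray:
        sl = self.chromosome_slice(chromosome)
        return self.loci["snp_id"].to_numpy()[sl]

    def subset(self, row_mask: np.ndarray) -> "GenotypeMatrix":
        """New matrix keeping loci where ``row_mask`` is True (order kept)."""
        row_mask = np.asarray(row_mask, dtype=bool)
        return GenotypeMatrix(
            loci=self.loci.loc[row_mask].reset_index(drop=True),
            lines=list(self.lines),
            calls=self.calls[row_mask].copy(),
        )


# ---------------------------------------------------------------------------
# genotype I/O


def read_genotypes(
    path: str | Path,
    format: str = "hapmap",
    het_policy: str = "missing",
) -> GenotypeMatrix:
    """Read a HapMap-dialect genotype file.

    Parameters
    ----------
    path : file path
    format : {"hapmap", "tsv"}
        Both dialects share the layout ``rs# alleles chrom pos <lines...>``;
        "tsv" accepts plain column names (``snp_id alleles chromosome
        position``) as written by :func:`write_genotypes`.
    het_policy : {"missing", "reject"}
        NAM RILs are inbred, so heterozygous IUPAC codes are treated as
        missing by default; ``"reject"`` raises on the first one.
    """
    if format not in ("hapmap", "tsv"):
        raise ValueError(f"unknown genotype format {format!r}")
    if het_policy not in ("missing", "reject"):
        raise ValueError(f"unknown het_policy {het_policy!r}")

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if len(cols) < 6:
        raise ValueError(
            f"{path}: expected 'rs# alleles chrom pos' plus >=2 line columns"
        )
    first4 = [c.lower() for c in cols[:4]]
    ok_hapmap = first4 == ["rs#", "alleles", "chrom", "pos"]
    ok_tsv = first4 == ["snp_id", "alleles", "chromosome", "position"]
    if not (ok_hapmap or ok_tsv):
        raise ValueError(
            f"{path}: header must start with 'rs# alleles chrom pos' "
            f"(got {cols[:4]})"
        )
    lines = [str(c) for c in cols[4:]]
    if len(lines) < 2:
        raise ValueError(f"{path}: fewer than 2 line columns")

    snp_ids = df.iloc[:, 0].astype(str)
    dup = snp_ids[snp_ids.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate snp_id {dup.iloc[0]!r}")

    try:
        positions = pd.to_numeric(df.iloc[:, 3], errors="raise").astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric position ({exc})") from None

    allele_pairs = df.iloc[:, 1].astype(str).str.upper()
    parts = allele_pairs.str.split("/", expand=True)
    if parts.shape[1] != 2 or parts.isna().any().any():
        bad = snp_ids[parts.isna().any(axis=1)].iloc[0]
        raise ValueError(f"{path}: SNP {bad!r}: alleles must be 'X/Y'")
    allele_a = parts[0].to_numpy()
    allele_b = parts[1].to_numpy()
    if (allele_a == allele_b).any():
        bad = snp_ids[allele_a == allele_b].iloc[0]
        raise ValueError(f"{path}: SNP {bad!r}: alleles must be distinct")

    raw = df.iloc[:, 4:].to_numpy(dtype="U1")
    raw = np.char.upper(raw)
    calls = np.full(raw.shape, CALL_MISSING, dtype=np.int8)
    calls[raw == allele_a[:, None]] = CALL_A
    calls[raw == allele_b[:, None]] = CALL_B
    unresolved = (calls == CALL_MISSING) & (raw != "N")
    if unresolved.any():
        i, j = np.argwhere(unresolved)[0]
        code = raw[i, j]
        if code in _HET_CODES:
            if het_policy == "reject":
                raise ValueError(
                    f"{path}: heterozygous call {code!r} at SNP "
                    f"{snp_ids.iloc[i]!r}, line {lines[j]!r}"
                )
            # policy "missing": leave every het code as CALL_MISSING
            het_mask = np.isin(raw, list(_HET_CODES))
            unresolved &= ~het_mask
            if unresolved.any():
                i, j = np.argwhere(unresolved)[0]
                raise ValueError(
                    f"{path}: call {raw[i, j]!r} at SNP {snp_ids.iloc[i]!r} "
                    f"matches neither declared allele"
                )
        else:
            raise ValueError(
                f"{path}: call {code!r} at SNP {snp_ids.iloc[i]!r} "
                f"matches neither declared allele"
            )

    loci = pd.DataFrame(
        {
            "snp_id": snp_ids.to_numpy(),
            "chromosome": df.iloc[:, 2].astype(str).to_numpy(),
            "position": positions.to_numpy(),
            "allele_a": allele_a,
            "allele_b": allele_b,
        }
    )
    return GenotypeMatrix(loci=loci, lines=lines, calls=calls)


def write_genotypes(
    matrix: GenotypeMatrix, path: str | Path, format: str = "hapmap"
) -> None:
    """Write a genotype matrix in the HapMap dialect (round-trips exactly)."""
    if format not in ("hapmap", "tsv"):
        raise ValueError(f"unknown genotype format {format!r}")
    header = (
        ["rs#", "alleles", "chrom", "pos"]
        if format == "hapmap"
        else ["snp_id", "alleles", "chromosome", "position"]
    )
    loci = matrix.loci
    allele_a = loci["allele_a"].to_numpy()
    allele_b = loci["allele_b"].to_numpy()
    codes = np.empty((matrix.n_loci, 3), dtype="U1")
    codes[:, CALL_A] = allele_a
    codes[:, CALL_B] = allele_b
    codes[:, CALL_MISSING] = "N"  # index -1 → last column
    glyphs = codes[np.arange(matrix.n_loci)[:, None], matrix.calls]

    buf = _io.StringIO()
    buf.write("\t".join(header + list(matrix.lines)) + "\n")
    alleles = np.char.add(np.char.add(allele_a, "/"), allele_b)
    chroms = loci["chromosome"].to_numpy()
    positions = loci["position"].to_numpy()
    ids = loci["snp_id"].to_numpy()
    for i in range(matrix.n_loci):
        buf.write(
            f"{ids[i]}\t{alleles[i]}\t{chroms[i]}\t{positions[i]}\t"
            + "\t".join(glyphs[i])
            + "\n"
        )
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# association I/O

_ASSOC_COLS = ["snp_id", "chromosome", "position", "significance", "effect"]


def read_associations(
    path: str | Path, mode: str = "rimp", cutoff: float | None = None
) -> pd.DataFrame:
    """Read a GWAS association table and call significance.

    In ``rimp`` mode significance is a resampling model inclusion
    probability count and a signal is significant when ``significance >=
    cutoff`` (default cutoff 2); in ``pvalue`` mode significance must lie in
    (0, 1] and a signal is significant when ``significance <= cutoff``
    (default 0.05).

    Returns a DataFrame with columns ``snp_id, chromosome, position,
    significance, effect, is_significant`` sorted by (chromosome, position).
    """
    cutoff = _default_cutoff(mode, cutoff)
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"snp_id": str, "chromosome": str},
    )
    missing = [c for c in _ASSOC_COLS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing association columns {missing}")
    if "effect" not in df.columns:
        df["effect"] = np.nan
    df = df[_ASSOC_COLS].copy()
    df["position"] = pd.to_numeric(df["position"], errors="raise").astype(np.int64)
    df["significance"] = pd.to_numeric(df["significance"], errors="raise")
    df["effect"] = pd.to_numeric(df["effect"], errors="coerce")
    return flag_significance(df, mode=mode, cutoff=cutoff, source=str(path))


def _default_cutoff(mode: str, cutoff: float | None) -> float:
    if mode not in ("rimp", "pvalue"):
        raise ValueError(f"unknown significance mode {mode!r}")
    if cutoff is None:
        return 2.0 if mode == "rimp" else 0.05
    return float(cutoff)


def flag_significance(
    df: pd.DataFrame,
    mode: str = "rimp",
    cutoff: float | None = None,
    source: str = "associations",
) -> pd.DataFrame:
    """Set ``is_significant`` per mode/cutoff and sort canonically."""
    cutoff = _default_cutoff(mode, cutoff)
    df = df.copy()
    sig = df["significance"].to_numpy(dtype=float)
    if (sig < 0).any():
        raise ValueError(f"{source}: negative significance value")
    if mode == "pvalue":
        bad = (sig <= 0) | (sig > 1)
        if bad.any():
            row = df.loc[bad].iloc[0]
            raise ValueError(
                f"{source}: p-value {row['significance']} for SNP "
                f"{row['snp_id']!r} outside (0, 1]"
            )
        df["is_significant"] = sig <= cutoff
    else:
        df["is_significant"] = sig >= cutoff
    df = df.sort_values(["chromosome", "position"], kind="stable")
    return df.reset_index(drop=True)


def write_associations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=_ASSOC_COLS)


# ---------------------------------------------------------------------------
# candidate-gene I/O

_GENE_COLS = ["gene_id", "chromosome", "start", "end", "annotation", "homology_class"]


def read_genes(path: str | Path) -> list[CandidateGene]:
    """Read a candidate-gene table, sorted by (chromosome, start)."""
    df = pd.read_csv(
        path, sep="\t", dtype={"gene_id": str, "chromosome": str}, keep_default_na=False
    )
    missing = [c for c in _GENE_COLS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing gene columns {missing}")
    if "annotation" not in df.columns:
        df["annotation"] = ""
    if "homology_class" not in df.columns:
        df["homology_class"] = "unknown"
    df["homology_class"] = df["homology_class"].replace("", "unknown")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate gene_id {dup.iloc[0]!r}")
    df = df.sort_values(["chromosome", "start"], kind="stable")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            CandidateGene(
                gene_id=str(row.gene_id),
                chromosome=str(row.chromosome),
                start=int(row.start),
                end=int(row.end),
                annotation=str(row.annotation),
                homology_class=str(row.homology_class),
            )
        )
    return genes


def write_genes(genes: Iterable[CandidateGene], path: str | Path) -> None:
    rows = [
        (g.gene_id, g.chromosome, g.start, g.end, g.annotation, g.homology_class)
        for g in genes
    ]
    pd.DataFrame(rows, columns=_GENE_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cross-file consistency


def match_associations(
    associations: pd.DataFrame, matrix: GenotypeMatrix
) -> pd.DataFrame:
    """Check that every association maps onto a genotyped locus.

    Matching is by ``snp_id`` when that id exists in the matrix, otherwise
    by (chromosome, position).  Any id found with a conflicting coordinate,
    or any coordinate absent from the matrix, raises — a mismatch between
    the GWAS table and the genotype panel is an input error, not something
    to repair silently.
    """
    loci = matrix.loci
    by_id = loci.set_index("snp_id")[["chromosome", "position"]]
    key = pd.MultiIndex.from_frame(loci[["chromosome", "position"]])
    for row in associations.itertuples(index=False):
        if row.snp_id in by_id.index:
            rec = by_id.loc[row.snp_id]
            if rec["chromosome"] != row.chromosome or int(rec["position"]) != int(
                row.position
            ):
                raise ValueError(
                    f"association {row.snp_id!r} at {row.chromosome}:"
                    f"{row.position} conflicts with genotyped locus at "
                    f"{rec['chromosome']}:{rec['position']}"
                )
        elif (row.chromosome, int(row.position)) not in key:
            raise ValueError(
                f"association {row.snp_id!r} at {row.chromosome}:"
                f"{row.position} has no genotyped locus"
            )
    return associations
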