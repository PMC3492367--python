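"""Minor-allele-frequency filtering and pairwise linkage disequilibrium.

LD between two biallelic loci is measured as r² = D² / (p_A p_a p_B p_b),
computed from two-locus haplotype counts.  Because the lines are homozygous
inbreds, each line contributes one observed haplotype and no phasing or EM
step is needed.  Missing calls are handled with pairwise-complete
observations; pairs with fewer than ``min_informative`` shared non-missing
lines are dropped so that tiny overlaps cannot manufacture spurious r² = 1.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from picara.io import CALL_MISSING, GenotypeMatrix

__all__ = ["compute_maf", "filter_maf", "pairwise_r2", "R2_TOL"]

logger = logging.getLogger(__name__)

# "perfect LD (r² = 1)" is tested as r2 >= 1 - R2_TOL
R2_TOL = 1e-9

_PAIR_COLUMNS = ["snp_a", "snp_b", "distance", "r2", "n_informative"]


def compute_maf(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-locus minor allele frequency over non-missing calls.

    Returns an array aligned with ``matrix.loci``; loci with every call
    missing get NaN (undefined) and should be removed by the caller.
    """
    calls = matrix.calls
    n_b = (calls == 1).sum(axis=1)
    n_obs = (calls != CALL_MISSING).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_b = np.where(n_obs > 0, n_b / np.maximum(n_obs, 1), np.nan)
    maf = np.minimum(freq_b, 1.0 - freq_b)
    maf[n_obs == 0] = np.nan
    return maf


def filter_maf(matrix: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Keep loci with MAF >= ``threshold`` (boundary inclusive).

    Loci whose MAF is undefined (all calls missing) are removed as well.
    Locus order is preserved.  An empty result is legal but logged.
    """
    maf = compute_maf(matrix)
    with np.errstate(invalid="ignore"):
        keep = maf >= threshold
    keep &= ~np.isnan(maf)
    if not keep.any():
        logger.warning(
            "MAF filter at %.3g removed all %d loci", threshold, matrix.n_loci
        )
    return matrix.subset(keep)


def pairwise_r2(
    matrix: GenotypeMatrix,
    chromosome: str,
    max_distance: Optional[int] = None,
    min_r2: Optional[float] = None,
    min_informative: int = 4,
    chunk: int = 512,
) -> pd.DataFrame:
    """All within-range LD pairs on one chromosome.

    Parameters
    ----------
    max_distance : bp or None
        Only pairs at most this far apart are enumerated (None = every
        pair).  A cap bounds the O(n²) enumeration on dense chromosomes.
    min_r2 : float or None
        If given, only rows with ``r2 >= min_r2 - R2_TOL`` are returned —
        a materialisation filter, the computation is unchanged.
    min_informative : int
        Minimum shared non-missing lines; smaller pairs are omitted.

    Returns
    -------
    DataFrame with columns ``snp_a, snp_b, distance, r2, n_informative``,
    one row per unordered pair (snp_a is the left locus).  Pairs that are
    monomorphic after missing-data removal (zero denominator) are omitted.
    """
    sl = matrix.chromosome_slice(chromosome)
    calls = matrix.calls[sl]
    positions = matrix.loci["position"].to_numpy()[sl]
    ids = matrix.loci["snp_id"].to_numpy()[sl]
    m = len(positions)
    if m < 2:
        return pd.DataFrame(columns=_PAIR_COLUMNS)

    valid = (calls != CALL_MISSING).astype(np.float64)
    dosage = (calls == 1).astype(np.float64)  # 1 for allele B, 0 otherwise

    out_frames: list[pd.DataFrame] = []
    for lo in range(0, m - 1, chunk):
        hi = min(lo + chunk, m)
        # partner window: loci to the right of lo, within max_distance of
        # every row in [lo, hi) — per-row trimming happens on the mask
        if max_distance is None:
            jhi = m
        else:
            jhi = int(np.searchsorted(positions, positions[hi - 1] + max_distance, "right"))
        jlo = lo
        if jhi - jlo < 2:
            continue
        V_i, V_j = valid[lo:hi], valid[jlo:jhi]
        D_i, D_j = dosage[lo:hi], dosage[jlo:jhi]

        n = V_i @ V_j.T  # shared non-missing lines
        n11 = D_i @ D_j.T  # haplotype B/B count
        nb_i = D_i @ V_j.T  # allele-B count at i over shared lines
        nb_j = V_i @ D_j.T

        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = nb_i / n
            p_j = nb_j / n
            disequilibrium = n11 / n - p_i * p_j
            denom = p_i * (1.0 - p_i) * p_j * (1.0 - p_j)
            r2 = disequilibrium * disequilibrium / denom

        rows = np.arange(lo, hi)[:, None]
        cols = np.arange(jlo, jhi)[None, :]
        mask = cols > rows  # upper triangle: each unordered pair once
        mask &= n >= min_informative
        mask &= denom > 0
        if max_distance is not None:
            mask &= (positions[jlo:jhi][None, :] - positions[lo:hi][:, None]) <= max_distance
        if min_r2 is not None:
            mask &= r2 >= min_r2 - R2_TOL
        if not mask.any():
            continue
        ii, jj = np.nonzero(mask)
        gi, gj = ii + lo, jj + jlo
        out_frames.append(
            pd.DataFrame(
                {
                    "snp_a": ids[gi],
                    "snp_b": ids[gj],
                    "distance": positions[gj] - positions[gi],
                    "r2": np.clip(r2[ii, jj], 0.0, 1.0),
                    "n_informative": n[ii, jj].astype(np.int64),
                }
            )
        )

    if not out_frames:
        return pd.DataFrame(columns=_PAIR_COLUMNS)
    out = pd.concat(out_frames, ignore_index=True)
    return out
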