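import numpy as np
import pandas as pd
import pytest

from picara.io import GenotypeMatrix


def matrix_from_calls(
    calls,
    chromosome: str = "chr1",
    positions=None,
    lines=None,
    snp_ids=None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a (loci x lines) array of 0/1/-1 codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n_loci, n_lines = calls.shape
    if positions is None:
        positions = np.arange(1, n_loci + 1) * 100
    if lines is None:
        lines = [f"L{j}" for j in range(n_lines)]
    if snp_ids is None:
        snp_ids = [f"s{i}" for i in range(n_loci)]
    loci = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chromosome": chromosome,
            "position": np.asarray(positions, dtype=np.int64),
            "allele_a": "A",
            "allele_b": "G",
        }
    )
    return GenotypeMatrix(loci=loci, lines=list(lines), calls=calls)


def random_matrix(rng: np.random.Generator, n_loci: int, n_lines: int,
                  missing_rate: float = 0.1) -> GenotypeMatrix:
    """Random biallelic matrix with missing calls, for oracle comparisons."""
    p = rng.uniform(0.1, 0.9, size=n_loci)
    calls = (rng.random((n_loci, n_lines)) < p[:, None]).astype(np.int8)
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = -1
    return matrix_from_calls(calls)


def r2_bruteforce(x: np.ndarray, y: np.ndarray):
    """Independent r² oracle: explicit 2x2 haplotype table → D → r².

    Returns (r2, n_informative), or (None, n) when either locus is
    monomorphic over the shared non-missing lines.
    """
    keep = (x != -1) & (y != -1)
    x, y = x[keep], y[keep]
    n = len(x)
    if n == 0:
        return None, 0
    n11 = int(np.sum((x == 1) & (y == 1)))
    n10 = int(np.sum((x == 1) & (y == 0)))
    n01 = int(np.sum((x == 0) & (y == 1)))
    n00 = int(np.sum((x == 0) & (y == 0)))
    p = (n11 + n10) / n
    q = (n11 + n01) / n
    denom = p * (1 - p) * q * (1 - q)
    if denom == 0:
        return None, n
    d = n11 / n - p * q
    return d * d / denom, n


@pytest.fixture(scope="session")
def small_fixture():
    from picara.simulate import simulate_fixture, small_config

    return simulate_fixture(small_config(seed=11))
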