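"""Vectorised without-replacement index sampling for permutation nulls.

Both permutation procedures in the pipeline draw k SNP indices out of n
without replacement, many times.  Two exact strategies are used:

* duplicate rejection — draw k with replacement, redraw rows containing a
  duplicate.  Conditioning a uniform i.i.d. draw on "all distinct" yields
  exactly the uniform distinct-tuple law; cheap when k² << n.
* random-key selection — argpartition of one uniform key per index
  (Gumbel-free top-k); O(n) per row, used when rejection would thrash.
"""

from __future__ import annotations

import numpy as np

__all__ = ["sample_without_replacement"]


def sample_without_replacement(
    rng: np.random.Generator, n: int, k: int, n_draws: int
) -> np.ndarray:
    """(n_draws, k) matrix of distinct indices in [0, n), uniform per row."""
    if k > n:
        raise ValueError(f"cannot draw {k} distinct indices from {n}")
    if k == 0:
        return np.empty((n_draws, 0), dtype=np.int64)
    # expected duplicate probability per row ~ k(k-1)/(2n)
    if k * k <= 0.25 * n:
        idx = rng.integers(0, n, size=(n_draws, k), dtype=np.int64)
        while True:
            srt = np.sort(idx, axis=1)
            bad = np.flatnonzero((srt[:, 1:] == srt[:, :-1]).any(axis=1))
            if bad.size == 0:
                return idx
            idx[bad] = rng.integers(0, n, size=(bad.size, k), dtype=np.int64)
    # key-based path, chunked to bound the (chunk, n) key matrix at ~64 MB
    chunk = max(1, int(8e6 // max(n, 1)))
    out = np.empty((n_draws, k), dtype=np.int64)
    for lo in range(0, n_draws, chunk):
        hi = min(lo + chunk, n_draws)
        keys = rng.random((hi - lo, n))
        out[lo:hi] = np.argpartition(keys, k - 1, axis=1)[:, :k]
    # argpartition's within-row order is arbitrary but not exchangeable;
    # re-shuffle rows so tuple order is uniform (pairing downstream is fair)
    order = np.argsort(rng.random((n_draws, k)), axis=1)
    return np.take_along_axis(out, order, axis=1)
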