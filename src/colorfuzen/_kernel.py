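"""Pairwise-template distance kernel shared by the three entropy measures.

Each anchor's template at size m+1 is flattened to a row of ``T``; the
columns are ordered so that the first ``csub`` components form the
size-m template (the m-template is geometrically nested inside the
(m+1)-template, so one sweep over the row yields both Chebyshev
distances).  A numba loop fills per-row-block distance buffers; the
r-dependent fuzzy memberships exp(-d^n / r) are then evaluated with
vectorized numpy over the buffer, for a whole vector of tolerances at
once (the distance pass dominates the cost and is r-independent, which
makes tolerance sweeps cheap).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["pair_similarity_sums"]

# pairs held in the distance buffer at a time (~2 x 32 MB of float64)
_BLOCK_PAIRS = 1 << 22


@njit(cache=True, fastmath=True)
def _block_distances(T, csub, i0, i1, d_m, d_m1):  # pragma: no cover - jitted
    """Chebyshev distances at sizes m and m+1 for all unordered pairs
    (i, j), i0 <= i < i1, j > i.  Returns the number of pairs written."""
    N, C = T.shape
    idx = 0
    for i in range(i0, i1):
        for j in range(i + 1, N):
            dm = 0.0
            for c in range(csub):
                diff = abs(T[i, c] - T[j, c])
                if diff > dm:
                    dm = diff
            dm1 = dm
            for c in range(csub, C):
                diff = abs(T[i, c] - T[j, c])
                if diff > dm1:
                    dm1 = diff
            d_m[idx] = dm
            d_m1[idx] = dm1
            idx += 1
    return idx


def _accumulate(buf: np.ndarray, n: float, rs: np.ndarray,
                out: np.ndarray) -> None:
    powered = buf * buf if n == 2.0 else buf ** n
    for q, r in enumerate(rs):
        out[q] += np.exp(powered / (-r)).sum()


def pair_similarity_sums(T: np.ndarray, csub: int, n: float,
                         rs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sums of exp(-d^n / r) over all unordered anchor pairs.

    Returns (sum_m, sum_m1), each of shape (len(rs),).  The mean over
    ordered pairs is 2 * sum / (N * (N - 1)).
    """
    N = T.shape[0]
    sum_m = np.zeros(rs.shape[0])
    sum_m1 = np.zeros(rs.shape[0])
    total_pairs = N * (N - 1) // 2
    cap = max(min(_BLOCK_PAIRS, total_pairs), N - 1)  # fits >= one row
    d_m = np.empty(cap)
    d_m1 = np.empty(cap)
    i0 = 0
    while i0 < N - 1:
        # grow the row block while its pair count fits the buffer
        i1, pairs = i0, 0
        while i1 < N - 1 and pairs + (N - 1 - i1) <= cap:
            pairs += N - 1 - i1
            i1 += 1
        cnt = _block_distances(T, csub, i0, i1, d_m, d_m1)
        _accumulate(d_m[:cnt], n, rs, sum_m)
        _accumulate(d_m1[:cnt], n, rs, sum_m1)
        i0 = i1
    return sum_m, sum_m1
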