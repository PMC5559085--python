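"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths under test: the local-alignment
oracle is a plain affine-gap Smith-Waterman DP over numpy rows, and the
merge oracle scores every overlap offset directly.
"""

from __future__ import annotations

import numpy as np

MATCH, MISMATCH, OPEN, EXTEND = 1.0, -1.0, -3.0, -1.0


def sw_score(a: str, b: str) -> float:
    """Best local alignment score of ``a`` vs ``b`` (affine gaps).

    Row-wise DP: within-row gap maxima are folded in exactly via the
    running-maximum identity E[j] = ext*j + open + max_{k<j}(H[k] - ext*k).
    """
    A = np.frombuffer(a.encode(), dtype=np.uint8)
    B = np.frombuffer(b.encode(), dtype=np.uint8)
    m = len(B)
    neg = -1e18
    h_prev = np.zeros(m + 1)
    f = np.full(m + 1, neg)
    best = 0.0
    for i in range(1, len(A) + 1):
        s = np.where(B == A[i - 1], MATCH, MISMATCH)
        f = np.maximum(f + EXTEND, h_prev + OPEN + EXTEND)
        h_no_e = np.maximum(0.0, np.maximum(np.concatenate(([neg], h_prev[:-1] + s)), f))
        # gaps in the second sequence (within-row dependency)
        idx = np.arange(m + 1)
        run = np.maximum.accumulate(h_no_e - EXTEND * idx)
        e = np.concatenate(([neg], (OPEN + EXTEND * idx[1:]) + run[:-1]))
        h = np.maximum(h_no_e, np.maximum(e, 0.0))
        best = max(best, float(h.max()))
        h_prev = h
    return best


def brute_force_merge(seq1: str, rc2: str, min_overlap: int, max_rate: float):
    """All-offset overlap scoring; returns (matches, overlap_len) or None."""
    best = None
    for L in range(min(len(seq1), len(rc2)), min_overlap - 1, -1):
        matches = sum(x == y for x, y in zip(seq1[-L:], rc2[:L]))
        if (L - matches) / L > max_rate:
            continue
        if best is None or matches > best[0]:
            best = (matches, L)
    return best


def tally_counts(values) -> tuple[int, int, int]:
    """Brute-force S_obs, F1, F2 from raw observation labels."""
    from collections import Counter

    c = Counter(values)
    return (
        len(c),
        sum(1 for v in c.values() if v == 1),
        sum(1 for v in c.values() if v == 2),
    )
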