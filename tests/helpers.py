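"""Independent oracles used by the test suite.

Kept deliberately separate from the package: brute-force interval scans and
a full quadratic dynamic-programming fit aligner (numba-compiled) against
which the package's implementations are checked.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -10**9


@njit(cache=False)
def _fit_dp(q: np.ndarray, t: np.ndarray, match: int, mismatch: int,
            gap_open: int, gap_extend: int) -> int:
    """Best fit-alignment score: query global, target local, affine gaps
    (a gap of length l costs open + (l-1)*extend).  Plain O(m*n) DP."""
    m, n = len(q), len(t)
    M_prev = np.zeros(n + 1, dtype=np.int64)  # empty query prefix: free start
    D_prev = np.full(n + 1, NEG_INF, dtype=np.int64)
    I_prev = np.full(n + 1, NEG_INF, dtype=np.int64)
    M_cur = np.empty(n + 1, dtype=np.int64)
    D_cur = np.empty(n + 1, dtype=np.int64)
    I_cur = np.empty(n + 1, dtype=np.int64)
    for i in range(1, m + 1):
        M_cur[0] = NEG_INF
        D_cur[0] = NEG_INF
        best0 = M_prev[0]
        if I_prev[0] > best0:
            best0 = I_prev[0]
        I_cur[0] = max(M_prev[0] + gap_open, I_prev[0] + gap_extend,
                       D_prev[0] + gap_open)
        for j in range(1, n + 1):
            s = match if q[i - 1] == t[j - 1] else mismatch
            diag = M_prev[j - 1]
            if D_prev[j - 1] > diag:
                diag = D_prev[j - 1]
            if I_prev[j - 1] > diag:
                diag = I_prev[j - 1]
            M_cur[j] = s + diag
            D_cur[j] = max(M_cur[j - 1] + gap_open, D_cur[j - 1] + gap_extend,
                           I_cur[j - 1] + gap_open)
            I_cur[j] = max(M_prev[j] + gap_open, I_prev[j] + gap_extend,
                           D_prev[j] + gap_open)
        M_prev, M_cur = M_cur, M_prev
        D_prev, D_cur = D_cur, D_prev
        I_prev, I_cur = I_cur, I_prev
    best = NEG_INF
    for j in range(n + 1):
        if M_prev[j] > best:
            best = M_prev[j]
        if I_prev[j] > best:
            best = I_prev[j]
    return best


def fit_alignment_score(query: str, target: str, match=5, mismatch=-4,
                        gap_open=-12, gap_extend=-4) -> int:
    q = np.frombuffer(query.encode(), dtype=np.uint8).astype(np.int64)
    t = np.frombuffer(target.encode(), dtype=np.uint8).astype(np.int64)
    return int(_fit_dp(q, t, match, mismatch, gap_open, gap_extend))


def brute_intersect(a_list, b_list):
    """Quadratic all-pairs overlap scan (half-open)."""
    out = []
    for a in a_list:
        for b in b_list:
            if a.seq_name == b.seq_name and max(a.start, b.start) < min(a.end, b.end):
                out.append((a, b, min(a.end, b.end) - max(a.start, b.start)))
    return out


def brute_closest(query, features):
    """Linear scan for all minimal-distance features (gap distance)."""
    best, best_d = [], None
    for f in features:
        if f.seq_name != query.seq_name:
            continue
        if max(f.start, query.start) < min(f.end, query.end):
            d = 0
        elif f.end <= query.start:
            d = query.start - f.end
        else:
            d = f.start - query.end
        if best_d is None or d < best_d:
            best, best_d = [f], d
        elif d == best_d:
            best.append(f)
    return best, best_d


def covered_bases(intervals) -> int:
    """Size of the set-union of intervals, by explicit base enumeration."""
    seen = set()
    for iv in intervals:
        for pos in range(iv.start, iv.end):
            seen.add((iv.seq_name, pos))
    return len(seen)


def base_set(intervals) -> set:
    out = set()
    for iv in intervals:
        for pos in range(iv.start, iv.end):
            out.add((iv.seq_name, pos))
    return out
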