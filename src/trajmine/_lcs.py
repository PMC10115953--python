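"""Numba kernels for longest-common-subsequence distances on state sequences.

The accelerated DP exploits run-length structure: daily treatment sequences
are long runs of identical states, so one side is processed run by run. For a
run of symbol ``c`` with length ``l`` appended to prefix ``x``, the
concatenation split identity

    LCS(x . c^l, y[:j]) = max_t  LCS(x, y[:t]) + min(l, count_c(y[t:j]))

turns the per-run row update into a sliding-window maximum (the window
boundary where ``count_c`` saturates at ``l`` is monotone in ``j``), giving
O(runs(x) * len(y)) per pair instead of O(len(x) * len(y)). The result is
exactly the naive DP value; tests assert equality on thousands of random
pairs.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def lcs_length_naive(x, y):  # pragma: no cover - oracle path, exercised via tests
    """Textbook O(|x|*|y|) LCS dynamic program."""
    n, m = x.shape[0], y.shape[0]
    prev = np.zeros(m + 1, dtype=np.int32)
    cur = np.zeros(m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if x[i - 1] == y[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev, cur = cur, prev
    return prev[m]


@njit(cache=True)
def _lcs_length_rle(run_sym, run_len, y):
    """LCS length of (run-encoded x) vs y via the per-run split identity."""
    m = y.shape[0]
    old = np.zeros(m + 1, dtype=np.int32)
    new = np.zeros(m + 1, dtype=np.int32)
    C = np.zeros(m + 1, dtype=np.int32)
    dq = np.zeros(m + 1, dtype=np.int32)
    for r in range(run_sym.shape[0]):
        c = run_sym[r]
        l = run_len[r]
        for j in range(1, m + 1):
            C[j] = C[j - 1] + (1 if y[j - 1] == c else 0)
        head = 0
        tail = 0
        t1 = -1
        for j in range(m + 1):
            gj = old[j] - C[j]
            while tail > head and old[dq[tail - 1]] - C[dq[tail - 1]] <= gj:
                tail -= 1
            dq[tail] = j
            tail += 1
            # largest t with C[t] <= C[j] - l (saturated window); monotone in j
            while t1 + 1 <= j and C[t1 + 1] <= C[j] - l:
                t1 += 1
            while head < tail and dq[head] <= t1:
                head += 1
            t = dq[head]
            best = C[j] + old[t] - C[t]
            if t1 >= 0 and old[t1] + l > best:
                best = old[t1] + l
            new[j] = best
        old, new = new, old
    return old[m]


@njit(cache=True)
def _encode_runs(x):
    sym = np.empty(x.shape[0], dtype=x.dtype)
    length = np.empty(x.shape[0], dtype=np.int32)
    k = 0
    i = 0
    n = x.shape[0]
    while i < n:
        j = i + 1
        while j < n and x[j] == x[i]:
            j += 1
        sym[k] = x[i]
        length[k] = j - i
        k += 1
        i = j
    return sym[:k], length[:k]


@njit(cache=True)
def lcs_length(x, y):
    """Exact LCS length; the side with fewer runs is run-encoded."""
    sx, lx = _encode_runs(x)
    sy, ly = _encode_runs(y)
    if sx.shape[0] <= sy.shape[0]:
        return _lcs_length_rle(sx, lx, y)
    return _lcs_length_rle(sy, ly, x)


@njit(cache=True)
def pairwise_lcs_matrix(seqs):
    """All-pairs LCS distances |x|+|y|-2L for rows of an (n, m) int array."""
    n, m = seqs.shape
    out = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        si, li = _encode_runs(seqs[i])
        for j in range(i + 1, n):
            L = _lcs_length_rle(si, li, seqs[j])
            d = 2.0 * (m - L)
            out[i, j] = d
            out[j, i] = d
    return out


@njit(cache=True)
def composite_om_distance(a, b, indel):
    """Optimal-matching edit distance on composite multi-channel states.

    ``a`` and ``b`` are (channels, days) arrays; substituting day i for day j
    costs 2 per differing channel, an indel costs ``indel`` (the per-channel
    LCS indel cost of 1, summed over channels, for 3 channels: 3).
    """
    n = a.shape[1]
    m = b.shape[1]
    ch = a.shape[0]
    prev = np.empty(m + 1, dtype=np.float64)
    cur = np.empty(m + 1, dtype=np.float64)
    for j in range(m + 1):
        prev[j] = indel * j
    for i in range(1, n + 1):
        cur[0] = indel * i
        for j in range(1, m + 1):
            sub = 0.0
            for c in range(ch):
                if a[c, i - 1] != b[c, j - 1]:
                    sub += 2.0
            best = prev[j - 1] + sub
            if prev[j] + indel < best:
                best = prev[j] + indel
            if cur[j - 1] + indel < best:
                best = cur[j - 1] + indel
            cur[j] = best
        prev, cur = cur, prev
    return prev[m]
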