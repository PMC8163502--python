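"""Lempel-Ziv 1976 exhaustive-history parsing of binary sequences.

The complexity of a finite symbol sequence is the number of words in its
exhaustive history: scanning left to right, each word is the shortest prefix
of the remaining suffix that cannot be produced by copying from an earlier
starting position (self-referential copying with overlap is allowed, as in
the original production-process definition). The final word may itself be
producible.

Two routes are provided:

``lz76_word_count_slow``
    Direct transcription of the definition; quadratic/cubic, used as a
    reference for exhaustive cross-checks on short strings.

``lz76_word_count``
    Linear-time route: suffix array (prefix doubling with counting sort),
    LCP by Kasai's algorithm, longest-previous-factor (LPF) by the
    stack-based algorithm of Crochemore & Ilie, then the factorization
    ``word_len = LPF + 1``. Compiled with numba; this is the path used for
    the 21-channel x 1000-sample windows where ~10^5 parses are needed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


def lz76_word_count_slow(bits) -> int:
    """Count exhaustive-history words by brute-force producibility search.

    ``bits`` is any sequence of 0/1 (or booleans). Quadratic in length;
    intended for validation, not production use.
    """
    s = "".join("1" if int(b) else "0" for b in bits)
    n = len(s)
    if n == 0:
        raise ValueError("empty sequence")
    p = 0
    c = 0
    while p < n:
        # grow l while s[p:p+l] is producible from an earlier start (< p),
        # overlap with the word itself allowed
        l = 0
        while p + l < n:
            cand = s[p : p + l + 1]
            if any(s[j : j + l + 1] == cand for j in range(p)):
                l += 1
            else:
                break
        if p + l >= n:
            # producible prefix reaches the end: last word is reproducible
            p = n
        else:
            p += l + 1
        c += 1
    return c


@njit(cache=True)
def _lz76_count(s):  # pragma: no cover - exercised via lz76_word_count
    n = s.shape[0]
    if n == 1:
        return 1

    # --- suffix array via prefix doubling + counting sort -------------
    sa = np.empty(n, np.int64)
    sa2 = np.empty(n, np.int64)
    rank = np.empty(n, np.int64)
    tmp = np.empty(n, np.int64)
    cnt = np.zeros(n + 2, np.int64)

    for i in range(n):
        rank[i] = s[i]
        sa[i] = i
    # initial sort by single symbol
    for i in range(n + 2):
        cnt[i] = 0
    for i in range(n):
        cnt[rank[i] + 1] += 1
    for i in range(1, n + 2):
        cnt[i] += cnt[i - 1]
    for i in range(n):
        sa[cnt[rank[i]]] = i
        cnt[rank[i]] += 1
    tmp[sa[0]] = 0
    for j in range(1, n):
        tmp[sa[j]] = tmp[sa[j - 1]] + (0 if rank[sa[j]] == rank[sa[j - 1]] else 1)
    for i in range(n):
        rank[i] = tmp[i]

    k = 1
    while rank[sa[n - 1]] != n - 1:
        # order by second key (rank[i+k], absent = smallest): suffixes with
        # i+k >= n first, then the rest in sa order shifted left by k
        p = 0
        for i in range(n - k, n):
            sa2[p] = i
            p += 1
        for j in range(n):
            if sa[j] >= k:
                sa2[p] = sa[j] - k
                p += 1
        # stable counting sort by first key rank[i]
        for i in range(n + 2):
            cnt[i] = 0
        for i in range(n):
            cnt[rank[i] + 1] += 1
        for i in range(1, n + 2):
            cnt[i] += cnt[i - 1]
        for j in range(n):
            i = sa2[j]
            sa[cnt[rank[i]]] = i
            cnt[rank[i]] += 1
        # re-rank
        tmp[sa[0]] = 0
        for j in range(1, n):
            a = sa[j - 1]
            b = sa[j]
            ka = rank[a + k] if a + k < n else -1
            kb = rank[b + k] if b + k < n else -1
            if rank[a] == rank[b] and ka == kb:
                tmp[b] = tmp[a]
            else:
                tmp[b] = tmp[a] + 1
        for i in range(n):
            rank[i] = tmp[i]
        k <<= 1

    # --- LCP (Kasai); lcp[r] = lcp(suffix sa[r-1], suffix sa[r]) ------
    lcp = np.zeros(n + 1, np.int64)
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and s[i + h] == s[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0

    # --- LPF (Crochemore & Ilie stack algorithm, overlap allowed) -----
    lpf = np.zeros(n, np.int64)
    stack_pos = np.empty(n + 1, np.int64)
    stack_lcp = np.empty(n + 1, np.int64)
    top = -1
    for i in range(n + 1):
        if i < n:
            pos = sa[i]
            cur = lcp[i]
        else:
            pos = -1
            cur = 0
        while top >= 0 and (
            pos < stack_pos[top] or (pos > stack_pos[top] and cur <= stack_lcp[top])
        ):
            if pos < stack_pos[top]:
                if stack_lcp[top] > cur:
                    lpf[stack_pos[top]] = stack_lcp[top]
                else:
                    lpf[stack_pos[top]] = cur
                if stack_lcp[top] < cur:
                    cur = stack_lcp[top]
            else:
                lpf[stack_pos[top]] = stack_lcp[top]
            top -= 1
        if i < n:
            top += 1
            stack_pos[top] = pos
            stack_lcp[top] = cur

    # --- exhaustive parsing: each word = LPF producible chars + 1 -----
    c = 0
    i = 0
    while i < n:
        c += 1
        i += lpf[i] + 1
    return c


def lz76_word_count(bits) -> int:
    """Number of words in the LZ76 exhaustive-history parsing of ``bits``."""
    arr = np.ascontiguousarray(np.asarray(bits).ravel(), dtype=np.uint8)
    if arr.size == 0:
        raise ValueError("empty sequence")
    return int(_lz76_count(arr))


@njit(cache=True)
def _lzc_raw_and_surrogate_mean(bits, n_surrogates, seed):
    """Raw LZ76 count of the column-major flattening of ``bits`` plus the
    mean count over surrogates that shuffle each row independently.

    Runs entirely in compiled code; the surrogate stream is numba's
    MT19937 seeded with ``seed``.
    """
    n_ch, n_t = bits.shape
    n = n_ch * n_t
    seq = np.empty(n, np.uint8)
    for t in range(n_t):
        for c in range(n_ch):
            seq[t * n_ch + c] = bits[c, t]
    raw = _lz76_count(seq)

    np.random.seed(seed)
    perm = np.empty(n_t, np.int64)
    total = 0.0
    for _ in range(n_surrogates):
        for c in range(n_ch):
            # Fisher-Yates permutation of row c, written column-major
            for t in range(n_t):
                perm[t] = t
            for t in range(n_t - 1, 0, -1):
                j = np.random.randint(0, t + 1)
                perm[t], perm[j] = perm[j], perm[t]
            for t in range(n_t):
                seq[t * n_ch + c] = bits[c, perm[t]]
        total += _lz76_count(seq)
    return raw, total / n_surrogates
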