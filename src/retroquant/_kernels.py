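"""Numba kernels for the alignment dynamic programme.

The DP runs in *reversed* coordinates (read and reference window reversed)
so that every alignment *start* in the original orientation becomes an
alignment *end* here and per-start optima fall out of single columns.

Alignments are canonical: they begin and end with a diagonal op
(match/mismatch); clips absorb would-be terminal gaps.  A fresh start
(free reference end plus read clip) enters only through the diagonal value
E, and finalisation is taken from E only, which enforces canonical ends.

Cell values are a single int64 scalarisation of the lexicographic objective
(score desc, aligned-read-bases desc, matches desc, deleted-bases asc),
where score = matches - mismatch_cost*mm - ins_cost*ins - del_cost*del:

    value = (-score)*B^3 - A*B^2 - M*B + D

with B a power of two exceeding every component magnitude; weights are
additive per DP transition, so the minimum value is the lexicographic
optimum and the component counts decode uniquely from it.
"""
import numpy as np
from numba import njit

INF = np.int64(1) << 62


@njit(cache=True, nogil=True)
def dp_scan(rd_rev, ref_rev, wm, wx, wi, wd, clamp):
    """Best diagonal-entry finalisation value per reference column.

    rd_rev/ref_rev: uint8 codes (A..T = 0..3, N = 4), reversed orientation.
    Fresh starts (value 0) are allowed before any diagonal step, at any cell:
    in the original orientation this is a free reference end plus an
    unconstrained trailing clip.

    Returns (best, best_i) arrays over columns 0..N; original-space
    placement start for column j is ``N - j`` (window-local).
    """
    L = rd_rev.shape[0]
    N = ref_rev.shape[0]
    best = np.full(N + 1, INF, np.int64)
    best_i = np.full(N + 1, -1, np.int32)
    prev = np.full(N + 1, INF, np.int64)
    cur = np.empty(N + 1, np.int64)
    for i in range(1, L + 1):
        c = rd_rev[i - 1]
        cur[0] = INF  # no diagonal or vertical entry into column 0
        if prev[0] != INF:
            v = prev[0] + wi
            if v < clamp:
                cur[0] = v
        for j in range(1, N + 1):
            t = ref_rev[j - 1]
            d = prev[j - 1]
            if d > 0:  # fresh start dominates any positive prefix
                d = 0
            if c == t and c < 4:
                e = d + wm
            else:
                e = d + wx
            if e >= clamp:
                e = INF
            v = e
            if prev[j] != INF:
                v2 = prev[j] + wi
                if v2 < v:
                    v = v2
            if cur[j - 1] != INF:
                v3 = cur[j - 1] + wd
                if v3 < v:
                    v = v3
            if v >= clamp:
                v = INF
            cur[j] = v
            if e < best[j]:
                best[j] = e
                best_i[j] = i
        tmp = prev
        prev = cur
        cur = tmp
    return best, best_i


@njit(cache=True, nogil=True)
def dp_matrix(rd_rev, ref_rev, wm, wx, wi, wd, clamp):
    """Full overall-value (F) matrix (for traceback of winners)."""
    L = rd_rev.shape[0]
    N = ref_rev.shape[0]
    F = np.full((L + 1, N + 1), INF, np.int64)
    for i in range(1, L + 1):
        c = rd_rev[i - 1]
        v = INF
        if F[i - 1, 0] != INF:
            v = F[i - 1, 0] + wi
            if v >= clamp:
                v = INF
        F[i, 0] = v
        for j in range(1, N + 1):
            t = ref_rev[j - 1]
            d = F[i - 1, j - 1]
            if d > 0:
                d = 0
            if c == t and c < 4:
                v = d + wm
            else:
                v = d + wx
            if F[i - 1, j] != INF:
                v2 = F[i - 1, j] + wi
                if v2 < v:
                    v = v2
            if F[i, j - 1] != INF:
                v3 = F[i, j - 1] + wd
                if v3 < v:
                    v = v3
            if v >= clamp:
                v = INF
            F[i, j] = v
    return F


@njit(cache=True, nogil=True)
def build_kmer_index(refc, k):
    """Counting-sort k-mer index of a reference (k-mers containing N skipped).

    Returns (starts, positions): positions[starts[code]:starts[code+1]] are
    the reference offsets whose k-mer has that code.
    """
    N = refc.shape[0]
    M = 1
    for _ in range(k):
        M *= 4
    n = N - k + 1
    starts = np.zeros(M + 1, np.int64)
    if n <= 0:
        return starts, np.empty(0, np.int64)
    codes = np.full(n, -1, np.int64)
    for s in range(n):
        code = 0
        ok = True
        for t in range(k):
            b = refc[s + t]
            if b > 3:
                ok = False
                break
            code = code * 4 + b
        if ok:
            codes[s] = code
    for s in range(n):
        if codes[s] >= 0:
            starts[codes[s] + 1] += 1
    for m in range(M):
        starts[m + 1] += starts[m]
    positions = np.empty(starts[M], np.int64)
    fill = starts.copy()
    for s in range(n):
        c = codes[s]
        if c >= 0:
            positions[fill[c]] = s
            fill[c] += 1
    return starts, positions


@njit(cache=True, nogil=True)
def seed_implied_starts(rdc, k, starts, positions):
    """Implied placement starts from exact matches of non-overlapping read
    segments against the k-mer index (pigeonhole seeding)."""
    L = rdc.shape[0]
    nseg = L // k
    total = 0
    for seg in range(nseg):
        off = seg * k
        code = 0
        ok = True
        for t in range(k):
            b = rdc[off + t]
            if b > 3:
                ok = False
                break
            code = code * 4 + b
        if ok:
            total += starts[code + 1] - starts[code]
    out = np.empty(total, np.int64)
    w = 0
    for seg in range(nseg):
        off = seg * k
        code = 0
        ok = True
        for t in range(k):
            b = rdc[off + t]
            if b > 3:
                ok = False
                break
            code = code * 4 + b
        if ok:
            for p in range(starts[code], starts[code + 1]):
                out[w] = positions[p] - off
                w += 1
    return out
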