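"""Slow reference implementation of the alignment contract.

``oracle_align`` enumerates, by exhaustive dynamic programming over every
reference start position and both strands, the same accepted maximum-score
placements that :func:`retroquant.align.align_read` returns.  It shares the
*definition* of the objective (the lexicographic score / aligned-bases /
matches / deletions order, canonical alignment ends, and the two acceptance
filters) but none of the search machinery: it is a vectorised numpy row
sweep with its own traceback, used to validate the production engines on
randomized inputs.
"""
from __future__ import annotations

import math

import numpy as np

from .align import AlignmentHit, AlignParams, encode_seq, revcomp_codes

_INF = np.int64(1) << 62


class _OracleScoring:
    def __init__(self, params: AlignParams, L: int):
        s = params.similarity_min
        mm = int(params.mismatch_cost)
        ins = int(params.insertion_cost)
        dl = int(params.deletion_cost)
        self.L = L
        self.a_min = max(1, math.ceil(params.length_fraction_min * L - 1e-9))
        e_cap = int(math.floor(L * (1.0 - s) / s + 1e-9)) if s < 1.0 else 0
        wmax = max(mm, ins, dl)
        self.cost_cap = wmax * e_cap + wmax
        need = max(2 * L + 4, (self.cost_cap + L) // dl + 4)
        B = 1
        while B < need:
            B <<= 1
        self.B = B
        self.wm = np.int64(-(B**3) - B * B - B)
        self.wx = np.int64(mm * B**3 - B * B)
        self.wi = np.int64(ins * B**3 - B * B)
        self.wd = np.int64(dl * B**3 + 1)
        self.clamp = np.int64((self.cost_cap + 1) * B**3)

    def decode(self, value: int) -> tuple[int, int, int, int]:
        B = self.B
        v = int(value)
        D = v % B
        v2 = (v - D) // B
        M = (-v2) % B
        v3 = (v2 + M) // B
        A = (-v3) % B
        neg_score = (v3 + A) // B
        return neg_score, A, M, D


def _sweep(q_rev: np.ndarray, t_rev: np.ndarray, sc: _OracleScoring,
           keep_rows: bool = False):
    """Row sweep of the reversed-space local DP.

    Fresh starts (value 0) enter only through the diagonal value; the best
    diagonal-entry value per column (over all rows) is recorded, which
    enforces canonical alignment ends.

    Returns (best, best_i) per column, and optionally the list of overall
    row arrays (row index == read position) for traceback.
    """
    L = q_rev.shape[0]
    N = t_rev.shape[0]
    idx = np.arange(N + 1, dtype=np.int64)
    shift = idx * sc.wd
    prev = np.full(N + 1, _INF, dtype=np.int64)
    best = np.full(N + 1, _INF, dtype=np.int64)
    best_i = np.full(N + 1, -1, dtype=np.int64)
    rows = [prev.copy()] if keep_rows else None
    for i in range(1, L + 1):
        c = q_rev[i - 1]
        if c < 4:
            w_diag = np.where(t_rev == c, sc.wm, sc.wx)
        else:
            w_diag = np.full(N, sc.wx, dtype=np.int64)
        diag = np.full(N + 1, _INF, dtype=np.int64)
        diag[1:] = np.minimum(prev[:-1], 0) + w_diag
        diag[diag >= sc.clamp] = _INF
        base = np.minimum(diag, prev + sc.wi)
        cur = np.minimum.accumulate(base - shift) + shift
        cur[cur >= sc.clamp] = _INF
        better = diag < best
        best[better] = diag[better]
        best_i[better] = i
        prev = cur
        if keep_rows:
            rows.append(cur.copy())
    return best, best_i, rows


def _oracle_traceback(q_rev, t_rev, i_end, j_end, value, sc: _OracleScoring):
    _, _, rows = _sweep(q_rev, t_rev, sc, keep_rows=True)

    def F(i, j):
        return int(rows[i][j])

    i, j = int(i_end), int(j_end)
    ops: list[str] = []
    nM = nX = nI = nD = 0
    v = int(value)
    while True:
        took = False
        if i > 0 and j > 0:
            c = q_rev[i - 1]
            t = t_rev[j - 1]
            ismatch = bool(c == t and c < 4)
            w = int(sc.wm) if ismatch else int(sc.wx)
            d = F(i - 1, j - 1)
            dmin = 0 if d > 0 else d
            if not ops:
                if dmin + w != v:
                    raise AssertionError("oracle traceback failed at the entry step")
                take_diag = True
            else:
                take_diag = dmin + w == v
            if take_diag:
                ops.append("=" if ismatch else "X")
                if ismatch:
                    nM += 1
                else:
                    nX += 1
                i -= 1
                j -= 1
                v = dmin
                took = True
                if v == 0:
                    break
        if took:
            continue
        if i > 0 and F(i - 1, j) != int(_INF) and F(i - 1, j) + int(sc.wi) == v:
            ops.append("I")
            nI += 1
            i -= 1
            v = F(i, j)
            continue
        if j > 0 and F(i, j - 1) != int(_INF) and F(i, j - 1) + int(sc.wd) == v:
            ops.append("D")
            nD += 1
            j -= 1
            v = F(i, j)
            continue
        raise AssertionError("oracle traceback failed")
    rle: list[tuple[str, int]] = []
    for op in ops:
        if rle and rle[-1][0] == op:
            rle[-1] = (op, rle[-1][1] + 1)
        else:
            rle.append((op, 1))
    return rle, nM, nX, nI, nD, i


def oracle_align(
    read: str,
    references: dict[str, str],
    params: AlignParams | None = None,
    read_id: str = "read",
) -> list[AlignmentHit]:
    """Exhaustive-DP hit set for ``read`` (validation oracle)."""
    params = params or AlignParams()
    read = read.upper().replace("U", "T")
    qc = encode_seq(read)
    L = qc.shape[0]
    sc = _OracleScoring(params, L)
    items = list(references.items())
    cands: dict[tuple[int, str, int], tuple[int, int]] = {}
    for ref_idx, (_, refseq) in enumerate(items):
        tc = encode_seq(refseq.upper().replace("U", "T"))
        t_rev = tc[::-1].copy()
        N = tc.shape[0]
        for strand in ("+", "-"):
            q = qc if strand == "+" else revcomp_codes(qc)
            q_rev = q[::-1].copy()
            best, best_i, _ = _sweep(q_rev, t_rev, sc)
            (cols,) = np.nonzero(best < _INF)
            for j in cols:
                j = int(j)
                key = (ref_idx, strand, N - j)
                val = int(best[j])
                old = cands.get(key)
                if old is None or val < old[0]:
                    cands[key] = (val, int(best_i[j]))

    accepted = []
    for (ref_idx, strand, s), (val, i_end) in cands.items():
        neg_score, A, M, D = sc.decode(val)
        if A + D == 0:
            continue
        if M / (A + D) < params.similarity_min - 1e-9:
            continue
        if A / L < params.length_fraction_min - 1e-9:
            continue
        accepted.append((neg_score, ref_idx, strand, s, val, i_end))
    if not accepted:
        return []
    top = min(a[0] for a in accepted)
    winners = sorted(
        (a for a in accepted if a[0] == top), key=lambda a: (a[1], a[2], a[3])
    )
    hits = []
    for _negS, ref_idx, strand, s, val, i_end in winners:
        name, refseq = items[ref_idx]
        tc = encode_seq(refseq.upper().replace("U", "T"))
        N = tc.shape[0]
        q = qc if strand == "+" else revcomp_codes(qc)
        j_end = N - s
        rle, nM, nX, nI, nD, trail = _oracle_traceback(
            q[::-1].copy(), tc[::-1].copy(), i_end, j_end, val, sc
        )
        lead = L - i_end
        full_ops = []
        if lead:
            full_ops.append(("S", lead))
        full_ops.extend(rle)
        if trail:
            full_ops.append(("S", trail))
        A = nM + nX + nI
        hits.append(
            AlignmentHit(
                read_id=read_id,
                ref_id=name,
                ref_start=s,
                strand=strand,
                ops=tuple(full_ops),
                n_match=nM,
                n_mismatch=nX,
                n_ins_bases=nI,
                n_del_bases=nD,
                n_clip_bases=lead + trail,
                cost=params.mismatch_cost * nX
                + params.insertion_cost * nI
                + params.deletion_cost * nD,
                similarity=nM / (nM + nX + nI + nD),
                length_fraction=A / L,
            )
        )
    return hits
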