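"""Read alignment against a consensus library or genome.

Implements the acceptance contract used throughout the pipeline: reads are
aligned on both strands with free end-clipping, a match reward of 1 and
linear penalties (mismatch 2, insertion 3, deletion 3 per base by default),
and a hit is accepted only when

* similarity  = matches / alignment columns (gap bases included) >= 0.9, and
* length fraction = aligned read bases / read length              >= 0.9,

both inclusive.  Alignments are canonical: they begin and end with an
aligned base pair (clips absorb would-be terminal gaps), as in conventional
read mappers.  For every placement ``(reference, strand, ref_start)`` the
*representative* alignment is the lexicographic optimum (maximum score,
then most aligned read bases, then most matches, then fewest deleted
bases); the filters are evaluated on that representative, and
``align_read`` returns all accepted placements attaining the maximum score.
A read is *unique* when exactly one placement attains that optimum, *multi*
otherwise.

Two engines share these semantics: an exhaustive one (full DP across each
reference) and a seeded one (pigeonhole k-mer seeding plus an edit-distance
window prefilter) that provably returns identical results and is the
default for references above a few kilobases.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

try:
    import edlib

    _HAVE_EDLIB = True
except ImportError:  # pragma: no cover - edlib is a hard dependency in practice
    _HAVE_EDLIB = False

from ._kernels import (
    INF,
    build_kmer_index,
    dp_matrix,
    dp_scan,
    seed_implied_starts,
)

MIN_READ_LENGTH = 20

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i
_ENCODE[ord("N")] = 4
_ENCODE[ord("n")] = 4

_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_RC_TABLE = bytes.maketrans(b"ACGTNacgtn", b"TGCANTGCAN")


def encode_seq(seq: str | bytes) -> np.ndarray:
    """Encode an ACGTN sequence as uint8 codes; reject other characters."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    codes = _ENCODE[np.frombuffer(seq, dtype=np.uint8)]
    if codes.size and codes.max() == 255:
        bad = chr(np.frombuffer(seq, dtype=np.uint8)[int(np.argmax(codes == 255))])
        raise ValueError(f"non-ACGTN character {bad!r} in sequence")
    return codes


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def revcomp(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


@dataclass(frozen=True)
class AlignParams:
    """Alignment acceptance parameters (defaults follow the pipeline contract)."""

    similarity_min: float = 0.9
    length_fraction_min: float = 0.9
    mismatch_cost: int = 2
    insertion_cost: int = 3
    deletion_cost: int = 3
    mode: str = "unique_only"  # or "multi_random"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.similarity_min <= 1.0):
            raise ValueError("similarity_min must be in (0, 1]")
        if not (0.0 < self.length_fraction_min <= 1.0):
            raise ValueError("length_fraction_min must be in (0, 1]")
        for name in ("mismatch_cost", "insertion_cost", "deletion_cost"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if self.mode not in ("unique_only", "multi_random"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class AlignmentHit:
    """One accepted placement of a read on a reference."""

    read_id: str
    ref_id: str
    ref_start: int
    strand: str
    ops: tuple[tuple[str, int], ...]
    n_match: int
    n_mismatch: int
    n_ins_bases: int
    n_del_bases: int
    n_clip_bases: int
    cost: int
    similarity: float
    length_fraction: float

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.n_match + self.n_mismatch + self.n_del_bases

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.ref_start + self.ref_end)

    @property
    def score(self) -> int:
        return self.n_match - self.cost


@dataclass
class ReadAssignment:
    """Final status of a read: unassigned, unique, or multi."""

    read_id: str
    status: str
    chosen_hit: AlignmentHit | None
    n_best_hits: int


class _Scoring:
    """Derived DP constants for one (params, read length) combination."""

    def __init__(self, params: AlignParams, read_len: int):
        s = params.similarity_min
        lf = params.length_fraction_min
        mm, ins, dl = (
            int(params.mismatch_cost),
            int(params.insertion_cost),
            int(params.deletion_cost),
        )
        L = read_len
        self.L = L
        self.a_min = max(1, math.ceil(lf * L - 1e-9))
        self.c_max = L - self.a_min
        self.e_cap = int(math.floor(L * (1.0 - s) / s + 1e-9)) if s < 1.0 else 0
        wmax = max(mm, ins, dl)
        self.cost_cap = wmax * self.e_cap + wmax
        need = max(2 * L + 4, (self.cost_cap + L) // dl + 4)
        B = 1
        while B < need:
            B <<= 1
        self.B = B
        # value = (-score)*B^3 - A*B^2 - M*B + D; per-op weight deltas:
        self.wm = np.int64(-(B**3) - B * B - B)  # match: score+1, A+1, M+1
        self.wx = np.int64(mm * B**3 - B * B)  # mismatch: score-mm, A+1
        self.wi = np.int64(ins * B**3 - B * B)  # insertion: score-ins, A+1
        self.wd = np.int64(dl * B**3 + 1)  # deletion: score-del, D+1
        self.clamp = np.int64((self.cost_cap + 1) * B**3)
        if (self.cost_cap + 3) * B**3 >= int(INF):
            raise ValueError("alignment parameters out of supported range")
        # pigeonhole seed length: every accepted alignment must leave at least
        # one of the floor(L/k) non-overlapping read segments intact.
        self.k = None
        for k in range(10, 3, -1):
            nseg = L // k
            if nseg >= self.e_cap + -(-self.c_max // k) + 3:
                self.k = k
                break
        self.margin_left = self.e_cap + self.c_max + 8
        self.margin_right = L + 2 * self.e_cap + 2 * self.c_max + 8
        self.edlib_threshold = self.e_cap + self.c_max + 1

    def decode(self, value: int) -> tuple[int, int, int, int]:
        """Decode (neg_score, aligned, matches, deletions) from a DP value."""
        B = self.B
        v = int(value)
        D = v % B
        v2 = (v - D) // B
        M = (-v2) % B
        v3 = (v2 + M) // B
        A = (-v3) % B
        neg_score = (v3 + A) // B
        return neg_score, A, M, D


@dataclass
class _Reference:
    name: str
    seq: str
    codes: np.ndarray
    kmer: dict = field(default_factory=dict)


class ReferenceIndex:
    """An indexed reference set (consensus library or genome) for alignment.

    ``seeded`` selects the engine: True/False force seeded or exhaustive
    search, None (default) picks the seeded engine for references longer than
    ~2 kb when a valid seed length exists for the read.
    """

    def __init__(
        self,
        references: dict[str, str] | Sequence[tuple[str, str]],
        seeded: bool | None = None,
    ):
        if isinstance(references, dict):
            items = list(references.items())
        else:
            items = [(n, s) for n, s in references]
        if not items:
            raise ValueError("reference set is empty")
        self.refs: list[_Reference] = []
        seen = set()
        for name, seq in items:
            if name in seen:
                raise ValueError(f"duplicate reference name {name!r}")
            seen.add(name)
            seq = seq.upper().replace("U", "T")
            self.refs.append(_Reference(name, seq, encode_seq(seq)))
        self.seeded = seeded
        self._scoring_cache: dict[tuple, _Scoring] = {}

    def names(self) -> list[str]:
        return [r.name for r in self.refs]

    def scoring(self, params: AlignParams, read_len: int) -> _Scoring:
        key = (
            params.similarity_min,
            params.length_fraction_min,
            params.mismatch_cost,
            params.insertion_cost,
            params.deletion_cost,
            read_len,
        )
        sc = self._scoring_cache.get(key)
        if sc is None:
            sc = _Scoring(params, read_len)
            self._scoring_cache[key] = sc
        return sc

    def _kmer_index(self, ref: _Reference, k: int):
        idx = ref.kmer.get(k)
        if idx is None:
            idx = build_kmer_index(ref.codes, k)
            ref.kmer[k] = idx
        return idx


def _merge_windows(imp: np.ndarray, sc: _Scoring, ref_len: int) -> list[tuple[int, int]]:
    imp = np.unique(imp)
    ws = np.maximum(imp - sc.margin_left, 0)
    we = np.minimum(imp + sc.margin_right, ref_len)
    merged: list[tuple[int, int]] = []
    cs, ce = int(ws[0]), int(we[0])
    for s_, e_ in zip(ws[1:], we[1:]):
        if int(s_) <= ce:
            ce = max(ce, int(e_))
        else:
            merged.append((cs, ce))
            cs, ce = int(s_), int(e_)
    merged.append((cs, ce))
    return merged


def _rle(ops: list[str]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op in ops:
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + 1)
        else:
            out.append((op, 1))
    return out


def _traceback(
    qc: np.ndarray,
    win_codes: np.ndarray,
    i_end: int,
    j_end: int,
    value: int,
    sc: _Scoring,
) -> tuple[list[tuple[str, int]], int, int, int, int, int, int]:
    """Recover ops and counts for a winning diagonal-entry finalisation.

    Returns (ops, n_match, n_mismatch, n_ins, n_del, trail_clip, j_start).
    """
    q_rev = qc[::-1].copy()
    w_rev = win_codes[::-1].copy()
    F = dp_matrix(q_rev, w_rev, sc.wm, sc.wx, sc.wi, sc.wd, sc.clamp)
    i, j = int(i_end), int(j_end)
    ops: list[str] = []
    nM = nX = nI = nD = 0
    v = int(value)
    while True:
        # diagonal step (mandatory for the first step; fresh start possible)
        took = False
        if i > 0 and j > 0:
            c = q_rev[i - 1]
            t = w_rev[j - 1]
            ismatch = c == t and c < 4
            w = int(sc.wm) if ismatch else int(sc.wx)
            d = int(F[i - 1, j - 1])
            dmin = 0 if d > 0 else d
            if not ops:
                if dmin + w != v:
                    raise AssertionError("traceback failed at the entry step")
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
        if i > 0 and F[i - 1, j] != INF and int(F[i - 1, j]) + int(sc.wi) == v:
            ops.append("I")
            nI += 1
            i -= 1
            v = int(F[i, j])
            continue
        if j > 0 and F[i, j - 1] != INF and int(F[i, j - 1]) + int(sc.wd) == v:
            ops.append("D")
            nD += 1
            j -= 1
            v = int(F[i, j])
            continue
        raise AssertionError("alignment traceback failed")
    return _rle(ops), nM, nX, nI, nD, i, j


def align_read(
    read: str,
    references: ReferenceIndex | dict[str, str] | Sequence[tuple[str, str]],
    params: AlignParams | None = None,
    read_id: str = "read",
) -> list[AlignmentHit]:
    """All accepted maximum-score placements of ``read`` on the reference set."""
    params = params or AlignParams()
    index = (
        references
        if isinstance(references, ReferenceIndex)
        else ReferenceIndex(references)
    )
    read = read.upper().replace("U", "T")
    qc_fwd = encode_seq(read)
    L = qc_fwd.shape[0]
    if L < MIN_READ_LENGTH:
        raise ValueError(f"read shorter than {MIN_READ_LENGTH} bases")
    sc = index.scoring(params, L)
    qc_by_strand = {"+": qc_fwd, "-": revcomp_codes(qc_fwd)}
    seq_by_strand = {"+": read, "-": revcomp(read)}

    # candidate placements: (ref_idx, strand, global_start) -> (value, payload)
    cands: dict[tuple[int, str, int], tuple[int, tuple]] = {}
    for ref_idx, ref in enumerate(index.refs):
        N = ref.codes.shape[0]
        use_seeded = index.seeded
        if use_seeded is None:
            use_seeded = sc.k is not None and N > 2000
        if use_seeded and sc.k is None:
            use_seeded = False
        for strand in ("+", "-"):
            qc = qc_by_strand[strand]
            if use_seeded:
                starts, positions = index._kmer_index(ref, sc.k)
                imp = seed_implied_starts(qc, sc.k, starts, positions)
                if imp.size == 0:
                    continue
                windows = _merge_windows(imp, sc, N)
            else:
                windows = [(0, N)]
            for ws, we in windows:
                W = we - ws
                if W <= 0:
                    continue
                win_codes = ref.codes[ws:we]
                if use_seeded and _HAVE_EDLIB and W < N:
                    res = edlib.align(
                        seq_by_strand[strand],
                        ref.seq[ws:we],
                        mode="HW",
                        task="distance",
                        k=sc.edlib_threshold,
                    )
                    if res["editDistance"] < 0:
                        continue
                best, best_i = dp_scan(
                    qc[::-1].copy(),
                    win_codes[::-1].copy(),
                    sc.wm,
                    sc.wx,
                    sc.wi,
                    sc.wd,
                    sc.clamp,
                )
                (cols,) = np.nonzero(best < INF)
                for j in cols:
                    j = int(j)
                    gs = ws + W - j
                    key = (ref_idx, strand, gs)
                    val = int(best[j])
                    payload = (int(best_i[j]), j, ws, we)
                    old = cands.get(key)
                    if old is None or val < old[0]:
                        cands[key] = (val, payload)

    # filter on the per-placement representative, then keep global max score
    accepted: list[tuple[int, int, str, int, int, tuple]] = []
    for (ref_idx, strand, gs), (val, payload) in cands.items():
        neg_score, A, M, D = sc.decode(val)
        if A + D == 0:
            continue
        if M / (A + D) < params.similarity_min - 1e-9:
            continue
        if A / L < params.length_fraction_min - 1e-9:
            continue
        accepted.append((neg_score, ref_idx, strand, gs, val, payload))
    if not accepted:
        return []
    top = min(a[0] for a in accepted)
    winners = [a for a in accepted if a[0] == top]
    winners.sort(key=lambda a: (a[1], a[2], a[3]))

    hits: list[AlignmentHit] = []
    for _negS, ref_idx, strand, gs, val, payload in winners:
        i_end, j_end, ws, we = payload
        ref = index.refs[ref_idx]
        qc = qc_by_strand[strand]
        win_codes = ref.codes[ws:we]
        ops, nM, nX, nI, nD, trail, _ = _traceback(qc, win_codes, i_end, j_end, val, sc)
        lead_clip = L - i_end
        full_ops: list[tuple[str, int]] = []
        if lead_clip:
            full_ops.append(("S", lead_clip))
        full_ops.extend(ops)
        if trail:
            full_ops.append(("S", trail))
        A = nM + nX + nI
        hits.append(
            AlignmentHit(
                read_id=read_id,
                ref_id=ref.name,
                ref_start=gs,
                strand=strand,
                ops=tuple(full_ops),
                n_match=nM,
                n_mismatch=nX,
                n_ins_bases=nI,
                n_del_bases=nD,
                n_clip_bases=lead_clip + trail,
                cost=params.mismatch_cost * nX
                + params.insertion_cost * nI
                + params.deletion_cost * nD,
                similarity=nM / (nM + nX + nI + nD),
                length_fraction=A / L,
            )
        )
    return hits


def assign_reads(
    reads: Iterable[tuple[str, str]],
    references: ReferenceIndex | dict[str, str] | Sequence[tuple[str, str]],
    params: AlignParams | None = None,
) -> list[ReadAssignment]:
    """Resolve each read to unassigned / unique / multi status.

    ``reads`` yields ``(read_id, sequence)`` pairs.  In ``multi_random`` mode
    the chosen placement of a multi-hit read is drawn uniformly from its best
    hits with the generator seeded from ``params.seed`` (deterministic for a
    fixed read order).
    """
    params = params or AlignParams()
    index = (
        references
        if isinstance(references, ReferenceIndex)
        else ReferenceIndex(references)
    )
    rng = np.random.default_rng(params.seed)
    out: list[ReadAssignment] = []
    for read_id, seq in reads:
        hits = align_read(seq, index, params, read_id=read_id)
        if not hits:
            out.append(ReadAssignment(read_id, "unassigned", None, 0))
        elif len(hits) == 1:
            out.append(ReadAssignment(read_id, "unique", hits[0], 1))
        else:
            chosen = None
            if params.mode == "multi_random":
                chosen = hits[int(rng.integers(len(hits)))]
            out.append(ReadAssignment(read_id, "multi", chosen, len(hits)))
    return out


def mappable_read_count(assignments: Iterable[ReadAssignment]) -> int:
    """Number of reads with any accepted placement (unique or multi)."""
    return sum(1 for a in assignments if a.status != "unassigned")
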