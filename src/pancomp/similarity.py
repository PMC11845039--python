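"""Whole-genome pairwise similarity and dereplication.

The scalar *intergenomic similarity* of a genome pair is the aligned genome
coverage multiplied by the percent identity, expressed as a percentage --
the quantity ICTV-style rank demarcation is based on (species at >=95%,
genus at >=70%). Coverage is symmetrized as the mean of the query- and
subject-side covered fractions, and identity is weighted by aligned columns
across all alignment blocks (gap columns count as mismatching).

Alignment is a desk-scale seed-and-chain procedure: exact k-mer anchors on
both strands (default k=13), merged along diagonals, chained collinearly by
dynamic programming, with inter-anchor gaps filled by exact alignment and
chain ends extended by a pinned-start/free-end DP. Gap pairs whose lengths
differ by more than ``indel_break`` are treated as unaligned insertions
(block boundaries), so whole-gene gain/loss reduces coverage instead of
diluting identity. Blocks with small windows are re-polished by the
canonical free-end-gap DP (see :mod:`pancomp.alignment`), making gene-scale
identities effectively exact; genome-scale blocks keep the chain result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .alignment import overlap_align
from .genome_io import GenomeRecord, reverse_complement

__all__ = [
    "AlignParams",
    "Block",
    "AlignmentBlocks",
    "PairwiseSimilarity",
    "align_pair",
    "intergenomic_similarity",
    "similarity_matrix",
    "matrix_to_dataframe",
    "pair_table",
    "dereplicate",
    "round_percent",
]


@dataclass(frozen=True)
class AlignParams:
    k: int = 13
    max_kmer_occurrence: int = 10
    nw_fill_limit: int = 600  # gaps up to this size are filled by exact DP
    polish_cells: int = 6_000_000  # blocks with window area below this are
    # re-aligned exactly; larger (genome-scale) blocks keep the chain fill
    min_chain_matches: int = 25
    merge_gap_limit: int = 2000
    indel_break: int = 100
    low_identity_floor: float = 0.45
    low_identity_min_len: int = 150
    extension_cap: int = 250
    max_chain_gap: int = 5000
    anchor_overlap_tol: int = 50


@dataclass(frozen=True)
class Block:
    """One gap-free-ish aligned block, 1-based inclusive on both genomes."""

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    matches: int
    aligned_cols: int
    strand: str = "+"


@dataclass
class AlignmentBlocks:
    query_id: str
    subject_id: str
    query_len: int
    subject_len: int
    blocks: list[Block] = field(default_factory=list)

    @property
    def identity(self) -> float:
        cols = sum(b.aligned_cols for b in self.blocks)
        if cols == 0:
            return 0.0
        return sum(b.matches for b in self.blocks) / cols

    def _covered(self, side: str, length: int) -> float:
        ivs = sorted(
            (b.q_start, b.q_end) if side == "q" else (b.s_start, b.s_end)
            for b in self.blocks
        )
        total = 0
        cur_s, cur_e = None, None
        for s, e in ivs:
            if cur_e is None or s > cur_e + 1:
                if cur_e is not None:
                    total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s + 1
        return total / length

    @property
    def coverage_query(self) -> float:
        return self._covered("q", self.query_len)

    @property
    def coverage_subject(self) -> float:
        return self._covered("s", self.subject_len)


@dataclass(frozen=True)
class PairwiseSimilarity:
    a_id: str
    b_id: str
    coverage_a: float
    coverage_b: float
    identity: float
    intergenomic_similarity: float


def round_percent(x: float, ndigits: int = 1) -> float:
    """Round half-up on the percent scale, as similarity tables are printed."""
    scale = 10**ndigits
    return np.floor(x * scale + 0.5) / scale


# ---------------------------------------------------------------------------
# k-mer seeding
# ---------------------------------------------------------------------------

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def _kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit packed k-mers and their 0-based start positions (N-free only)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    code = _BASE_CODE[raw]
    n = len(code) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    arr = np.zeros(n, dtype=np.uint64)
    for i in range(k):
        arr = (arr << np.uint64(2)) | code[i : i + n].astype(np.uint64)
    invalid = (code >= 4).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(invalid)])
    ok = (csum[k:] - csum[:-k]) == 0
    pos = np.nonzero(ok)[0]
    return arr[ok], pos


def _seed_matches(
    qk: np.ndarray, qp: np.ndarray, sk: np.ndarray, sp: np.ndarray, max_occ: int
) -> tuple[np.ndarray, np.ndarray]:
    if len(qk) == 0 or len(sk) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    order = np.argsort(sk, kind="stable")
    sks, sps = sk[order], sp[order]
    lo = np.searchsorted(sks, qk, "left")
    hi = np.searchsorted(sks, qk, "right")
    cnt = hi - lo
    ok = (cnt > 0) & (cnt <= max_occ)
    reps = cnt[ok]
    if reps.sum() == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    qpos = np.repeat(qp[ok], reps)
    starts = np.repeat(lo[ok], reps)
    offsets = np.arange(reps.sum()) - np.repeat(np.cumsum(reps) - reps, reps)
    spos = sps[starts + offsets]
    return qpos, spos


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

@dataclass
class _Anchor:
    q_start: int  # 0-based inclusive
    q_end: int  # 0-based inclusive
    s_start: int
    s_end: int
    matches: int
    cols: int


def _runs_to_anchors(qpos: np.ndarray, spos: np.ndarray, k: int) -> list[_Anchor]:
    """Merge seed hits into maximal exact runs along each diagonal."""
    if len(qpos) == 0:
        return []
    diag = qpos - spos
    order = np.lexsort((qpos, diag))
    qq, dd = qpos[order], diag[order]
    brk = np.nonzero((np.diff(dd) != 0) | (np.diff(qq) != 1))[0] + 1
    starts = np.concatenate([[0], brk])
    ends = np.concatenate([brk, [len(qq)]])
    anchors = []
    for s, e in zip(starts, ends):
        q0 = int(qq[s])
        q1 = int(qq[e - 1]) + k - 1
        d = int(dd[s])
        length = q1 - q0 + 1
        anchors.append(_Anchor(q0, q1, q0 - d, q1 - d, length, length))
    return anchors


def _hamming(a: str, b: str) -> int:
    ea = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    eb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    return int(np.count_nonzero(ea == eb))


def _merge_same_diagonal(anchors: list[_Anchor], q: str, s: str, params: AlignParams) -> list[_Anchor]:
    """Join runs on one diagonal across substitution gaps (counted as columns)."""
    by_diag: dict[int, list[_Anchor]] = {}
    for a in anchors:
        by_diag.setdefault(a.q_start - a.s_start, []).append(a)
    merged: list[_Anchor] = []
    for diag_anchors in by_diag.values():
        diag_anchors.sort(key=lambda a: a.q_start)
        cur = diag_anchors[0]
        for nxt in diag_anchors[1:]:
            gap = nxt.q_start - cur.q_end - 1
            if 0 <= gap <= params.merge_gap_limit:
                seg_m, seg_c = _edlib_fill(
                    q[cur.q_end + 1 : nxt.q_start], s[cur.s_end + 1 : nxt.s_start],
                    params.nw_fill_limit,
                )
                seg_ident_ok = gap <= params.low_identity_min_len or (
                    seg_c > 0 and seg_m / seg_c >= params.low_identity_floor
                )
                if seg_ident_ok:
                    cur = _Anchor(
                        cur.q_start,
                        nxt.q_end,
                        cur.s_start,
                        nxt.s_end,
                        cur.matches + nxt.matches + seg_m,
                        cur.cols + nxt.cols + seg_c,
                    )
                    continue
            if nxt.q_start <= cur.q_end:  # contained/overlapping run, keep larger
                if nxt.matches > cur.matches:
                    cur = nxt
                continue
            merged.append(cur)
            cur = nxt
        merged.append(cur)
    merged.sort(key=lambda a: (a.q_start, a.s_start))
    return merged


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------

def _best_chain(anchors: list[_Anchor], params: AlignParams) -> tuple[list[int], float]:
    """DP over anchors: maximal total matches along a collinear chain."""
    n = len(anchors)
    if n == 0:
        return [], 0.0
    qs = np.array([a.q_start for a in anchors])
    qe = np.array([a.q_end for a in anchors])
    ss = np.array([a.s_start for a in anchors])
    se = np.array([a.s_end for a in anchors])
    mt = np.array([a.matches for a in anchors], dtype=np.float64)
    cl = np.array([a.cols for a in anchors], dtype=np.float64)
    value = 2 * mt - cl  # canonical score of the anchor itself
    score = value.copy()
    prev = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        # small anchor overlaps are tolerated (trimmed later), large forbidden
        ov = np.maximum(
            np.maximum(qe[:i] - qs[i] + 1, se[:i] - ss[i] + 1), 0
        )
        ok = ov <= params.anchor_overlap_tol
        gq = qs[i] - qe[:i] - 1
        gs = ss[i] - se[:i] - 1
        ok &= (gq <= params.max_chain_gap) & (gs <= params.max_chain_gap)
        ok &= (qe[:i] < qe[i]) & (se[:i] < se[i])
        if ok.any():
            cand = np.where(ok, score[:i], -np.inf)
            # approximate fill cost: net gap columns plus expected fill
            # mismatches, in units of the canonical score
            gapdiff = np.abs(gq - gs)
            fill_cost = gapdiff + 0.3 * np.maximum(np.minimum(gq, gs), 0)
            cand = cand - fill_cost - 2 * ov
            j = int(np.argmax(cand))
            if cand[j] + value[i] > score[i]:
                score[i] = cand[j] + value[i]
                prev[i] = j
    best = int(np.argmax(score))
    chain = []
    while best != -1:
        chain.append(best)
        best = prev[best]
    chain.reverse()
    return chain, float(score[chain[-1]])


def _nw_fill(qseg: str, sseg: str) -> tuple[int, int]:
    """Exact global alignment of a gap segment, both ends pinned, under the
    package's canonical scoring (match +1, mismatch -1, gap -1)."""
    m, n = len(qseg), len(sseg)
    ea = np.frombuffer(qseg.encode(), dtype=np.uint8)
    eb = np.frombuffer(sseg.encode(), dtype=np.uint8)
    H = np.empty((m + 1, n + 1), dtype=np.int32)
    idx = np.arange(n + 1, dtype=np.int32)
    H[0] = -idx
    for i in range(1, m + 1):
        sub = np.where(eb == ea[i - 1], 1, -1).astype(np.int32)
        T = np.empty(n + 1, dtype=np.int32)
        T[0] = -i
        np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] - 1, out=T[1:])
        H[i] = np.maximum.accumulate(T + idx) - idx
    i, j = m, n
    matches = cols = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + (1 if ea[i - 1] == eb[j - 1] else -1):
            matches += ea[i - 1] == eb[j - 1]
            i -= 1
            j -= 1
        elif i > 0 and H[i, j] == H[i - 1, j] - 1:
            i -= 1
        else:
            j -= 1
        cols += 1
    return int(matches), cols


def _edlib_fill(qseg: str, sseg: str, nw_limit: int = 600) -> tuple[int, int]:
    """(matches, columns) of a global alignment of two gap segments.

    Equal-length segments are usually substitution runs and are compared
    column-wise; when that looks poor (indels hiding inside), or lengths
    differ, the segment is realigned -- exactly under the canonical scoring
    for small segments, by edit distance for large ones.
    """
    if not qseg and not sseg:
        return 0, 0
    if not qseg or not sseg:
        return 0, max(len(qseg), len(sseg))
    if len(qseg) == len(sseg):
        m = _hamming(qseg, sseg)
        if m / len(qseg) >= 0.7 or len(qseg) <= 10:
            return m, len(qseg)
    if max(len(qseg), len(sseg)) <= nw_limit:
        return _nw_fill(qseg, sseg)
    res = edlib.align(qseg, sseg, mode="NW", task="path")
    cols = 0
    matches = 0
    qi = si = 0
    for count, op in _parse_cigar(res["cigar"]):
        cols += count
        if op == "=":
            matches += count
            qi += count
            si += count
        elif op in ("X", "M"):
            if op == "M":
                matches += _hamming(qseg[qi : qi + count], sseg[si : si + count])
            qi += count
            si += count
        elif op == "I":  # consumes query only
            qi += count
        else:  # 'D' consumes target only
            si += count
    return matches, cols


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _extend(
    q: str,
    s: str,
    qi: int,
    si: int,
    direction: int,
    params: AlignParams,
    q_limit: int | None = None,
    s_limit: int | None = None,
) -> tuple[int, int, int, int]:
    """Gapped extension from an anchor end: pinned start, free end.

    Aligns up to ``extension_cap`` residues beyond position (qi, si) in
    ``direction`` with match +1 / mismatch -1 / gap -1, keeping the
    best-scoring prefix (ties toward the longer extension). Returns
    (q_len, s_len, matches, columns); all zero when nothing scores > 0.
    """
    cap = params.extension_cap
    qc = cap if q_limit is None else min(cap, q_limit)
    sc = cap if s_limit is None else min(cap, s_limit)
    if direction > 0:
        qseg = q[qi + 1 : qi + 1 + qc]
        sseg = s[si + 1 : si + 1 + sc]
    else:
        qseg = q[max(0, qi - qc) : qi][::-1]
        sseg = s[max(0, si - sc) : si][::-1]
    m, n = len(qseg), len(sseg)
    if m == 0 or n == 0:
        return 0, 0, 0, 0
    ea = np.frombuffer(qseg.encode(), dtype=np.uint8)
    eb = np.frombuffer(sseg.encode(), dtype=np.uint8)
    H = np.empty((m + 1, n + 1), dtype=np.int32)
    idx = np.arange(n + 1, dtype=np.int32)
    H[0] = -idx
    for i in range(1, m + 1):
        sub = np.where(eb == ea[i - 1], 1, -1).astype(np.int32)
        T = np.empty(n + 1, dtype=np.int32)
        T[0] = -i
        np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] - 1, out=T[1:])
        H[i] = np.maximum.accumulate(T + idx) - idx
    # deterministic best cell: max score, then longest, then largest i
    best_score = int(H.max())
    if best_score <= 0:
        return 0, 0, 0, 0
    ii, jj = np.nonzero(H == best_score)
    k = int(np.argmax(ii + jj + ii / (m + n + 2.0)))
    i, j = int(ii[k]), int(jj[k])
    q_len, s_len = i, j
    matches = columns = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + (1 if ea[i - 1] == eb[j - 1] else -1):
            matches += ea[i - 1] == eb[j - 1]
            i -= 1
            j -= 1
        elif i > 0 and H[i, j] == H[i - 1, j] - 1:
            i -= 1
        else:
            j -= 1
        columns += 1
    return q_len, s_len, int(matches), columns


# ---------------------------------------------------------------------------
# pair alignment
# ---------------------------------------------------------------------------

def _trim_chain_ends(chain: list[_Anchor], q: str, s: str, params: AlignParams) -> list[_Anchor]:
    """Drop terminal anchors whose inclusion scores <= 0 under the canonical
    match/mismatch/gap scoring -- a free-end-gap DP would trim them too."""
    chain = list(chain)
    for terminal in (-1, 0):
        while len(chain) > 1:
            if terminal == -1:
                prev, last = chain[-2], chain[-1]
                gq = last.q_start - prev.q_end - 1
                gs = last.s_start - prev.s_end - 1
            else:
                last, nxt = chain[0], chain[1]
                gq = nxt.q_start - last.q_end - 1
                gs = nxt.s_start - last.s_end - 1
            if gq < 0 or gs < 0 or abs(gq - gs) > params.indel_break:
                break  # overlap/structural break: handled as separate blocks
            if terminal == -1:
                m, c = _edlib_fill(
                    q[prev.q_end + 1 : last.q_start], s[prev.s_end + 1 : last.s_start],
                    params.nw_fill_limit,
                )
            else:
                m, c = _edlib_fill(
                    q[last.q_end + 1 : nxt.q_start], s[last.s_end + 1 : nxt.s_start],
                    params.nw_fill_limit,
                )
            score = (2 * last.matches - last.cols) + (2 * m - c)
            if score > 0:
                break
            chain.pop(terminal)
    return chain


def _chain_to_blocks(
    chain: list[_Anchor],
    q: str,
    s: str,
    strand: str,
    s_orig_len: int,
    params: AlignParams,
    q_bounds: tuple[int, int] | None = None,
) -> tuple[list[Block], tuple[int, int]]:
    """Blocks of one chain plus the consumed query span (0-based), which
    covers every considered anchor so the caller can mask it. ``q_bounds``
    confines end extensions to the not-yet-consumed query window."""
    span_lo = chain[0].q_start
    span_hi = chain[-1].q_end
    q_lo_lim, q_hi_lim = q_bounds if q_bounds is not None else (0, len(q) - 1)
    chain = _trim_chain_ends(chain, q, s, params)
    lq, ls, ext_lm, ext_lc = _extend(
        q, s, chain[0].q_start, chain[0].s_start, -1, params,
        q_limit=max(chain[0].q_start - q_lo_lim, 0),
    )
    rq, rs, ext_rm, ext_rc = _extend(
        q, s, chain[-1].q_end, chain[-1].s_end, +1, params,
        q_limit=max(q_hi_lim - chain[-1].q_end, 0),
    )

    blocks: list[Block] = []
    bq0 = chain[0].q_start - lq
    bs0 = chain[0].s_start - ls
    end_rq, end_rs = rq, rs
    matches = ext_lm + ext_rm
    cols = ext_lc + ext_rc
    prev = chain[0]
    matches += prev.matches
    cols += prev.cols
    for a in chain[1:]:
        trim = max(prev.q_end - a.q_start + 1, prev.s_end - a.s_start + 1, 0)
        if trim:
            if trim >= a.cols:
                continue
            a = _Anchor(
                a.q_start + trim,
                a.q_end,
                a.s_start + trim,
                a.s_end,
                a.matches - trim,
                a.cols - trim,
            )
        gq = a.q_start - prev.q_end - 1
        gs = a.s_start - prev.s_end - 1
        fill = None
        if abs(gq - gs) <= params.indel_break:
            m, c = _edlib_fill(
                q[prev.q_end + 1 : a.q_start], s[prev.s_end + 1 : a.s_start],
                params.nw_fill_limit,
            )
            if c <= params.low_identity_min_len or (c and m / c >= params.low_identity_floor):
                fill = (m, c)
        if fill is None:
            # unaligned insertion: close the block, extending inward so the
            # shared sequence right at the break boundary is not trimmed
            bq, bs, brk_rm, brk_rc = _extend(
                q, s, prev.q_end, prev.s_end, +1, params,
                q_limit=max(gq, 0), s_limit=max(gs, 0),
            )
            blocks.append(
                _make_block(
                    *_polish(
                        q, s, bq0, prev.q_end + bq, bs0, prev.s_end + bs,
                        matches + brk_rm, cols + brk_rc, params,
                        lmargin=params.extension_cap if not blocks else 0,
                        q_window=(q_lo_lim, q_hi_lim),
                    ),
                    strand, s_orig_len,
                )
            )
            bq, bs, brk_lm, brk_lc = _extend(
                q, s, a.q_start, a.s_start, -1, params,
                q_limit=max(gq - bq, 0), s_limit=max(gs - bs, 0),
            )
            bq0, bs0 = a.q_start - bq, a.s_start - bs
            matches, cols = a.matches + brk_lm, a.cols + brk_lc
        else:
            matches += fill[0] + a.matches
            cols += fill[1] + a.cols
        prev = a
    blocks.append(
        _make_block(
            *_polish(
                q, s, bq0, prev.q_end + end_rq, bs0, prev.s_end + end_rs,
                matches, cols, params,
                lmargin=params.extension_cap if not blocks else 0,
                rmargin=params.extension_cap,
                q_window=(q_lo_lim, q_hi_lim),
            ),
            strand, s_orig_len,
        )
    )
    span_lo = min(span_lo, min(bl.q_start for bl in blocks) - 1)
    span_hi = max(span_hi, max(bl.q_end for bl in blocks) - 1)
    return blocks, (span_lo, span_hi)


def _polish(
    q: str, s: str, q0: int, q1: int, s0: int, s1: int, matches: int, cols: int,
    params: AlignParams,
    lmargin: int = 0,
    rmargin: int = 0,
    q_window: tuple[int, int] | None = None,
) -> tuple[int, int, int, int, int, int]:
    """Re-align a small block window exactly under the canonical scoring.

    The seed-and-chain stage decides *where* the genomes align; for windows
    small enough to afford it the alignment itself is recomputed by the
    exact free-end-gap DP, which also places ragged block ends the same way
    a whole-sequence DP would (terminal blocks get extra window margin so
    weak end regions beyond the outermost anchors are considered). Inputs
    and outputs are 0-based inclusive window coordinates.
    """
    if (q1 - q0 + 1) * (s1 - s0 + 1) > params.polish_cells:
        return q0, q1, s0, s1, matches, cols
    q_lo_lim, q_hi_lim = q_window if q_window is not None else (0, len(q) - 1)
    w_q0 = max(q0 - lmargin, q_lo_lim, 0)
    w_q1 = min(q1 + rmargin, q_hi_lim, len(q) - 1)
    w_s0 = max(s0 - lmargin, 0)
    w_s1 = min(s1 + rmargin, len(s) - 1)
    res = overlap_align(q[w_q0 : w_q1 + 1], s[w_s0 : w_s1 + 1])
    if res.columns == 0:
        return q0, q1, s0, s1, matches, cols
    return (
        w_q0 + res.a_start - 1,
        w_q0 + res.a_end - 1,
        w_s0 + res.b_start - 1,
        w_s0 + res.b_end - 1,
        res.matches,
        res.columns,
    )


def _make_block(q0, q1, s0, s1, matches, cols, strand, s_orig_len) -> Block:
    if strand == "+":
        return Block(q0 + 1, q1 + 1, s0 + 1, s1 + 1, matches, cols, "+")
    # coordinates were computed on the reverse complement of the subject
    return Block(
        q0 + 1, q1 + 1, s_orig_len - s1, s_orig_len - s0, matches, cols, "-"
    )


def align_pair(a: GenomeRecord, b: GenomeRecord, params: AlignParams | None = None) -> AlignmentBlocks:
    """Seed, chain and polish alignments between two genomes (both strands)."""
    params = params or AlignParams()
    out = AlignmentBlocks(a.genome_id, b.genome_id, a.length_bp, b.length_bp)
    if min(a.length_bp, b.length_bp) < params.k:
        return out
    q = a.sequence
    qk, qp = _kmer_codes(q, params.k)
    anchors_by_strand: dict[str, list[_Anchor]] = {}
    subj = {"+": b.sequence, "-": reverse_complement(b.sequence)}
    for strand, s_seq in subj.items():
        sk, sp = _kmer_codes(s_seq, params.k)
        qpos, spos = _seed_matches(qk, qp, sk, sp, params.max_kmer_occurrence)
        anchors = _runs_to_anchors(qpos, spos, params.k)
        anchors_by_strand[strand] = _merge_same_diagonal(anchors, q, s_seq, params)

    min_matches = min(params.min_chain_matches, max(params.k, min(len(q), b.length_bp) // 2))
    consumed: list[tuple[int, int]] = []
    while True:
        best = None
        for strand, anchors in anchors_by_strand.items():
            if not anchors:
                continue
            idxs, score = _best_chain(anchors, params)
            if idxs and (best is None or score > best[2]):
                best = (strand, idxs, score)
        if best is None:
            break
        strand, idxs, _ = best
        chain = [anchors_by_strand[strand][i] for i in idxs]
        if sum(c.matches for c in chain) < min_matches:
            break
        # extensions may not creep into query regions already aligned
        free_lo = max(
            (hi + 1 for lo, hi in consumed if hi < chain[0].q_start), default=0
        )
        free_hi = min(
            (lo - 1 for lo, hi in consumed if lo > chain[-1].q_end),
            default=len(q) - 1,
        )
        blocks, (q_lo, q_hi) = _chain_to_blocks(
            chain, q, subj[strand], strand, b.length_bp, params, (free_lo, free_hi)
        )
        out.blocks.extend(blocks)
        consumed.append((q_lo, q_hi))
        # mask the consumed query span on both strands and iterate
        for st in anchors_by_strand:
            anchors_by_strand[st] = [
                an
                for an in anchors_by_strand[st]
                if an.q_end < q_lo or an.q_start > q_hi
            ]
    return out


def intergenomic_similarity(
    a: GenomeRecord, b: GenomeRecord, params: AlignParams | None = None
) -> PairwiseSimilarity:
    """Coverage x identity for a genome pair, on the percent scale."""
    if a.genome_id == b.genome_id and a.sequence == b.sequence:
        return PairwiseSimilarity(a.genome_id, b.genome_id, 1.0, 1.0, 1.0, 100.0)
    res = align_pair(a, b, params)
    cov_a = res.coverage_query
    cov_b = res.coverage_subject
    ident = res.identity
    sim = 100.0 * 0.5 * (cov_a + cov_b) * ident
    return PairwiseSimilarity(a.genome_id, b.genome_id, cov_a, cov_b, ident, sim)


def similarity_matrix(
    genomes: list[GenomeRecord], params: AlignParams | None = None
) -> tuple[np.ndarray, list[str]]:
    """All-vs-all intergenomic similarity; diagonal fixed at 100."""
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    ids = [g.genome_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome_id in input set")
    n = len(genomes)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            s = intergenomic_similarity(genomes[i], genomes[j], params)
            mat[i, j] = mat[j, i] = s.intergenomic_similarity
    return mat, ids


def matrix_to_dataframe(mat: np.ndarray, ids: list[str]):
    import pandas as pd

    return pd.DataFrame(mat, index=ids, columns=ids)


def pair_table(genomes: list[GenomeRecord], params: AlignParams | None = None):
    """All unordered pairs as a tidy frame: a, b, coverage_a, coverage_b,
    identity, similarity (percent, one decimal as printed)."""
    import pandas as pd

    rows = []
    for i, a in enumerate(genomes):
        for b in genomes[i + 1 :]:
            s = intergenomic_similarity(a, b, params)
            rows.append(
                (
                    s.a_id,
                    s.b_id,
                    s.coverage_a,
                    s.coverage_b,
                    s.identity,
                    round_percent(s.intergenomic_similarity),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["a", "b", "coverage_a", "coverage_b", "identity", "similarity"],
    )


def dereplicate(
    genomes: list[GenomeRecord],
    id_threshold: float = 95.0,
    cov_threshold: float = 80.0,
    params: AlignParams | None = None,
) -> tuple[list[GenomeRecord], dict[str, str]]:
    """Greedy longest-first dereplication.

    A genome is redundant iff its aligned identity to an already-kept
    representative is >= ``id_threshold`` percent AND the mean coverage is
    >= ``cov_threshold`` percent; otherwise it founds a new representative.
    """
    order = sorted(genomes, key=lambda g: (-g.length_bp, g.genome_id))
    reps: list[GenomeRecord] = []
    member_map: dict[str, str] = {}
    for g in order:
        assigned = None
        for rep in reps:
            if g.sequence == rep.sequence:
                assigned = rep
                break
            res = align_pair(g, rep, params)
            mean_cov = 0.5 * (res.coverage_query + res.coverage_subject)
            if res.identity * 100.0 >= id_threshold and mean_cov * 100.0 >= cov_threshold:
                assigned = rep
                break
        if assigned is None:
            reps.append(g)
            member_map[g.genome_id] = g.genome_id
        else:
            member_map[g.genome_id] = assigned.genome_id
    return reps, member_map
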