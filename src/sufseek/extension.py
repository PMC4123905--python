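"""Seed extension: X-drop ungapped extension, chain filtering, gapped DP.

Seeds surviving the suffix-array search are grown in three stages, mirroring
the BLAST tradition:

1. **Ungapped extension** pushes each seed left and right one residue at a
   time, keeping the best-scoring extent; a direction terminates at a
   sequence boundary (``#``) or once the running score falls more than
   ``x_drop`` below the best seen (dropoff termination).  The result is a
   high-scoring segment pair (HSP).
2. **Chain filtering** merges redundant HSPs that share a diagonal: pairs
   that overlap are unioned, and non-overlapping pairs are unioned when the
   ungapped score of the intervening diagonal segment stays above
   ``-x_drop`` (the same dropoff budget the ungapped stage uses).  Merging
   repeats until no pair satisfies either condition.
3. **Gapped extension** runs affine-gap dynamic programming outward from an
   anchor pair inside the HSP (the midpoint of its maximal-scoring
   sub-segment), in both directions, discarding frontier cells that fall
   ``x_drop_gapped`` below the running best.  With an infinite dropoff the
   result is the Smith–Waterman optimum among alignments through the anchor.

Gap costs follow the BLAST convention: a gap of length L costs
``gap_open + L * gap_extend`` (open 11 / extend 1 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scoring import ScoreMatrix
from .seed_search import SearchParams, Seed
from .suffix_index import ConcatenatedText

__all__ = [
    "HSP",
    "GappedHit",
    "ungapped_extend",
    "chain_filter",
    "gapped_extend",
    "cull_contained",
]

NEG_INF = -(10**9)


@dataclass(frozen=True)
class HSP:
    """Gap-free local alignment, half-open coordinates in concatenated
    texts; ``db_start - q_start`` is constant along the segment."""

    q_start: int
    q_end: int
    db_start: int
    db_end: int
    score: int

    @property
    def diagonal(self) -> int:
        return self.db_start - self.q_start

    def __len__(self) -> int:
        return self.q_end - self.q_start


@dataclass
class GappedHit:
    """Final gapped local alignment with traceback statistics."""

    q_start: int
    q_end: int
    db_start: int
    db_end: int
    raw_score: int
    n_identical: int
    n_mismatch: int
    n_gap_openings: int
    aligned_length: int
    bit_score: float = 0.0
    evalue: float = float("inf")
    query_id: str = ""
    subject_id: str = ""
    frame: int = 0


def _segment_bounds(code: np.ndarray, pos: int, delim: int, n: int):
    """Bounds [lo, hi) of the delimiter-free segment containing ``pos``."""
    lo = pos
    while lo > 0 and code[lo - 1] != delim:
        lo -= 1
    hi = pos
    while hi < n and code[hi] != delim:
        hi += 1
    return lo, hi


def ungapped_extend(seed: Seed, q_text: ConcatenatedText,
                    db_text: ConcatenatedText, matrix: ScoreMatrix,
                    x_drop: int) -> HSP:
    """Grow a seed without gaps to its best dropoff-reachable extent.

    Each direction walks until a boundary or until the running score drops
    strictly more than ``x_drop`` below the best seen in that direction; the
    returned extent is the best-scoring one and always contains the seed.
    """
    qc, dc = q_text.code, db_text.code
    scores = matrix.scores
    delim = matrix.delimiter_code
    nq, nd = len(q_text), len(db_text)

    # right of the seed
    run = 0
    best = 0
    best_r = 0
    qi, di = seed.q_pos + seed.length, seed.db_pos + seed.length
    k = 0
    while qi + k < nq and di + k < nd:
        a, b = qc[qi + k], dc[di + k]
        if a == delim or b == delim:
            break
        run += int(scores[a, b])
        k += 1
        if run > best:
            best, best_r = run, k
        elif run < best - x_drop:
            break
    right_gain, right_len = best, best_r

    # left of the seed
    run = 0
    best = 0
    best_l = 0
    qi, di = seed.q_pos, seed.db_pos
    k = 0
    while qi - k > 0 and di - k > 0:
        a, b = qc[qi - k - 1], dc[di - k - 1]
        if a == delim or b == delim:
            break
        run += int(scores[a, b])
        k += 1
        if run > best:
            best, best_l = run, k
        elif run < best - x_drop:
            break
    left_gain, left_len = best, best_l

    return HSP(
        q_start=seed.q_pos - left_len,
        q_end=seed.q_pos + seed.length + right_len,
        db_start=seed.db_pos - left_len,
        db_end=seed.db_pos + seed.length + right_len,
        score=seed.score + left_gain + right_gain,
    )


def _diagonal_segment_score(q_code, db_code, scores, q_from, q_to, diag) -> int:
    if q_from >= q_to:
        return 0
    qs = q_code[q_from:q_to]
    ds = db_code[q_from + diag:q_to + diag]
    return int(scores[qs, ds].sum())


def chain_filter(hsps: list[HSP], q_text: ConcatenatedText,
                 db_text: ConcatenatedText, matrix: ScoreMatrix,
                 x_drop: int) -> list[HSP]:
    """Merge same-diagonal HSPs to a fixed point.

    Two HSPs on one diagonal merge when they overlap, or when the ungapped
    score of the segment between them is at least ``-x_drop``.  Merged
    extents are rescored from the texts.  Output is sorted by
    (diagonal, q_start); the result is idempotent.
    """
    scores = matrix.scores
    qc, dc = q_text.code, db_text.code
    by_diag: dict[int, list[HSP]] = {}
    for h in hsps:
        by_diag.setdefault(h.diagonal, []).append(h)

    out: list[HSP] = []
    for diag, group in sorted(by_diag.items()):
        group = sorted(set(group), key=lambda h: (h.q_start, h.q_end))
        changed = True
        while changed:
            changed = False
            for i in range(len(group)):
                for j in range(i + 1, len(group)):
                    a, b = group[i], group[j]
                    if a.q_start > b.q_start:
                        a, b = b, a
                    overlap = b.q_start < a.q_end
                    if not overlap:
                        gap_score = _diagonal_segment_score(
                            qc, dc, scores, a.q_end, b.q_start, diag)
                        if gap_score < -x_drop:
                            continue
                    q0 = min(a.q_start, b.q_start)
                    q1 = max(a.q_end, b.q_end)
                    merged = HSP(
                        q_start=q0, q_end=q1,
                        db_start=q0 + diag, db_end=q1 + diag,
                        score=_diagonal_segment_score(qc, dc, scores, q0, q1, diag),
                    )
                    group = [h for k, h in enumerate(group) if k not in (i, j)]
                    group.append(merged)
                    group.sort(key=lambda h: (h.q_start, h.q_end))
                    changed = True
                    break
                if changed:
                    break
        out.extend(group)
    out.sort(key=lambda h: (h.diagonal, h.q_start))
    return out


def _best_subsegment_mid(q_code, db_code, scores, h: HSP) -> int:
    """Offset (within the HSP) of the midpoint of its maximal-scoring
    sub-segment (Kadane); the gapped extension anchors here."""
    best = NEG_INF
    best_lo = best_hi = 0
    run = 0
    lo = 0
    diag = h.diagonal
    for k in range(len(h)):
        s = int(scores[q_code[h.q_start + k], db_code[h.q_start + k + diag]])
        if run <= 0:
            run = s
            lo = k
        else:
            run += s
        if run > best:
            best, best_lo, best_hi = run, lo, k
    return (best_lo + best_hi) // 2


@dataclass
class _HalfExtension:
    score: int
    q_len: int
    db_len: int
    n_identical: int
    n_mismatch: int
    n_gap_openings: int
    aligned: int


def _extend_half(q_code, db_code, scores, gap_open, gap_extend,
                 x_drop) -> _HalfExtension:
    """Best global-from-origin affine alignment of two (possibly empty)
    sequences, with X-drop frontier pruning; origin scores 0 (empty
    extension allowed).  Returns the best cell's score, extents, and
    traceback statistics from origin to that cell."""
    nq, nd = len(q_code), len(db_code)
    if nq == 0 or nd == 0:
        # at a boundary only gap-less (empty) extension is sensible
        return _HalfExtension(0, 0, 0, 0, 0, 0, 0)
    go_ge = gap_open + gap_extend
    M = np.full((nq + 1, nd + 1), NEG_INF, dtype=np.int64)
    Ix = np.full_like(M, NEG_INF)  # gap in query (consumes db)
    Iy = np.full_like(M, NEG_INF)  # gap in db (consumes query)
    ptr_m = np.zeros((nq + 1, nd + 1), dtype=np.uint8)  # 1=M,2=Ix,3=Iy origin
    ptr_x = np.zeros_like(ptr_m)  # 1: opened from M, 0: extended
    ptr_y = np.zeros_like(ptr_m)
    M[0, 0] = 0
    best = 0
    best_cell = (0, 0)
    lo, hi = 0, 0  # alive column band of the previous row (inclusive)
    for i in range(0, nq + 1):
        new_lo, new_hi = None, 0
        j = lo
        while j <= nd:
            # Ix: gap consuming db[j-1]; the only edge that can push the
            # band rightwards within a row.
            if j > 0:
                open_x = int(M[i, j - 1]) - go_ge
                ext_x = int(Ix[i, j - 1]) - gap_extend
                if open_x >= ext_x:
                    Ix[i, j] = open_x
                    ptr_x[i, j] = 1
                else:
                    Ix[i, j] = ext_x
            # Iy: gap consuming q[i-1]
            if i > 0:
                open_y = int(M[i - 1, j]) - go_ge
                ext_y = int(Iy[i - 1, j]) - gap_extend
                if open_y >= ext_y:
                    Iy[i, j] = open_y
                    ptr_y[i, j] = 1
                else:
                    Iy[i, j] = ext_y
            # M: substitution consuming both
            if i > 0 and j > 0:
                prev_m = int(M[i - 1, j - 1])
                prev_x = int(Ix[i - 1, j - 1])
                prev_y = int(Iy[i - 1, j - 1])
                pbest = max(prev_m, prev_x, prev_y)
                if pbest > NEG_INF // 2:
                    M[i, j] = pbest + int(scores[q_code[i - 1], db_code[j - 1]])
                    ptr_m[i, j] = 1 if pbest == prev_m else (2 if pbest == prev_x else 3)
            cell = max(int(M[i, j]), int(Ix[i, j]), int(Iy[i, j]))
            if cell > best:
                best = cell
                best_cell = (i, j)
            alive = cell > NEG_INF // 2 and cell >= best - x_drop
            if alive:
                if new_lo is None:
                    new_lo = j
                new_hi = j
            else:
                M[i, j] = Ix[i, j] = Iy[i, j] = NEG_INF
                # beyond the previous row's reach only Ix propagates; once it
                # dies nothing to the right can revive.
                if j > hi + 1:
                    break
            j += 1
        if new_lo is None:
            break
        lo, hi = new_lo, new_hi

    bi, bj = best_cell
    # prefer ending in a substitution when scores tie (trim dangling gaps)
    state = 1
    bv = M[bi, bj]
    if Ix[bi, bj] > bv:
        state, bv = 2, Ix[bi, bj]
    if Iy[bi, bj] > bv:
        state, bv = 3, Iy[bi, bj]
    n_id = n_mm = n_go = aligned = 0
    i, j = bi, bj
    while (i, j) != (0, 0):
        aligned += 1
        if state == 1:
            if q_code[i - 1] == db_code[j - 1]:
                n_id += 1
            else:
                n_mm += 1
            state = int(ptr_m[i, j])
            i, j = i - 1, j - 1
        elif state == 2:
            opened = ptr_x[i, j] == 1
            j -= 1
            if opened:
                n_go += 1
                state = 1
        else:
            opened = ptr_y[i, j] == 1
            i -= 1
            if opened:
                n_go += 1
                state = 1
    return _HalfExtension(int(best), bi, bj, n_id, n_mm, n_go, aligned)


def gapped_extend(group: HSP, q_text: ConcatenatedText,
                  db_text: ConcatenatedText, matrix: ScoreMatrix,
                  gap_open: int, gap_extend: int,
                  x_drop_gapped: float) -> GappedHit:
    """Affine-gap X-drop extension outward from an anchor pair in ``group``.

    The anchor pair is always aligned; the total is
    ``left extension + anchor substitution + right extension``, each
    extension being the best global-from-anchor alignment within the
    delimiter-free segments.  ``x_drop_gapped=inf`` disables pruning.
    """
    qc, dc = q_text.code, db_text.code
    scores = matrix.scores
    delim = matrix.delimiter_code
    xd = int(x_drop_gapped) if np.isfinite(x_drop_gapped) else 10**9

    off = _best_subsegment_mid(qc, dc, scores, group)
    qa = group.q_start + off
    da = group.db_start + off
    q_lo, q_hi = _segment_bounds(qc, qa, delim, len(q_text))
    d_lo, d_hi = _segment_bounds(dc, da, delim, len(db_text))

    anchor = int(scores[qc[qa], dc[da]])
    right = _extend_half(qc[qa + 1:q_hi], dc[da + 1:d_hi], scores,
                         gap_open, gap_extend, xd)
    left = _extend_half(qc[q_lo:qa][::-1].copy(), dc[d_lo:da][::-1].copy(),
                        scores, gap_open, gap_extend, xd)

    n_id = left.n_identical + right.n_identical + (1 if qc[qa] == dc[da] else 0)
    n_mm = left.n_mismatch + right.n_mismatch + (0 if qc[qa] == dc[da] else 1)
    return GappedHit(
        q_start=qa - left.q_len,
        q_end=qa + 1 + right.q_len,
        db_start=da - left.db_len,
        db_end=da + 1 + right.db_len,
        raw_score=left.score + anchor + right.score,
        n_identical=n_id,
        n_mismatch=n_mm,
        n_gap_openings=left.n_gap_openings + right.n_gap_openings,
        aligned_length=left.aligned + right.aligned + 1,
    )


def cull_contained(hits: list[GappedHit]) -> list[GappedHit]:
    """Per (query, subject): keep the best hit of every region, dropping
    hits whose query and subject spans are both contained in a kept,
    higher-scoring hit."""
    kept: list[GappedHit] = []
    for h in sorted(hits, key=lambda x: (-x.raw_score, x.q_start, x.db_start)):
        contained = any(
            k.query_id == h.query_id and k.subject_id == h.subject_id
            and k.frame == h.frame
            and k.q_start <= h.q_start and h.q_end <= k.q_end
            and k.db_start <= h.db_start and h.db_end <= k.db_end
            for k in kept)
        if not contained:
            kept.append(h)
    return kept
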