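"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's suffix-array / X-drop machinery:
suffix sorting is plain string sorting, interval narrowing is a linear
filter, the seed walk enumerates every coordinate pair, and the alignment
oracles are dense dynamic programs with no pruning.
"""

from __future__ import annotations

import numpy as np

from sufseek.scoring import ALPHABET, DELIMITER, ScoreMatrix

_CODE = {c: i for i, c in enumerate(ALPHABET)}


def encode(s: str) -> np.ndarray:
    return np.array([_CODE[c] for c in s], dtype=np.int64)


# ---------------------------------------------------------------------- SA

def naive_suffix_sort(text: str) -> list[int]:
    """All suffix start positions, sorted by python string comparison
    (ASCII collation coincides with the package's '#'<'*'<letters order)."""
    return sorted(range(len(text)), key=lambda i: text[i:])


def naive_narrow(sa, text: str, sp: int, ep: int, depth: int, c: str):
    """Linear filter of an interval on the symbol at ``depth``."""
    ranks = [r for r in range(sp, ep)
             if sa[r] + depth < len(text) and text[sa[r] + depth] == c]
    if not ranks:
        return (sp, sp)
    return (ranks[0], ranks[-1] + 1)


# -------------------------------------------------------------- seed walk

def seed_walk_oracle(q_text: str, db_text: str, m: ScoreMatrix,
                     t_seed: int, d: int, length_max: int) -> set:
    """Every (q_pos, db_pos, length, score) seed, by walking each coordinate
    pair: extend one symbol at a time, stop hard at '#'/text end, emit at
    the first length reaching ``t_seed``, discard at the first length where
    score <= 0 or score <= score_max - d (emission checked first)."""
    nq, nd = len(q_text), len(db_text)
    if nq == 0 or nd == 0:
        return set()
    qc, dc = encode(q_text), encode(db_text)
    M = m.scores.astype(np.int64)
    delim = _CODE[DELIMITER]
    score = np.zeros((nq, nd), dtype=np.int64)
    smax = np.zeros((nq, nd), dtype=np.int64)
    active = np.ones((nq, nd), dtype=bool)
    out = set()
    for k in range(1, length_max + 1):
        a, b = nq - k + 1, nd - k + 1
        if a <= 0 or b <= 0:
            break
        active[a:, :] = False
        active[:, b:] = False
        qk = qc[k - 1:]
        dk = dc[k - 1:]
        sub = active[:a, :b]
        sub &= (qk != delim)[:, None]
        sub &= (dk != delim)[None, :]
        sc = score[:a, :b]
        sm = smax[:a, :b]
        sc += M[qk[:, None], dk[None, :]] * sub
        sm += np.diag(M)[qk][:, None] * sub
        emit = sub & (sc >= t_seed)
        for j, i in zip(*np.nonzero(emit)):
            out.add((int(j), int(i), k, int(sc[j, i])))
        sub &= ~emit
        sub &= ~((sc <= 0) | (sc <= sm - d))
    return out


# ------------------------------------------------------- ungapped extents

def ungapped_extent_oracle(seed, q_text: str, db_text: str, m: ScoreMatrix,
                           x_drop: int):
    """Best (left, right) extension lengths and score gain by exhaustive
    search over all dropoff-reachable extents in each direction."""

    def reachable_gains(pairs):
        # cumulative gains along the walk, truncated at '#'/end or at the
        # first step where the running score < best-so-far - x_drop
        gains = [0]
        run = best = 0
        for a, b in pairs:
            if a == DELIMITER or b == DELIMITER:
                break
            run += m.score(a, b)
            if run < best - x_drop:
                break
            best = max(best, run)
            gains.append(run)
        return gains

    q0, d0, L = seed.q_pos, seed.db_pos, seed.length
    right = reachable_gains(zip(q_text[q0 + L:], db_text[d0 + L:]))
    left = reachable_gains(zip(reversed(q_text[:q0]), reversed(db_text[:d0])))
    best_r = max(range(len(right)), key=lambda i: (right[i], -i))
    best_l = max(range(len(left)), key=lambda i: (left[i], -i))
    return best_l, left[best_l], best_r, right[best_r]


# ------------------------------------------------------- gapped alignment

def anchored_dp_oracle(q: str, s: str, qa: int, sa_: int, m: ScoreMatrix,
                       gap_open: int, gap_extend: int):
    """Best local alignment score that aligns ``q[qa]`` with ``s[sa_]``,
    by two dense affine global-from-anchor DPs (no dropoff, no band)."""

    def half(a: str, b: str) -> int:
        na, nb = len(a), len(b)
        NEG = -(10 ** 9)
        Mm = [[NEG] * (nb + 1) for _ in range(na + 1)]
        Ix = [[NEG] * (nb + 1) for _ in range(na + 1)]
        Iy = [[NEG] * (nb + 1) for _ in range(na + 1)]
        Mm[0][0] = 0
        best = 0
        for i in range(na + 1):
            for j in range(nb + 1):
                if j > 0:
                    Ix[i][j] = max(Mm[i][j - 1] - gap_open - gap_extend,
                                   Ix[i][j - 1] - gap_extend)
                if i > 0:
                    Iy[i][j] = max(Mm[i - 1][j] - gap_open - gap_extend,
                                   Iy[i - 1][j] - gap_extend)
                if i > 0 and j > 0:
                    p = max(Mm[i - 1][j - 1], Ix[i - 1][j - 1],
                            Iy[i - 1][j - 1])
                    if p > NEG // 2:
                        Mm[i][j] = p + m.score(a[i - 1], b[j - 1])
                best = max(best, Mm[i][j], Ix[i][j], Iy[i][j])
        return best

    anchor = m.score(q[qa], s[sa_])
    right = half(q[qa + 1:], s[sa_ + 1:])
    left = half(q[qa - 1::-1], s[sa_ - 1::-1])
    return left + anchor + right


def smith_waterman_scores(query: str, subjects: list[str], m: ScoreMatrix,
                          gap_open: int = 11, gap_extend: int = 1) -> np.ndarray:
    """Local-alignment optimum of one query against many subjects at once
    (vectorised across subjects; gap of length L costs open + L*extend)."""
    if not query or not subjects:
        return np.zeros(len(subjects))
    L = max(len(s) for s in subjects)
    pad = _CODE[DELIMITER]
    S = np.full((len(subjects), L), pad, dtype=np.int64)
    for i, s in enumerate(subjects):
        S[i, :len(s)] = encode(s)
    qc = encode(query)
    Msc = m.scores.astype(np.float64)
    go, ge = float(gap_open), float(gap_extend)
    nS = len(subjects)
    ncols = L
    colw = np.arange(1, ncols + 1, dtype=np.float64) * ge
    NEG = -1e12
    Hprev = np.zeros((nS, ncols + 1))
    Frow = np.full((nS, ncols), NEG)
    best = np.zeros(nS)
    for qi in qc:
        diag = Hprev[:, :-1] + Msc[qi, S]
        Frow = np.maximum(Frow - ge, Hprev[:, 1:] - go - ge)
        G = np.maximum(0.0, np.maximum(diag, Frow))
        # E[j] = max_{j'<j}(G[j'] + j'*ge) - go - j*ge  (lazy gap scan; a
        # row gap opening from an E cell is dominated by extending it)
        A = G + colw
        P = np.maximum.accumulate(A, axis=1)
        E = np.full_like(G, NEG)
        E[:, 1:] = P[:, :-1] - go - colw[1:]
        H = np.maximum(G, E)
        best = np.maximum(best, H.max(axis=1))
        Hprev = np.concatenate([np.zeros((nS, 1)), H], axis=1)
    return best
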