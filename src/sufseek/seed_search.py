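"""Score-adaptive variable-length seed search over paired suffix arrays.

Instead of hashing fixed-length words, the engine walks the query suffix
array and the database suffix array *simultaneously*, depth first.  A search
state is a pair of intervals — all query substrings equal to some string
``X_q`` and all database substrings equal to ``X_db`` — together with the
running pair score and the running exact-match (self-alignment) score of the
query substring, ``score_max``.  At each step every one-symbol refinement on
both sides is considered (at most |Σ|² child pairs).

A state whose score reaches the threshold ``T_seed`` is emitted as seeds
(the cross product of its two intervals, translated to text coordinates) and
not extended further — seeds are minimal-length attainments of the
threshold; longer similarity is recovered by the extension stages.  A state
is abandoned when

* its score lags the best achievable by at least ``D``
  (``score <= score_max - D``),
* its score is non-positive (a shorter suffix pair would dominate), or
* it has reached ``length_max`` symbols.

The delimiter ``#`` is a hard barrier: neither side is ever extended across
it, so no seed spans a sequence boundary.  Stops (``*``) and ambiguity
(``X``) are ordinary, heavily penalised symbols.

With BLOSUM62 (diagonal >= 4) the defaults ``T_seed=30, D=4`` mean a state
surviving the lag prune to depth 13 must already have scored 4*13-4 > 30, so
``length_max=13`` loses nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

from .scoring import DELIMITER, RESIDUES, ScoreMatrix
from .suffix_index import (ConcatenatedText, DatabaseChunk, PrefixTable,
                           SAInterval, SuffixArray, full_interval,
                           interval_children)

__all__ = ["SearchParams", "Seed", "seed_search", "expand_state"]


@dataclass(frozen=True)
class SearchParams:
    """Tunables for the whole pipeline; defaults follow the BLAST tradition
    where the seed stage leaves them unstated."""

    t_seed: int = 30          # minimum seed score
    d: int = 4                # max lag of score behind score_max
    length_max: int = 13      # seed length cap, residues
    x_drop_ungapped: int = 20     # raw-score dropoff, ungapped extension
    x_drop_gapped: int = 38       # raw-score dropoff, gapped extension
    gap_open: int = 11
    gap_extend: int = 1
    l_db: int = 2**31         # database chunk budget, residues
    max_interval_product: int | None = None  # cap on seeds per emitted state
    max_targets: int = 10     # reported subjects per query
    evalue_threshold: float = 10.0
    query_block: int = 2000   # query frames per suffix-array batch

    def __post_init__(self):
        if self.t_seed <= 0 or self.d < 1 or self.length_max < 1:
            raise ValueError("require t_seed > 0, d >= 1, length_max >= 1")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")


@dataclass(frozen=True)
class Seed:
    """A matched substring pair anchored at text coordinates."""

    q_pos: int
    db_pos: int
    length: int
    score: int


def expand_state(iv_q: SAInterval, iv_db: SAInterval,
                 q_sa: SuffixArray, db_sa: SuffixArray,
                 depth: int, score: int,
                 max_interval_product: int | None = None) -> list[Seed]:
    """Materialise one emitted state as coordinate seeds: the cross product
    of query ranks × database ranks, ascending, truncated at the cap."""
    seeds: list[Seed] = []
    cap = max_interval_product
    qpos = q_sa.positions
    dpos = db_sa.positions
    for qr in range(iv_q.sp, iv_q.ep):
        qp = int(qpos[qr])
        for dr in range(iv_db.sp, iv_db.ep):
            if cap is not None and len(seeds) >= cap:
                return seeds
            seeds.append(Seed(qp, int(dpos[dr]), depth, score))
    return seeds


def seed_search(q_text: ConcatenatedText, q_sa: SuffixArray,
                db_chunk: DatabaseChunk, matrix: ScoreMatrix,
                params: SearchParams) -> list[Seed]:
    """Find every substring pair whose score first reaches ``t_seed``.

    Output order is deterministic: depth-first, children in ascending
    (query symbol, database symbol) collation order.
    """
    db_text, db_sa, ptable = db_chunk.text, db_chunk.sa, db_chunk.ptable
    scores = matrix.scores
    delim = matrix.delimiter_code
    t_seed, d_bound, length_max = params.t_seed, params.d, params.length_max
    cap = params.max_interval_product
    seeds: list[Seed] = []

    table_children = _make_table_children(ptable, db_sa, db_text)

    def descend(iv_q: SAInterval, iv_db: SAInterval, depth: int,
                score: int, score_max: int, db_label: str) -> None:
        q_kids = interval_children(q_sa, q_text, iv_q)
        if not q_kids:
            return
        if depth < ptable.max_depth and _residues_only(db_label):
            db_kids = table_children(iv_db, depth, db_label)
        else:
            db_kids = interval_children(db_sa, db_text, iv_db)
        for cq, sub_q in q_kids:
            if cq == delim:
                continue
            row = scores[cq]
            diag = int(row[cq])
            for cdb, sub_db in db_kids:
                if cdb == delim:
                    continue
                s = score + int(row[cdb])
                smax = score_max + diag
                if s >= t_seed:
                    seeds.extend(expand_state(sub_q, sub_db, q_sa, db_sa,
                                              depth + 1, s, cap))
                elif s <= smax - d_bound or s <= 0:
                    continue
                elif depth + 1 < length_max:
                    descend(sub_q, sub_db, depth + 1, s, smax,
                            db_label + matrix.alphabet[cdb])

    descend(full_interval(q_sa), full_interval(db_sa), 0, 0, 0, "")
    return seeds


def _residues_only(w: str) -> bool:
    return all(c in RESIDUES for c in w)


from .scoring import ALPHABET as _ALPHABET

_SYM2CODE = {s: i for i, s in enumerate(_ALPHABET)}
_RESIDUE_CODE = [( _SYM2CODE[c], c) for c in sorted(RESIDUES)]


def _make_table_children(ptable: PrefixTable, db_sa: SuffixArray,
                         db_text: ConcatenatedText):
    """Child enumeration on the database side via the prefix table for
    residue-only paths shallower than the table depth.

    The table only covers residue children; if their disjoint sub-intervals
    do not exhaust the parent interval, some suffixes continue with ``X``,
    ``*``, ``#`` or run out — fall back to the generic interval scan so those
    children are not lost.
    """

    def children(iv_db: SAInterval, depth: int, label: str):
        kids = []
        covered = 0
        for code_c, c in _RESIDUE_CODE:
            sub = ptable.lookup(label + c)
            if not sub.empty:
                kids.append((code_c, sub))
                covered += len(sub)
        if covered == len(iv_db):
            return kids
        return interval_children(db_sa, db_text, iv_db)

    return children
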