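"""End-to-end translated search: six-frame translation, per-chunk seed
search and extension, merging, and BLAST-style tabular output.

DNA queries are translated in all six reading frames with the standard
codon table (stops kept in frame as ``*``, ambiguous codons as ``X``).
Translated frames are batched, concatenated and suffix-indexed on the query
side; each database chunk is then searched independently
(seed search → ungapped extension → chain filter → gapped extension) and
rows are merged across chunks, frames and batches.  The merge is
deterministic, so neither the chunking of the database, the batching of the
queries, nor the number of worker threads changes the output.

Output rows are the 12 BLAST tabular columns; query coordinates follow the
BLASTX convention (positions on the DNA read, reverse strand indicated by
start > end).
"""

from __future__ import annotations

import itertools
import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, replace
from pathlib import Path

from Bio.Data.CodonTable import standard_dna_table

from . import scoring
from .extension import (GappedHit, HSP, chain_filter, cull_contained,
                        gapped_extend, ungapped_extend)
from .scoring import KarlinAltschulParams, ScoreMatrix
from .seed_search import SearchParams, seed_search
from .suffix_index import (ConcatenatedText, DatabaseChunk, InputError,
                           build_suffix_array, concat_sequences)

__all__ = [
    "QueryFrame",
    "ResultRow",
    "translate_six_frames",
    "search",
    "read_fasta",
    "write_tabular",
    "read_tabular",
]

log = logging.getLogger("sufseek")

_CODON = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON[_stop] = "*"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class QueryFrame:
    """One translated reading frame of a query (frame 0 = native protein).

    ``dna_len`` is the untranslated read length, needed to map protein
    coordinates back onto the read (1-based, strand-aware).
    """

    query_id: str
    frame: int  # +1,+2,+3,-1,-2,-3, or 0 for protein input
    protein: str
    dna_len: int = 0

    def dna_span(self, p_start: int, p_end: int) -> tuple[int, int]:
        """Map a half-open protein interval to 1-based inclusive DNA
        coordinates; reverse frames report start > end."""
        if self.frame == 0:
            return p_start + 1, p_end
        f = abs(self.frame) - 1
        if self.frame > 0:
            return f + 3 * p_start + 1, f + 3 * p_end
        return self.dna_len - f - 3 * p_start, self.dna_len - f - 3 * p_end + 1


def _translate(dna: str) -> str:
    usable = len(dna) - len(dna) % 3
    return "".join(_CODON.get(dna[i:i + 3], "X") for i in range(0, usable, 3))


def translate_six_frames(dna: str, query_id: str = "") -> list[QueryFrame]:
    """All six reading frames of a read; trailing partial codons dropped,
    stop codons kept as ``*``, codons outside the standard table (anything
    with N/ambiguity) as ``X``."""
    dna = dna.upper().replace("U", "T")
    if not dna:
        return []
    rc = reverse_complement(dna)
    frames = []
    for f in (1, 2, 3):
        fwd = _translate(dna[f - 1:])
        if fwd:
            frames.append(QueryFrame(query_id, f, fwd, len(dna)))
    for f in (1, 2, 3):
        rev = _translate(rc[f - 1:])
        if rev:
            frames.append(QueryFrame(query_id, -f, rev, len(dna)))
    return frames


@dataclass(frozen=True)
class ResultRow:
    """The 12 BLAST tabular columns."""

    query_id: str
    subject_id: str
    pct_identity: float
    alignment_length: int
    mismatches: int
    gap_openings: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float


def read_fasta(source) -> list[tuple[str, str]]:
    """Read FASTA records (multi-line, CRLF-tolerant); ``*`` permitted in
    the body.  Header-only records are rejected with the record name."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(source), "fasta"):
        seq = str(rec.seq).strip().upper()
        if not seq:
            raise InputError(f"FASTA record {rec.id!r} has no sequence")
        out.append((rec.id, seq))
    return out


def _format_evalue(e: float) -> str:
    if e == 0:
        return "0.0"
    return f"{e:.1e}" if e < 1e-2 else f"{e:.2g}"


def write_tabular(rows: list[ResultRow], sink) -> None:
    """Write hits as tab-separated BLAST ``-outfmt 6`` rows, no header."""
    close = False
    if isinstance(sink, (str, Path)):
        sink = open(sink, "w")
        close = True
    try:
        for r in rows:
            sink.write("\t".join([
                r.query_id, r.subject_id, f"{r.pct_identity:.2f}",
                str(r.alignment_length), str(r.mismatches),
                str(r.gap_openings), str(r.q_start), str(r.q_end),
                str(r.s_start), str(r.s_end), _format_evalue(r.evalue),
                f"{r.bit_score:.1f}",
            ]) + "\n")
    finally:
        if close:
            sink.close()


def read_tabular(source) -> list[ResultRow]:
    rows = []
    with open(source) as fh:
        for ln in fh:
            f = ln.rstrip("\n").split("\t")
            if len(f) != 12:
                raise InputError(f"malformed tabular row: {ln!r}")
            rows.append(ResultRow(f[0], f[1], float(f[2]), int(f[3]),
                                  int(f[4]), int(f[5]), int(f[6]), int(f[7]),
                                  int(f[8]), int(f[9]), float(f[10]),
                                  float(f[11])))
    return rows


def _query_frames(queries, query_type: str) -> list[QueryFrame]:
    frames: list[QueryFrame] = []
    for qid, seq in queries:
        if query_type == "dna":
            frames.extend(translate_six_frames(seq, qid))
        else:
            frames.append(QueryFrame(qid, 0, seq, 0))
    return frames


def _batched(iterable, size):
    it = iter(iterable)
    while True:
        block = list(itertools.islice(it, size))
        if not block:
            return
        yield block


@dataclass
class StageCounts:
    seeds: int = 0
    hsps: int = 0
    chained: int = 0
    gapped: int = 0
    rows: int = 0

    def add(self, other: "StageCounts") -> None:
        for f in ("seeds", "hsps", "chained", "gapped", "rows"):
            setattr(self, f, getattr(self, f) + getattr(other, f))


def _search_block(frames: list[QueryFrame], chunk: DatabaseChunk,
                  matrix: ScoreMatrix, params: SearchParams,
                  ka: KarlinAltschulParams, db_residues: int,
                  counts: StageCounts) -> list[GappedHit]:
    q_text = concat_sequences([(str(i), f.protein) for i, f in enumerate(frames)])
    q_sa = build_suffix_array(q_text)
    seeds = seed_search(q_text, q_sa, chunk, matrix, params)
    counts.seeds += len(seeds)
    if not seeds:
        return []

    # bucket seeds by (query frame, subject)
    buckets: dict[tuple[int, int], list] = {}
    for s in seeds:
        fi, _ = q_text.locate(s.q_pos)
        si, _ = chunk.text.locate(s.db_pos)
        buckets.setdefault((fi, si), []).append(s)

    hits: list[GappedHit] = []
    for (fi, si) in sorted(buckets):
        frame = frames[fi]
        hsps = {ungapped_extend(s, q_text, chunk.text, matrix,
                                params.x_drop_ungapped)
                for s in buckets[(fi, si)]}
        counts.hsps += len(hsps)
        chained = chain_filter(sorted(hsps, key=lambda h: (h.diagonal, h.q_start)),
                               q_text, chunk.text, matrix,
                               params.x_drop_ungapped)
        counts.chained += len(chained)
        pair_hits = []
        for h in chained:
            g = gapped_extend(h, q_text, chunk.text, matrix,
                              params.gap_open, params.gap_extend,
                              params.x_drop_gapped)
            counts.gapped += 1
            # concatenated-text coordinates -> frame/subject-local
            fb = int(q_text.boundaries[fi])
            sb = int(chunk.text.boundaries[si])
            g.q_start -= fb
            g.q_end -= fb
            g.db_start -= sb
            g.db_end -= sb
            g.query_id = frame.query_id
            g.subject_id = chunk.text.ids[si]
            g.frame = frame.frame
            g.bit_score = scoring.bit_score(g.raw_score, ka)
            g.evalue = scoring.evalue(g.raw_score, max(len(frame.protein), 1),
                                      db_residues, ka)
            pair_hits.append(g)
        hits.extend(cull_contained(pair_hits))
    return hits


def _hit_to_row(g: GappedHit,
                frames_by_id: dict[tuple[str, int], QueryFrame]) -> ResultRow:
    frame = frames_by_id[(g.query_id, g.frame)]
    q1, q2 = frame.dna_span(g.q_start, g.q_end)
    pct = round(100.0 * g.n_identical / g.aligned_length, 2)
    return ResultRow(
        query_id=g.query_id, subject_id=g.subject_id,
        pct_identity=pct, alignment_length=g.aligned_length,
        mismatches=g.n_mismatch, gap_openings=g.n_gap_openings,
        q_start=q1, q_end=q2, s_start=g.db_start + 1, s_end=g.db_end,
        evalue=g.evalue, bit_score=g.bit_score,
    )


def search(queries: list[tuple[str, str]], chunks: list[DatabaseChunk],
           matrix: ScoreMatrix, params: SearchParams | None = None,
           query_type: str = "dna",
           ka: KarlinAltschulParams | None = None,
           threads: int = 1) -> list[ResultRow]:
    """Search translated (or native protein) queries against an indexed
    database and return sorted, deduplicated tabular rows.

    Rows are sorted per query by bit score descending (ties: E-value
    ascending, then subject id), truncated to ``params.max_targets``
    subjects per query, and filtered at ``params.evalue_threshold``.
    """
    params = params or SearchParams()
    ka = ka or KarlinAltschulParams()
    if not queries:
        return []
    frames = _query_frames(queries, query_type)
    if not frames:
        return []
    frames_by_id = {(f.query_id, f.frame): f for f in frames}
    db_residues = sum(ch.residue_count for ch in chunks)
    counts = StageCounts()

    def run_block(block):
        local = StageCounts()
        hits = []
        for chunk in chunks:
            hits.extend(_search_block(block, chunk, matrix, params, ka,
                                      db_residues, local))
        return hits, local

    blocks = list(_batched(frames, params.query_block))
    all_hits: list[GappedHit] = []
    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            for hits, local in pool.map(run_block, blocks):
                all_hits.extend(hits)
                counts.add(local)
    else:
        for block in blocks:
            hits, local = run_block(block)
            all_hits.extend(hits)
            counts.add(local)

    # frame-local coordinates were set inside _search_block via buckets on
    # the concatenated text; normalise them here
    rows = _merge_hits(all_hits, frames_by_id, params)
    counts.rows = len(rows)
    log.info("stage counts: seeds=%d hsps=%d chained=%d gapped=%d rows=%d",
             counts.seeds, counts.hsps, counts.chained, counts.gapped,
             counts.rows)
    return rows


def _merge_hits(hits: list[GappedHit],
                frames_by_id: dict[tuple[str, int], QueryFrame],
                params: SearchParams) -> list[ResultRow]:
    hits = cull_contained(hits)
    by_query: dict[str, list[GappedHit]] = {}
    for g in hits:
        if g.evalue <= params.evalue_threshold:
            by_query.setdefault(g.query_id, []).append(g)
    rows: list[ResultRow] = []
    for qid in sorted(by_query):
        qhits = sorted(by_query[qid],
                       key=lambda g: (-g.bit_score, g.evalue, g.subject_id,
                                      g.frame, g.q_start, g.db_start))
        seen_subjects: list[str] = []
        for g in qhits:
            if g.subject_id not in seen_subjects:
                if len(seen_subjects) >= params.max_targets:
                    continue
                seen_subjects.append(g.subject_id)
            rows.append(_hit_to_row(g, frames_by_id))
    return rows
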