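"""Synthetic protein databases and planted-homolog query reads.

Every stage of the search engine is testable without external downloads:
:func:`make_protein_db` draws i.i.d. protein sequences from the
Robinson–Robinson background amino-acid frequencies (the composition BLAST
assumes for random protein), and :func:`plant_queries` copies segments out
of that database, degrades them to a target identity with point
substitutions (plus optional single-residue indels), reverse-translates
them through uniformly chosen synonymous codons, and optionally flips them
onto the reverse strand — emitting DNA reads whose true origin is recorded
in a truth table.

Everything is deterministic per seed; regeneration is byte-identical.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pipeline import reverse_complement, translate_six_frames
from .scoring import RESIDUES
from .suffix_index import InputError

__all__ = ["PlantedHomologSet", "TruthRow", "make_protein_db",
           "plant_queries", "ROBINSON_FREQUENCIES"]

#: Robinson & Robinson background amino-acid frequencies.
ROBINSON_FREQUENCIES = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}

# codons per residue, standard table, for reverse-translation
_SYNONYMS: dict[str, list[str]] = {}
from Bio.Data.CodonTable import standard_dna_table as _tab  # noqa: E402

for _codon, _aa in sorted(_tab.forward_table.items()):
    _SYNONYMS.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class TruthRow:
    """Provenance of one planted read."""

    query_id: str
    source_id: str
    src_start: int  # protein coordinates in the source, half-open
    src_end: int
    identity: float  # realised substitution identity (before indels)
    n_insertions: int
    n_deletions: int
    strand: int  # +1 / -1
    mutated_protein: str  # the edited segment the read encodes


@dataclass
class PlantedHomologSet:
    """A synthetic database, reads planted from it, and the ground truth."""

    database: list[tuple[str, str]]
    queries: list[tuple[str, str]]
    truth: list[TruthRow]
    seed: int

    def truth_by_query(self) -> dict[str, TruthRow]:
        return {t.query_id: t for t in self.truth}

    def write_truth_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["query_id", "source_id", "src_start", "src_end",
                        "identity", "n_insertions", "n_deletions", "strand",
                        "mutated_protein"])
            for t in self.truth:
                w.writerow([t.query_id, t.source_id, t.src_start, t.src_end,
                            f"{t.identity:.4f}", t.n_insertions,
                            t.n_deletions, t.strand, t.mutated_protein])


def make_protein_db(n: int, length: int | tuple[int, int] = 300,
                    seed: int = 0) -> list[tuple[str, str]]:
    """Draw ``n`` random protein sequences from the Robinson–Robinson
    background; ``length`` is a fixed residue count or an inclusive
    ``(lo, hi)`` uniform range."""
    if n < 1:
        raise InputError("need at least one database sequence")
    rng = np.random.default_rng(seed)
    residues = np.array(sorted(ROBINSON_FREQUENCIES))
    probs = np.array([ROBINSON_FREQUENCIES[r] for r in residues])
    probs = probs / probs.sum()
    out = []
    for i in range(n):
        if isinstance(length, tuple):
            ln = int(rng.integers(length[0], length[1] + 1))
        else:
            ln = length
        seq = "".join(rng.choice(residues, size=ln, p=probs))
        out.append((f"db{i:05d}", seq))
    return out


def _mutate(segment: str, identity: float, indel_rate: float, rng):
    """Point-substitute to the target identity, then sprinkle single-residue
    indels; returns (protein, n_sub, n_ins, n_del)."""
    others = {r: [o for o in RESIDUES if o != r] for r in RESIDUES}
    chars = list(segment)
    n_sub = 0
    for k in range(len(chars)):
        if rng.random() > identity:
            chars[k] = others[chars[k]][int(rng.integers(0, 19))]
            n_sub += 1
    n_ins = n_del = 0
    if indel_rate > 0:
        residues = sorted(ROBINSON_FREQUENCIES)
        out = []
        for c in chars:
            r = rng.random()
            if r < indel_rate / 2:
                n_del += 1
                continue
            out.append(c)
            if r >= 1 - indel_rate / 2:
                out.append(residues[int(rng.integers(0, 20))])
                n_ins += 1
        chars = out
    return "".join(chars), n_sub, n_ins, n_del


def _reverse_translate(protein: str, rng) -> str:
    return "".join(_SYNONYMS[aa][int(rng.integers(0, len(_SYNONYMS[aa])))]
                   for aa in protein)


def plant_queries(db: list[tuple[str, str]], n_queries: int,
                  identity: float = 0.8, indel_rate: float = 0.0,
                  read_len_nt: int = 150, seed: int = 0,
                  both_strands: bool = True) -> PlantedHomologSet:
    """Plant ``n_queries`` DNA reads copied from random database segments.

    Each read encodes a database segment of ``read_len_nt // 3`` residues
    degraded to the requested substitution ``identity``; indels are applied
    at ``indel_rate`` per position (half insertions, half deletions).  With
    ``both_strands`` half the reads (per coin flip) are emitted as the
    reverse complement.
    """
    if not 0 < identity <= 1:
        raise InputError("identity must be in (0, 1]")
    seg_len = read_len_nt // 3
    rng = np.random.default_rng(seed)
    queries = []
    truth = []
    eligible = [(sid, s) for sid, s in db if len(s) >= seg_len]
    if not eligible:
        raise InputError(f"read length {read_len_nt} nt exceeds every "
                         "database sequence")
    for qi in range(n_queries):
        sid, s = eligible[int(rng.integers(0, len(eligible)))]
        start = int(rng.integers(0, len(s) - seg_len + 1))
        segment = s[start:start + seg_len]
        protein, n_sub, n_ins, n_del = _mutate(segment, identity,
                                               indel_rate, rng)
        dna = _reverse_translate(protein, rng)
        strand = 1
        if both_strands and rng.random() < 0.5:
            dna = reverse_complement(dna)
            strand = -1
        qid = f"q{qi:05d}"
        queries.append((qid, dna))
        truth.append(TruthRow(
            query_id=qid, source_id=sid, src_start=start,
            src_end=start + seg_len,
            identity=1.0 - n_sub / seg_len,
            n_insertions=n_ins, n_deletions=n_del, strand=strand,
            mutated_protein=protein,
        ))
    return PlantedHomologSet(database=db, queries=queries, truth=truth,
                             seed=seed)


def write_fasta(seqs: list[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for sid, s in seqs:
            fh.write(f">{sid}\n")
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")
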