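"""Concatenated sequence text, suffix arrays, prefix tables and chunking.

The database (and each batch of translated query frames) is flattened into a
single delimited string ``S_0#S_1#...#S_{N-1}`` and indexed with a suffix
array — the permutation of suffix start positions in lexicographic order
(delimiter collates lowest).  All pattern matching is interval narrowing: the
set of suffixes sharing a prefix ``w`` is a contiguous half-open rank range
``[sp, ep)``, and appending one symbol to ``w`` shrinks the range by binary
search in O(log n).

For the database side a prefix lookup table additionally stores the interval
of every residue-only substring of length 1–5 that occurs in the text, so
short lookups skip the binary searches entirely.

Databases larger than a residue budget ``l_db`` are split greedily (in input
order, never splitting a sequence) into chunks, each indexed independently;
searching chunk-by-chunk and merging yields the same results as one big
index.  Indexes serialise to little-endian 32-bit files with a JSON manifest.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .scoring import ALPHABET, DELIMITER, RESIDUES, ScoreMatrix

__all__ = [
    "ConcatenatedText",
    "SuffixArray",
    "SAInterval",
    "PrefixTable",
    "DatabaseChunk",
    "InputError",
    "FormatError",
    "concat_sequences",
    "build_suffix_array",
    "narrow_interval",
    "build_prefix_table",
    "chunk_database",
    "build_chunk",
    "save_index",
    "load_index",
]

_CODES = np.full(128, -1, dtype=np.int16)
for _i, _c in enumerate(ALPHABET):
    _CODES[ord(_c)] = _i
_RESIDUE_CODES = frozenset(int(_CODES[ord(c)]) for c in RESIDUES)
_MIN_RESIDUE_CODE = min(_RESIDUE_CODES)  # residues+X are a contiguous code block


class InputError(ValueError):
    """Invalid user-supplied sequences."""


class FormatError(ValueError):
    """Corrupt or incompatible index files."""


@dataclass
class ConcatenatedText:
    """``S_0#S_1#...#S_{N-1}`` plus the bookkeeping to invert positions.

    ``code`` is the text encoded in collation order (int16), padded with a
    trailing ``-1`` sentinel block so length-5 windows can be read at any
    position without bounds checks.
    """

    text: str
    ids: list[str]
    boundaries: np.ndarray  # start offset of each sequence in `text`
    lengths: np.ndarray  # residue count per sequence
    code: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.text)

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    def locate(self, pos: int) -> tuple[int, int]:
        """Map a text offset to ``(sequence index, offset within sequence)``.

        Raises ``ValueError`` on a delimiter position.
        """
        i = int(np.searchsorted(self.boundaries, pos, side="right")) - 1
        off = pos - int(self.boundaries[i])
        if off >= int(self.lengths[i]):
            raise ValueError(f"position {pos} is a delimiter")
        return i, off

    def is_delimiter(self, pos: int) -> bool:
        return self.text[pos] == DELIMITER

    def sequence(self, i: int) -> str:
        b = int(self.boundaries[i])
        return self.text[b:b + int(self.lengths[i])]


def _encode(text: str) -> np.ndarray:
    arr = _CODES[np.frombuffer(text.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = text[int(np.argmax(arr < 0))]
        raise InputError(f"symbol {bad!r} not in alphabet")
    return np.concatenate([arr, np.full(8, -1, dtype=np.int16)])


def concat_sequences(seqs: list[tuple[str, str]]) -> ConcatenatedText:
    """Join sequences with ``#`` delimiters into one indexable text."""
    if not seqs:
        raise InputError("empty sequence list")
    ids = [s[0] for s in seqs]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise InputError(f"duplicate sequence id {dup!r}")
    for sid, s in seqs:
        if not s:
            raise InputError(f"empty sequence {sid!r}")
    text = DELIMITER.join(s for _, s in seqs)
    boundaries = np.cumsum([0] + [len(s) + 1 for _, s in seqs[:-1]])
    lengths = np.array([len(s) for _, s in seqs], dtype=np.int64)
    return ConcatenatedText(text=text, ids=ids, boundaries=boundaries,
                            lengths=lengths, code=_encode(text))


def split_text(t: ConcatenatedText) -> list[tuple[str, str]]:
    """Inverse of :func:`concat_sequences`."""
    return [(t.ids[i], t.sequence(i)) for i in range(t.n_sequences)]


@dataclass
class SuffixArray:
    """Suffix start positions of a text in lexicographic order."""

    positions: np.ndarray  # int32

    def __len__(self) -> int:
        return len(self.positions)


def build_suffix_array(t: ConcatenatedText) -> SuffixArray:
    """Sort all suffixes by prefix doubling (O(n log² n) worst case).

    A suffix that runs off the end compares below every extension of it
    (the sentinel rank ``-1``), matching plain string comparison.
    """
    n = len(t)
    if n == 0:
        raise InputError("cannot index empty text")
    rank = t.code[:n].astype(np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[:n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r1, r2 = rank[order], key2[order]
        bump = np.empty(n, dtype=np.int64)
        bump[0] = 0
        bump[1:] = (np.diff(r1) != 0) | (np.diff(r2) != 0)
        new_rank = np.cumsum(bump)
        rank = np.empty(n, dtype=np.int64)
        rank[order] = new_rank
        if new_rank[-1] == n - 1 or k >= n:
            return SuffixArray(positions=order.astype(np.int32))
        k *= 2


@dataclass(frozen=True)
class SAInterval:
    """Half-open rank range ``[sp, ep)`` of suffixes sharing a ``depth``-long
    prefix; empty iff ``sp == ep``."""

    sp: int
    ep: int
    depth: int = 0

    def __len__(self) -> int:
        return self.ep - self.sp

    @property
    def empty(self) -> bool:
        return self.sp >= self.ep


def full_interval(sa: SuffixArray) -> SAInterval:
    return SAInterval(0, len(sa), 0)


def narrow_interval(sa: SuffixArray, t: ConcatenatedText,
                    iv: SAInterval, c: str) -> SAInterval:
    """Restrict ``iv`` to suffixes whose symbol at offset ``iv.depth`` is
    ``c``, by two binary searches over the rank range."""
    target = int(_CODES[ord(c)])
    if target < 0:
        raise InputError(f"symbol {c!r} not in alphabet")
    sp, ep = _narrow_codes(sa.positions, t.code, iv.sp, iv.ep, iv.depth, target)
    return SAInterval(sp, ep, iv.depth + 1)


def _narrow_codes(positions, code, sp, ep, depth, target):
    # first rank whose char-at-depth >= target (chars within [sp,ep) at
    # `depth` are non-decreasing because the interval shares a depth-prefix)
    lo, hi = sp, ep
    while lo < hi:
        mid = (lo + hi) // 2
        if code[positions[mid] + depth] < target:
            lo = mid + 1
        else:
            hi = mid
    new_sp = lo
    hi = ep
    while lo < hi:
        mid = (lo + hi) // 2
        if code[positions[mid] + depth] <= target:
            lo = mid + 1
        else:
            hi = mid
    return new_sp, lo


def interval_children(sa: SuffixArray, t: ConcatenatedText,
                      iv: SAInterval) -> list[tuple[int, SAInterval]]:
    """All one-symbol refinements of ``iv`` with non-empty intervals, as
    ``(symbol_code, sub-interval)`` in ascending code order.

    Small intervals are scanned directly; large ones are partitioned by
    run-hopping binary searches (one per distinct next symbol).
    """
    positions, code, depth = sa.positions, t.code, iv.depth
    out = []
    if len(iv) <= 48:
        chars = code[positions[iv.sp:iv.ep] + depth]
        start = 0
        m = len(chars)
        while start < m:
            c = int(chars[start])
            end = start
            while end < m and chars[end] == c:
                end += 1
            if c >= 0:
                out.append((c, SAInterval(iv.sp + start, iv.sp + end, depth + 1)))
            start = end
        return out
    sp = iv.sp
    while sp < iv.ep:
        c = int(code[positions[sp] + depth])
        _, ep = _narrow_codes(positions, code, sp, iv.ep, depth, c)
        if c >= 0:
            out.append((c, SAInterval(sp, ep, depth + 1)))
        sp = ep
    return out


@dataclass
class PrefixTable:
    """Intervals of every residue-only substring of length 1–5 in the text.

    Keys containing ``X``, ``*`` or ``#`` are excluded (computed on demand by
    narrowing); a key absent from the table denotes the empty interval.
    """

    max_depth: int
    entries: dict[str, tuple[int, int]]

    def lookup(self, w: str) -> SAInterval:
        sp, ep = self.entries.get(w, (0, 0))
        return SAInterval(sp, ep, len(w))

    def __contains__(self, w: str) -> bool:
        return w in self.entries


def build_prefix_table(sa: SuffixArray, t: ConcatenatedText,
                       max_depth: int = 5) -> PrefixTable:
    """Enumerate intervals of all short residue-only substrings in one pass
    per depth: suffixes sharing a k-prefix are contiguous in the array, so
    runs of equal packed k-mer codes delimit the intervals directly."""
    positions = sa.positions.astype(np.int64)
    code = t.code
    n = len(positions)
    base = len(ALPHABET) + 1
    entries: dict[str, tuple[int, int]] = {}
    packed = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    res_lo = _MIN_RESIDUE_CODE
    res_codes = np.zeros(len(ALPHABET) + 1, dtype=bool)
    for c in RESIDUES:
        res_codes[int(_CODES[ord(c)])] = True
    for k in range(1, max_depth + 1):
        ck = code[positions + k - 1]
        valid &= res_codes[np.where(ck >= 0, ck, len(ALPHABET))]
        packed = packed * base + np.where(ck >= 0, ck, 0)
        starts = np.flatnonzero(np.r_[True, (packed[1:] != packed[:-1])
                                      | (valid[1:] != valid[:-1])])
        ends = np.r_[starts[1:], n]
        for s, e in zip(starts.tolist(), ends.tolist()):
            if valid[s]:
                p = int(positions[s])
                entries[t.text[p:p + k]] = (s, e)
    return PrefixTable(max_depth=max_depth, entries=entries)


def lookup_or_descend(w: str, ptable: PrefixTable | None,
                      sa: SuffixArray, t: ConcatenatedText) -> SAInterval:
    """Interval of substring ``w``: table hit for short residue-only keys,
    otherwise (or beyond the table depth) narrowed symbol by symbol."""
    if not w:
        raise ValueError("empty pattern")
    iv = full_interval(sa)
    start = 0
    if ptable is not None:
        head_len = min(len(w), ptable.max_depth)
        head = w[:head_len]
        if all(c in RESIDUES for c in head):
            iv = ptable.lookup(head)
            start = head_len
    for c in w[start:]:
        if iv.empty:
            return SAInterval(iv.sp, iv.ep, len(w))
        iv = narrow_interval(sa, t, iv, c)
    return iv


@dataclass
class DatabaseChunk:
    """One self-contained slice of the database: text + suffix array +
    prefix table, holding at most ``l_db`` residues."""

    chunk_index: int
    text: ConcatenatedText
    sa: SuffixArray
    ptable: PrefixTable
    residue_count: int


def build_chunk(seqs: list[tuple[str, str]], chunk_index: int = 0) -> DatabaseChunk:
    text = concat_sequences(seqs)
    sa = build_suffix_array(text)
    return DatabaseChunk(
        chunk_index=chunk_index,
        text=text,
        sa=sa,
        ptable=build_prefix_table(sa, text),
        residue_count=int(text.lengths.sum()),
    )


def chunk_database(seqs: list[tuple[str, str]], l_db: int) -> list[DatabaseChunk]:
    """Greedy in-order packing of sequences into indexed chunks of at most
    ``l_db`` residues; a sequence is never split across chunks."""
    if l_db > 2**31:
        raise InputError("l_db exceeds the 32-bit offset limit (2^31 symbols)")
    for sid, s in seqs:
        if len(s) > l_db:
            raise InputError(f"sequence {sid!r} ({len(s)} residues) exceeds l_db={l_db}")
    groups: list[list[tuple[str, str]]] = []
    cur: list[tuple[str, str]] = []
    cur_size = 0
    for sid, s in seqs:
        if cur and cur_size + len(s) > l_db:
            groups.append(cur)
            cur, cur_size = [], 0
        cur.append((sid, s))
        cur_size += len(s)
    if cur:
        groups.append(cur)
    return [build_chunk(g, i) for i, g in enumerate(groups)]


# ---------------------------------------------------------------------------
# on-disk format: <prefix>.manifest.json + per chunk .text/.sa binary files
# (magic + version byte + little-endian payload, 32-bit suffix offsets)

_MAGIC = b"SFSK"
_VERSION = 1


def _write_blob(path: Path, kind: bytes, payload: bytes) -> None:
    with open(path, "wb") as fh:
        fh.write(_MAGIC + bytes([_VERSION]) + kind)
        fh.write(struct.pack("<Q", len(payload)))
        fh.write(payload)


def _read_blob(path: Path, kind: bytes) -> bytes:
    data = path.read_bytes()
    if len(data) < 14 or data[:4] != _MAGIC:
        raise FormatError(f"{path}: bad magic")
    if data[4] != _VERSION:
        raise FormatError(f"{path}: unsupported index version {data[4]}")
    if data[5:6] != kind:
        raise FormatError(f"{path}: wrong section kind")
    (size,) = struct.unpack("<Q", data[6:14])
    payload = data[14:]
    if len(payload) != size:
        raise FormatError(f"{path}: truncated file")
    return payload


def save_index(chunks: list[DatabaseChunk], prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": "sufseek-index",
        "version": _VERSION,
        "n_chunks": len(chunks),
        "chunks": [
            {"ids": ch.text.ids,
             "lengths": [int(v) for v in ch.text.lengths],
             "residue_count": ch.residue_count}
            for ch in chunks
        ],
    }
    (prefix.parent / (prefix.name + ".manifest.json")).write_text(
        json.dumps(manifest, indent=1))
    for ch in chunks:
        stem = prefix.parent / f"{prefix.name}.{ch.chunk_index}"
        _write_blob(stem.parent / (stem.name + ".text"), b"T",
                    ch.text.text.encode("ascii"))
        _write_blob(stem.parent / (stem.name + ".sa"), b"S",
                    ch.sa.positions.astype("<i4").tobytes())


def load_index(prefix: str | Path) -> list[DatabaseChunk]:
    prefix = Path(prefix)
    mpath = prefix.parent / (prefix.name + ".manifest.json")
    if not mpath.is_file():
        raise FormatError(f"missing manifest {mpath}")
    try:
        manifest = json.loads(mpath.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"{mpath}: unreadable manifest") from e
    if manifest.get("format") != "sufseek-index" or manifest.get("version") != _VERSION:
        raise FormatError(f"{mpath}: incompatible index version")
    chunks = []
    for i, meta in enumerate(manifest["chunks"]):
        stem = prefix.parent / f"{prefix.name}.{i}"
        raw = _read_blob(stem.parent / (stem.name + ".text"),
                         b"T").decode("ascii")
        positions = np.frombuffer(
            _read_blob(stem.parent / (stem.name + ".sa"), b"S"),
            dtype="<i4").astype(np.int32)
        boundaries = np.cumsum([0] + [l + 1 for l in meta["lengths"][:-1]])
        text = ConcatenatedText(text=raw, ids=list(meta["ids"]),
                                boundaries=boundaries,
                                lengths=np.array(meta["lengths"], dtype=np.int64),
                                code=_encode(raw))
        sa = SuffixArray(positions=positions)
        chunks.append(DatabaseChunk(
            chunk_index=i, text=text, sa=sa,
            ptable=build_prefix_table(sa, text),
            residue_count=int(meta["residue_count"])))
    return chunks
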