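"""Substitution matrices and Karlin–Altschul significance statistics.

The search engine scores candidate alignments as sums of substitution-matrix
entries over aligned residue pairs (BLOSUM62 by default).  Besides the 20
amino acids the working alphabet carries three extra symbols:

``X``
    ambiguity (scored with the canonical BLOSUM62 ``X`` row),
``*``
    a stop codon arising from six-frame translation,
``#``
    the delimiter inserted between concatenated sequences.

``*`` and ``#`` are given a score of (minimum matrix entry − 1) against every
symbol so that extensions crossing a stop or a sequence boundary are heavily
penalised; the seed search additionally treats ``#`` as a hard barrier.

Raw scores are converted to bit scores and E-values with Karlin–Altschul
statistics; the constants for gapped BLOSUM62 / gap 11,1 alignments are the
standard published values and can be overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "ScoreMatrix",
    "KarlinAltschulParams",
    "ConfigurationError",
    "load_score_matrix",
    "pair_score",
    "exact_match_score",
    "evalue",
    "bit_score",
    "RESIDUES",
    "AMBIGUOUS",
    "STOP",
    "DELIMITER",
    "ALPHABET",
]

#: The 20 standard amino acids in the collation order used for suffix sorting.
RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS = "X"
STOP = "*"
DELIMITER = "#"

#: Full working alphabet in collation order: the delimiter sorts lowest, then
#: the stop symbol, then residues and 'X' alphabetically.  This matches plain
#: ASCII ordering, which keeps brute-force oracles (python string comparison)
#: and the package's suffix sort in agreement.
ALPHABET = DELIMITER + STOP + "ACDEFGHIKLMNPQRSTVWXY"


class ConfigurationError(ValueError):
    """Unknown matrix name or unparseable matrix file."""


@dataclass(frozen=True)
class ScoreMatrix:
    """Substitution scores over the working alphabet.

    Parameters
    ----------
    alphabet : str
        Symbols in collation order (delimiter first).
    scores : numpy.ndarray
        ``(len(alphabet), len(alphabet))`` integer array of substitution
        scores indexed by symbol code.
    name : str
        Label, e.g. ``"BLOSUM62"``.
    """

    alphabet: str
    scores: np.ndarray
    name: str = "custom"
    _codes: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        codes = np.full(128, -1, dtype=np.int16)
        for i, c in enumerate(self.alphabet):
            codes[ord(c)] = i
        object.__setattr__(self, "_codes", codes)

    @property
    def size(self) -> int:
        return len(self.alphabet)

    def code(self, symbol: str) -> int:
        c = int(self._codes[ord(symbol)])
        if c < 0:
            raise KeyError(f"symbol {symbol!r} not in alphabet")
        return c

    def encode(self, s: str) -> np.ndarray:
        """Encode a symbol string as an int16 code array (collation order)."""
        arr = self._codes[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
        if (arr < 0).any():
            bad = s[int(np.argmax(arr < 0))]
            raise KeyError(f"symbol {bad!r} not in alphabet")
        return arr

    def score(self, a: str, b: str) -> int:
        return int(self.scores[self.code(a), self.code(b)])

    @property
    def delimiter_code(self) -> int:
        return self.code(DELIMITER)


def _parse_ncbi_matrix(lines, name: str) -> ScoreMatrix:
    rows = [ln for ln in (l.strip() for l in lines) if ln and not ln.startswith("#")]
    if not rows:
        raise ConfigurationError(f"{name}: empty matrix file")
    header = rows[0].split()
    if any(len(tok) != 1 for tok in header):
        bad = next(tok for tok in header if len(tok) != 1)
        raise ConfigurationError(f"{name}: malformed header token {bad!r}")
    raw: dict[tuple[str, str], int] = {}
    for ln in rows[1:]:
        toks = ln.split()
        sym = toks[0]
        if len(sym) != 1 or len(toks) != len(header) + 1:
            raise ConfigurationError(f"{name}: malformed row starting {toks[0]!r}")
        try:
            vals = [int(v) for v in toks[1:]]
        except ValueError as e:
            raise ConfigurationError(f"{name}: non-integer entry in row {sym!r}") from e
        for h, v in zip(header, vals):
            raw[(sym, h)] = v

    needed = set(RESIDUES + AMBIGUOUS)
    missing = needed - set(header)
    if missing:
        raise ConfigurationError(f"{name}: matrix lacks symbols {sorted(missing)}")

    n = len(ALPHABET)
    scores = np.zeros((n, n), dtype=np.int16)
    plain = RESIDUES + AMBIGUOUS
    for a in plain:
        for b in plain:
            scores[ALPHABET.index(a), ALPHABET.index(b)] = raw[(a, b)]
    # '#' and '*' score below every residue pair against everything, so no
    # extension can profit from crossing a boundary or a stop codon.
    res_idx = [ALPHABET.index(c) for c in plain]
    sentinel = int(scores[np.ix_(res_idx, res_idx)].min()) - 1
    for s in (DELIMITER, STOP):
        i = ALPHABET.index(s)
        scores[i, :] = sentinel
        scores[:, i] = sentinel
    return ScoreMatrix(alphabet=ALPHABET, scores=scores, name=name)


def load_score_matrix(name_or_path: str = "BLOSUM62") -> ScoreMatrix:
    """Load a bundled matrix by name or an NCBI-format matrix file by path.

    The bundled ``"BLOSUM62"`` is the canonical NCBI table; any readable
    whitespace-separated NCBI matrix file (header row of single-symbol
    columns) is also accepted.
    """
    bundled = resources.files("sufseek.matrices")
    candidate = bundled / f"{name_or_path}.txt"
    if candidate.is_file():
        return _parse_ncbi_matrix(candidate.read_text().splitlines(), name_or_path)
    p = Path(name_or_path)
    if p.is_file():
        return _parse_ncbi_matrix(p.read_text().splitlines(), p.stem)
    raise ConfigurationError(f"unknown score matrix {name_or_path!r}")


def pair_score(a: str, b: str, m: ScoreMatrix) -> int:
    """Ungapped score of two equal-length strings: sum of per-column entries."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if not a:
        return 0
    return int(m.scores[m.encode(a), m.encode(b)].sum())


def exact_match_score(a: str, m: ScoreMatrix) -> int:
    """Self-alignment score of ``a`` — the maximum any equal-length string
    can score against it under a matrix with dominant diagonal."""
    return pair_score(a, a, m)


@dataclass(frozen=True)
class KarlinAltschulParams:
    """Karlin–Altschul constants for converting raw scores to E-values.

    Defaults are the standard published values for gapped BLOSUM62 alignments
    with gap open 11 / extend 1: lambda = 0.267 (per raw-score unit),
    K = 0.041, and relative entropy H = 0.14 nats per aligned pair (H is used
    only for the effective-length adjustment).
    """

    lam: float = 0.267
    K: float = 0.041
    H: float = 0.14
    gapped: bool = True

    def __post_init__(self):
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("Karlin-Altschul lambda and K must be positive")


#: Ungapped BLOSUM62 constants, for reference / configuration.
UNGAPPED_BLOSUM62 = KarlinAltschulParams(lam=0.3176, K=0.134, H=0.4012, gapped=False)


def _effective_lengths(query_len: int, db_len: int, p: KarlinAltschulParams):
    # single-shot BLAST-style length adjustment
    ell = math.log(p.K * query_len * db_len) / p.H
    return max(query_len - ell, 1.0), max(db_len - ell, 1.0)


def evalue(raw_score: int, query_len: int, db_len: int,
           p: KarlinAltschulParams | None = None) -> float:
    """Expected number of chance alignments scoring >= ``raw_score``.

    ``E = K m' n' exp(-lambda S)`` with effective lengths m', n'.
    Strictly decreasing in the raw score and increasing in the database size.
    """
    if query_len <= 0 or db_len <= 0:
        raise ValueError("sequence lengths must be positive")
    if raw_score < 0:
        raise ValueError("raw score must be non-negative")
    p = p or KarlinAltschulParams()
    m_eff, n_eff = _effective_lengths(query_len, db_len, p)
    return p.K * m_eff * n_eff * math.exp(-p.lam * raw_score)


def bit_score(raw_score: int, p: KarlinAltschulParams | None = None) -> float:
    """Normalised score ``(lambda S - ln K) / ln 2``."""
    p = p or KarlinAltschulParams()
    return (p.lam * raw_score - math.log(p.K)) / math.log(2.0)
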