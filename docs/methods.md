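# Methods

## Model of the search problem

`sufseek` solves translated protein homology search: given DNA reads (or
proteins) and a protein database, report local alignments in BLAST tabular
form. It is a seed–extend engine. The defining design choice is the seed
stage: instead of enumerating fixed-length words, it finds *variable-length*
substring pairs whose substitution score first reaches a threshold, by a
simultaneous depth-first traversal of a query suffix array and a database
suffix array. High-information matches (e.g. `WWW`, BLOSUM62 self-score 33)
seed at length 3; low-information ones (`AAA`, self-score 12) only seed
after growing long enough to be worth extending. This lets the engine use a
much higher seed threshold than fixed-length word seeding at the same
sensitivity, which is the whole point: fewer, better seeds mean fewer
ungapped and gapped extensions.

## Seed search

Both texts are concatenations `S_0#S_1#...#S_{N-1}`. A state is
`(iv_q, iv_db, depth, score, score_max)` where the intervals hold all
occurrences of the current query/database substrings and `score_max` is the
query substring's self-alignment score. Per step every one-symbol
refinement pair is considered (≤ |Σ|² children, enumerated in ascending
collation order for deterministic output). The decision order at a child
is:

1. emit if `score >= T_seed` (the state's interval cross product becomes
   coordinate seeds; the state is not extended further — seeds are the
   *minimal-length* attainments, and longer similarity is recovered by the
   extension stages);
2. otherwise discard if `score <= score_max − D` or `score <= 0`;
3. otherwise extend, up to `length_max` symbols.

The comparison in (1) is `>=` and is centralised in one place; the
alternative strict inequality is a one-line change. With emission checked
before the lag prune, a state that simultaneously reaches the threshold and
lags by ≥ D is still emitted.

**Delimiters, stops and ambiguity.** `#` is a hard barrier: the traversal
never extends across it on either side, so no seed spans a sequence
boundary. This is enforced structurally rather than through scoring —
penalising `#` at (minimum entry − 1) alone would not guarantee exclusion,
because a sufficiently strong prefix could absorb the penalty and re-reach
the threshold on the far side. `*` (stop) and `X` (ambiguity) remain
ordinary walkable symbols: `*` scores (min − 1) against everything, `X`
uses the canonical BLOSUM62 `X` row. The brute-force oracle in the test
suite walks every coordinate pair under exactly these rules, and the
suffix-array search must reproduce its output set exactly.

**Defaults.** `T_seed = 30`, `D = 4` (the balanced operating point for
sensitivity versus speed), `length_max = 13`: since the BLOSUM62 diagonal
is ≥ 4, a state surviving the lag prune to depth 13 has score
≥ 4·13 − 4 = 48 > 30 and must already have been emitted, so the cap loses
nothing; it is exposed as a parameter regardless. Lowering `T_seed` or
raising `D` strictly enlarges the seed set (a tested monotonicity).

**Prefix table.** Database-side intervals for residue-only substrings of
length 1–5 are precomputed in one pass per depth over the suffix array
(runs of equal packed k-mers delimit the intervals), so the traversal's
shallow database narrowings are table lookups; keys containing `X`, `*` or
`#` fall back to binary narrowing, as do all deeper extensions. A table of
all ≤5-mers is the memory/speed sweet spot: each extra character multiplies
the table by |Σ|.

## Extension stages

**Ungapped.** Each direction walks one residue at a time, tracking running
and best scores, stopping at a boundary or when `running < best − x_drop`
(default 20 raw-score units, ≈ BLAST's ungapped dropoff under BLOSUM62);
the reported HSP is the best extent and always contains the seed.

**Chain filter.** Within a diagonal, overlapping HSPs are unioned; two
non-overlapping HSPs are unioned when the ungapped score of the segment
between them is ≥ −x_drop (the same budget as the ungapped stage). Merging
repeats until no pair qualifies, so the filter is idempotent; unions are
rescored from the texts. Only same-diagonal pairs chain — cross-diagonal
chaining would require a gap model this stage deliberately does not have,
and the gapped stage covers those cases.

**Gapped.** Affine-gap DP (gap of length L costs `open + L·extend`;
defaults 11/1, the BLAST defaults) extends outward from an anchor — the
midpoint of the HSP's maximal-scoring sub-segment — in both directions,
bounded by the enclosing delimiter-free segments. The anchor pair is always
aligned; the total is left extension + anchor + right extension. Frontier
cells falling more than `x_drop_gapped` (default 38, ≈ BLAST's 15-bit
cutoff) below the running best are dropped; rows die when no cell survives.
With an infinite dropoff the result equals the dense anchored
Smith–Waterman optimum (tested against an independent full-matrix DP), and
the score is monotone in the dropoff. Traceback yields identities,
mismatches and gap openings. Per (query, subject, frame), hits whose query
and subject spans are both contained in a better hit are culled.

## Statistics

E-values use Karlin–Altschul statistics, `E = K·m′·n′·exp(−λS)`, with the
standard published gapped BLOSUM62/11/1 constants λ = 0.267, K = 0.041 and
a single-shot length adjustment `l = ln(K·m·n)/H` with H = 0.14
(`m′ = max(m−l, 1)`, `n′ = max(n−l, 1)`); bit score is
`(λS − ln K)/ln 2`. The constants are configurable
(`KarlinAltschulParams`), and ungapped constants are provided. The choice
of gapped constants and the simple one-shot adjustment (rather than
BLAST's iterated one) is a pragmatic default for ranking and thresholding;
absolute E-values at the margins should not be over-interpreted.

## Pipeline

DNA queries are translated in all six frames with the standard codon table
(stops kept in frame as `*`; any codon outside the unambiguous table, e.g.
containing `N`, becomes `X`; trailing partial codons dropped). Frames are
batched (default 2000 frames per query suffix array — a memory knob with
no output effect, asserted by test) and searched against each database
chunk. Query coordinates in output follow the BLASTX convention: positions
on the DNA read, reverse strand as start > end. Rows are sorted per query
by bit score descending (ties: E-value, subject id), capped at
`max_targets` subjects per query (default 10 — ample for short-read
assignment) and filtered at E ≤ 10. Chunking (`l_db`, capped at 2³¹
symbols to fit 32-bit suffix offsets), batching and the thread count
(threads partition queries; merge order is fixed) provably do not change
the output — each is a tested invariance.

## Synthetic data

`sufseek.synthetic` generates the study conditions for all tests:
databases drawn i.i.d. from Robinson–Robinson background frequencies, and
reads planted by copying database segments, substituting residues to a
target identity (default benchmark: 500 proteins of 300 residues, 50 reads
of 150 nt at 80% identity), optionally adding single-residue indels,
reverse-translating through uniformly chosen synonymous codons and
coin-flipping the strand. The truth table records source, interval,
realised identity, indel counts, strand and the edited protein, and
regeneration is byte-identical per seed. What this does *not* emulate:
realistic base-call errors and quality profiles, codon-usage bias,
compositionally biased (low-complexity) protein families, and database
redundancy. Passing the planted-homolog benchmarks therefore demonstrates
algorithmic correctness and sensitivity at controlled divergence, not
performance on any particular real metagenome.

## Numerical and degenerate-input choices

- Collation `# < * < A < C < …` (ASCII order), so brute-force string
  comparison and the packaged suffix sort agree; suffix arrays are built by
  prefix doubling (O(n log² n) worst case) and verified against naive
  sorting.
- Intervals are half-open `[sp, ep)`; empty intervals propagate silently.
- Ungapped extension breaks ties toward the shorter extent (first best).
- Chain-filter merging iterates over all same-diagonal pairs to a fixed
  point rather than adjacent pairs only: two distant HSPs can qualify even
  when neither qualifies with an HSP between them.
- Duplicate seeds are impossible by construction (one DFS path per
  coordinate pair); tests assert rather than filter.
- Empty queries, empty intervals, seeds abutting delimiters, and
  header-only FASTA records are all exercised in the suite; the first
  three yield empty results, the last a named input error.

## Problem sizes used by the test suite

Oracle-equivalence suites run on texts of up to 500 residues (seed search,
100 fixtures over the T_seed × D grid), 200×200 dynamic programs (gapped
extension, 50 fixtures), 200 random extents (ungapped), 100 random HSP
sets (chain filter), and the 500×300-residue planted benchmark above for
chunk invariance and end-to-end recovery against a vectorised full
Smith–Waterman oracle. These sizes were chosen so each property is
exercised far beyond its edge cases while the whole suite stays
interactive (≈ 1–2 minutes).

## Known limitations

- No composition-based statistics and no reduced-alphabet mode.
- Seed emission stops extension; a single coordinate pair yields one seed.
- Cross-diagonal chaining is not performed (see above).
- The thread pool parallelises query partitions only; it exists for the
  output-invariance contract rather than throughput, and CPU-bound Python
  limits its speedup.
- E-value calibration is nominal (standard constants), not re-estimated
  from simulation.
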