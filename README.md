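# sufseek

Translated protein homology search with paired query/database suffix
arrays — a BLASTX-style seed–extend engine for assigning short DNA reads
(or proteins) to a protein database, aimed at metagenomic-scale workloads
where exhaustive Smith–Waterman or even word-hashing heuristics spend most
of their time on unpromising seeds.

## The algorithm

The engine runs in three stages:

1. **Score-adaptive seed search.** Database sequences are concatenated with
   `#` delimiters into one text S_db and suffix-indexed; each batch of
   translated query frames is indexed the same way as S_q. A depth-first
   traversal then walks *both* suffix arrays simultaneously: a search state
   is a pair of suffix-array intervals (all occurrences of a query
   substring X_q, all occurrences of a database substring X_db) with the
   running pair score and the query substring's self-alignment score
   `score_max`. Seeds are not fixed-length words — a state is emitted as
   seeds once its score reaches the threshold `T_seed` (default 30), so a
   `WWW` exact match (BLOSUM62 score 33) seeds immediately while `AAA`
   (score 12) must extend and prove itself. Two prunes keep the search
   space small: a state is dropped when `score <= score_max − D`
   (default D = 4) or when `score <= 0`. Short database-side lookups
   (length < 6) come from a precomputed prefix table instead of binary
   search.
2. **Ungapped extension and chain filtering.** Each seed is extended
   without gaps under X-drop termination, producing HSPs; same-diagonal
   HSPs that overlap, or whose intervening segment scores within the
   dropoff budget, are merged before the expensive stage.
3. **Gapped extension.** Surviving HSP chains are extended by affine-gap
   dynamic programming (open 11 / extend 1) outward from an anchor inside
   the HSP, with X-drop frontier pruning, and reported with
   Karlin–Altschul E-values and bit scores in the 12-column BLAST tabular
   format.

Large databases are split into chunks of at most `l_db` residues (never
splitting a sequence), searched chunk by chunk and merged — the output is
invariant under chunking, query batching and thread count.

## Worked example

Everything is testable without downloads: the `sufseek.synthetic` module
generates a random protein database and DNA reads copied from it at a
controlled identity.

```python
import sufseek as sk
from sufseek import synthetic as syn

db = syn.make_protein_db(100, 300, seed=5)              # 100 proteins, 300 aa
ps = syn.plant_queries(db, 3, identity=0.8,
                       read_len_nt=150, seed=6)         # 3 planted DNA reads
chunks = sk.chunk_database(db, 10**6)
matrix = sk.load_score_matrix("BLOSUM62")
rows = sk.search(ps.queries, chunks, matrix, sk.SearchParams())
sk.write_tabular(rows, "hits.tsv")
```

The first lines of `hits.tsv`:

```
q00000	db00044	75.51	49	12	0	1	147	136	184	6.7e-20	78.6
q00001	db00021	70.00	50	15	0	1	150	15	64	3.8e-15	62.8
q00002	db00053	80.00	50	10	0	1	150	80	129	8.7e-20	78.2
q00002	db00089	57.14	14	4	1	9	50	67	78	0.11	18.1
```

Columns are query id, subject id, % identity, alignment length,
mismatches, gap openings, query start/end (positions on the DNA read,
reverse strand shown as start > end), subject start/end, E-value and bit
score. The truth table records that q00000 was planted from db00044 at 74%
identity, q00001 from db00021, q00002 from db00053 — each is the top hit;
the two weak extra rows for q00002 are chance matches at E-values near 0.1.

The same search runs from the shell:

```
sufseek index -i db.fasta -o idx --chunk-size 2000000000
sufseek aln -i reads.fasta -d idx -o hits.tsv --seed-threshold 30 --mismatch-bound 4
```

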