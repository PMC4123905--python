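import numpy as np
import pytest

from helpers import anchored_dp_oracle, smith_waterman_scores, ungapped_extent_oracle
from sufseek.extension import (HSP, chain_filter, cull_contained,
                               gapped_extend, ungapped_extend,
                               _best_subsegment_mid)
from sufseek.scoring import exact_match_score, pair_score
from sufseek.seed_search import Seed
from sufseek.suffix_index import concat_sequences


def planted_pair(rng, n, motif_len, q_at, d_at, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    def rp(k):
        return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), k))
    motif = rp(motif_len)
    q = rp(n)
    d = rp(n)
    q = q[:q_at] + motif + q[q_at + motif_len:]
    d = d[:d_at] + motif + d[d_at + motif_len:]
    return q, d, motif


class TestUngappedExtend:
    def test_identity_run_extends_fully(self, blosum62):
        """A seed inside identical flanks covers the whole identity run."""
        flank = "HKWYC"
        q = flank + "WWW" + flank
        seed = Seed(5, 5, 3, 33)
        qt = concat_sequences([("q", q)])
        dt = concat_sequences([("d", q)])
        h = ungapped_extend(seed, qt, dt, blosum62, 20)
        assert (h.q_start, h.q_end) == (0, len(q))
        assert h.score == exact_match_score(q, blosum62)

    def test_seed_abutting_delimiters_stays_put(self, blosum62):
        qt = concat_sequences([("a", "CC"), ("q", "WWW"), ("b", "CC")])
        dt = concat_sequences([("a", "HH"), ("d", "WWW"), ("b", "HH")])
        seed = Seed(3, 3, 3, 33)
        h = ungapped_extend(seed, qt, dt, blosum62, 20)
        assert (h.q_start, h.q_end, h.db_start, h.db_end) == (3, 6, 3, 6)
        assert h.score == 33

    def test_matches_exhaustive_extent_search(self, blosum62, rng):
        """200 random seeds vs brute-force search over dropoff-reachable
        extents."""
        for _ in range(200):
            n = int(rng.integers(40, 120))
            L = int(rng.integers(3, 8))
            q_at = int(rng.integers(0, n - L))
            d_at = int(rng.integers(0, n - L))
            q, d, motif = planted_pair(rng, n, L, q_at, d_at)
            seed = Seed(q_at, d_at, L, pair_score(motif, motif, blosum62))
            qt = concat_sequences([("q", q)])
            dt = concat_sequences([("d", d)])
            h = ungapped_extend(seed, qt, dt, blosum62, 20)
            bl, lg, br, rg = ungapped_extent_oracle(seed, q, d, blosum62, 20)
            assert h == HSP(q_at - bl, q_at + L + br, d_at - bl,
                            d_at + L + br, seed.score + lg + rg)


def mk_hsp(qt, dt, m, q_start, q_end, diag):
    return HSP(q_start, q_end, q_start + diag, q_end + diag,
               pair_score(qt.text[q_start:q_end],
                          dt.text[q_start + diag:q_end + diag], m))


class TestChainFilter:
    def test_total_overlap_collapses(self, blosum62, rng):
        q, d, _ = planted_pair(rng, 60, 20, 10, 10)
        qt, dt = concat_sequences([("q", q)]), concat_sequences([("d", d)])
        h = mk_hsp(qt, dt, blosum62, 12, 25, 0)
        assert chain_filter([h, h], qt, dt, blosum62, 20) == [h]

    def test_different_diagonals_untouched(self, blosum62, rng):
        q, d, _ = planted_pair(rng, 60, 20, 10, 14)
        qt, dt = concat_sequences([("q", q)]), concat_sequences([("d", d)])
        a = mk_hsp(qt, dt, blosum62, 12, 20, 0)
        b = mk_hsp(qt, dt, blosum62, 30, 40, 4)
        assert set(chain_filter([a, b], qt, dt, blosum62, 20)) == {a, b}

    def test_gap_segment_score_decides_merging(self, blosum62):
        """Same-diagonal HSPs separated by one cheap mismatch merge; the
        same pair separated by a high-penalty stretch does not."""
        # cheap: one aligned (S,T) column scores +1 >= -20
        q1 = "WWWW" + "S" + "WWWW"
        d1 = "WWWW" + "T" + "WWWW"
        qt, dt = concat_sequences([("q", q1)]), concat_sequences([("d", d1)])
        a = mk_hsp(qt, dt, blosum62, 0, 4, 0)
        b = mk_hsp(qt, dt, blosum62, 5, 9, 0)
        merged = chain_filter([a, b], qt, dt, blosum62, 20)
        assert merged == [mk_hsp(qt, dt, blosum62, 0, 9, 0)]
        # expensive: 5 aligned (W,P) columns score -20 < -x_drop for x_drop=19
        q2 = "WWWW" + "WWWWW" + "WWWW"
        d2 = "WWWW" + "PPPPP" + "WWWW"
        qt, dt = concat_sequences([("q", q2)]), concat_sequences([("d", d2)])
        a = mk_hsp(qt, dt, blosum62, 0, 4, 0)
        b = mk_hsp(qt, dt, blosum62, 9, 13, 0)
        assert set(chain_filter([a, b], qt, dt, blosum62, 19)) == {a, b}
        # the same stretch merges once the dropoff budget covers it
        assert len(chain_filter([a, b], qt, dt, blosum62, 20)) == 1

    def _random_hsps(self, blosum62, rng):
        q, d, _ = planted_pair(rng, 150, 30, 40, 40)
        qt, dt = concat_sequences([("q", q)]), concat_sequences([("d", d)])
        hsps = []
        for _ in range(int(rng.integers(2, 12))):
            diag = int(rng.integers(-3, 4)) * int(rng.integers(0, 2))
            q0 = int(rng.integers(5, 120))
            ln = int(rng.integers(3, 15))
            if 0 <= q0 + diag and q0 + ln + diag <= 150:
                hsps.append(mk_hsp(qt, dt, blosum62, q0, q0 + ln, diag))
        return hsps, qt, dt

    def test_idempotent_and_postconditions(self, blosum62, rng):
        """filter(filter(x)) == filter(x); survivors satisfy neither merge
        condition pairwise. 100 random HSP sets."""
        from sufseek.extension import _diagonal_segment_score

        for _ in range(100):
            hsps, qt, dt = self._random_hsps(blosum62, rng)
            once = chain_filter(hsps, qt, dt, blosum62, 20)
            assert chain_filter(once, qt, dt, blosum62, 20) == once
            for i, a in enumerate(once):
                for b in once[i + 1:]:
                    if a.diagonal != b.diagonal:
                        continue
                    lo, hi = sorted([a, b], key=lambda h: h.q_start)
                    assert lo.q_end <= hi.q_start  # no overlap survives
                    gap = _diagonal_segment_score(
                        qt.code, dt.code, blosum62.scores,
                        lo.q_end, hi.q_start, a.diagonal)
                    assert gap < -20


class TestGappedExtend:
    def test_identical_sequences_full_identity(self, blosum62, rng):
        q, _, _ = planted_pair(rng, 50, 10, 20, 20)
        qt = concat_sequences([("q", q)])
        h = HSP(20, 30, 20, 30, pair_score(q[20:30], q[20:30], blosum62))
        g = gapped_extend(h, qt, qt, blosum62, 11, 1, float("inf"))
        assert g.raw_score == exact_match_score(q, blosum62)
        assert g.n_gap_openings == 0 and g.n_mismatch == 0
        assert g.aligned_length == len(q) and g.n_identical == len(q)

    def test_infinite_dropoff_equals_anchored_smith_waterman(self, blosum62,
                                                             rng):
        """50 instances up to 200x200 vs the dense anchored-DP oracle."""
        for _ in range(50):
            n = int(rng.integers(60, 200))
            L = 12
            q_at = int(rng.integers(5, n - L - 5))
            d_at = int(rng.integers(5, n - L - 5))
            q, d, motif = planted_pair(rng, n, L, q_at, d_at)
            qt, dt = concat_sequences([("q", q)]), concat_sequences([("d", d)])
            h = HSP(q_at, q_at + L, d_at, d_at + L,
                    pair_score(motif, motif, blosum62))
            g = gapped_extend(h, qt, dt, blosum62, 11, 1, float("inf"))
            off = _best_subsegment_mid(qt.code, dt.code, blosum62.scores, h)
            expected = anchored_dp_oracle(q, d, q_at + off, d_at + off,
                                          blosum62, 11, 1)
            assert g.raw_score == expected

    def test_score_monotone_in_dropoff(self, blosum62, rng):
        for _ in range(20):
            q, d, motif = planted_pair(rng, 120, 10, 30, 50)
            qt, dt = concat_sequences([("q", q)]), concat_sequences([("d", d)])
            h = HSP(30, 40, 50, 60, pair_score(motif, motif, blosum62))
            scores = [gapped_extend(h, qt, dt, blosum62, 11, 1, xd).raw_score
                      for xd in (5, 15, 38, float("inf"))]
            assert all(a <= b for a, b in zip(scores, scores[1:]))

    def test_planted_two_residue_insertion(self, blosum62, rng):
        """A homolog with one 2-residue insertion aligns with exactly one
        gap of length 2 under open 11 / extend 1."""
        core = "WHKRFDEYCMNQWHKRFDEYCMNQ"
        q = core
        s = core[:12] + "GG" + core[12:]
        qt, st = concat_sequences([("q", q)]), concat_sequences([("s", s)])
        h = HSP(0, 10, 0, 10, pair_score(core[:10], core[:10], blosum62))
        g = gapped_extend(h, qt, st, blosum62, 11, 1, float("inf"))
        assert g.n_gap_openings == 1
        assert g.aligned_length - (g.n_identical + g.n_mismatch) == 2
        assert g.raw_score == exact_match_score(core, blosum62) - 11 - 2 * 1

    def test_against_independent_local_aligner(self, blosum62, rng):
        """Where the optimum passes the anchor (a strong planted core), the
        anchored score equals Biopython's unconstrained local optimum."""
        from Bio import Align
        from Bio.Align import substitution_matrices

        al = Align.PairwiseAligner()
        al.mode = "local"
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
        al.open_gap_score = -12
        al.extend_gap_score = -1
        for _ in range(5):
            q, d, motif = planted_pair(rng, 80, 25, 20, 30)
            qt, dt = concat_sequences([("q", q)]), concat_sequences([("d", d)])
            h = HSP(20, 45, 30, 55, pair_score(motif, motif, blosum62))
            g = gapped_extend(h, qt, dt, blosum62, 11, 1, float("inf"))
            assert g.raw_score == int(al.score(q, d))


class TestCullContained:
    def test_contained_hit_dropped_crossing_kept(self):
        from sufseek.extension import GappedHit

        def gh(q0, q1, s0, s1, score):
            return GappedHit(q0, q1, s0, s1, score, 0, 0, 0, q1 - q0,
                             query_id="q", subject_id="s")

        big = gh(0, 50, 0, 50, 100)
        inner = gh(10, 20, 10, 20, 30)
        shifted = gh(40, 60, 40, 60, 30)
        kept = cull_contained([inner, big, shifted])
        assert big in kept and shifted in kept and inner not in kept
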