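"""Seed finding, x-drop extension and equivalence with exact DP."""

import numpy as np
import pytest

from helpers import point_mutate, random_dna

from mitocomp.seedalign import (
    AlignmentHit,
    Scoring,
    Seed,
    extend_hit,
    find_seeds,
    hits_table,
    local_align_exact,
)
from mitocomp.seqio import SequenceRecord, revcomp


class TestFindSeeds:
    def test_self_identity_seeds(self):
        seeds = find_seeds("ACGTACGT", "ACGTACGT", 7)
        plus = {(s.q, s.s) for s in seeds if s.strand == "+"}
        assert plus == {(0, 0), (1, 1)}
        # every reported seed satisfies exact (rc-)k-mer equality
        for s in seeds:
            q = "ACGTACGT"[s.q : s.q + 7]
            t = "ACGTACGT"[s.s : s.s + 7]
            assert q == (t if s.strand == "+" else revcomp(t))

    def test_reverse_complement_seed(self):
        assert find_seeds("AAAAAAA", "TTTTTTT", 7) == [Seed(0, 0, "-", 7)]

    def test_planted_shared_kmer_block(self, rng):
        k = 12
        block = random_dna(50, rng)
        q = random_dna(400, rng) + block + random_dna(400, rng)
        s = random_dna(300, rng) + block + random_dna(300, rng)
        seeds = [x for x in find_seeds(q, s, k) if x.strand == "+"]
        inside = [x for x in seeds if 400 <= x.q <= 450 - k and 300 <= x.s <= 350 - k]
        assert len(inside) >= 50 - k + 1

    def test_word_too_long_returns_empty(self):
        assert find_seeds("ACGT", "ACGTACGT", 6) == []

    def test_small_word_rejected(self):
        with pytest.raises(ValueError, match="word size"):
            find_seeds("ACGTACGT", "ACGTACGT", 3)

    def test_n_never_matches(self):
        assert find_seeds("ANNNA" * 3, "ANNNA" * 3, 5) == []


class TestExtendHit:
    def test_identical_sequences_full_span(self, rng):
        a = random_dna(200, rng)
        h = extend_hit(Seed(90, 90, "+", 12), a, a)
        assert (h.q_start, h.q_end, h.s_start, h.s_end) == (0, 200, 0, 200)
        assert h.identity == 1.0
        assert h.score == 400

    def test_planted_mutated_copy_matches_exact_dp(self, rng):
        core = random_dna(100, rng)
        # scatter 5 substitutions through the interior of the copy
        mutated = list(core)
        for p in (15, 32, 51, 68, 84):
            mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
        q = random_dna(60, rng) + core + random_dna(60, rng)
        s = random_dna(60, rng) + "".join(mutated) + random_dna(60, rng)
        seeds = find_seeds(q, s, 12)
        best = max((extend_hit(x, q, s) for x in seeds), key=lambda h: h.score)
        oracle = local_align_exact(q, s)
        assert best.score == oracle.score
        assert best.identity >= 0.95
        # the hit covers the planted copy
        assert best.q_start <= 62 and best.q_end >= 158

    def test_random_seed_stays_short(self, rng):
        # an isolated chance k-mer match in random sequence barely extends
        k = 8
        q = random_dna(300, rng)
        s = random_dna(300, rng)
        for seed in find_seeds(q, s, k)[:20]:
            h = extend_hit(seed, q, s)
            assert h.length < 2 * k + 10

    def test_minus_strand_coordinates_ascending(self, rng):
        core = random_dna(80, rng)
        q = random_dna(50, rng) + core + random_dna(50, rng)
        s = random_dna(40, rng) + revcomp(core) + random_dna(40, rng)
        seeds = [x for x in find_seeds(q, s, 12) if x.strand == "-"]
        h = extend_hit(seeds[0], q, s)
        assert h.strand == "-"
        assert h.q_start < h.q_end and h.s_start < h.s_end
        assert h.identity == 1.0
        # covers the planted copy (chance flank matches may add a few bp)
        assert h.s_start <= 40 and h.s_end >= 120
        assert h.s_end - h.s_start <= 85


class TestOracleEquivalence:
    @pytest.mark.parametrize("trial", range(12))
    def test_best_extension_equals_smith_waterman(self, trial):
        """On planted-homology instances <= 300 bp the seeded x-drop
        extension attains the optimal local alignment score."""
        rng = np.random.default_rng(9000 + trial)
        core_len = int(rng.integers(40, 80))
        n_mut = int(rng.integers(0, core_len // 10))
        core = random_dna(core_len, rng)
        q = random_dna(80, rng) + core + random_dna(80, rng)
        s = random_dna(80, rng) + point_mutate(core, n_mut, rng) + random_dna(80, rng)
        seeds = find_seeds(q, s, 11)
        assert seeds, "planted homology must produce at least one seed"
        best = max(extend_hit(x, q, s).score for x in seeds)
        assert best == local_align_exact(q, s).score

    def test_symmetry_swapped_inputs(self, rng):
        core = random_dna(60, rng)
        q = random_dna(70, rng) + core + random_dna(70, rng)
        s = random_dna(70, rng) + core + random_dna(70, rng)
        fwd = max((extend_hit(x, q, s) for x in find_seeds(q, s, 12)), key=lambda h: h.score)
        rev = max((extend_hit(x, s, q) for x in find_seeds(s, q, 12)), key=lambda h: h.score)
        assert fwd.score == rev.score
        assert fwd.swapped().q_interval == rev.q_interval
        assert fwd.swapped().s_interval == rev.s_interval


class TestLocalAlignExact:
    def test_trivial_identity(self):
        h = local_align_exact("ACGT", "ACGT")
        assert h.score == 8 and h.identity == 1.0

    def test_reverse_complement_full_hit(self):
        a = "AAACGGT"
        h = local_align_exact(a, revcomp(a))
        assert h.strand == "-"
        assert h.length == len(a) and h.identity == 1.0

    def test_planted_core_contained(self, rng):
        core = random_dna(40, rng)
        a = random_dna(55, rng) + core + random_dna(55, rng)
        b = random_dna(55, rng) + core + random_dna(55, rng)
        h = local_align_exact(a, b)
        assert h.q_start <= 55 and h.q_end >= 95

    def test_size_cap_refused(self):
        with pytest.raises(ValueError, match="quadratic"):
            local_align_exact("A" * 2000, "A" * 2000)


class TestScoringAndTypes:
    def test_scoring_validation(self):
        with pytest.raises(ValueError):
            Scoring(match=-1)
        with pytest.raises(ValueError):
            Scoring(mismatch=1)
        with pytest.raises(ValueError):
            Scoring(gap_extend=0)

    def test_hit_invariants(self):
        with pytest.raises(ValueError):
            AlignmentHit(5, 5, 0, 3, "+", 1.0, 3, 6)
        with pytest.raises(ValueError):
            AlignmentHit(0, 3, 0, 3, "+", 1.5, 3, 6)

    def test_sequence_record_validation(self):
        with pytest.raises(ValueError):
            SequenceRecord("", "ACGT")
        with pytest.raises(ValueError):
            SequenceRecord("x", "")
        with pytest.raises(ValueError):
            SequenceRecord("x", "ACGU")

    def test_hits_table_blast_style(self, rng):
        core = random_dna(60, rng)
        q = random_dna(30, rng) + core + random_dna(30, rng)
        s = random_dna(30, rng) + revcomp(core) + random_dna(30, rng)
        seeds = [x for x in find_seeds(q, s, 12) if x.strand == "-"]
        df = hits_table([extend_hit(seeds[0], q, s)], "q", "s")
        row = df.iloc[0]
        assert row["qstart"] < row["qend"]
        assert row["sstart"] > row["send"]  # minus hits print descending
        assert row["pident"] == 100.0
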