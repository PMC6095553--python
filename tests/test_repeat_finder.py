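"""Repeat detection, classification and the published worked example."""

from collections import Counter

import pytest

from helpers import covers, overlap_fraction, random_dna

from mitocomp.repeat_finder import (
    RepeatPair,
    classify_repeat_size,
    find_repeats,
    load_reference_repeat_table,
    orient_repeat,
    repeats_to_table,
    summarize_repeats,
    table_to_pairs,
)
from mitocomp.seqio import SequenceRecord, revcomp


def _toy_genome(rng):
    """10 kb circular genome with a planted 2,160 bp DR and a 446 bp IR."""
    bg = list(random_dna(10_000, rng))
    bg[5000:7160] = bg[1000:3160]
    bg[8000:8446] = list(revcomp("".join(bg[3500:3946])))
    return SequenceRecord("toy", "".join(bg), circular=True)


class TestFindRepeats:
    def test_planted_direct_and_inverted_pairs(self, rng):
        reps = find_repeats(_toy_genome(rng))
        big = [r for r in reps if r.size >= 100]
        assert len(big) == 2
        dr, ir = sorted(big, key=lambda r: -r.size)

        def close(iv, expected, slack=3):
            # chance matches in the random flanks may extend a hit a few bp
            return abs(iv[0] - expected[0]) <= slack and abs(iv[1] - expected[1]) <= slack

        assert dr.orientation == "DR" and dr.size_class == "large"
        assert close(dr.copy1, (1000, 3160)) and close(dr.copy2, (5000, 7160))
        assert dr.identity == 100.0
        assert ir.orientation == "IR" and ir.size_class == "medium"
        assert close(ir.copy1, (3500, 3946)) and close(ir.copy2, (8000, 8446))

    def test_random_genome_has_no_big_repeats(self, rng):
        g = SequenceRecord("r", random_dna(2000, rng), circular=True)
        reps = find_repeats(g)
        assert not [r for r in reps if r.size >= 100]
        assert all(r.identity >= 80.0 for r in reps)

    def test_deterministic_and_sorted(self, rng):
        g = _toy_genome(rng)
        a, b = find_repeats(g), find_repeats(g)
        assert a == b
        assert a == sorted(a, key=lambda r: (r.copy1, r.copy2))

    def test_rotation_invariance(self, rng):
        """Rotating the origin leaves the repeat set unchanged modulo
        coordinate rotation."""
        g = _toy_genome(rng)
        L = len(g)
        off = 4321
        rot = SequenceRecord("rot", g.seq[off:] + g.seq[:off], circular=True)

        def keyset(reps, shift):
            out = set()
            for r in reps:
                if r.size < 100:
                    continue
                ivs = sorted(
                    ((s + shift) % L, (s + shift) % L + (e - s)) for s, e in (r.copy1, r.copy2)
                )
                out.add((tuple(ivs[0]), tuple(ivs[1]), r.orientation, r.size))
            return out

        assert keyset(find_repeats(g), 0) == keyset(find_repeats(rot), off)

    def test_genome_too_short_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            find_repeats(SequenceRecord("s", "ACGT" * 5, circular=True), min_len=20)

    def test_planted_recovery_noise_free(self, repeat_only_sim):
        """Precision = recall = 1.0 for planted copies >= 100 bp."""
        sim = repeat_only_sim
        found = [r for r in find_repeats(sim.genome) if r.size >= 100]
        truth = sim.truth.repeats

        def matches(t, f):
            # coverage of the planted copy plus bounded dilation: chance
            # flank matches may extend a hit some bp past the boundaries
            return (
                covers(tuple(t["copy1"]), f.copy1)
                and overlap_fraction(tuple(t["copy1"]), f.copy1) >= 0.8
                and covers(tuple(t["copy2"]), f.copy2)
                and overlap_fraction(tuple(t["copy2"]), f.copy2) >= 0.8
                and t["orientation"] == f.orientation
            )

        assert all(any(matches(t, f) for f in found) for t in truth)  # recall
        assert all(any(matches(t, f) for t in truth) for f in found)  # precision


class TestClassification:
    @pytest.mark.parametrize(
        "size,expected",
        [
            (20, "small"),
            (99, "small"),
            (100, "medium"),
            (999, "medium"),
            (1000, "large"),
            (795, "medium"),
            (2160, "large"),
        ],
    )
    def test_size_classes(self, size, expected):
        assert classify_repeat_size(size) == expected

    def test_below_reporting_threshold(self):
        with pytest.raises(ValueError, match="threshold"):
            classify_repeat_size(19)

    def test_orientation_from_coordinate_directions(self):
        # copy2 printed descending -> inverted repeat
        assert orient_repeat((131028, 131822), (199473, 198679)) == "IR"
        # copy2 ascending -> direct repeat
        assert orient_repeat((150477, 152636), (323868, 326027)) == "DR"
        with pytest.raises(ValueError, match="degenerate"):
            orient_repeat((5, 5), (1, 10))

    def test_palindrome_is_self_overlapping_ir(self):
        p = RepeatPair((100, 130), (100, 130), 100.0, 30, "IR")
        assert p.self_overlap


class TestSummary:
    def test_counts_and_union(self):
        reps = [
            RepeatPair((0, 150), (300, 450), 100.0, 150, "DR"),
            RepeatPair((0, 150), (600, 750), 100.0, 150, "DR"),  # shared copy1 span
            RepeatPair((1000, 2100), (3000, 4100), 99.0, 1100, "DR"),
        ]
        s = summarize_repeats(reps, 10_000)
        assert (s.n_small, s.n_medium, s.n_large) == (0, 2, 1)
        assert s.total_pairs == 3
        # shared copy1 span counted once: 150*3 + 1100*2
        assert s.total_bp == 150 * 3 + 1100 * 2
        assert s.fraction == s.total_bp / 10_000

    def test_one_copy_mode(self):
        reps = [RepeatPair((0, 100), (500, 600), 100.0, 100, "DR")]
        assert summarize_repeats(reps, 1000, count_mode="one_copy").total_bp == 100

    def test_empty(self):
        s = summarize_repeats([], 1000)
        assert s.total_bp == 0 and s.fraction == 0.0

    def test_bad_length(self):
        with pytest.raises(ValueError):
            summarize_repeats([], 0)


class TestReferenceTable:
    """The published 21-pair repeat table of the S. japonica mitogenome."""

    def test_size_classes_and_counts(self):
        pairs = table_to_pairs(load_reference_repeat_table())
        assert len(pairs) == 21
        counts = Counter(p.size_class for p in pairs)
        assert counts == {"medium": 20, "large": 1}
        assert max(p.size for p in pairs) == 2160

    def test_orientation_reproduces_printed_types(self):
        df = load_reference_repeat_table()
        pairs = table_to_pairs(df)
        assert [p.orientation for p in pairs] == list(df["Type"])
        assert Counter(df["Type"]) == {"IR": 13, "DR": 8}

    def test_roundtrip_through_report_layout(self, rng):
        reps = find_repeats(_toy_genome(rng))
        df = repeats_to_table(reps, 10_000)
        back = table_to_pairs(df)
        assert {(p.copy1, p.copy2, p.orientation) for p in back} == {
            (p.copy1, p.copy2, p.orientation) for p in reps
        }
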