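"""Intron length tables, deletion blocks and deletion-edge repeats."""

import math

import pytest

from helpers import random_dna

from mitocomp.intron_scan import (
    edge_repeat_search,
    find_deletion_blocks,
    intron_length_table,
    read_alignment_fasta,
)
from mitocomp.synthetic import make_intron_alignment


class TestIntronLengthTable:
    def test_gap_reduces_length(self):
        aln = {"t1": "ACGTACGTAC", "t2": "ACGT----AC", "t3": "ACGTACGTAC"}
        table = intron_length_table({"i1": aln})
        assert table.loc["t1", "i1"] == 10
        assert table.loc["t2", "i1"] == 6

    def test_missing_taxon_is_nan(self):
        table = intron_length_table({"i1": {"t1": "ACGT"}, "i2": {"t2": "AC--"}})
        assert math.isnan(table.loc["t2", "i1"])
        assert table.loc["t2", "i2"] == 2

    def test_invariant_to_column_permutation(self, rng):
        cols = ["AC-", "CG-", "T-A", "GAT"]
        aln1 = {t: "".join(c[i] for c in cols) for i, t in enumerate(["a", "b", "c"])}
        perm = [cols[j] for j in rng.permutation(len(cols))]
        aln2 = {t: "".join(c[i] for c in perm) for i, t in enumerate(["a", "b", "c"])}
        t1 = intron_length_table({"x": aln1})
        t2 = intron_length_table({"x": aln2})
        assert t1.equals(t2)

    def test_bimodal_lengths_recovered(self):
        """Mimics an intron present as ~950 bp in some taxa and ~4 kb in
        others (an ancestral-short / derived-long pattern)."""
        aln, _ = make_intron_alignment(
            n_taxa=4, n_deleted=2, intron_len=4000, deletion_len=3050, seed=8
        )
        lengths = sorted(intron_length_table({"ccmFci829": aln})["ccmFci829"])
        assert lengths[:2] == [950.0, 950.0]
        assert lengths[2:] == [4000.0, 4000.0]

    def test_duplicate_taxon_rejected(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">a\nACGT\n>a\nACGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_alignment_fasta(p)


class TestFindDeletionBlocks:
    def test_single_gap_run(self, rng):
        keep = random_dna(300, rng)
        aln = {"t1": keep, "t2": keep[:100] + "-" * 100 + keep[200:]}
        blocks = find_deletion_blocks(aln, min_del=50)
        assert len(blocks) == 1
        b = blocks[0]
        assert (b.taxon, b.col_start, b.col_end, b.length) == ("t2", 100, 200, 100)
        assert b.affected_taxa == ("t2",)

    def test_nearby_runs_merged(self, rng):
        keep = random_dna(300, rng)
        gapped = keep[:100] + "-" * 60 + keep[160:165] + "-" * 60 + keep[225:]
        blocks = find_deletion_blocks({"t1": keep, "t2": gapped}, min_del=50, merge_gap=10)
        assert len(blocks) == 1
        assert blocks[0].length == 125

    def test_all_taxon_gap_is_not_a_deletion(self):
        aln = {"t1": "AC" + "-" * 60 + "GT", "t2": "AC" + "-" * 60 + "GT"}
        assert find_deletion_blocks(aln, min_del=50) == []

    def test_invariant_to_all_gap_columns(self, rng):
        keep = random_dna(200, rng)
        aln = {"t1": keep, "t2": keep[:50] + "-" * 80 + keep[130:]}
        # inject 20 all-gap columns inside the run
        aln2 = {t: s[:90] + "-" * 20 + s[90:] for t, s in aln.items()}
        b1 = find_deletion_blocks(aln, min_del=50)
        b2 = find_deletion_blocks(aln2, min_del=50)
        assert [(b.taxon, b.length, b.affected_taxa) for b in b1] == [
            (b.taxon, b.length, b.affected_taxa) for b in b2
        ]

    def test_needs_two_taxa(self):
        with pytest.raises(ValueError):
            find_deletion_blocks({"t1": "ACGT"})


class TestEdgeRepeatSearch:
    def test_repeat_at_exact_edges(self):
        aln, truth = make_intron_alignment(edge_offset=0, repeat_len=15, seed=4)
        block = find_deletion_blocks(aln, alignment_id="i")[0]
        hits = edge_repeat_search(aln["taxon_1"], block)
        assert hits, "planted edge repeat must be found"
        top = hits[0]
        assert top.length >= truth["repeat_len"]
        assert top.offset_left == 0 and top.offset_right == 0
        assert truth["repeat_seq"] in top.seq or top.seq in truth["repeat_seq"]

    def test_repeat_inside_edges_within_window(self):
        aln, truth = make_intron_alignment(edge_offset=3, repeat_len=13, seed=6)
        block = find_deletion_blocks(aln, alignment_id="i")[0]
        hits = edge_repeat_search(aln["taxon_1"], block, window=5)
        assert hits
        assert hits[0].offset_left <= 3 and hits[0].offset_right <= 3
        # a strict window of 0 misses a repeat 3 bp inside the edges
        assert edge_repeat_search(aln["taxon_1"], block, window=0) == []

    def test_no_planted_repeat_returns_empty(self):
        aln, _ = make_intron_alignment(plant_repeat=False, seed=4)
        block = find_deletion_blocks(aln, alignment_id="i")[0]
        assert edge_repeat_search(aln["taxon_1"], block) == []

    def test_planted_recall_and_negative_rate(self):
        """Recall 1.0 over repeat lengths 10-20 and offsets 0-5; empirical
        false positives on unplanted alignments stay below the analytic
        k-mer collision expectation."""
        found = 0
        total = 0
        for rep_len in (10, 13, 15, 20):
            for off in (0, 2, 5):
                total += 1
                aln, truth = make_intron_alignment(
                    edge_offset=off, repeat_len=rep_len, seed=100 + rep_len * 10 + off
                )
                block = find_deletion_blocks(aln)[0]
                hits = edge_repeat_search(aln["taxon_1"], block, window=5)
                if hits and hits[0].length >= rep_len and max(
                    hits[0].offset_left, hits[0].offset_right
                ) <= 5:
                    found += 1
        assert found == total

        fp = 0
        n_neg = 30
        for s in range(n_neg):
            aln, _ = make_intron_alignment(plant_repeat=False, seed=2000 + s)
            block = find_deletion_blocks(aln)[0]
            if edge_repeat_search(aln["taxon_1"], block, window=5):
                fp += 1
        # expected chance 10-mer pairs anchored in two 11-position windows:
        # ~ 11 * 11 * 4^-10 per alignment plus slack for boundary effects
        expected = n_neg * (11 * 11 * 2 * 30) * 0.25**10
        assert fp <= max(1, math.ceil(expected * 3))

    def test_deletion_outside_retained_span_rejected(self):
        aln, _ = make_intron_alignment(seed=4)
        block = find_deletion_blocks(aln)[0]
        with pytest.raises(ValueError, match="outside"):
            edge_repeat_search(aln["taxon_4"], block)  # taxon_4 is the deleted one

    def test_inverted_edge_search_behind_flag(self, rng):
        from mitocomp.seqio import revcomp

        seq = list(random_dna(500, rng))
        bs, be = 150, 350
        left = "GATTACAGATTAC"
        seq[bs : bs + 13] = list(left)
        seq[be - 13 : be] = list(revcomp(left))
        s = "".join(seq)
        aligned = {"keep": s, "del": s[:bs] + "-" * (be - bs) + s[be:]}
        block = find_deletion_blocks(aligned, min_del=50)[0]
        direct = edge_repeat_search(aligned["keep"], block, min_rep=13)
        inv = edge_repeat_search(aligned["keep"], block, min_rep=13, include_inverted=True)
        assert not any(h.length >= 13 for h in direct)
        assert any(h.inverted and h.length >= 13 for h in inv)
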