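"""Pseudogene fragments, mtDNA sharing and anonymous-content accounting."""

import pytest

from helpers import covers, overlap_fraction, point_mutate, random_dna

from mitocomp.homology_scan import (
    PseudogeneHit,
    anonymous_content,
    flag_repeat_association,
    scan_pseudogenes,
    shared_content,
)
from mitocomp.repeat_finder import RepeatPair
from mitocomp.seqio import Annotation, Feature, SequenceRecord
from mitocomp.synthetic import DivergenceSpec, derive_pair


def _genome_with_fragment(rng, identity, inside_intron=False):
    """20 kb genome: one 2 kb gene (with intron) plus a planted fragment."""
    seq = list(random_dna(20_000, rng))
    gene_seq = random_dna(2000, rng)
    seq[1000:3000] = list(gene_seq)
    feats = [
        Feature("atp1", "gene", 1000, 3000, "+"),
        Feature("atp1", "exon", 1000, 1800, "+"),
        Feature("atp1", "intron", 1800, 2400, "+"),
        Feature("atp1", "exon", 2400, 3000, "+"),
    ]
    frag = gene_seq[300:450]
    n_mut = round(len(frag) * (1 - identity))
    frag = point_mutate(frag, n_mut, rng) if n_mut else frag
    pos = 2000 if inside_intron else 10_000
    seq[pos : pos + 150] = list(frag)
    genome = SequenceRecord("g", "".join(seq), circular=True)
    return genome, Annotation("g", 20_000, feats), {"atp1": gene_seq}, (pos, pos + 150)


class TestScanPseudogenes:
    def test_planted_fragment_found_with_source(self, rng):
        genome, ann, genes, iv = _genome_with_fragment(rng, 0.95)
        hits = scan_pseudogenes(genome, ann, genes)
        assert len(hits) == 1
        h = hits[0]
        assert h.gene == "atp1"
        assert overlap_fraction(h.interval, iv) > 0.9
        assert h.identity >= 92.0

    def test_low_identity_fragment_rejected(self, rng):
        genome, ann, genes, _ = _genome_with_fragment(rng, 0.85)
        assert scan_pseudogenes(genome, ann, genes) == []

    def test_fragment_inside_intron_not_intergenic(self, rng):
        genome, ann, genes, _ = _genome_with_fragment(rng, 1.0, inside_intron=True)
        assert scan_pseudogenes(genome, ann, genes) == []

    def test_missing_gene_sequence_warns(self, rng):
        genome, ann, genes, _ = _genome_with_fragment(rng, 0.95)
        with pytest.warns(UserWarning, match="no sequence"):
            hits = scan_pseudogenes(genome, ann, {"atp1": genes["atp1"], "ghost": ""})
        assert len(hits) == 1

    def test_full_envelope_recovery(self, full_sim):
        """All 25 planted fragments in the 28-182 bp / 92-100% envelope
        are recovered, and nothing else is reported."""
        sim = full_sim
        hits = scan_pseudogenes(sim.genome, sim.annotation, sim.gene_sequences())
        truth = sim.truth.pseudogenes
        assert len(hits) == len(truth) == 25
        for t in truth:
            assert any(
                covers((t["start"], t["end"]), h.interval) and h.gene == t["gene"]
                for h in hits
            )
        assert all(h.length >= 28 and h.identity >= 92.0 for h in hits)


class TestRepeatAssociation:
    reps = [RepeatPair((1000, 1500), (5000, 5500), 100.0, 500, "DR")]

    def _hit(self, start, end):
        return PseudogeneHit("x", start, end, end - start, 95.0, "+")

    def test_containment_inside_and_outside(self):
        inside, outside = self._hit(1100, 1300), self._hit(1501, 1600)
        flagged = flag_repeat_association([inside, outside], self.reps, 10_000)
        assert [h.inside_repeat for h in flagged] == [True, False]

    def test_half_overlap_mode_dependent(self):
        straddling = self._hit(1400, 1600)
        by_containment = flag_repeat_association([straddling], self.reps, 10_000)
        by_overlap = flag_repeat_association([straddling], self.reps, 10_000, mode="overlap")
        assert not by_containment[0].inside_repeat
        assert by_overlap[0].inside_repeat


class TestSharedContent:
    def test_self_sharing_is_total(self, rng):
        g = SequenceRecord("a", random_dna(20_000, rng), circular=True)
        rep = shared_content(g, g)
        assert rep.fraction_a == 1.0 and rep.fraction_b == 1.0

    def test_insertion_closed_form(self, repeat_only_sim):
        g = repeat_only_sim.genome
        derived, truth = derive_pair(g, DivergenceSpec(insertion_lengths=(10_000,)), seed=21)
        rep = shared_content(g, derived)
        assert rep.shared_bp_a >= 0.999 * len(g)
        expected = truth.extras["expected_shared_fraction_derived"]
        assert rep.fraction_b == pytest.approx(expected, abs=0.005)

    def test_unrelated_genomes_share_little(self, rng):
        a = SequenceRecord("a", random_dna(20_000, rng), circular=True)
        b = SequenceRecord("b", random_dna(20_000, rng), circular=True)
        assert shared_content(a, b).fraction_a < 0.05

    def test_threshold_monotonicity(self, repeat_only_sim):
        g = repeat_only_sim.genome
        derived, _ = derive_pair(
            g, DivergenceSpec(substitution_rate=0.02, insertion_lengths=(5000,)), seed=8
        )
        base = shared_content(g, derived, min_len=100, min_identity=0.70)
        longer = shared_content(g, derived, min_len=500, min_identity=0.70)
        stricter = shared_content(g, derived, min_len=100, min_identity=0.95)
        assert longer.shared_bp_a <= base.shared_bp_a
        assert stricter.shared_bp_a <= base.shared_bp_a


class TestAnonymousContent:
    def test_published_arithmetic(self):
        # a 484,916 bp genome with 75% known content leaves 121,229 bp (25%)
        bp, frac = anonymous_content(484_916, [(0, 363_687)])
        assert bp == 121_229
        assert frac == pytest.approx(0.25, abs=0.001)

    def test_fully_known_genome(self):
        assert anonymous_content(1000, [(0, 1000)]) == (0, 0.0)

    def test_overlapping_known_intervals_counted_once(self):
        bp, _ = anonymous_content(1000, [(0, 600), (400, 800)])
        assert bp == 200

    def test_conservation(self, rng):
        L = 5000
        ivs = []
        pos = 0
        while pos < L - 100:
            w = int(rng.integers(10, 100))
            ivs.append((pos, min(L, pos + w)))
            pos += w + int(rng.integers(0, 50))
        from mitocomp import intervals

        bp, _ = anonymous_content(L, ivs)
        assert bp + intervals.union_length(ivs) == L

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            anonymous_content(1000, [(500, 1200)])
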