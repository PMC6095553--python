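"""Seeded synthetic circular mitogenomes with machine-readable truth.

The generator emulates the statistical structure of a plant
mitochondrial genome as seen by this package's detectors: i.i.d.
background sequence at a requested GC content, a gene roster with a
couple of intron-bearing genes, planted repeat pairs in the three
canonical size tiers (direct or inverted, at controlled identity),
pseudogene fragments of genes dropped into intergenic spacers, intron
alignments carrying repeat-mediated deletions, gene orders diverged by
known inversions, codon sequence pairs diverged at known dS/dN, and
long reads with a controlled fraction of recombined molecules across a
designated repeat.

Every emitter is deterministic given its seed, and every planted
feature is recorded in a :class:`TruthSet` keyed to the emitted
coordinates, so detector precision and recall can be scored exactly.

The defaults mirror a repeat-poor Faboideae-like mitogenome — one large
(2,160 bp) direct repeat, twenty medium repeats, 25 pseudogene
fragments of 28-182 bp at 92-100% identity — at a 100 kb scale chosen
so a full analysis of one synthetic genome completes in seconds; a
real-genome-scale blueprint (~485 kb) has the same structure, only longer.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
import numpy as np

from mitocomp.gene_order import GeneOrder, invert_segment
from mitocomp.rates import SENSE_CODONS, STOP_CODONS, _AA, _neighbors
from mitocomp.repeat_finder import RepeatPair
from mitocomp.seqio import Annotation, Feature, SequenceRecord, revcomp


class PackingError(ValueError):
    """Requested features cannot be placed in the requested length."""


_BASES = np.array(list("ACGT"))

# a realistic mitochondrial gene roster to draw names from
GENE_ROSTER = (
    "nad1 nad2 nad4 nad5 nad7 cox1 cox2 cox3 cob atp1 atp6 atp9 ccmB ccmC "
    "ccmFc rps3 rps4 rps10 rpl5 rpl16 matR mttB"
).split()


def random_sequence(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def mutate_to_identity(
    seq: str, identity: float, rng: np.random.Generator, protect_ends: int = 2
) -> tuple[str, int]:
    """Substitute bases to reach the target identity (no indels).

    The mutation count is floored so the realized identity never drops
    below the requested one. The terminal ``protect_ends`` bases are
    left untouched: a planted feature emulates a maximal-scoring local
    alignment, and such alignments always begin and end on matches — a
    substituted terminal base would simply be trimmed off the feature.
    """
    n_mut = math.floor(len(seq) * (1.0 - identity))
    if n_mut == 0:
        return seq, 0
    lo = min(protect_ends, len(seq) // 4)
    eligible = np.arange(lo, len(seq) - lo)
    pos = rng.choice(eligible, size=min(n_mut, len(eligible)), replace=False)
    out = list(seq)
    for p in pos:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out), len(pos)


def add_uniform_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for p in hits:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


# ---------------------------------------------------------------------------
# blueprints


@dataclass(frozen=True)
class RepeatSpec:
    size: int
    orientation: str = "DR"  # DR | IR
    identity: float = 1.0


@dataclass(frozen=True)
class PseudogeneSpec:
    length: int
    identity: float
    source_gene: str | None = None


@dataclass(frozen=True)
class ReadSpec:
    """Long-read simulation parameters.

    Defaults follow a low-coverage single-molecule run over a plant
    mitogenome: ~14 kb mean read length at 15x depth.
    """

    mean_len: int = 14_000
    sd_len: int = 2_000
    min_len: int = 2_000
    coverage: float = 15.0
    error_rate: float = 0.0
    recombined_fraction: float = 0.0
    span_flank: int = 500


def _default_repeats() -> tuple[RepeatSpec, ...]:
    # one large DR plus twenty medium repeats, mixed orientation
    sizes = [2160, 795, 446, 463, 315, 299, 232, 217, 160, 146, 135, 127, 126, 117, 114, 112, 111, 107, 102, 101, 144]
    orientations = ["DR", "IR", "IR", "IR", "DR", "IR", "IR", "IR", "DR", "DR", "DR", "IR", "IR", "IR", "DR", "IR", "IR", "IR", "IR", "DR", "DR"]
    return tuple(RepeatSpec(s, o) for s, o in zip(sizes, orientations))


def _default_pseudogenes() -> tuple[PseudogeneSpec, ...]:
    # 25 fragments spanning the 28-182 bp / 92-100% envelope
    lengths = np.linspace(28, 182, 25).round().astype(int)
    idents = np.linspace(0.92, 1.00, 25)
    return tuple(PseudogeneSpec(int(l), float(i)) for l, i in zip(lengths, idents))


@dataclass(frozen=True)
class GenomeBlueprint:
    """Everything :func:`generate` needs to build one genome."""

    seed: int = 0
    length: int = 100_000
    gc: float = 0.454
    n_genes: int = 12
    gene_len: int = 900
    n_intron_genes: int = 2
    intron_len: int = 1_200
    n_trna: int = 3
    n_rrna: int = 1
    repeats: tuple[RepeatSpec, ...] = field(default_factory=_default_repeats)
    pseudogenes: tuple[PseudogeneSpec, ...] = field(default_factory=_default_pseudogenes)
    margin: int = 30


@dataclass
class TruthSet:
    """Planted ground truth, keyed to the emitted genome coordinates."""

    genome_id: str
    length: int
    genes: list[dict] = field(default_factory=list)
    repeats: list[dict] = field(default_factory=list)
    pseudogenes: list[dict] = field(default_factory=list)
    insertions: list[dict] = field(default_factory=list)
    reads: list[dict] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    def repeat_pairs(self) -> list[RepeatPair]:
        return [
            RepeatPair(
                copy1=tuple(r["copy1"]),
                copy2=tuple(r["copy2"]),
                identity=100.0 * r["identity"],
                size=r["size"],
                orientation=r["orientation"],
            )
            for r in self.repeats
        ]


@dataclass
class SyntheticGenome:
    genome: SequenceRecord
    annotation: Annotation
    truth: TruthSet

    def gene_sequences(self) -> dict[str, str]:
        out = {}
        for g in self.truth.genes:
            s = self.genome.seq[g["start"] : g["end"]]
            out[g["gene"]] = s if g["strand"] == "+" else revcomp(s)
        return out


class _Packer:
    def __init__(self, length: int, margin: int, rng: np.random.Generator):
        self.length = length
        self.margin = margin
        self.rng = rng
        self.occupied: list[tuple[int, int]] = []

    def alloc(self, size: int, tries: int = 2000) -> int:
        if size + 2 * self.margin >= self.length:
            raise PackingError(f"feature of {size} bp cannot fit in {self.length} bp genome")
        for _ in range(tries):
            start = int(self.rng.integers(self.margin, self.length - size - self.margin))
            s, e = start - self.margin, start + size + self.margin
            if all(e <= os or oe <= s for os, oe in self.occupied):
                self.occupied.append((s, e))
                return start
        raise PackingError(
            f"could not place a {size} bp feature after {tries} tries; blueprint too dense"
        )


def generate(blueprint: GenomeBlueprint) -> SyntheticGenome:
    """Build a genome, its annotation and the matching truth set.

    Byte-identical outputs for identical blueprints (incl. seed).
    Raises :class:`PackingError` when the features cannot be placed.
    """
    bp = blueprint
    rng = np.random.default_rng(bp.seed)
    seq = list(random_sequence(bp.length, bp.gc, rng))
    packer = _Packer(bp.length, bp.margin, rng)
    ann = Annotation("synthetic", bp.length)
    truth = TruthSet(genome_id="synthetic", length=bp.length)

    # --- genes (some with one intron) -------------------------------------
    roster = list(GENE_ROSTER)
    while len(roster) < bp.n_genes:
        roster.append(f"orf{100 + len(roster)}")
    for gi in range(bp.n_genes):
        name = roster[gi]
        strand = "+" if rng.random() < 0.5 else "-"
        has_intron = gi < bp.n_intron_genes
        glen = bp.gene_len + (bp.intron_len if has_intron else 0)
        start = packer.alloc(glen)
        end = start + glen
        ann.features.append(Feature(name, "gene", start, end, strand))
        if has_intron:
            e1 = bp.gene_len * 2 // 5
            ann.features.append(Feature(name, "exon", start, start + e1, strand))
            ann.features.append(
                Feature(name, "intron", start + e1, start + e1 + bp.intron_len, strand)
            )
            ann.features.append(Feature(name, "exon", start + e1 + bp.intron_len, end, strand))
        truth.genes.append(
            {"gene": name, "start": start, "end": end, "strand": strand, "intron": has_intron}
        )
    for ti in range(bp.n_trna):
        start = packer.alloc(75)
        ann.features.append(Feature(f"trnX{ti}", "tRNA", start, start + 75, "+"))
    for ri in range(bp.n_rrna):
        start = packer.alloc(1800)
        ann.features.append(Feature(f"rrn{26 - ri}", "rRNA", start, start + 1800, "+"))

    # --- repeat pairs ------------------------------------------------------
    for spec in bp.repeats:
        s1 = packer.alloc(spec.size)
        s2 = packer.alloc(spec.size)
        if s2 < s1:
            s1, s2 = s2, s1
        copy = "".join(seq[s1 : s1 + spec.size])
        mutated, n_mut = mutate_to_identity(copy, spec.identity, rng)
        planted = mutated if spec.orientation == "DR" else revcomp(mutated)
        seq[s2 : s2 + spec.size] = list(planted)
        truth.repeats.append(
            {
                "copy1": (s1, s1 + spec.size),
                "copy2": (s2, s2 + spec.size),
                "size": spec.size,
                "orientation": spec.orientation,
                "identity": 1.0 - n_mut / spec.size,
            }
        )

    # --- pseudogene fragments ---------------------------------------------
    gene_intervals = {g["gene"]: (g["start"], g["end"], g["strand"]) for g in truth.genes}
    gene_names = sorted(gene_intervals)
    for pi, spec in enumerate(bp.pseudogenes):
        source = spec.source_gene or gene_names[pi % len(gene_names)]
        gs, ge, gstrand = gene_intervals[source]
        gseq = "".join(seq[gs:ge])
        if gstrand == "-":
            gseq = revcomp(gseq)
        if spec.length > len(gseq):
            raise PackingError(f"pseudogene fragment of {spec.length} bp exceeds gene {source}")
        off = int(rng.integers(0, len(gseq) - spec.length + 1))
        frag = gseq[off : off + spec.length]
        frag, n_mut = mutate_to_identity(frag, spec.identity, rng)
        start = packer.alloc(spec.length)
        seq[start : start + spec.length] = list(frag)
        truth.pseudogenes.append(
            {
                "gene": source,
                "start": start,
                "end": start + spec.length,
                "length": spec.length,
                "identity": 1.0 - n_mut / spec.length,
            }
        )

    genome = SequenceRecord("synthetic", "".join(seq), circular=True)
    return SyntheticGenome(genome=genome, annotation=ann, truth=truth)


# ---------------------------------------------------------------------------
# derived genome pairs (sharing / divergence)


@dataclass(frozen=True)
class DivergenceSpec:
    substitution_rate: float = 0.0
    insertion_lengths: tuple[int, ...] = ()
    n_inversions: int = 0
    min_inversion: int = 2_000
    max_inversion: int = 10_000


def derive_pair(
    genome: SequenceRecord,
    spec: DivergenceSpec,
    seed: int = 0,
    derived_id: str | None = None,
) -> tuple[SequenceRecord, TruthSet]:
    """A second genome derived by substitutions, insertions and inversions.

    The truth set records every inserted unique segment and inversion;
    with no substitutions the expected shared fraction on the derived
    genome is ``L / (L + sum(insertions))`` in closed form (inverted
    segments stay shared on the minus strand).
    """
    rng = np.random.default_rng(seed)
    seq = genome.seq
    L = len(seq)
    truth = TruthSet(genome_id=derived_id or f"{genome.id}_derived", length=0)

    if spec.substitution_rate > 0:
        seq = add_uniform_errors(seq, spec.substitution_rate, rng)
    for k in range(spec.n_inversions):
        span = int(rng.integers(spec.min_inversion, spec.max_inversion + 1))
        start = int(rng.integers(0, len(seq) - span))
        seq = seq[:start] + revcomp(seq[start : start + span]) + seq[start + span :]
        truth.extras.setdefault("inversions", []).append({"start": start, "span": span})
    # insertions of unique (random) sequence, positions drawn on the current seq
    for ln in spec.insertion_lengths:
        pos = int(rng.integers(0, len(seq)))
        ins = random_sequence(ln, 0.45, rng)
        seq = seq[:pos] + ins + seq[pos:]
        truth.insertions.append({"pos": pos, "length": ln})
    truth.length = len(seq)
    truth.extras["expected_shared_bp"] = L
    truth.extras["expected_shared_fraction_derived"] = L / len(seq)
    return SequenceRecord(truth.genome_id, seq, circular=True), truth


# ---------------------------------------------------------------------------
# long reads


def simulate_reads(
    genome: SequenceRecord,
    spec: ReadSpec,
    repeat: RepeatPair | None = None,
    seed: int = 0,
) -> tuple[list[SequenceRecord], TruthSet]:
    """Uniformly sampled circular reads, optionally with recombinants.

    With a designated ``repeat``, every read whose sampled interval
    spans either repeat copy plus ``span_flank`` on both sides is
    turned into a recombination product with probability
    ``recombined_fraction``: the read follows the spanned copy's left
    context through the repeat and exits into the *other* copy's
    context, exactly as a crossover molecule would. Per-read truth
    labels are emitted.
    """
    # separate streams: the read layout is identical across error rates
    layout_rng, error_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(2)
    )
    rng = layout_rng
    L = len(genome)
    n_reads = max(1, round(spec.coverage * L / spec.mean_len))
    truth = TruthSet(genome_id=genome.id, length=L)
    reads: list[SequenceRecord] = []
    f = spec.span_flank
    for i in range(n_reads):
        ln = int(np.clip(round(rng.normal(spec.mean_len, spec.sd_len)), spec.min_len, L))
        start = int(rng.integers(0, L))
        label = "parental"
        spans = 0
        start_f = start
        if repeat is not None:
            for which, (cs, ce) in ((1, repeat.copy1), (2, repeat.copy2)):
                for frame in (start, start - L):
                    if frame <= cs - f and frame + ln >= ce + f:
                        spans = which
                        start_f = frame
                        break
                if spans:
                    break
        if spans and rng.random() < spec.recombined_fraction:
            seq = _chimeric_read(genome, repeat, start_f, ln, spans)
            label = "recombined"
        else:
            seq = genome.fetch(start, start + ln)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        seq = add_uniform_errors(seq, spec.error_rate, error_rng)
        rid = f"read_{i:05d}"
        reads.append(SequenceRecord(rid, seq))
        truth.reads.append(
            {"read": rid, "start": start, "length": ln, "label": label, "spanning": bool(spans)}
        )
    return reads, truth


def _chimeric_read(
    genome: SequenceRecord, repeat: RepeatPair, start: int, ln: int, which: int = 1
) -> str:
    """Crossover molecule through the spanned copy into the other context.

    For a direct repeat the read exits into the other copy's downstream
    sequence; for an inverted repeat it exits into the reverse
    complement of the other copy's upstream sequence (the geometry of a
    crossover between copies on opposite strands).
    """
    this, other = (repeat.copy1, repeat.copy2) if which == 1 else (repeat.copy2, repeat.copy1)
    left = genome.fetch(start, this[1])
    tail = ln - len(left)
    if repeat.orientation == "DR":
        right = genome.fetch(other[1], other[1] + tail)
    else:
        right = revcomp(genome.fetch(other[0] - tail, other[0]))
    return left + right


# ---------------------------------------------------------------------------
# intron alignments with repeat-mediated deletions


def make_intron_alignment(
    n_taxa: int = 4,
    n_deleted: int = 1,
    intron_len: int = 4_000,
    deletion_len: int = 2_000,
    repeat_len: int = 15,
    edge_offset: int = 0,
    plant_repeat: bool = True,
    gc: float = 0.45,
    seed: int = 0,
) -> tuple[dict[str, str], dict]:
    """An intron alignment with a taxon-specific deletion.

    The deletion block sits centrally; when ``plant_repeat`` is true a
    direct repeat of ``repeat_len`` bp is planted with one copy
    ``edge_offset`` bp inside each deletion edge — the signature left
    by repeat-mediated recombination collapse. Deleted taxa carry a gap
    over the block; the remaining taxa retain the full sequence.
    """
    if n_deleted >= n_taxa:
        raise ValueError("at least one taxon must retain the region")
    if deletion_len + 2 * (repeat_len + edge_offset) > intron_len:
        raise ValueError("deletion and repeats do not fit in the intron")
    rng = np.random.default_rng(seed)
    anc = list(random_sequence(intron_len, gc, rng))
    bs = (intron_len - deletion_len) // 2
    be = bs + deletion_len
    repeat_seq = ""
    if plant_repeat:
        left = bs + edge_offset
        right = be - edge_offset - repeat_len
        repeat_seq = "".join(anc[left : left + repeat_len])
        anc[right : right + repeat_len] = list(repeat_seq)
    anc = "".join(anc)
    aln: dict[str, str] = {}
    for i in range(n_taxa):
        taxon = f"taxon_{i + 1}"
        if i < n_taxa - n_deleted:
            aln[taxon] = anc
        else:
            aln[taxon] = anc[:bs] + "-" * deletion_len + anc[be:]
    truth = {
        "block": (bs, be),
        "deletion_len": deletion_len,
        "repeat_len": repeat_len if plant_repeat else 0,
        "edge_offset": edge_offset,
        "repeat_seq": repeat_seq,
        "deleted_taxa": [f"taxon_{i + 1}" for i in range(n_taxa - n_deleted, n_taxa)],
    }
    return aln, truth


# ---------------------------------------------------------------------------
# codon sequence pairs at known dS/dN


def simulate_codon_pair(
    n_codons: int, ds: float, dn: float, seed: int = 0
) -> tuple[str, str]:
    """A coding sequence pair diverged at expected dS and dN.

    Ancestral codons are uniform over the 61 sense codons; the derived
    sequence evolves by a continuous-time process in which each codon
    position mutates to its viable (non-stop) neighbours, the
    per-position rate is split over those neighbours, and
    nonsynonymous changes are slowed by a factor omega. Under this
    parameterisation the instantaneous synonymous divergence per
    synonymous *site* (sites in the counting convention that divides by
    viable neighbours) equals ``3*mu*t``, uniformly across codons, so
    setting ``3*mu*t = ds`` and ``omega = dn/ds`` gives the requested
    expected per-site divergences before multiple-hit saturation —
    which the Jukes-Cantor correction is meant to undo.
    """
    if ds < 0 or dn < 0:
        raise ValueError("divergences must be non-negative")
    rng = np.random.default_rng(seed)
    mu_t = ds / 3.0
    omega_mu_t = dn / 3.0
    anc_idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    a = "".join(SENSE_CODONS[i] for i in anc_idx)
    derived = []
    for i in anc_idx:
        codon = SENSE_CODONS[i]
        t = 0.0
        while True:
            moves = []
            rates = []
            for pos in range(3):
                viable = [nb for nb in _neighbors(codon, pos) if nb not in STOP_CODONS]
                if not viable:
                    continue
                # a position carries one full site's worth of rate,
                # split over its viable neighbours
                per_neighbor = 3.0 / len(viable)
                for nb in viable:
                    rate = (mu_t if _AA[nb] == _AA[codon] else omega_mu_t) * per_neighbor
                    if rate > 0:
                        moves.append(nb)
                        rates.append(rate)
            total = sum(rates)
            if total == 0:
                break
            t += rng.exponential(1.0 / total)
            if t >= 1.0:
                break
            codon = moves[rng.choice(len(moves), p=np.array(rates) / total)]
        derived.append(codon)
    return a, "".join(derived)


# ---------------------------------------------------------------------------
# gene orders


def random_gene_order(n_genes: int, seed: int = 0, genome_id: str = "anc") -> GeneOrder:
    rng = np.random.default_rng(seed)
    genes = tuple(
        (f"g{i:02d}", 1 if rng.random() < 0.5 else -1) for i in range(n_genes)
    )
    return GeneOrder(genome_id, genes)


def evolve_by_inversions(
    order: GeneOrder, k: int, seed: int = 0, derived_id: str | None = None
) -> tuple[GeneOrder, list[tuple[int, int]]]:
    """Apply k pairwise-disjoint segmental inversions (DCJ distance = k).

    Segments are separated by at least one untouched gene, so each
    inversion breaks two private adjacencies and the DCJ distance to
    the ancestor equals exactly k.
    """
    n = len(order.genes)
    if k * 2 + 1 >= n:
        raise ValueError(f"cannot fit {k} disjoint inversions in {n} genes")
    rng = np.random.default_rng(seed)
    for _ in range(10_000):
        cuts = sorted(rng.choice(n, size=2 * k, replace=False))
        segs = [(cuts[2 * i], cuts[2 * i + 1]) for i in range(k)]
        # enforce >= 1 untouched gene between consecutive segments and at the ends
        ok = all(segs[i][1] + 1 < segs[i + 1][0] for i in range(k - 1))
        if ok and segs[0][0] > 0 and segs[-1][1] < n - 1:
            out = order
            for i, j in segs:
                out = invert_segment(out, i, j + 1)
            return GeneOrder(derived_id or f"{order.genome_id}_inv{k}", out.genes), segs
    raise RuntimeError("failed to sample disjoint inversions")
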