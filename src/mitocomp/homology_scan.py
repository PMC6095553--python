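"""Pseudogene fragments, pairwise mtDNA sharing and anonymous content.

Plant mitochondrial intergenic spacers accumulate short degraded copies
of functional genes (pseudogene fragments) and large tracts of sequence
with no detectable homology to anything known ("anonymous" DNA). This
module scans spacers for gene fragments, measures the sequence two
genomes share as the interval union of their local-alignment hits, and
computes anonymous content as total length minus known-interval
coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from mitocomp import intervals
from mitocomp.repeat_finder import RepeatPair, _wrap_interval
from mitocomp.seedalign import (
    DEFAULT_SCORING,
    AlignmentHit,
    Scoring,
    Seed,
    extend_hit,
    refine_hit_window,
    _kmer_index,
)
from mitocomp.seqio import Annotation, SequenceRecord, revcomp


def scan_hits(
    query: SequenceRecord | str,
    subject: SequenceRecord | str,
    k: int = 13,
    min_len: int = 100,
    min_identity: float = 0.70,
    scoring: Scoring = DEFAULT_SCORING,
) -> list[AlignmentHit]:
    """Seeded local-alignment scan with length/identity filters.

    Seeds falling inside an already-extended hit on a compatible
    diagonal are skipped, so long homologous tracts cost one extension
    each. Both strands are searched.
    """
    q = query.seq if isinstance(query, SequenceRecord) else str(query).upper()
    s = subject.seq if isinstance(subject, SequenceRecord) else str(subject).upper()
    if k > len(q) or k > len(s):
        return []
    index = _kmer_index(s, k)
    band = scoring.xdrop // scoring.gap_extend + 5
    all_hits: list[AlignmentHit] = []
    plus_runs: dict[int, int] = {}
    minus_runs: dict[int, int] = {}
    for i in range(len(q) - k + 1):
        kmer = q[i : i + k]
        if "N" in kmer:
            continue
        for j in index.get(kmer, ()):
            if plus_runs.get(i - j) == i - 1:
                plus_runs[i - j] = i
                continue
            plus_runs[i - j] = i
            if not _covered(i, j, k, "+", all_hits, band):
                all_hits.append(extend_hit(Seed(i, j, "+", k), q, s, scoring))
        for j in index.get(revcomp(kmer), ()):
            if minus_runs.get(i + j) == i - 1:
                minus_runs[i + j] = i
                continue
            minus_runs[i + j] = i
            if not _covered(i, j, k, "-", all_hits, band):
                all_hits.append(extend_hit(Seed(i, j, "-", k), q, s, scoring))
    out = []
    seen = set()
    for h in all_hits:
        if h.length < min_len or h.identity < min_identity:
            continue
        key = (h.q_interval, h.s_interval, h.strand)
        if key in seen:
            continue
        seen.add(key)
        out.append(h)
    out.sort(key=lambda h: (h.q_start, h.s_start))
    return out


def _covered(i: int, j: int, k: int, strand: str, hits: list[AlignmentHit], band: int) -> bool:
    for h in hits:
        if h.strand != strand:
            continue
        if not (h.q_start <= i and i + k <= h.q_end and h.s_start <= j and j + k <= h.s_end):
            continue
        if strand == "+":
            if abs((i - j) - (h.q_start - h.s_start)) <= band:
                return True
        else:
            if abs((i + j) - (h.q_start + h.s_end - k)) <= 2 * band + k:
                return True
    return False


# ---------------------------------------------------------------------------
# pseudogene fragments


@dataclass(frozen=True)
class PseudogeneHit:
    """A degraded gene copy found in an intergenic spacer."""

    gene: str
    start: int
    end: int
    length: int
    identity: float  # percent
    strand: str
    inside_repeat: bool = False

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def scan_pseudogenes(
    genome: SequenceRecord,
    annotation: Annotation,
    gene_seqs: Mapping[str, str],
    min_len: int = 28,
    min_identity: float = 0.92,
    k: int = 9,
    scoring: Scoring = DEFAULT_SCORING,
) -> list[PseudogeneHit]:
    """Gene fragments in intergenic spacers.

    Each functional gene sequence is aligned against the genome; hits
    are kept when they are at least ``min_len`` bp at ``min_identity``
    and fall wholly outside every annotated gene, exon, intron, tRNA
    and rRNA interval. Overlapping hits from the same source gene are
    merged. Default thresholds (28 bp, 92%) bracket the envelope of
    fragment sizes and identities typically reported for mitogenome
    spacers; the 9-bp word size guarantees a seed inside any fragment
    within that envelope (a 28 bp copy at 92% identity still contains
    an exact 9-mer by pigeonhole).
    """
    genic = intervals.merge([f.interval for f in annotation.features])
    hits_by_gene: dict[str, list[PseudogeneHit]] = {}
    # scan with a relaxed identity floor, then trim each candidate to its
    # best window at the requested identity: x-drop extension can append
    # chance background runs that dilute a short fragment's identity.
    # The refined window must retain the bulk of the alignment — trimming
    # boundary junk is allowed, cherry-picking a chance sub-window out of a
    # genuinely sub-threshold alignment is not.
    scan_floor = max(0.5, min_identity - 0.10)
    for gene in sorted(gene_seqs):
        seq = gene_seqs[gene]
        if not seq:
            import warnings

            warnings.warn(f"gene {gene!r} has no sequence; skipped")
            continue
        for raw in scan_hits(seq, genome, k=k, min_len=min_len, min_identity=scan_floor, scoring=scoring):
            h = refine_hit_window(raw, seq, genome.seq, min_identity, min_len)
            if h is None or h.length < 0.6 * raw.length:
                continue
            iv = h.s_interval
            if intervals.overlaps(genic, iv):
                continue
            hits_by_gene.setdefault(gene, []).append(
                PseudogeneHit(
                    gene=gene,
                    start=iv[0],
                    end=iv[1],
                    length=iv[1] - iv[0],
                    identity=round(100.0 * h.identity, 2),
                    strand=h.strand,
                )
            )
    out: list[PseudogeneHit] = []
    for gene, hits in sorted(hits_by_gene.items()):
        merged = intervals.merge([h.interval for h in hits])
        for s, e in merged:
            members = [h for h in hits if h.start < e and s < h.end]
            out.append(
                PseudogeneHit(
                    gene=gene,
                    start=s,
                    end=e,
                    length=e - s,
                    identity=max(h.identity for h in members),
                    strand=members[0].strand,
                )
            )
    out.sort(key=lambda h: (h.start, h.gene))
    return out


def flag_repeat_association(
    hits: Iterable[PseudogeneHit],
    repeats: Iterable[RepeatPair],
    genome_length: int,
    mode: Literal["containment", "overlap"] = "containment",
) -> list[PseudogeneHit]:
    """Set ``inside_repeat`` on pseudogene hits lying in repeat copies.

    ``containment`` (default) requires the whole fragment inside the
    union of repeat copy intervals — fragments described as "located in"
    repeats; ``overlap`` accepts one shared basepair.
    """
    cover: list[tuple[int, int]] = []
    for r in repeats:
        cover.extend(_wrap_interval(r.copy1, genome_length))
        cover.extend(_wrap_interval(r.copy2, genome_length))
    cover = intervals.merge(cover)
    test = intervals.contains if mode == "containment" else intervals.overlaps
    return [replace(h, inside_repeat=bool(test(cover, h.interval))) for h in hits]


def pseudogenes_table(hits: Iterable[PseudogeneHit]) -> pd.DataFrame:
    rows = [
        {
            "gene": h.gene,
            "start": h.start + 1,
            "end": h.end,
            "length": h.length,
            "identity": h.identity,
            "strand": h.strand,
            "inside_repeat": h.inside_repeat,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows, columns=["gene", "start", "end", "length", "identity", "strand", "inside_repeat"]
    )


# ---------------------------------------------------------------------------
# mtDNA sharing and anonymous content


@dataclass(frozen=True)
class SharingReport:
    """Shared-sequence accounting between two genomes.

    Shared basepairs on each genome are the interval union of all
    qualifying local-alignment hits projected onto that genome, so the
    two sides of one report may differ (duplications collapse).
    """

    id_a: str
    id_b: str
    length_a: int
    length_b: int
    shared_bp_a: int
    shared_bp_b: int
    min_len: int
    min_identity: float

    @property
    def fraction_a(self) -> float:
        return self.shared_bp_a / self.length_a

    @property
    def fraction_b(self) -> float:
        return self.shared_bp_b / self.length_b

    @property
    def unshared_bp_a(self) -> int:
        return self.length_a - self.shared_bp_a

    @property
    def unshared_bp_b(self) -> int:
        return self.length_b - self.shared_bp_b


def shared_content(
    genome_a: SequenceRecord,
    genome_b: SequenceRecord,
    min_len: int = 100,
    min_identity: float = 0.70,
    k: int = 13,
    scoring: Scoring = DEFAULT_SCORING,
) -> SharingReport:
    """Pairwise mtDNA sharing as alignment-hit interval-union coverage."""
    hits = scan_hits(genome_a, genome_b, k=k, min_len=min_len, min_identity=min_identity, scoring=scoring)
    shared_a = intervals.union_length([h.q_interval for h in hits])
    shared_b = intervals.union_length([h.s_interval for h in hits])
    return SharingReport(
        id_a=genome_a.id,
        id_b=genome_b.id,
        length_a=len(genome_a),
        length_b=len(genome_b),
        shared_bp_a=min(shared_a, len(genome_a)),
        shared_bp_b=min(shared_b, len(genome_b)),
        min_len=min_len,
        min_identity=min_identity,
    )


def shared_intervals(
    genome_a: SequenceRecord,
    genome_b: SequenceRecord,
    min_len: int = 100,
    min_identity: float = 0.70,
    k: int = 13,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Merged shared intervals on each genome (for BED export)."""
    hits = scan_hits(genome_a, genome_b, k=k, min_len=min_len, min_identity=min_identity)
    return (
        intervals.merge([h.q_interval for h in hits]),
        intervals.merge([h.s_interval for h in hits]),
    )


def anonymous_content(
    genome_length: int, known_intervals: Sequence[tuple[int, int]]
) -> tuple[int, float]:
    """Anonymous basepairs and fraction: length minus known coverage.

    ``known_intervals`` may overlap; the union is counted once. Raises
    for intervals outside ``[0, genome_length)``.
    """
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    for s, e in known_intervals:
        if s < 0 or e > genome_length:
            raise ValueError(f"known interval ({s}, {e}) outside [0, {genome_length})")
    known = intervals.union_length(known_intervals)
    bp = genome_length - known
    return bp, bp / genome_length


def intervals_to_bed(ivs: Iterable[tuple[int, int]], chrom: str) -> pd.DataFrame:
    return pd.DataFrame(
        [{"chrom": chrom, "start": s, "end": e} for s, e in ivs],
        columns=["chrom", "start", "end"],
    )
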