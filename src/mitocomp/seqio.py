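"""Sequence and annotation containers plus FASTA/FASTQ/GFF3 I/O.

Sequences are plain uppercase strings over ``{A, C, G, T, N}``; the
:class:`SequenceRecord` adds an identifier and a circular-topology flag.
Annotations are flat feature lists (gene/exon/intron/tRNA/rRNA) in
0-based half-open coordinates; the GFF3 emitted and parsed here uses the
conventional 1-based inclusive columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement; ``N`` maps to ``N``."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A nucleotide sequence with explicit topology.

    Parameters
    ----------
    id:
        Non-empty label.
    seq:
        Uppercase nucleotide string over ``{A, C, G, T, N}``.
    circular:
        Whether the molecule is circular; circular records are the
        coordinate authority for wrap-around arithmetic downstream.
    """

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains characters outside ACGTN: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence ``[start, end)`` honouring circular wrap-around.

        For circular records ``start`` may be negative and ``end`` may
        exceed the length; the sequence wraps (span capped at L).
        """
        L = len(self.seq)
        if not self.circular:
            if start < 0 or end > L:
                raise IndexError(f"[{start}, {end}) outside linear sequence of length {L}")
            return self.seq[start:end]
        span = end - start
        if span > L:
            raise IndexError("circular fetch longer than the genome")
        if span <= 0:
            return ""
        start %= L
        end = start + span
        if end <= L:
            return self.seq[start:end]
        return self.seq[start:] + self.seq[: end - L]


def read_fasta(path: str | Path, circular: bool = False) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into :class:`SequenceRecord` objects."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(SequenceRecord(rec.id, str(rec.seq).upper(), circular=circular))
    return out


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [_BioRecord(Seq(r.seq), id=r.id, description="circular" if r.circular else "") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_reads(path: str | Path) -> list[SequenceRecord]:
    """Read long reads from FASTA or FASTQ (decided by extension/content)."""
    p = str(path)
    fmt = "fastq" if p.endswith((".fastq", ".fq")) else "fasta"
    return [SequenceRecord(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(p, fmt)]


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


# ---------------------------------------------------------------------------
# annotations

FEATURE_TYPES = ("gene", "exon", "intron", "tRNA", "rRNA")


@dataclass(frozen=True)
class Feature:
    """One annotated feature in 0-based half-open coordinates."""

    gene: str
    ftype: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end}) for {self.gene}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class Annotation:
    """Feature list for one genome."""

    genome_id: str
    length: int
    features: list[Feature] = field(default_factory=list)

    def of_type(self, *ftypes: str) -> list[Feature]:
        return [f for f in self.features if f.ftype in ftypes]

    def genes(self) -> list[Feature]:
        return self.of_type("gene")

    def coding_intervals(self) -> list[tuple[int, int]]:
        """Exons of protein genes plus tRNA and rRNA loci."""
        ivs = [f.interval for f in self.of_type("exon", "tRNA", "rRNA")]
        # single-exon protein genes may be annotated as bare gene features
        exon_parents = {f.gene for f in self.of_type("exon")}
        ivs += [f.interval for f in self.genes() if f.gene not in exon_parents]
        return ivs

    def intron_intervals(self) -> list[tuple[int, int]]:
        return [f.interval for f in self.of_type("intron")]


def write_gff3(ann: Annotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {ann.genome_id} 1 {ann.length}\n")
        for f in sorted(ann.features, key=lambda x: (x.start, x.end)):
            attrs = f"ID={f.gene}.{f.ftype}.{f.start + 1};gene={f.gene}"
            fh.write(
                "\t".join(
                    [
                        ann.genome_id,
                        "mitocomp",
                        f.ftype,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path, length: int | None = None) -> Annotation:
    """Parse the GFF3-like annotation dialect written by :func:`write_gff3`."""
    features: list[Feature] = []
    genome_id = "genome"
    declared_len = length
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                genome_id = parts[1]
                declared_len = declared_len or int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seqid, _src, ftype, start, end, _score, strand, _frame, attrs = cols[:9]
            genome_id = seqid
            gene = ""
            for kv in attrs.split(";"):
                if kv.startswith("gene="):
                    gene = kv[5:]
            if not gene:
                gene = attrs.split(";")[0].split("=")[-1]
            if ftype in FEATURE_TYPES:
                features.append(Feature(gene, ftype, int(start) - 1, int(end), strand))
    if declared_len is None:
        declared_len = max((f.end for f in features), default=0)
    return Annotation(genome_id, declared_len, features)
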