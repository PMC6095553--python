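"""Genome composition: coding / intron / intergenic partition and GC.

A mitogenome is partitioned exactly into three categories with the
precedence coding > intron > intergenic: coding covers protein exons
plus tRNA and rRNA loci, introns cover annotated intron intervals not
claimed by coding, and everything else is intergenic spacer. Reported
percentages are rounded to one decimal, half-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import pandas as pd

from mitocomp import intervals
from mitocomp.seqio import Annotation, SequenceRecord


def round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CompositionReport:
    """Exact three-way composition of one genome."""

    genome_id: str
    length: int
    coding_bp: int
    intron_bp: int
    intergenic_bp: int
    gc_percent: float | None = None

    def __post_init__(self) -> None:
        if self.coding_bp + self.intron_bp + self.intergenic_bp != self.length:
            raise ValueError(
                "partition does not conserve length: "
                f"{self.coding_bp} + {self.intron_bp} + {self.intergenic_bp} != {self.length}"
            )

    def _pct(self, bp: int) -> float:
        return round_half_up(100.0 * bp / self.length, 1)

    @property
    def coding_percent(self) -> float:
        return self._pct(self.coding_bp)

    @property
    def intron_percent(self) -> float:
        return self._pct(self.intron_bp)

    @property
    def intergenic_percent(self) -> float:
        return self._pct(self.intergenic_bp)

    @classmethod
    def from_lengths(
        cls,
        length: int,
        gene_bp: int,
        intron_bp: int,
        genome_id: str = "genome",
        gc_percent: float | None = None,
    ) -> "CompositionReport":
        """Build a report from summary lengths.

        ``gene_bp`` is total gene length including introns; the coding
        category is gene minus intron, and the intergenic remainder is
        length minus gene.
        """
        coding = gene_bp - intron_bp
        return cls(
            genome_id=genome_id,
            length=length,
            coding_bp=coding,
            intron_bp=intron_bp,
            intergenic_bp=length - gene_bp,
            gc_percent=gc_percent,
        )


def gc_percent(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    if not acgt:
        raise ValueError("sequence has no unambiguous bases")
    return round_half_up(100.0 * (seq.count("G") + seq.count("C")) / acgt, 1)


def partition_genome(
    length: int,
    annotation: Annotation,
    sequence: SequenceRecord | None = None,
) -> CompositionReport:
    """Exact coding/intron/intergenic partition of a genome.

    Overlaps are resolved by precedence coding > intron > intergenic.
    An intron interval wholly swallowed by coding is unresolvable by
    precedence and raises, listing the offenders.
    """
    coding = intervals.merge(annotation.coding_intervals())
    for s, e in coding:
        if s < 0 or e > length:
            raise ValueError(f"coding interval ({s}, {e}) outside [0, {length})")
    introns = intervals.merge(annotation.intron_intervals())
    swallowed = [iv for iv in introns if intervals.contains(coding, iv)]
    if swallowed:
        raise ValueError(f"intron intervals wholly inside coding sequence: {swallowed}")
    coding_bp = intervals.union_length(coding)
    intron_bp = intervals.union_length(introns) - intervals.intersect_length(introns, coding)
    intergenic_bp = length - coding_bp - intron_bp
    gc = gc_percent(sequence.seq) if sequence is not None else None
    return CompositionReport(
        genome_id=annotation.genome_id,
        length=length,
        coding_bp=coding_bp,
        intron_bp=intron_bp,
        intergenic_bp=intergenic_bp,
        gc_percent=gc,
    )


def composition_table(reports: list[CompositionReport]) -> pd.DataFrame:
    rows = [
        {
            "genome": r.genome_id,
            "length_bp": r.length,
            "GC_percent": r.gc_percent,
            "coding_bp": r.coding_bp,
            "intron_bp": r.intron_bp,
            "intergenic_bp": r.intergenic_bp,
            "coding_percent": r.coding_percent,
            "intron_percent": r.intron_percent,
            "intergenic_percent": r.intergenic_percent,
        }
        for r in reports
    ]
    return pd.DataFrame(rows)


def load_reference_traits() -> dict[str, float]:
    """Published summary lengths of the *Sophora japonica* 'JinhuaiJ2'
    mitogenome (GenBank MG757109), shipped as a worked example."""
    with resources.files("mitocomp.data").joinpath("sophora_mg757109_traits.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return {str(r["trait"]): float(r["value"]) for _, r in df.iterrows()}
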