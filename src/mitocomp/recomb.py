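"""Long-read evidence for repeat-mediated homologous recombination.

A read that spans a full repeat copy plus flanking sequence on both
sides ties the two flanks to one genomic context. If the left flank
matches the neighbourhood of one repeat copy and the right flank the
neighbourhood of the other, the molecule is a recombination product;
if both flanks belong to the same copy's neighbourhood, the molecule is
parental. The summary statistic is recombined / spanning with a Wilson
score interval.

Reads are placed with exact semi-global (infix) alignment of the repeat
copy and of each flank context, so calls are deterministic and robust
to the uniform few-percent error of long reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import edlib
import pandas as pd
from scipy.stats import norm

from mitocomp.repeat_finder import RepeatPair
from mitocomp.seqio import SequenceRecord, revcomp

FlankCall = Literal["copy1", "copy2", "ambiguous"]


@dataclass(frozen=True)
class SpanningRead:
    """Flank assignments and the resulting call for one spanning read."""

    read_id: str
    left: FlankCall
    right: FlankCall
    left_identity: tuple[float, float]  # identity of left flank vs copy1/copy2 context
    right_identity: tuple[float, float]

    @property
    def call(self) -> str:
        if "ambiguous" in (self.left, self.right):
            return "uninformative"
        return "parental" if self.left == self.right else "recombined"


def _infix_identity(query: str, target: str) -> float:
    """Identity of the best infix placement of query inside target."""
    if not query or not target:
        return 0.0
    res = edlib.align(query, target, mode="HW", task="distance")
    d = res["editDistance"]
    if d < 0:
        return 0.0
    return max(0.0, 1.0 - d / len(query))


def _locate(query: str, target: str) -> tuple[int, int, float]:
    """Best infix location of query in target: (start, end, identity)."""
    res = edlib.align(query, target, mode="HW", task="locations")
    d = res["editDistance"]
    if d < 0 or not res["locations"]:
        return (-1, -1, 0.0)
    s, e = res["locations"][0]
    return (s, e + 1, max(0.0, 1.0 - d / len(query)))


def _orient_read(read: SequenceRecord, core: str) -> tuple[str, int, int, float]:
    """Orient the read so the repeat core aligns forward; locate the core."""
    fwd = _locate(core, read.seq)
    rc = revcomp(read.seq)
    rev = _locate(core, rc)
    if fwd[2] >= rev[2]:
        return (read.seq, *fwd)
    return (rc, *rev)


def _copy_contexts(
    genome: SequenceRecord, repeat: RepeatPair, flank: int
) -> tuple[list[str], list[str]]:
    """Oriented left/right flank contexts of both repeat copies.

    Contexts are oriented in the frame of copy 1, so for an inverted
    repeat the copy-2 neighbourhood is reverse-complemented. A read
    whose repeat core aligns forward can then be compared flank-by-flank
    against both contexts directly.
    """
    pad = min(flank // 2, 200)
    lefts, rights = [], []
    for (s, e), orient in ((repeat.copy1, "+"), (repeat.copy2, "+" if repeat.orientation == "DR" else "-")):
        ctx = genome.fetch(s - flank - pad, e + flank + pad)
        if orient == "-":
            ctx = revcomp(ctx)
        lefts.append(ctx[: flank + 2 * pad])
        rights.append(ctx[-(flank + 2 * pad) :])
    return lefts, rights


def find_spanning_reads(
    reads: Sequence[SequenceRecord],
    genome: SequenceRecord,
    repeat: RepeatPair,
    min_flank: int = 500,
    min_core_identity: float = 0.70,
) -> list[str]:
    """Ids of reads covering a full repeat copy plus flanks on both sides.

    A read qualifies when the repeat core places inside it (infix
    alignment at >= ``min_core_identity``) with at least ``min_flank``
    read bases on each side of the placement.
    """
    core = genome.fetch(*repeat.copy1)
    size = repeat.copy1[1] - repeat.copy1[0]
    if not reads or size > max(len(r) for r in reads):
        warnings.warn(
            f"repeat of {size} bp is longer than the longest read; no read can span it"
        )
        return []
    out = []
    for read in reads:
        oriented, s, e, ident = _orient_read(read, core)
        if ident < min_core_identity or s < 0:
            continue
        if s >= min_flank and len(oriented) - e >= min_flank:
            out.append(read.id)
    return out


def classify_spanning_read(
    read: SequenceRecord,
    genome: SequenceRecord,
    repeat: RepeatPair,
    min_flank: int = 500,
    max_flank_mismatch: float = 0.02,
) -> SpanningRead:
    """Assign each flank of a spanning read to a repeat copy's context.

    Each flank is aligned against the corresponding neighbourhood of
    both copies; it is assigned to the higher-identity context when the
    margin exceeds ``max_flank_mismatch``, else called ambiguous. The
    read call follows: same copy on both sides = parental, different
    copies = recombined, any ambiguity = uninformative.
    """
    core = genome.fetch(*repeat.copy1)
    oriented, s, e, _ident = _orient_read(read, core)
    lefts, rights = _copy_contexts(genome, repeat, min_flank)
    left_seq = oriented[max(0, s - min_flank) : s]
    right_seq = oriented[e : e + min_flank]
    li = (_infix_identity(left_seq, lefts[0]), _infix_identity(left_seq, lefts[1]))
    ri = (_infix_identity(right_seq, rights[0]), _infix_identity(right_seq, rights[1]))
    return SpanningRead(
        read_id=read.id,
        left=_assign(li, max_flank_mismatch),
        right=_assign(ri, max_flank_mismatch),
        left_identity=li,
        right_identity=ri,
    )


def _assign(ident: tuple[float, float], margin: float) -> FlankCall:
    if abs(ident[0] - ident[1]) <= margin:
        return "ambiguous"
    return "copy1" if ident[0] > ident[1] else "copy2"


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        return (0.0, 1.0)
    z = float(norm.ppf(0.5 + conf / 2))
    p = k / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * ((p * (1 - p) / n + z**2 / (4 * n**2)) ** 0.5) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


@dataclass(frozen=True)
class RecombinationSummary:
    """Per-repeat summary: recombined / spanning with a Wilson 95% CI."""

    n_spanning: int
    n_parental: int
    n_recombined: int
    n_uninformative: int

    @property
    def fraction(self) -> float:
        informative = self.n_parental + self.n_recombined
        return self.n_recombined / informative if informative else float("nan")

    @property
    def wilson95(self) -> tuple[float, float]:
        return wilson_interval(self.n_recombined, self.n_parental + self.n_recombined)


def survey_repeat(
    reads: Sequence[SequenceRecord],
    genome: SequenceRecord,
    repeat: RepeatPair,
    min_flank: int = 500,
    max_flank_mismatch: float = 0.02,
) -> tuple[RecombinationSummary, list[SpanningRead]]:
    """Find spanning reads for one repeat and classify each of them."""
    ids = set(
        find_spanning_reads(reads, genome, repeat, min_flank=min_flank)
    )
    calls = [
        classify_spanning_read(r, genome, repeat, min_flank, max_flank_mismatch)
        for r in reads
        if r.id in ids
    ]
    tally = {"parental": 0, "recombined": 0, "uninformative": 0}
    for c in calls:
        tally[c.call] += 1
    return (
        RecombinationSummary(
            n_spanning=len(calls),
            n_parental=tally["parental"],
            n_recombined=tally["recombined"],
            n_uninformative=tally["uninformative"],
        ),
        calls,
    )


def spanning_reads_table(calls: Iterable[SpanningRead], repeat_id: str = "R1") -> pd.DataFrame:
    rows = [
        {
            "read": c.read_id,
            "repeat": repeat_id,
            "left_flank": c.left,
            "right_flank": c.right,
            "call": c.call,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=["read", "repeat", "left_flank", "right_flank", "call"])
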