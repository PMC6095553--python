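"""Dispersed-repeat detection and classification on a circular genome.

A genome is compared against itself with the seed-and-extend kernel;
hit pairs with unique start/end coordinates are kept, the trivial
full-length self-match is dropped, and each pair is classified by
orientation (DR: both copies on the same strand; IR: opposite strands)
and by size tier: small [20, 100), medium [100, 1000) and large
(>= 1000 bp). Circularity is handled by scanning the doubled sequence
and deduplicating coordinates modulo the genome length, so the repeat
set is invariant under rotation of the origin.

The default filters (length >= 20 bp, identity >= 80%) are deliberate,
deterministic replacements for an E-value cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from mitocomp import intervals
from mitocomp.seedalign import (
    DEFAULT_SCORING,
    AlignmentHit,
    Scoring,
    Seed,
    extend_hit,
    _kmer_index,
)
from mitocomp.seqio import SequenceRecord, revcomp

SizeClass = Literal["small", "medium", "large"]

SMALL_MAX = 100
MEDIUM_MAX = 1000
MIN_REPORTABLE = 20


def classify_repeat_size(size: int) -> SizeClass:
    """Size tier of a repeat: small [20,100), medium [100,1000), large >= 1000.

    1000 bp itself is large ("large" is defined by the explicit
    inequality >= 1000 bp; the medium tier is half-open).
    """
    if size < MIN_REPORTABLE:
        raise ValueError(f"repeat of {size} bp is below the {MIN_REPORTABLE} bp reporting threshold")
    if size < SMALL_MAX:
        return "small"
    if size < MEDIUM_MAX:
        return "medium"
    return "large"


def orient_repeat(copy1_raw: tuple[int, int], copy2_raw: tuple[int, int]) -> str:
    """Orientation call from raw per-copy coordinate directions.

    Raw coordinates are (start, end) pairs as an aligner reports them:
    ascending on the plus strand, descending on the minus strand (the
    blastn convention). Copies on the same strand form a direct repeat
    (DR); opposite strands an inverted repeat (IR). A perfect palindrome
    aligned to itself in reverse has identical, direction-opposed
    coordinates and is an IR by definition.
    """
    for c in (copy1_raw, copy2_raw):
        if c[0] == c[1]:
            raise ValueError(f"degenerate interval {c}")
    asc1 = copy1_raw[1] > copy1_raw[0]
    asc2 = copy2_raw[1] > copy2_raw[0]
    return "DR" if asc1 == asc2 else "IR"


@dataclass(frozen=True)
class RepeatPair:
    """One repeat pair: two genomic intervals plus alignment metadata.

    Intervals are 0-based half-open on the forward strand with start in
    [0, L); on a circular genome ``end`` may exceed L, meaning the copy
    wraps the origin. ``identity`` is a percentage, ``size`` the
    alignment column count.
    """

    copy1: tuple[int, int]
    copy2: tuple[int, int]
    identity: float
    size: int
    orientation: str

    def __post_init__(self) -> None:
        if self.orientation not in ("DR", "IR"):
            raise ValueError("orientation must be DR or IR")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity is a percentage in [0, 100]")

    @property
    def size_class(self) -> SizeClass:
        return classify_repeat_size(self.size)

    @property
    def self_overlap(self) -> bool:
        """True when the two copies share genomic positions (e.g. palindromes)."""
        s1, e1 = self.copy1
        s2, e2 = self.copy2
        return s1 < e2 and s2 < e1


@dataclass(frozen=True)
class RepeatSummary:
    """Aggregate repeat statistics for one genome."""

    n_small: int
    n_medium: int
    n_large: int
    total_bp: int
    fraction: float

    @property
    def total_pairs(self) -> int:
        return self.n_small + self.n_medium + self.n_large


def _wrap_interval(iv: tuple[int, int], L: int) -> list[tuple[int, int]]:
    """Split a possibly origin-wrapping interval into linear pieces."""
    s, e = iv
    s %= L
    e = s + (iv[1] - iv[0])
    if e <= L:
        return [(s, e)]
    return [(s, L), (0, e - L)]


def _canonical(hit_q: tuple[int, int], hit_s: tuple[int, int], L: int) -> tuple:
    a = (hit_q[0] % L, hit_q[0] % L + (hit_q[1] - hit_q[0]))
    b = (hit_s[0] % L, hit_s[0] % L + (hit_s[1] - hit_s[0]))
    return (min(a, b), max(a, b))


def find_repeats(
    genome: SequenceRecord,
    min_len: int = 20,
    min_identity: float = 0.80,
    k: int = 12,
    scoring: Scoring = DEFAULT_SCORING,
) -> list[RepeatPair]:
    """Self-comparison repeat detection on one genome.

    Parameters
    ----------
    genome:
        The genome; circular topology is honoured by scanning the
        doubled sequence and reducing coordinates modulo L.
    min_len, min_identity:
        Reporting filters on alignment length (bp) and identity
        (fraction). Defaults correspond to length > 19 bp, identity
        >= 80%.
    k:
        Seed word size. Smaller words are exhaustive for shorter/less
        similar repeats at a quadratic cost in random seed matches.

    Returns
    -------
    list of :class:`RepeatPair`, sorted by copy1 start, deduplicated so
    that (A, B) and (B, A) count once and the trivial self-match is
    absent. Every reported pair re-validates at >= min_identity by
    construction (identity is computed from the realigned hit).
    """
    L = len(genome)
    if L < 2 * min_len:
        raise ValueError(f"genome of {L} bp is shorter than twice min_len={min_len}")
    subject = genome.seq
    query = subject + subject if genome.circular else subject

    index = _kmer_index(subject, k)
    # collapse seed runs: exact-match runs share a (anti)diagonal
    plus_firsts: dict[int, list[int]] = {}
    minus_firsts: dict[int, list[int]] = {}
    raw_seeds: list[Seed] = []
    for i in range(len(query) - k + 1):
        kmer = query[i : i + k]
        if "N" in kmer:
            continue
        for j in index.get(kmer, ()):
            if (i - j) % L == 0:
                continue  # trivial self-diagonal
            d = i - j
            run = plus_firsts.setdefault(d, [])
            if run and run[-1] == i - 1:
                run[-1] = i
                continue
            run.append(i)
            raw_seeds.append(Seed(i, j, "+", k))
        for j in index.get(revcomp(kmer), ()):
            c = i + j
            run = minus_firsts.setdefault(c, [])
            if run and run[-1] == i - 1:
                run[-1] = i
                continue
            run.append(i)
            raw_seeds.append(Seed(i, j, "-", k))

    band = scoring.xdrop // scoring.gap_extend + 5
    accepted: list[AlignmentHit] = []
    seen: set[tuple] = set()
    pairs: list[RepeatPair] = []
    for seed in raw_seeds:
        if _seed_covered(seed, accepted, band):
            continue
        hit = extend_hit(seed, query, subject, scoring)
        accepted.append(hit)
        if hit.length < min_len or hit.length > L:
            continue
        if hit.identity < min_identity:
            continue
        key = _canonical(hit.q_interval, hit.s_interval, L) + (hit.strand,)
        if key in seen:
            continue
        seen.add(key)
        (c1, c2) = key[0], key[1]
        if hit.strand == "+" and c1 == c2:
            continue  # identical intervals: degenerate self-hit
        pairs.append(
            RepeatPair(
                copy1=c1,
                copy2=c2,
                identity=round(100.0 * hit.identity, 2),
                size=hit.length,
                orientation="DR" if hit.strand == "+" else "IR",
            )
        )
    pairs.sort(key=lambda p: (p.copy1, p.copy2))
    return pairs


def _seed_covered(seed: Seed, hits: list[AlignmentHit], band: int) -> bool:
    i, j, strand, k = seed
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


def summarize_repeats(
    repeats: Iterable[RepeatPair],
    genome_length: int,
    count_mode: Literal["union_both_copies", "one_copy"] = "union_both_copies",
) -> RepeatSummary:
    """Counts per size class and total repeat-covered basepairs.

    ``union_both_copies`` (default) counts every genomic position lying
    under any repeat copy once; ``one_copy`` counts the union of copy-1
    spans only.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    reps = list(repeats)
    counts = {"small": 0, "medium": 0, "large": 0}
    ivs: list[tuple[int, int]] = []
    for r in reps:
        counts[r.size_class] += 1
        ivs.extend(_wrap_interval(r.copy1, genome_length))
        if count_mode == "union_both_copies":
            ivs.extend(_wrap_interval(r.copy2, genome_length))
    total = intervals.union_length(ivs)
    return RepeatSummary(
        n_small=counts["small"],
        n_medium=counts["medium"],
        n_large=counts["large"],
        total_bp=total,
        fraction=total / genome_length,
    )


# ---------------------------------------------------------------------------
# repeat-table I/O (1-based inclusive reporting layout)


def repeats_to_table(repeats: Iterable[RepeatPair], genome_length: int) -> pd.DataFrame:
    """Repeat pairs as a report table.

    Copy coordinates are 1-based inclusive; the second copy of an IR is
    printed with descending coordinates, mirroring aligner output
    conventions.
    """
    rows = []
    for n, r in enumerate(sorted(repeats, key=lambda p: -p.size), start=1):
        c1s, c1e = r.copy1[0] + 1, (r.copy1[1] - 1) % genome_length + 1
        if r.orientation == "DR":
            c2s, c2e = r.copy2[0] + 1, (r.copy2[1] - 1) % genome_length + 1
        else:
            c2s, c2e = (r.copy2[1] - 1) % genome_length + 1, r.copy2[0] + 1
        rows.append(
            {
                "No.": f"R{n}",
                "Identity": f"{r.identity:.2f}",
                "Copy1_Start": c1s,
                "Copy1_End": c1e,
                "Copy2_Start": c2s,
                "Copy2_End": c2e,
                "Size": r.size,
                "Type": r.orientation,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["No.", "Identity", "Copy1_Start", "Copy1_End", "Copy2_Start", "Copy2_End", "Size", "Type"],
    )


def read_repeat_table(path: str | Path) -> pd.DataFrame:
    """Read a repeat table in the report layout written by :func:`repeats_to_table`."""
    return pd.read_csv(path, sep="\t")


def table_to_pairs(df: pd.DataFrame) -> list[RepeatPair]:
    """Reconstruct :class:`RepeatPair` rows from a report-layout table.

    Orientation is recomputed from the printed coordinate directions,
    not taken from the Type column, so the table's own Type column can
    be cross-checked against the coordinate geometry.
    """
    pairs = []
    for _, row in df.iterrows():
        c1 = (int(row["Copy1_Start"]), int(row["Copy1_End"]))
        c2 = (int(row["Copy2_Start"]), int(row["Copy2_End"]))
        orientation = orient_repeat(c1, c2)
        c1 = (min(c1) - 1, max(c1))
        c2 = (min(c2) - 1, max(c2))
        lo, hi = sorted([c1, c2])
        pairs.append(
            RepeatPair(
                copy1=lo,
                copy2=hi,
                identity=float(row["Identity"]),
                size=int(row["Size"]),
                orientation=orientation,
            )
        )
    return pairs


def load_reference_repeat_table() -> pd.DataFrame:
    """The published dispersed-repeat table (>100 bp) of the *Sophora
    japonica* 'JinhuaiJ2' mitogenome (GenBank MG757109), shipped with
    the package as a worked example and regression fixture."""
    with resources.files("mitocomp.data").joinpath("sophora_mg757109_repeats.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def circos_links(repeats: Iterable[RepeatPair], chrom: str, genome_length: int) -> pd.DataFrame:
    """Repeat pairs as a Circos-style link table (chr start end chr start end)."""
    rows = []
    for r in repeats:
        rows.append(
            {
                "chr1": chrom,
                "start1": r.copy1[0] + 1,
                "end1": (r.copy1[1] - 1) % genome_length + 1,
                "chr2": chrom,
                "start2": r.copy2[0] + 1,
                "end2": (r.copy2[1] - 1) % genome_length + 1,
            }
        )
    return pd.DataFrame(rows, columns=["chr1", "start1", "end1", "chr2", "start2", "end2"])
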