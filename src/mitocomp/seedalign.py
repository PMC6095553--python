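"""Minimal seed-and-extend local alignment kernel.

The repeat, pseudogene, sharing and read-evidence scans all reduce to
finding high-identity local alignments between nucleotide sequences.
This module provides the shared kernel: exhaustive exact k-mer seeding
on both strands, gapped x-drop extension with blastn-like affine
scoring, and an exact Smith–Waterman reference (:func:`local_align_exact`)
used as the equivalence oracle in tests.

Hits are filtered downstream by minimum length and identity rather than
by E-value, which keeps the results deterministic and independent of
database size. Coordinates are 0-based half-open and always ascending on
both sequences; minus-strand hits carry a strand flag instead of
descending ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import edlib
import pandas as pd
from Bio import Align

from mitocomp.seqio import SequenceRecord, revcomp

NEG = -(10**9)


@dataclass(frozen=True)
class Scoring:
    """Affine alignment scores; a gap of length g costs open + extend*g."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    xdrop: int = 20

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("scoring requires match > 0 and mismatch < 0")
        if self.gap_open < 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive costs")

    @property
    def first_gap(self) -> int:
        return self.gap_open + self.gap_extend


DEFAULT_SCORING = Scoring()


class Seed(NamedTuple):
    """Exact k-mer match: query[q:q+k] equals subject[s:s+k] (rc for '-')."""

    q: int
    s: int
    strand: str
    k: int


@dataclass(frozen=True)
class AlignmentHit:
    """A local alignment between two sequence intervals.

    ``identity`` is the fraction of alignment columns that are exact
    matches; ``length`` counts alignment columns (including gap
    columns). Subject coordinates of minus-strand hits are ascending on
    the forward strand of the subject.
    """

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    identity: float
    length: int
    score: int

    def __post_init__(self) -> None:
        if not (self.q_start < self.q_end and self.s_start < self.s_end):
            raise ValueError("hit intervals must be non-empty and ascending")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must lie in [0, 1]")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    @property
    def q_interval(self) -> tuple[int, int]:
        return (self.q_start, self.q_end)

    @property
    def s_interval(self) -> tuple[int, int]:
        return (self.s_start, self.s_end)

    def swapped(self) -> "AlignmentHit":
        """The same hit with query and subject roles exchanged."""
        return AlignmentHit(
            self.s_start,
            self.s_end,
            self.q_start,
            self.q_end,
            self.strand,
            self.identity,
            self.length,
            self.score,
        )


def _as_seq(x: SequenceRecord | str) -> str:
    return x.seq if isinstance(x, SequenceRecord) else str(x).upper()


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for j in range(len(seq) - k + 1):
        kmer = seq[j : j + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(j)
    return index


def find_seeds(
    query: SequenceRecord | str, subject: SequenceRecord | str, k: int
) -> list[Seed]:
    """Exhaustive exact k-mer matches between query and subject.

    Both strands are searched; a minus-strand seed ``(i, j, '-')``
    satisfies ``query[i:i+k] == revcomp(subject[j:j+k])`` with ``j``
    the ascending forward-strand coordinate. K-mers containing ``N``
    never match.
    """
    if k < 4:
        raise ValueError("word size k must be >= 4")
    q, s = _as_seq(query), _as_seq(subject)
    if k > len(q) or k > len(s):
        return []
    index = _kmer_index(s, k)
    seeds: list[Seed] = []
    for i in range(len(q) - k + 1):
        kmer = q[i : i + k]
        if "N" in kmer:
            continue
        for j in index.get(kmer, ()):
            seeds.append(Seed(i, j, "+", k))
        for j in index.get(revcomp(kmer), ()):
            seeds.append(Seed(i, j, "-", k))
    seeds.sort()
    return seeds


def _xdrop_extend(
    q: str, s: str, qi: int, sj: int, scoring: Scoring
) -> tuple[int, int, int]:
    """Extend rightwards aligning q[qi:] with s[sj:] under x-drop pruning.

    Returns ``(dq, ds, score)`` of the best-scoring prefix alignment.
    Affine three-state DP; rows advance over query offsets and only the
    column window whose score stays within ``xdrop`` of the running best
    is kept alive.
    """
    ma, mm = scoring.match, scoring.mismatch
    g1, ge = scoring.first_gap, scoring.gap_extend
    xdrop = scoring.xdrop
    nq, ns = len(q) - qi, len(s) - sj

    best_score, best_dq, best_ds = 0, 0, 0
    # row 0: only the query-gap (Iy) state is reachable
    row: dict[int, tuple[int, int, int]] = {0: (0, NEG, NEG)}
    j, sc = 1, -g1
    while j <= ns and sc >= -xdrop:
        row[j] = (NEG, NEG, sc)
        j += 1
        sc -= ge
    lo, hi = 0, j - 1

    for i in range(1, nq + 1):
        qc = q[qi + i - 1]
        nrow: dict[int, tuple[int, int, int]] = {}
        nlo = -1
        prev: tuple[int, int, int] | None = None  # live cell (i, jj-1)
        jj = lo
        limit = min(ns, hi + 1)  # beyond this, only in-row gap chains reach
        while jj <= ns:
            if jj > limit and prev is None:
                break
            up = row.get(jj)
            cix = max(up[0] - g1, up[1] - ge, up[2] - g1) if up else NEG
            if jj == 0:
                cm = ciy = NEG
            else:
                dg = row.get(jj - 1)
                if dg:
                    sub = ma if (qc == s[sj + jj - 1] and qc != "N") else mm
                    cm = max(dg) + sub
                else:
                    cm = NEG
                ciy = max(prev[0] - g1, prev[1] - g1, prev[2] - ge) if prev else NEG
            cell = (cm, cix, ciy)
            if max(cell) > NEG // 2 and max(cell) >= best_score - xdrop:
                nrow[jj] = cell
                if nlo < 0:
                    nlo = jj
                if cm > best_score:
                    best_score, best_dq, best_ds = cm, i, jj
                prev = cell
            else:
                prev = None
            jj += 1
        if nlo < 0:
            break
        lo, hi = nlo, max(nrow)
        row = nrow
    return best_dq, best_ds, best_score


def _alignment_identity(a: str, b: str) -> tuple[float, int]:
    """Identity fraction and column count of a global alignment of a, b."""
    if a == b:
        return 1.0, len(a)
    res = edlib.align(a, b, mode="NW", task="path")
    cols = 0
    matches = 0
    # cigar like '10=2X5I' when using extended notation; edlib returns '=XDI'
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            cols += n
            if ch == "=":
                matches += n
    return (matches / cols if cols else 0.0), cols


def extend_hit(
    seed: Seed,
    query: SequenceRecord | str,
    subject: SequenceRecord | str,
    scoring: Scoring = DEFAULT_SCORING,
) -> AlignmentHit:
    """Gapped x-drop extension of an exact seed into a local hit.

    The returned hit always contains the seed; in random sequence the
    extension terminates almost immediately and the hit stays close to
    the seed itself.
    """
    q, s = _as_seq(query), _as_seq(subject)
    qi, sj, strand, k = seed
    if strand == "-":
        s_rc = revcomp(s)
        sj_rc = len(s) - (sj + k)
        hit = _extend_plus(q, s_rc, Seed(qi, sj_rc, "+", k), scoring)
        return AlignmentHit(
            hit.q_start,
            hit.q_end,
            len(s) - hit.s_end,
            len(s) - hit.s_start,
            "-",
            hit.identity,
            hit.length,
            hit.score,
        )
    return _extend_plus(q, s, seed, scoring)


def _extend_plus(q: str, s: str, seed: Seed, scoring: Scoring) -> AlignmentHit:
    qi, sj, _strand, k = seed
    dqr, dsr, score_r = _xdrop_extend(q, s, qi + k, sj + k, scoring)
    dql, dsl, score_l = _xdrop_extend(q[:qi][::-1], s[:sj][::-1], 0, 0, scoring)
    q_start, q_end = qi - dql, qi + k + dqr
    s_start, s_end = sj - dsl, sj + k + dsr
    score = scoring.match * k + score_l + score_r
    identity, cols = _alignment_identity(q[q_start:q_end], s[s_start:s_end])
    return AlignmentHit(q_start, q_end, s_start, s_end, "+", identity, cols, score)


def _alignment_path(a: str, b: str) -> list[tuple[int, int, bool]]:
    """Per-column (a_offset, b_offset, is_match) of a global alignment.

    Offsets are the positions *after* consuming the column; gap columns
    count as non-matches.
    """
    res = edlib.align(a, b, mode="NW", task="path")
    cols: list[tuple[int, int, bool]] = []
    i = j = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        for _ in range(n):
            if ch == "=":
                i += 1
                j += 1
                cols.append((i, j, True))
            elif ch == "X":
                i += 1
                j += 1
                cols.append((i, j, False))
            elif ch == "I":  # consumes query
                i += 1
                cols.append((i, j, False))
            else:  # 'D': consumes target
                j += 1
                cols.append((i, j, False))
    return cols


def refine_hit_window(
    hit: AlignmentHit, query: str, subject: str, min_identity: float, min_len: int
) -> AlignmentHit | None:
    """Trim a hit to its longest sub-window at or above ``min_identity``.

    X-drop extension occasionally appends a chance high-scoring run of
    background beyond a true homologous segment, diluting the hit's
    overall identity. This picks the longest alignment window (ending
    on match columns) whose identity meets the threshold; returns None
    when no window of ``min_len`` alignment columns qualifies.
    """
    q_sub = query[hit.q_start : hit.q_end]
    s_sub = subject[hit.s_start : hit.s_end]
    if hit.strand == "-":
        s_sub = revcomp(s_sub)
    cols = _alignment_path(q_sub, s_sub)
    n = len(cols)
    match_prefix = [0] * (n + 1)
    for idx, (_, _, ok) in enumerate(cols):
        match_prefix[idx + 1] = match_prefix[idx] + ok
    match_cols = [idx for idx, c in enumerate(cols) if c[2]]
    best: tuple[int, float, int, int] | None = None  # (length, identity, i, j)
    for ii in match_cols:
        for jj in reversed(match_cols):
            if jj < ii:
                break
            length = jj - ii + 1
            if best is not None and length < max(best[0], min_len):
                break
            ident = (match_prefix[jj + 1] - match_prefix[ii]) / length
            if ident >= min_identity and length >= min_len:
                cand = (length, ident, ii, jj)
                if best is None or cand[:2] > best[:2]:
                    best = cand
                break  # longer windows from this ii already seen
    if best is None:
        return None
    _, ident, ii, jj = best
    q0 = cols[ii][0] - 1
    q1 = cols[jj][0]
    t0 = cols[ii][1] - 1
    t1 = cols[jj][1]
    if hit.strand == "+":
        s0, s1 = hit.s_start + t0, hit.s_start + t1
    else:
        s0, s1 = hit.s_end - t1, hit.s_end - t0
    return AlignmentHit(
        hit.q_start + q0,
        hit.q_start + q1,
        s0,
        s1,
        hit.strand,
        ident,
        jj - ii + 1,
        hit.score,
    )


def local_align_exact(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    scoring: Scoring = DEFAULT_SCORING,
) -> AlignmentHit:
    """Optimal local alignment over both strands (Smith–Waterman).

    Exact dynamic programming via Bio.Align; quadratic, so restricted to
    ``len(a) * len(b) <= 10**6``. Serves as the reference the x-drop
    extension is validated against.
    """
    sa, sb = _as_seq(a), _as_seq(b)
    if len(sa) * len(sb) > 10**6:
        raise ValueError(
            "local_align_exact is a quadratic reference implementation; "
            f"refusing {len(sa)} x {len(sb)} problem (> 1e6 cells)"
        )
    if "N" in sa or "N" in sb:
        raise ValueError("exact reference alignment requires N-free sequences")
    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=scoring.match,
        mismatch_score=scoring.mismatch,
        open_gap_score=-scoring.first_gap,
        extend_gap_score=-scoring.gap_extend,
    )
    best: AlignmentHit | None = None
    for strand, sb_oriented in (("+", sb), ("-", revcomp(sb))):
        alns = aligner.align(sa, sb_oriented)
        if len(alns) == 0 or alns.score <= 0:
            continue
        aln = alns[0]
        qs, qe = int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])
        ss, se = int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1])
        matches = 0
        cols = 0
        for (qb0, qb1), (sb0, sb1) in zip(aln.aligned[0], aln.aligned[1]):
            blk_q = sa[qb0:qb1]
            blk_s = sb_oriented[sb0:sb1]
            matches += sum(x == y for x, y in zip(blk_q, blk_s))
            cols += qb1 - qb0
        # gap columns between aligned blocks
        for idx in range(1, len(aln.aligned[0])):
            cols += (aln.aligned[0][idx][0] - aln.aligned[0][idx - 1][1]) + (
                aln.aligned[1][idx][0] - aln.aligned[1][idx - 1][1]
            )
        if strand == "-":
            ss, se = len(sb) - se, len(sb) - ss
        hit = AlignmentHit(
            qs, qe, ss, se, strand, matches / cols if cols else 0.0, cols, int(alns.score)
        )
        if best is None or hit.score > best.score:
            best = hit
    if best is None:
        raise ValueError("no positive-scoring local alignment exists")
    return best


def hits_table(hits: Iterable[AlignmentHit], qid: str, sid: str) -> pd.DataFrame:
    """Hits as a blastn outfmt-6-style table (1-based inclusive coords).

    Minus-strand hits are reported with descending subject coordinates,
    as blastn prints them.
    """
    rows = []
    for h in hits:
        if h.strand == "+":
            ss, se = h.s_start + 1, h.s_end
        else:
            ss, se = h.s_end, h.s_start + 1
        rows.append(
            {
                "qseqid": qid,
                "sseqid": sid,
                "pident": round(100.0 * h.identity, 2),
                "length": h.length,
                "qstart": h.q_start + 1,
                "qend": h.q_end,
                "sstart": ss,
                "send": se,
                "score": h.score,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["qseqid", "sseqid", "pident", "length", "qstart", "qend", "sstart", "send", "score"],
    )
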