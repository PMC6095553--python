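"""Intron length variation, deletion blocks and deletion-edge repeats.

Orthologous intron alignments across related mitogenomes often show
taxon-specific deletions of tens of bases to kilobases. When such a
deletion arose by homologous recombination between two short direct
repeats, the taxa retaining the region carry one repeat copy at (or
within a few bases of) each deletion edge, while the deleted lineage
keeps a single collapsed copy. This module tabulates per-taxon intron
lengths, extracts taxon-specific deletion blocks from alignments, and
searches the retained sequence for direct repeats anchored at the
deletion edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from mitocomp.seqio import revcomp

GAP = "-"


def read_alignment_fasta(path: str | Path) -> dict[str, str]:
    """Aligned FASTA -> {taxon: aligned sequence}; lengths must agree."""
    aln: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in aln:
            raise ValueError(f"duplicate taxon {rec.id!r} in {path}")
        aln[rec.id] = str(rec.seq).upper()
    lengths = {len(s) for s in aln.values()}
    if len(lengths) > 1:
        raise ValueError(f"ragged alignment in {path}: lengths {sorted(lengths)}")
    return aln


def intron_length_table(
    alignments: Mapping[str, Mapping[str, str]]
) -> pd.DataFrame:
    """Ungapped per-taxon length of each intron alignment.

    Rows are taxa, columns introns; a taxon absent from an alignment
    yields a missing (NaN) cell. Lengths depend only on per-taxon
    residue counts, never on column order.
    """
    taxa = sorted({t for aln in alignments.values() for t in aln})
    data = {}
    for intron_id, aln in alignments.items():
        if len(set(aln)) != len(aln):
            raise ValueError(f"duplicate taxon in alignment {intron_id!r}")
        col = {}
        for t in taxa:
            seq = aln.get(t)
            col[t] = float(len(seq) - seq.count(GAP)) if seq is not None else float("nan")
        data[intron_id] = col
    return pd.DataFrame(data, index=taxa)


@dataclass(frozen=True)
class DeletionBlock:
    """A taxon-specific deletion in one intron alignment.

    ``col_start``/``col_end`` are 0-based half-open alignment columns of
    the merged gap run; ``length`` counts the columns carrying sequence
    in at least one reference taxon (i.e. deleted basepairs relative to
    the retained state). ``affected_taxa`` lists every taxon whose gap
    spans the whole block.
    """

    alignment_id: str
    taxon: str
    col_start: int
    col_end: int
    length: int
    affected_taxa: tuple[str, ...]


def _informative_columns(aln: Mapping[str, str]) -> list[int]:
    ncol = len(next(iter(aln.values())))
    return [c for c in range(ncol) if any(seq[c] != GAP for seq in aln.values())]


def find_deletion_blocks(
    alignment: Mapping[str, str],
    min_del: int = 50,
    merge_gap: int = 10,
    alignment_id: str = "alignment",
) -> list[DeletionBlock]:
    """Maximal taxon-specific gap runs of at least ``min_del`` deleted bp.

    Runs in one taxon separated by fewer than ``merge_gap`` informative
    columns are merged into one block. Columns that are gaps in every
    taxon carry no sequence and are ignored throughout, so the result is
    invariant under removal of all-gap columns. A gap shared by all taxa
    never forms a block: no reference retains sequence there.
    """
    if len(alignment) < 2:
        raise ValueError("need at least two taxa to call deletions")
    cols = _informative_columns(alignment)
    if not cols:
        return []

    blocks: dict[tuple[int, int], set[str]] = {}
    for taxon, seq in alignment.items():
        # gap runs over informative columns only
        runs: list[list[int]] = []  # [start_idx, end_idx) in reduced space
        in_run = False
        for idx, c in enumerate(cols):
            if seq[c] == GAP:
                if in_run:
                    runs[-1][1] = idx + 1
                else:
                    runs.append([idx, idx + 1])
                    in_run = True
            else:
                in_run = False
        merged: list[list[int]] = []
        for r in runs:
            if merged and r[0] - merged[-1][1] < merge_gap:
                merged[-1][1] = r[1]
            else:
                merged.append(r)
        for start_idx, end_idx in merged:
            if end_idx - start_idx < min_del:
                continue
            key = (start_idx, end_idx)
            blocks.setdefault(key, set()).add(taxon)

    out = []
    for (start_idx, end_idx), primary in sorted(blocks.items()):
        lo, hi = cols[start_idx], cols[end_idx - 1] + 1
        affected = sorted(
            t
            for t, seq in alignment.items()
            if all(seq[cols[i]] == GAP for i in range(start_idx, end_idx))
        )
        for taxon in sorted(primary):
            out.append(
                DeletionBlock(
                    alignment_id=alignment_id,
                    taxon=taxon,
                    col_start=lo,
                    col_end=hi,
                    length=end_idx - start_idx,
                    affected_taxa=tuple(affected),
                )
            )
    return out


@dataclass(frozen=True)
class EdgeRepeat:
    """A direct repeat with one copy at each edge of a deletion.

    Positions are 0-based starts in the ungapped retained sequence;
    each offset is the distance between the copy interval and its
    deletion edge (0 = the copy touches or straddles the edge). Using
    the interval-to-edge distance makes the call independent of which
    of the two copies the deleted lineage's surviving copy was aligned
    to.
    """

    seq: str
    length: int
    left_pos: int
    right_pos: int
    offset_left: int
    offset_right: int
    mismatches: int
    inverted: bool = False


def _degap_map(aligned: str) -> tuple[str, list[int]]:
    """Ungapped sequence plus per-column ungapped offsets.

    ``colmap[c]`` is the number of residues strictly before column c.
    """
    colmap = []
    n = 0
    for ch in aligned:
        colmap.append(n)
        if ch != GAP:
            n += 1
    colmap.append(n)
    return aligned.replace(GAP, ""), colmap


def _edge_offset(pos: int, length: int, edge: int) -> int:
    """Distance between the copy interval [pos, pos+length) and an edge point."""
    return max(0, pos - edge, edge - (pos + length))


def edge_repeat_search(
    retained_seq: str,
    deletion: DeletionBlock,
    min_rep: int = 10,
    window: int = 5,
    max_mismatch: int = 0,
    max_rep: int = 50,
    include_inverted: bool = False,
) -> list[EdgeRepeat]:
    """Direct repeats anchored at the edges of a deletion.

    Parameters
    ----------
    retained_seq:
        The **aligned** row of a taxon retaining the deleted region, in
        the same column space as ``deletion``.
    min_rep:
        Minimum repeat length (bp); the recombinogenic repeats observed
        at real intron deletions measure roughly 10-20 bp.
    window:
        Maximum distance (bp) between a copy and its deletion edge; 0
        demands repeats touching the edges.
    max_mismatch:
        Mismatches tolerated between the two copies (0 = exact).
    max_rep:
        Search cap on repeat length.

    Returns hits sorted by length descending, the maximal hit per
    copy-spacing; each hit has one copy within ``window`` of the left
    edge and one within ``window`` of the right edge.
    """
    seq, colmap = _degap_map(retained_seq)
    d_start, d_end = colmap[deletion.col_start], colmap[deletion.col_end]
    if d_end - d_start <= 0:
        raise ValueError(
            "deletion lies outside the span retained by this taxon "
            f"(columns {deletion.col_start}-{deletion.col_end} are all gaps here)"
        )
    return _edge_repeats_ungapped(
        seq, d_start, d_end, min_rep, window, max_mismatch, max_rep, include_inverted
    )


def _extension(seq: str, p1: int, q1: int, cap: int, max_mismatch: int) -> tuple[int, int]:
    """Longest common extension of the two starts within a mismatch budget."""
    mism = r = 0
    best_r = best_m = 0
    while q1 + r < len(seq) and p1 + r < q1 and r < cap:
        if seq[p1 + r] != seq[q1 + r] or seq[p1 + r] == "N":
            mism += 1
            if mism > max_mismatch:
                break
        r += 1
        best_r, best_m = r, mism
    # trim trailing mismatches so reported copies end on a match
    while best_r > 0 and (seq[p1 + best_r - 1] != seq[q1 + best_r - 1] or seq[p1 + best_r - 1] == "N"):
        best_r -= 1
        best_m -= 1
    return best_r, best_m


def _edge_repeats_ungapped(
    seq: str,
    d_start: int,
    d_end: int,
    min_rep: int,
    window: int,
    max_mismatch: int,
    max_rep: int,
    include_inverted: bool,
) -> list[EdgeRepeat]:
    n = len(seq)
    best_per_diag: dict[tuple[int, bool], EdgeRepeat] = {}
    for p1 in range(max(0, d_start - window - max_rep), min(n, d_start + window) + 1):
        for q1 in range(
            max(p1 + min_rep, d_end - window - max_rep), min(n - min_rep, d_end + window) + 1
        ):
            rmax, mism = _extension(seq, p1, q1, min(max_rep, q1 - p1, n - q1), max_mismatch)
            # window conditions only bound the length from below
            r_lb = max(min_rep, d_start - window - p1, d_end - window - q1)
            if rmax < r_lb:
                continue
            r = rmax
            if _edge_offset(p1, r, d_start) > window or _edge_offset(q1, r, d_end) > window:
                continue
            hit = EdgeRepeat(
                seq=seq[p1 : p1 + r],
                length=r,
                left_pos=p1,
                right_pos=q1,
                offset_left=_edge_offset(p1, r, d_start),
                offset_right=_edge_offset(q1, r, d_end),
                mismatches=mism,
            )
            key = (q1 - p1, False)
            prev = best_per_diag.get(key)
            if prev is None or hit.length > prev.length:
                best_per_diag[key] = hit
    if include_inverted:
        for p1 in range(max(0, d_start - window - max_rep), min(n, d_start + window) + 1):
            for r in range(min_rep, max_rep + 1):
                if p1 + r > n or _edge_offset(p1, r, d_start) > window:
                    continue
                left = seq[p1 : p1 + r]
                for q1 in range(max(p1 + r, d_end - window - r), min(n - r, d_end + window) + 1):
                    if _edge_offset(q1, r, d_end) > window:
                        continue
                    right = seq[q1 : q1 + r]
                    mism = sum(a != b or a == "N" for a, b in zip(left, revcomp(right)))
                    if mism <= max_mismatch:
                        hit = EdgeRepeat(
                            seq=left,
                            length=r,
                            left_pos=p1,
                            right_pos=q1,
                            offset_left=_edge_offset(p1, r, d_start),
                            offset_right=_edge_offset(q1, r, d_end),
                            mismatches=mism,
                            inverted=True,
                        )
                        key = (q1 - p1, True)
                        prev = best_per_diag.get(key)
                        if prev is None or hit.length > prev.length:
                            best_per_diag[key] = hit
    hits = sorted(
        best_per_diag.values(),
        key=lambda h: (-h.length, h.offset_left + h.offset_right, h.left_pos),
    )
    return hits


def deletion_blocks_table(blocks: Iterable[DeletionBlock]) -> pd.DataFrame:
    rows = [
        {
            "alignment": b.alignment_id,
            "taxon": b.taxon,
            "col_start": b.col_start + 1,
            "col_end": b.col_end,
            "deleted_bp": b.length,
            "affected_taxa": ",".join(b.affected_taxa),
        }
        for b in blocks
    ]
    return pd.DataFrame(
        rows, columns=["alignment", "taxon", "col_start", "col_end", "deleted_bp", "affected_taxa"]
    )


def edge_repeats_table(hits: Iterable[EdgeRepeat]) -> pd.DataFrame:
    rows = [
        {
            "repeat": h.seq,
            "length": h.length,
            "left_pos": h.left_pos + 1,
            "right_pos": h.right_pos + 1,
            "offset_left": h.offset_left,
            "offset_right": h.offset_right,
            "mismatches": h.mismatches,
            "orientation": "IR" if h.inverted else "DR",
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "repeat",
            "length",
            "left_pos",
            "right_pos",
            "offset_left",
            "offset_right",
            "mismatches",
            "orientation",
        ],
    )
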