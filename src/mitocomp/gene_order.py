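"""Signed gene orders and DCJ rearrangement distances.

A genome is reduced to the circular sequence of its genes with signs
giving transcriptional strand. The double-cut-and-join (DCJ) distance —
the minimal number of operations that cut two adjacencies and rejoin
the four ends — between two single-chromosome circular genomes over the
same single-copy gene set is ``N - C``, where ``N`` is the number of
shared genes and ``C`` the number of alternating cycles in the
adjacency graph. A single segmental inversion is one DCJ operation, so
the distance counts inversions on inversion-only histories.

The circle has no intrinsic origin or orientation: rotations and
whole-genome reflection leave the adjacency set, and hence the
distance, unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from mitocomp.seqio import Annotation

SignedGene = tuple[str, int]  # (symbol, +1 | -1)


@dataclass(frozen=True)
class GeneOrder:
    """An ordered, signed gene list for one genome."""

    genome_id: str
    genes: tuple[SignedGene, ...]
    topology: Literal["circular", "linear"] = "circular"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene order for {self.genome_id!r} is empty")
        symbols = [g for g, _ in self.genes]
        if len(symbols) != len(set(symbols)):
            dups = sorted({s for s in symbols if symbols.count(s) > 1})
            raise ValueError(f"duplicate gene symbols in {self.genome_id!r}: {dups}")
        if any(s not in (1, -1) for _, s in self.genes):
            raise ValueError("gene signs must be +1 or -1")

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.genes)

    def restricted(self, keep: Iterable[str]) -> "GeneOrder":
        keep = set(keep)
        sub = tuple(g for g in self.genes if g[0] in keep)
        return GeneOrder(self.genome_id, sub, self.topology)

    def __str__(self) -> str:
        body = " ".join(("" if s > 0 else "-") + g for g, s in self.genes)
        term = ")" if self.topology == "circular" else "|"
        return f"{self.genome_id}: {body} {term}"


def invert_segment(order: GeneOrder, i: int, j: int) -> GeneOrder:
    """Invert genes ``i..j-1``: reverse their order and flip their signs."""
    if not (0 <= i < j <= len(order.genes)):
        raise ValueError(f"bad inversion bounds [{i}, {j})")
    seg = tuple((g, -s) for g, s in reversed(order.genes[i:j]))
    return GeneOrder(order.genome_id, order.genes[:i] + seg + order.genes[j:], order.topology)


def extract_gene_order(
    annotation: Annotation,
    dedup: Literal["drop-all", "first"] = "drop-all",
    trans_spliced: Iterable[str] = (),
) -> GeneOrder:
    """Signed gene order from an annotation.

    Genes are sorted by start coordinate; the sign is the strand.
    Fragments of trans-spliced genes (several gene features sharing one
    symbol) are collapsed to a single marker at the lowest-coordinate
    fragment. Any other duplicated symbol is resolved per ``dedup``:
    ``drop-all`` removes the symbol entirely (multi-copy genes carry no
    unambiguous order information), ``first`` keeps the first copy.
    """
    feats = sorted(annotation.genes(), key=lambda f: (f.start, f.end))
    trans = set(trans_spliced)
    counts: dict[str, int] = {}
    for f in feats:
        counts[f.gene] = counts.get(f.gene, 0) + 1

    out: list[SignedGene] = []
    seen: set[str] = set()
    for f in feats:
        if f.gene in seen:
            continue
        if counts[f.gene] > 1 and f.gene not in trans:
            if dedup == "drop-all":
                warnings.warn(
                    f"gene {f.gene!r} occurs {counts[f.gene]} times in "
                    f"{annotation.genome_id}; dropped from the gene order"
                )
                seen.add(f.gene)
                continue
            warnings.warn(
                f"gene {f.gene!r} occurs {counts[f.gene]} times in "
                f"{annotation.genome_id}; keeping the first copy"
            )
        out.append((f.gene, 1 if f.strand == "+" else -1))
        seen.add(f.gene)
    return GeneOrder(annotation.genome_id, tuple(out), "circular")


# ---------------------------------------------------------------------------
# DCJ distance


def _adjacencies(order: GeneOrder) -> dict[tuple[str, int], tuple[str, int]]:
    """Adjacency map of a circular signed order.

    Each gene g has a tail extremity (g, 0) and a head (g, 1); a gene
    read with sign + is traversed tail->head. The map sends each
    extremity to the extremity it abuts, and is symmetric.
    """
    genes = order.genes
    n = len(genes)
    adj: dict[tuple[str, int], tuple[str, int]] = {}
    for idx in range(n):
        g1, s1 = genes[idx]
        g2, s2 = genes[(idx + 1) % n]
        left = (g1, 1 if s1 > 0 else 0)   # outgoing extremity of g1
        right = (g2, 0 if s2 > 0 else 1)  # incoming extremity of g2
        adj[left] = right
        adj[right] = left
    return adj


def dcj_distance(a: GeneOrder, b: GeneOrder) -> int:
    """DCJ distance between two circular single-chromosome gene orders.

    The orders are restricted to their shared gene set first. Distance
    is ``N - C`` with ``C`` the number of cycles of the adjacency graph;
    it is 0 iff the orders agree up to rotation and whole-circle
    reflection.
    """
    if a.topology != "circular" or b.topology != "circular":
        raise ValueError("dcj_distance is defined here for circular gene orders")
    shared = a.symbols & b.symbols
    if not shared:
        raise ValueError(f"no shared genes between {a.genome_id!r} and {b.genome_id!r}")
    ra, rb = a.restricted(shared), b.restricted(shared)
    adj_a, adj_b = _adjacencies(ra), _adjacencies(rb)

    cycles = 0
    unvisited = set(adj_a)
    while unvisited:
        start = next(iter(unvisited))
        cur = start
        while True:
            unvisited.discard(cur)
            nxt = adj_a[cur]
            unvisited.discard(nxt)
            cur = adj_b[nxt]
            if cur == start:
                break
        cycles += 1
    return len(shared) - cycles


def pairwise_matrix(orders: Sequence[GeneOrder]) -> pd.DataFrame:
    """Symmetric matrix of pairwise DCJ distances.

    Each pair is compared on its own shared gene set, mirroring how
    pairwise rearrangement counts are computed across genomes with
    slightly different gene rosters.
    """
    if len(orders) < 2:
        raise ValueError("need at least two gene orders")
    ids = [o.genome_id for o in orders]
    if len(ids) != len(set(ids)):
        raise ValueError("genome ids must be unique")
    mat = pd.DataFrame(0, index=ids, columns=ids, dtype=int)
    for i, oa in enumerate(orders):
        for ob in orders[i + 1 :]:
            d = dcj_distance(oa, ob)
            mat.loc[oa.genome_id, ob.genome_id] = d
            mat.loc[ob.genome_id, oa.genome_id] = d
    return mat


def matrix_long_format(mat: pd.DataFrame) -> pd.DataFrame:
    """Long-format pair table (genome_a, genome_b, distance) for plotting."""
    rows = [
        {"genome_a": a, "genome_b": b, "distance": int(mat.loc[a, b])}
        for a in mat.index
        for b in mat.columns
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene-order text format: "id: +a -b c )"  (')' circular, '|' linear)


def parse_gene_order(line: str) -> GeneOrder:
    gid, _, rest = line.partition(":")
    gid = gid.strip()
    if not gid or not rest.strip():
        raise ValueError(f"malformed gene-order line: {line!r}")
    tokens = rest.split()
    topology: Literal["circular", "linear"] = "linear"
    if tokens and tokens[-1] in (")", "|"):
        topology = "circular" if tokens[-1] == ")" else "linear"
        tokens = tokens[:-1]
    genes: list[SignedGene] = []
    for t in tokens:
        if t.startswith("-"):
            genes.append((t[1:], -1))
        elif t.startswith("+"):
            genes.append((t[1:], 1))
        else:
            genes.append((t, 1))
    return GeneOrder(gid, tuple(genes), topology)


def read_gene_orders(path: str | Path) -> list[GeneOrder]:
    orders = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                orders.append(parse_gene_order(line))
    return orders


def write_gene_orders(orders: Iterable[GeneOrder], path: str | Path) -> None:
    with open(path, "w") as fh:
        for o in orders:
            fh.write(str(o) + "\n")
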