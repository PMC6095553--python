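"""Shared test utilities: independent oracles and interval matchers."""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np

from mitocomp.gene_order import GeneOrder


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def point_mutate(seq: str, n_mut: int, rng: np.random.Generator) -> str:
    out = list(seq)
    for p in rng.choice(len(seq), size=n_mut, replace=False):
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def overlap_fraction(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    return inter / max(a[1] - a[0], b[1] - b[0])


def covers(truth: tuple[int, int], hit: tuple[int, int], frac: float = 0.9) -> bool:
    """True when ``hit`` covers at least ``frac`` of the truth interval."""
    inter = max(0, min(truth[1], hit[1]) - max(truth[0], hit[0]))
    return inter / (truth[1] - truth[0]) >= frac


# ---------------------------------------------------------------------------
# independent DCJ oracle: breadth-first search over perfect matchings of
# gene extremities, where one DCJ move replaces two adjacencies {a,b},{c,d}
# by {a,c},{b,d} or {a,d},{b,c}.


def matching_of(order: GeneOrder, gene_index: dict[str, int]) -> tuple[int, ...]:
    """Adjacency perfect matching of a circular signed order.

    Gene g has tail extremity 2g and head 2g+1; the matching maps each
    extremity to the one it abuts.
    """
    genes = order.genes
    n = len(genes)
    m = [0] * (2 * n)
    for i in range(n):
        g1, s1 = genes[i]
        g2, s2 = genes[(i + 1) % n]
        a = 2 * gene_index[g1] + (1 if s1 > 0 else 0)
        b = 2 * gene_index[g2] + (0 if s2 > 0 else 1)
        m[a] = b
        m[b] = a
    return tuple(m)


def bfs_distances_from(start: tuple[int, ...]) -> dict[tuple[int, ...], int]:
    """Minimal DCJ operation counts from ``start`` to every matching."""
    n2 = len(start)
    dist = {start: 0}
    queue = deque([start])
    while queue:
        cur = queue.popleft()
        d = dist[cur]
        adjs = [(i, cur[i]) for i in range(n2) if i < cur[i]]
        for (a, b), (c, e) in combinations(adjs, 2):
            for x, y, z, w in ((a, c, b, e), (a, e, b, c)):
                nxt = list(cur)
                nxt[x], nxt[y] = y, x
                nxt[z], nxt[w] = w, z
                t = tuple(nxt)
                if t not in dist:
                    dist[t] = d + 1
                    queue.append(t)
    return dist


def all_signed_circular_orders(n: int):
    """All distinct circular signed orders of n genes, gene 0 fixed at +."""
    from itertools import permutations, product

    base = list(range(1, n))
    for perm in permutations(base):
        for signs in product((1, -1), repeat=n - 1):
            genes = [("g0", 1)] + [
                (f"g{g}", s) for g, s in zip(perm, signs)
            ]
            yield GeneOrder("x", tuple(genes))


def random_signed_order(n: int, rng: np.random.Generator, gid: str = "r") -> GeneOrder:
    perm = rng.permutation(n)
    genes = tuple(
        (f"g{int(g)}", 1 if rng.random() < 0.5 else -1) for g in perm
    )
    return GeneOrder(gid, genes)
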