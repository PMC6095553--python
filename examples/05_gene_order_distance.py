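"""Pairwise DCJ rearrangement distances between gene orders.

An ancestral 30-gene circular order is diverged by three and four
disjoint inversions; the DCJ distance (N - C over the adjacency graph)
recovers the inversion counts exactly, and the pairwise matrix is the
input one would plot as a rearrangement heatmap.
"""

from mitocomp.gene_order import pairwise_matrix
from mitocomp.synthetic import evolve_by_inversions, random_gene_order

ancestor = random_gene_order(30, seed=1, genome_id="ancestor")
three, _ = evolve_by_inversions(ancestor, 3, seed=2, derived_id="three_inv")
four, _ = evolve_by_inversions(ancestor, 4, seed=3, derived_id="four_inv")

mat = pairwise_matrix([ancestor, three, four])
print(mat.to_string())
print(
    "\nEach entry is the minimal number of double-cut-and-join operations "
    "separating two circular orders; one inversion costs one operation, so "
    "ancestor->three_inv = 3 and ancestor->four_inv = 4."
)
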