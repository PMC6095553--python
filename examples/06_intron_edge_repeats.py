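"""Detect a repeat-mediated deletion in an intron alignment.

One taxon lost a 2 kb block from a 4 kb intron; a 15 bp direct repeat sits
precisely at the deletion edges in the taxa retaining the region — the
fingerprint of homologous recombination between the two repeat copies.
"""

from mitocomp.intron_scan import (
    edge_repeat_search,
    find_deletion_blocks,
    intron_length_table,
)
from mitocomp.synthetic import make_intron_alignment

aln, truth = make_intron_alignment(
    n_taxa=4, intron_len=4_000, deletion_len=2_000, repeat_len=15, edge_offset=0, seed=4
)

print(intron_length_table({"ccmFci829_like": aln}).to_string())

block = find_deletion_blocks(aln, alignment_id="ccmFci829_like")[0]
print(
    f"\ndeletion block: columns {block.col_start + 1}-{block.col_end} "
    f"({block.length} bp) absent from {', '.join(block.affected_taxa)}"
)

hits = edge_repeat_search(aln["taxon_1"], block, window=5)
top = hits[0]
print(
    f"edge repeat: {top.seq} ({top.length} bp), copies at {top.left_pos + 1} and "
    f"{top.right_pos + 1}, offsets {top.offset_left}/{top.offset_right} bp from the edges"
)
print("Offsets of 0 mean the copies touch the deletion edges exactly — "
      "recombination between them removes the intervening sequence.")
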