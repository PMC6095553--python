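# Methods

`mitocomp` re-implements, as one tested library, the comparative analyses
commonly applied to circular plant mitochondrial genomes: dispersed-repeat
detection and classification, repeat-mediated recombination evidence from
long reads, pseudogene-fragment and shared-DNA accounting, gene-order
rearrangement distances, intron-deletion breakpoint analysis, and
synonymous/nonsynonymous substitution rates. This note records the models,
parameter choices and numerical conventions, and what the synthetic test
conditions do and do not demonstrate.

## Local alignment kernel (`mitocomp.seedalign`)

All homology searches run on one seed-and-extend kernel: exhaustive exact
k-mer seeding on both strands followed by gapped x-drop extension with
blastn-like affine scoring (match +2, mismatch −3, gap open 5, gap extend 2,
x-drop 20). The published analyses this package mirrors used blastn with an
E-value cut-off; E-values depend on database size and leave the effective
inclusion rule implicit, so `mitocomp` filters instead by minimum alignment
length and identity — deterministic thresholds that appear verbatim in its
report headers. The scoring values are an assumption (the original blastn
parameterisation is not recorded anywhere we can consult); they are the
NCBI megablast-family defaults and are configurable.

Correctness anchor: `local_align_exact` computes the optimal local alignment
by full dynamic programming (via Bio.Align) under the same scoring, and the
test suite asserts that the best seeded extension attains the optimal score
on planted-homology instances. Identity is defined as matched columns over
alignment columns, computed from an exact edit-distance alignment (edlib) of
the hit interval.

Word sizes are chosen per task, trading exhaustiveness against the quadratic
number of chance seed matches: 12 for genome self-comparison (exhaustive for
any repeat ≥ 100 bp at ≥ 80% identity, and in practice for nearly all
shorter ones), 9 for the pseudogene scan — by pigeonhole, a 28 bp fragment
at 92% identity (≥ 2 substitutions) always retains an exact 9-mer — and 13
for genome-vs-genome sharing. A word size of 7 (as a blastn run would use)
is exhaustive down to shorter, more degenerate matches but is not tractable
for a pure-Python scan at genome scale; the chosen sizes are exhaustive for
every planted regime the test suite asserts on.

Because x-drop extension occasionally appends a chance high-scoring run of
background sequence to a true short homology (diluting its identity), the
pseudogene scan runs at a 10-point relaxed identity floor and then refines
each candidate to its longest alignment window meeting the identity
threshold (`refine_hit_window`) — the programmatic equivalent of curating
blast hits against an identity envelope. The refined window must retain at
least 60% of the raw alignment's columns: trimming boundary junk is
legitimate, but mining a short chance sub-window out of an alignment that
is uniformly below threshold is not (observed boundary trims keep 69–87%
of the alignment; a qualifying sub-window of a genuinely low-identity
fragment keeps ~20%).

## Repeat detection and classification (`mitocomp.repeat_finder`)

A genome is compared against itself; the trivial full-diagonal self-match
and identical-interval hits are dropped, (A,B)/(B,A) duplicates are
canonicalised, and nested or overlapping hits with distinct coordinates are
all retained, since each distinct coordinate pair is a distinct repeat
relationship. Circularity is handled by scanning the doubled sequence and
reducing coordinates modulo the genome length; the repeat set is invariant
under rotation of the origin (property-tested).

Orientation: copies on the same strand are direct repeats (DR), opposite
strands inverted repeats (IR). Size tiers: small [20, 100), medium
[100, 1000), large ≥ 1000 bp — 1000 bp itself is "large" because that bound
is stated as an explicit inequality, while the medium range is not. Total
repeat content counts every genomic position under any repeat copy once
(union of both copies); a one-copy accounting is available as an option
because the published totals do not state which convention they used.

The package ships the published 21-pair repeat table of the
*Sophora japonica* 'JinhuaiJ2' mitogenome (GenBank MG757109) as a worked
example; re-deriving each row's orientation from the printed coordinate
directions reproduces the printed DR/IR column exactly, and the size tiers
give 20 medium + 1 large (2,160 bp). One shipped row (Ru, 79.86% identity)
sits below the nominal "identity > 80" filter of the original table — the
original's effective filter is evidently looser; `mitocomp` keeps its own
threshold configurable and defaults to ≥ 0.80.

## Long-read recombination evidence (`mitocomp.recomb`)

A read spanning a full repeat copy plus flanking sequence on both sides ties
its two flanks to one genomic context. Flanks are aligned against the
corresponding neighbourhoods of both copies (for an inverted repeat the
second copy's neighbourhood is reverse-complemented into the first copy's
frame); a flank is assigned to the higher-identity context only when the
identity margin exceeds 2% (`max_flank_mismatch`), else it is ambiguous.
Same copy on both sides ⇒ parental; different copies ⇒ recombined; any
ambiguity ⇒ uninformative. The summary statistic is recombined/spanning
with a Wilson 95% interval. Defaults — 500 bp minimum flank, 2% margin —
are this package's choices; the source analyses do not state theirs.
Read placement uses exact semi-global (infix) alignment (edlib), which is
deterministic and robust to the ~1% residual error of corrected long reads
(property-tested: calls are unchanged at 1% uniform error).

## Pseudogene fragments, sharing, anonymous content (`mitocomp.homology_scan`)

Pseudogene fragments are local alignments of functional gene sequences into
intergenic space (wholly outside annotated genes, exons, introns, tRNAs and
rRNAs), merged per source gene, with defaults 28 bp / 92% — the envelope of
fragment sizes and identities reported for mitogenome spacers. Association
with repeats defaults to containment ("located in" a repeat copy), with an
overlap mode available.

Shared mtDNA between two genomes is the interval union of qualifying hits
projected onto each genome (defaults min_len 100 bp, identity 0.70). The
published analyses used Mauve locally-collinear blocks; interval-union hit
coverage is a deterministic, dependency-free approximation whose thresholds
are recorded in the output header. Raising either threshold can only shrink
the union (property-tested). Anonymous content is total length minus the
union of known intervals; known + anonymous = L is asserted as an invariant.

## Gene orders and DCJ distance (`mitocomp.gene_order`)

Gene orders are signed circular sequences extracted from annotations (sign =
strand, genes sorted by start). Fragments of trans-spliced genes collapse to
one marker at the lowest-coordinate fragment; any other duplicated symbol is
dropped from both orders before comparison (policy `drop-all`, configurable
to `first`), because the distance model assumes single-copy content.

For two circular single-chromosome genomes over a shared gene set of size N,
the double-cut-and-join (DCJ) distance is N − C, where C counts the cycles
of the adjacency graph. Rotation and whole-circle reflection leave the
adjacency set unchanged, so the distance is 0 exactly for orders equal up to
those symmetries, and one segmental inversion costs one operation. The
implementation is validated against an independent breadth-first search over
the space of extremity perfect matchings: exhaustively for every signed
circular order of ≤ 6 genes and on 500 sampled orders each for 7 and 8 genes
(the n = 8 sweep, over 2,027,025 matchings, runs in the acceptance script;
the test suite runs n ≤ 7). Whether published pairwise rearrangement counts
for real mitogenomes were computed under DCJ or another model is not
recorded, so real-genome counts are not asserted anywhere.

## Intron deletions and edge repeats (`mitocomp.intron_scan`)

Deletion blocks are maximal per-taxon gap runs in an intron alignment,
computed after discarding all-gap columns (making the result invariant to
their presence), merged across interruptions shorter than `merge_gap`
(default 10 columns) and reported when at least `min_del` (default 50) bp of
sequence retained by some other taxon is missing. A gap shared by all taxa
is not a deletion — no reference retains sequence.

The repeat-mediated-deletion signature is a short direct repeat with one
copy at each edge of the block in the retained sequence. "At the edge" is
operationalised as interval-to-edge distance ≤ `window` (default 5 bp,
settable to 0 for a strict reading); measuring distance from the copy
*interval* (zero when the copy touches or straddles the edge) makes the call
independent of which copy the deleted lineage's surviving copy was aligned
to — the two alignment anchorings of a collapsed repeat shift the block by
one repeat length. Defaults `min_rep` 10 bp and 0 mismatches reflect the
13–15 bp exact repeats observed at real intron deletions; inverted-edge
search exists behind a flag but is off by default since the documented
deletion-edge repeats are all direct.

## Substitution rates (`mitocomp.rates`)

dS and dN are estimated by Nei–Gojobori (1986) counting — explicitly a
desk-scale estimator standing in for maximum-likelihood codon-model fitting
(MG94×HKY85), which is out of scope. Sites: each codon position contributes
syn/viable synonymous sites, where `viable` counts non-stop single-nucleotide
neighbours; every sense codon then has exactly S + N = 3 (exhaustively
asserted). Differences: averaged over all substitution orderings between the
two codons that avoid stop codons, with equal weights. Proportions are
Jukes–Cantor corrected (d = −3/4 ln(1 − 4p/3)); p ≥ 3/4 is flagged
saturated. Absolute rates divide a divergence by the branch or split age:
R = d / (T_Myr / 1000), per site per billion years — ages are user inputs
(no dating is performed).

The codon simulator used for validation evolves each codon by a
continuous-time process whose per-position rate is split over viable
neighbours and slowed by ω for nonsynonymous changes; under this
convention the nominal dS is exactly the expected synonymous divergence per
NG86 site at small times (a naive per-neighbour parameterisation
under-delivers divergence at stop-adjacent codons by up to 3×, which would
masquerade as estimator bias). Recovery: mean dS and dN over three
10,000-codon replicates land within 10% of nominal across
dS ∈ {0.05, 0.2, 0.5} × ω ∈ {0.1, 0.5}; mean dS bias is within 5% for
dS ≤ 0.2 (20 replicates, 5,000 codons). At dS = 0.5 the residual few-percent
dN overestimate is the classic NG86 equal-weight pathway bias; single
replicates of dN ≈ 0.05 also carry ~5% sampling noise, which is why the
recovery condition is stated on replicate means.

## Synthetic genomes (`mitocomp.synthetic`)

The generator emulates the statistical structure the detectors see, with
exact truth bookkeeping: i.i.d. background at a requested GC (45.4% by
default, the measured value for large Faboideae mitogenomes), a gene roster
with a couple of intron-bearing genes, planted repeat pairs (default
profile: one 2,160 bp DR plus twenty medium repeats — the repeat complement
of a repeat-poor Faboideae mitogenome), 25 pseudogene fragments spanning
28–182 bp at 92–100% identity, intron alignments with central deletions and
planted edge repeats, reads at ~14 kb / 15× (scalable), and codon pairs as
above. The default 100 kb scale (vs ~485 kb for the real genome) keeps a
full analysis under ten seconds; the structure, not the length, is what the
detectors consume, and a real-genome-scale blueprint is one constructor
argument away.

Deliberate conventions: substitutions planted to a target identity avoid the
terminal 2 bp of a feature, because the feature being emulated is a maximal
local alignment and such alignments end on matches — a terminal mismatch
would merely redefine the feature as shorter; the mutation count is floored
so realized identity never leaves the requested envelope. The read simulator
applies recombination at both copy junctions (a read spanning either copy of
the pair is a spanning read) and draws layout and sequencing errors from
separate RNG streams, so changing the error rate does not change which
molecules are sampled.

What the generator does **not** model: higher-order base composition,
tandem/microsatellite structure, indel sequencing errors, chimeric artefacts
other than the planted recombinants, transfer RNA structure, or realistic
organellar mutation spectra. Passing the planted-signal suites therefore
demonstrates algorithmic correctness under the stated signal definitions —
exact recovery thresholds on real genomes will additionally depend on those
unmodelled features.

## Orchestration and reporting conventions

Internally all coordinates are 0-based half-open; every emitted table is
1-based inclusive, with the second copy of an inverted repeat printed with
descending coordinates (the aligner convention readers of such tables
expect). Percentages are rounded to one decimal, half-up. Every stage report
carries `#`-prefixed header lines with the tool version and effective
parameters; a rerun of the same configuration is byte-identical. Stage
gating: with an explicit stage list a missing input fails fast (exit 2,
unsatisfiable synthetic blueprints exit 3); without one, feasible stages run
and the rest are logged as skipped.

`scripts/acceptance.py --seed S --out F` regenerates every synthetic
condition from S and recomputes: the reference-genome composition
percentages from its published summary lengths, the repeat-table
classification, DCJ/BFS agreement (n ≤ 6 exhaustive, 500 samples each at
n = 7, 8), planted repeat/pseudogene/edge-repeat recovery, the recombined
read fraction against a planted 1/3, shared-fraction error against the
insertion closed form, and the NG86 recovery errors. Runtime ≈ 3 minutes on
one CPU, dominated by the n = 8 BFS oracle.
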