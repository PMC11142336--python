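# Methods

## Scope and data model

`grapepan` implements the downstream, desk-scale computations of a
population comparative-genomics study of gene gain and loss: everything
after assembly, annotation, SV discovery, domain scanning and graph
construction. Upstream products are consumed as plain formats — GFF3 gene
models, VCF SV calls (SVTYPE/SVLEN/GT), an OrthoFinder-style orthogroup TSV,
a domain/motif hit TSV, trunk/bubble gene labels, and an accession →
population map. All intervals are converted to 0-based half-open
coordinates at the I/O boundary and kept that way internally; insertions are
stored as 1-bp breakpoints, optionally carrying the inserted sequence's span
on the assembly when the caller annotated it. Haplotype-resolved assemblies
are modelled as two accessions sharing a parent ID so haplotype comparisons
reuse the ordinary presence/absence machinery.

## Pan-genome matrix and frequency classes

Presence means ≥ 1 annotated member; multiplicity matters only for gene
totals and the gain/loss tests. For an *N*-accession matrix the default
core threshold is presence in more than *N*−2 accessions (≥ *N*−1, i.e. 16
of 17), cloud is presence in exactly one, shell everything between; in the
degenerate overlap (single-accession matrices) the cloud rule wins.
Saturation curves average pan(k) and core(k) over seeded random accession
orderings (default 1,000 permutations; exhaustive enumeration is available
and used in tests at N = 5). Printed-percentage arithmetic uses half-up
rounding at 2 (or 1) decimals, the rule that reproduces conventionally
printed percentages from printed counts; note that half-up cannot reproduce
a truncated figure, and one of the six published percentages we recompute
(20,303/38,485 = 52.7556% → 52.76) appears to have been truncated in print.

## Gain/loss testing

Member counts are small, heavily tied integers, so the exact mode of the
Mann–Whitney test is permutation-exact: it enumerates all C(n₁+n₂, n₁)
assignments of the observed pooled values and reports the two-sided tail of
|U − n₁n₂/2|. This is valid under ties, handles the singleton outgroup
contrast (1 vs 16 → 17 assignments), and is cheap at study-design sizes
(C(14,9) = 2,002). The normal mode delegates to scipy's tie-corrected
asymptotic test with continuity correction; `auto` uses exact while the
enumeration is ≤ C(16,8) and normal beyond. Loss ("missed all members") is
resolved before testing; zero-vs-zero families are `ns`. Direction is the
side with the larger mean midrank; significance is two-sided p < α with
post-hoc direction, matching the two-sided language of the original
analysis; one-sided alternatives are available. The published-analysis parity flag uses
raw p < 0.05 across all families with no multiple-testing correction; a
Benjamini–Hochberg column is always emitted alongside so reuse does not
inherit that choice silently.

Enrichment of a study gene set is the upper hypergeometric tail per term
(equivalent to one-sided Fisher; property-tested against it), with the same
raw-p flag plus a BH column.

## Ka/Ks (NG86)

The estimator is Nei–Gojobori (1986) with Jukes–Cantor correction, the
canonical fully specified baseline: per-codon synonymous site fractions
(changes to stop codons count as nonsynonymous), site totals averaged over
the two sequences, differences resolved by averaging over all shortest
mutational pathways with equal weights, pathways through stop codons
excluded unless all are. p ≥ 3/4 makes the correction undefined; undefined
values and ratios (Ks = 0) are reported as `None`, never as 0 or ∞. The
implementation is cross-checked in the test suite against Biopython's
independent NG86 (`cal_dn_ds`) on randomly mutated pairs, including the
single-difference reference pair AAA→AGA, whose correct value under site
averaging is Ka = 0.5716 (S = (1/3 + 2/3)/2).

## Hemizygosity

"Surrounded by a heterozygous insertion/deletion" is interpreted as full
containment of the gene interval in one het deletion's span (or the
annotated inserted interval of a het insertion; breakpoint-only insertions
never qualify). Containment is the conservative reading — hemizygosity
requires the whole gene on one haplotype — and is the default; an
any-overlap mode exists for sensitivity analysis. Length filtering keeps
50 bp–1 Mb inclusive (the dropped sets are *shorter than* 50 bp and *longer
than* 1 Mb). The read-support floor defaults to 5 (the SV caller's
convention; the original threshold is unstated). Population summaries are
unweighted means of per-accession proportions, excluding accessions without
SV data.

## NLR toolkit

Candidacy requires NB-ARC, TIR or RPW8; class assignment follows a fixed
first-match table with N-terminal precedence TIR > RPW8 > CC. CC and LRR
evidence is accepted from any predictor as boolean rows (`CC`, `COILS`,
`LRR`, or common LRR Pfam models) since no specific source is prescribed.
The conserved-motif filter counts *distinct* class-specific motif IDs
(≥ 5 to pass), reading "five conserved domains" as five distinct regions.
Pairing counts only non-NLR genes as intervening (default ≤ 1, "fewer than
two"); intervening NLRs form their own pairs. Clusters are connected
components of the pairing graph with ≥ 4 members ("more than three"), with
3 available by configuration. ADC divides bubble-resident NLR genes by the
number of accessions in the graph; the published bubble fraction and
ADC-implied bubble counts disagree slightly in the source material, so both
statistics are always reported from the module's own inputs without
reconciliation.

## Markov clustering

The in-house MCL is the dense textbook algorithm: self-loops at the maximum
incident weight (≥ 1), column-stochastic normalisation, expansion by
squaring, inflation by element-wise power (default 1.5, the orthogroup
tool's default) with re-normalisation, pruning below 1e-8, iterated to a
1e-6 sup-norm fixed point (cap 100 iterations, warning on non-convergence).
Clusters are read from attractor systems; nodes attracted by several
systems go to the one holding more of their column mass, ties to the
lexicographically smallest attractor. Intended for desk-scale graphs
(≤ ~10⁴ nodes, cubic cost); at cohort scale the pipeline consumes a
precomputed orthogroup table instead, and the analysis drivers demonstrate
that MCL recovers the same partition on a cohort slice. Correctness is
checked against planted, provable structure — disconnected components can
never merge, weakly bridged cliques must split — rather than against
another MCL implementation, since those properties pin the answer down
exactly on the test graphs.

## Synthetic cohort

The generator emulates the 17-accession study design (1 outgroup, 5 wild,
9 cultivars, 2 relatives) on 19 chromosomes. Family member counts where
present are zero-truncated Poisson(λ = 1.2), which produces the tie-heavy
counts the exact test must cope with. Core families are planted in all
accessions, cloud in exactly one (rotating), shell in 2..N−2 random
accessions. Gained families put 1 + `gained_effect` members in every
cultivar against a baseline of 1 elsewhere (deterministic, so recovery is a
property of the test, not the draw); lost families have members in all wild
accessions and none elsewhere. Genes (1–4 kb) are placed uniformly without
overlap with 2–8 kb gaps. Planted hemizygous genes get a containing het
deletion padded to stay clear of neighbouring genes; decoy SVs exercise
every rejection path (30 bp deletions, partial overlaps, homozygous and
low-support containments, breakpoint insertions) and are constructed never
to contain a gene heterozygously, so planted truth is recovered *exactly* —
a generation-time assertion enforces this. NLRs are planted with
class-matching domain rows and 5 distinct motifs (decoys get 3), spaced ≥ 4
gene ranks from other NLR entities so planted physical clusters are the
only pairing components. Trunk/bubble labels follow family class (core →
trunk, cloud → bubble, shell → bubble with probability 0.5). Codon pairs
per frequency class carry (syn, nonsyn) mutation loads of (6,1), (4,3),
(1,8) so the cloud-vs-core Ka/Ks contrast is recoverable.

What the generator does **not** emulate: nucleotide-level realism (no
sequences beyond the codon pairs), TE content, assembly and annotation
error, linked SVs, or population phylogenetic structure. Passing tests
therefore demonstrate correctness of the downstream rules and statistics on
well-formed inputs, not robustness to upstream noise — and the cohort-scale
headline numbers of the original study (50,750 families, 5,420 NLRs,
16.56%/15.49% hemizygosity, ADC 284.8/162) depend on the real assemblies
and are reproduced only at the level of their printed-count arithmetic.

## Problem sizes and numerics

Default analysis/test sizes: 1,000 families (~16,600 genes) for the cohort
drivers and recovery checks, 300–400 families for fixture cohorts, 10,000
replicates for the type-I error measurement, 1,000 permutations for
saturation (exhaustive at N = 5 in tests). These sizes make every driver
and the full test suite run in seconds while keeping planted effects at the
study's population sizes (9 vs 5). Determinism: every random draw flows
from one seeded NumPy generator; pipeline reruns with the same config are
byte-identical, which the tests assert. Tie-breaks are lexicographic
throughout (gene IDs in ranks and cluster IDs, attractor choice in MCL) so
outputs are order-independent.
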