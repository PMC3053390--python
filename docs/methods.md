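# Methods

This note documents the models, estimators and design choices behind the
package, and what the simulation-based tests do and do not establish.

## The simulated study system

`simulate.EvolutionParams` defines the conditions of the simulated
two-lineage comparison. Defaults describe a gene-dense rice region and are
chosen once, on the scale of the real system the package analyses:

| parameter | default | rationale |
|---|---|---|
| `region_length` / `gene_count` | 600 kb / 100 | one gene per 6 kb, the density of gene-rich rice euchromatin; 600 kb keeps a full analysis in minutes on one CPU |
| `mean_cds_length` | 900 bp (≈300 codons) | typical plant CDS |
| `exons_per_gene` | 1–5 | typical rice gene structure |
| `branch_sub_rate` | 0.0175 proposals/site/branch | two branches give pairwise synonymous divergence ≈ 0.035, the scale seen between recently diverged rice species |
| default ω mix | 85% at 0.12, 9% at 0.7, 6% at 1.3 | a mostly purifying spectrum with a few neutral and relaxed genes; yields mean Ka ≈ 0.008 at the default rate |
| `te_insertions_per_branch` | 12 (≈50 kb) | ≈9–13% lineage-specific TE content per branch; accepts an `(A, B)` pair for asymmetric loads |
| `te_nesting_prob` | 0.1 | occasional nested elements |
| `pack_mule_captures_per_branch` | 3 | pack-MULEs carrying frameshifted gene fragments are the dominant source of "extra" genes |
| `inversion_spec` | none (45 kb in the study defaults) | one paracentric inversion seeded by an ancestral inverted duplication |
| `bac_length` / `bes_read_length` | 130 ± 10 kb / 500 bp | finished BAC clones and Sanger end reads |
| `te_deletions_per_branch` | 0 | deletion rates are not separately quantifiable from a two-way comparison; exposed but off |

**Substitution engine.** Mutations are proposed per CDS position at the
branch rate; proposals creating stop codons are always rejected;
synonymous proposals are accepted with probability 1 and nonsynonymous
ones with probability ω (for ω > 1 the synonymous acceptance is thinned to
1/ω instead). Because proposals are uniform over positions, the expected
accepted nonsynonymous/synonymous ratio matches ω on the same site scale
that NG86 counts, giving direct parameter recovery without full
codon-model machinery. Multiple hits in one codon are applied
sequentially against the current codon.

**Ectopic inversion.** The operator models non-allelic homologous
recombination between two near-identical genes on opposite strands: the
crossover is placed at the homologous midpoint of the two gene bodies, the
open interval between the crossover points is reverse-complemented,
internal features are re-coordinated and strand-flipped, and the flank
genes remain intact while exchanging upstream regions. Total length is
conserved and the operation is an involution. In `evolve_lineages` the
flank duplication is applied to the shared ancestor (both lineages carry
the duplicated family) and the inversion to lineage A only, mirroring a
rearrangement fixed in one species.

**Seeds.** One master seed spawns named substreams (ancestor, shared
ancestral events, lineage A, lineage B, BES libraries), recorded in the
TruthSet; identical parameters and seed reproduce every output
byte-for-byte. Truth spans are resolved against final descendant
coordinates, so breakpoints and insertion spans are exact.

**What the simulator does not emulate:** sequencing error, assembly gaps,
annotation error, indels inside CDS (beyond pack-MULE frameshifts),
segmental deletions, and population-level processes. Tests passing on
simulated data therefore demonstrate the correctness of the estimators and
detectors under clean annotations, not robustness to annotation noise.

## Divergence estimation

NG86 counting with equal-weight pathway averaging: per-codon synonymous
site fractions exclude changes to stops from the denominator; sites are
averaged between the two sequences, so N + S = 3 × aligned codons exactly.
Multi-difference codons average over all substitution orderings, skipping
orderings that pass through a stop (all orderings are used if every one is
blocked). Codon pairs with gaps, ambiguity codes or stop codons are
excluded whole. Alignment is at the protein level (global,
BLOSUM62, gap open −10, extend −0.5) and back-threaded to codons; ortholog
pairs with clearly different annotated structure (unequal exon counts) are
excluded upstream, as are pseudogenes. Jukes–Cantor is undefined at
p ≥ 3/4 and such rates are flagged and excluded from means.

Set-level ω uses pooled counts (`pooled_omega`): per-gene ratios are
biased upward at low divergence because the synonymous denominator is
noisy (a Jensen-inequality effect measurable in the recovery study), while
the pooled estimator recovers ω ∈ {0.05, 0.5, 1.0} within 2 SE over
50 genes × 20 replicates.

Region summaries use arithmetic means over defined rates and flag a pair
when Ka or Ks is at least `factor` (default 2.0) times the respective
mean. Selection classes default to ω < 0.5 purifying, 0.5–1.0 neutral,
> 1.0 positive-or-relaxed; the bands are configurable because they are
interpretive conventions, not estimands. Ks = 0 (or an undefined rate)
makes ω undefined. Between-region comparisons use the tie-corrected
Kruskal–Wallis test (scipy) with the all-identical edge case defined as
H = 0, p = 1.

## Collinearity

CDS similarity uses local alignment (match +1, mismatch −2, gap open −5,
extend −2); identity is gap-excluded, coverage is relative to the shorter
CDS. Pairs below a 60% identity / 0.3 coverage reporting floor are
omitted, and a shared 12-mer prefilter skips alignments of unrelated pairs
(unrelated ~1 kb rice CDS share essentially no exact 12-mers; pairs near
the reporting floor still share several). TE-enclosed gene copies are
excluded from the matrix, following the practice of comparing only non-TE
coding genes.

Orthologs are reciprocal best hits; score ties break by coverage, then by
smaller positional distance, and an unresolved tie leaves the gene
unpaired rather than guessing. The conserved-order fraction counts
ortholog pairs in the longest strictly increasing subsequence of partner
ranks whose strands also agree. Families are single-linkage clusters at
≥ 70% identity and ≥ 0.5 coverage; a family is a tandem cluster when every
adjacent member pair has at most 10 intervening non-member genes
(calibrated so that a two-member family ~30 genes apart reads dispersed
while a clustered seven-member family reads tandem).

## Structural comparison

Dot plots report exact shared k-mers (default k = 16) on both strands,
dropping k-mers occurring more than 50 times on either sequence. Chaining
is three-stage: same-diagonal runs split at gaps > g (default 2 kb);
same-strand merge across diagonal shifts ≤ 10 g; and an order-consistent
join across TE-scale indels (default 20 kb). Blocks require dense support
(≥ 1 match per 100 bp) and blocks lying ≥ 80% inside an annotated TE on
either sequence are masked before clustering — mobile elements (notably
captured gene fragments in pack-MULEs) produce matches that are not
positional homology. Reverse-strand clusters become inversion calls when
they span ≥ `min_block` (default 5 kb) on the reference, cover comparable
extents on both sequences (within twice the join gap) with ≥ 50% member
coverage on each — scattered duplicate-gene artifacts fail these — and
breakpoints are reported as intervals because the exact points are
unknowable when they fall inside duplicated genes. A call is annotated
with a duplicated family when members overlap both breakpoint intervals
(widened inward by k+g, the positional uncertainty of a block edge).

TE attribution projects each element through its bracketing ortholog
anchors (gene midpoints) into the other region; an element with no
same-class element overlapping the projected interval is
lineage-specific. At least two anchors are required.

## BES inversion genotyping

Reads are placed by banded edit-distance alignment (edlib, infix mode) on
both strands at ≥ 90% identity over ≥ 100 bp; a placement is rejected as
ambiguous when a second location scores within 5% of the best (probed by
masking the best hit), so repeat-derived ends never vote. A pair spans a
breakpoint when exactly one end lies inside the inversion span and the
mapped span is under 300 kb (a plausibility bound on clone length).
Spanning pairs with ends in opposite orientation are reference-like;
identical orientation means the inverted arrangement. Species verdicts
are majority votes; ties are reported ambiguous, never resolved silently.

## Assembly

Finished clones are ordered by exact suffix–prefix overlaps of at least
2 kb (Sanger-finished sequence has error rates far below one per 10 kb, so
exact matching suffices); N matches nothing; the longest overlap wins and
equal-best successors are a hard error listing the alternatives, as is a
disconnected or cyclic overlap graph (components are listed). The contig
length always equals the summed clone lengths minus merged overlaps.

## Reporting conventions

Coordinates are 1-based inclusive (GFF3) everywhere; BED companions are
0-based half-open and labelled as such. Kilobase values are printed both
as floor-kb and exact bp because published summaries mix conventions (a
5,685 bp/gene density reads "one gene per 6 kb" under nearest-kb rounding
but "5 kb" under floor). The consolidated report regenerates entirely
from stored stage outputs, and every output directory receives the exact
configuration used.

## Problem sizes

The default analysis runs a 600 kb / 100-gene pair; the test suite uses
120–300 kb regions and 20–50 genes, and the recovery studies use 50 genes
× 20 replicates per ω regime — sizes at which every stage's statistical
behaviour is already stable while a full run stays in the minutes range
on a single CPU.

## Known limitations

Assembly handles finished, unidirectional clones only (no
reverse-complemented clones, no scaffolding across gaps). The dot-plot
detector reports measured inversion extents per sequence, which include
elements inserted after the rearrangement, so sizes legitimately differ
between the two sequences and from the ancestral extent. Nested
inversions are reported as their observable strand-alternating segments
rather than reconstructed as a hierarchy. BES genotyping assumes clone
ends are correctly paired and the clone has no internal rearrangement.
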