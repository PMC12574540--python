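# Methods

This note documents the models and procedures implemented in `panfam`,
the defaults and why they were chosen, what the synthetic pangenome does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Family identification

The scanner is a gapless position-specific score matrix (PSSM), not a
profile HMM: no insert/delete states, no forward algorithm, no E-value
calibration. A profile is built from a seed alignment of the conserved
domain; columns with more than 50% gaps are dropped (the trimming step),
and each remaining column scores residue *a* as
log₂((cₐ + λ·bₐ)/(n + λ)/bₐ) with count cₐ over the n non-gap residues,
pseudocount weight λ (default 1) and background frequency bₐ (default
uniform 1/20, overridable). A sequence's score is the best gapless
placement of the profile along it; windows running off either end are
allowed, with unmatched columns scoring 0 bits.

The iterative scan mirrors the species-specific-profile strategy: scan
with the seed profile, realign hits at or above the *confident* threshold
(default 25 bits) by anchoring each at its best window (gapless — a
documented simplification that avoids re-implementing a multiple
aligner), rebuild the profile, rescan, and finally report everything at
or above the *inclusion* threshold (default 15 bits). Thresholds are bit
scores because without E-value machinery a gathering-threshold semantics
cannot be reproduced; a `read_domtblout` adapter ingests scores from an
external HMMER run for users who prefer it, and an optional keep-list
filter stands in for external domain validation. On the simulator's
proteomes (domain conserved at ~85–90% identity over 60 columns) the two
thresholds separate family from background by >150 bits, so the defaults
are not delicate.

Subfamily labels come from best global-alignment identity (BLOSUM62,
gap open −11/extend −1, identity = identities / alignment columns)
against a labelled reference set; queries below `min_identity` (default
0.4) are called "species-specific". Ties break to the lexicographically
first label and are logged.

## Orthogroups and presence/absence

Orthogroups are connected components of the similarity graph restricted
to edges with E ≤ 1e−20 and bit score ≥ `min_bitscore`; singletons form
singleton OGGs, and ids follow the OG%07d convention ordered by
decreasing size then smallest member id. This is a deliberate, auditable
stand-in for full orthology inference (no MCL inflation, no gene-tree
splitting) — on data where intra-group similarity dominates inter-group
similarity it is exact, which the simulator's truth-recovery tests
verify.

Presence means ≥ 1 member gene in the genome (copy number is ignored for
PAV). With N genomes the categories partition presence counts as
core = N, softcore = exactly N−1, dispensable = 2..N−2, private = 1.
The softcore/dispensable boundary is made exclusive at N−1 so that the
four categories partition every OGG.

Group frequencies are integer percentages rounded half-up; gene-share
percentages are reported to two decimals, also half-up (computed through
exact `Fraction`/`Decimal` arithmetic, never binary floats). A
trajectory across ≥ 3 ordered groups is *rising* when non-decreasing,
not constant, and its total change is at least `min_delta` (default 10
percentage points — a parameter because no published criterion exists);
*falling* is symmetric.

## Tandem arrays

After isoform filtering (one model per locus: longest CDS, ties to the
smallest gene id), similar gene pairs (E ≤ 1e−20) on the same chromosome
are clustered by single linkage on gene-rank distance with cutoff
`max_rank_gap` (default 5). Rank distance rather than base-pair distance
makes an array a contiguous run of genes regardless of intergenic
spans; a bp mode (`distance="bp"`, default cutoff 100 kb) is available.
Single linkage with a hard cutoff equals the transitive closure of
near-adjacent similar pairs, which is exactly the tandem-array notion;
strand is not restricted. Clusters of size ≥ 2 become arrays, members
ordered by rank, and arrays are disjoint by construction.

## Collinear blocks and copy retention

Anchors are similarity hits (E ≤ *e*, default 1e−20) between two
genomes. Per chromosome pair, each anchor is placed at its *anchor
ordinal* — its gene's position among anchor-participating genes on that
chromosome. A chain must advance 1..*u*+1 ordinals on both genomes
(*u* = 1 by default), strictly increasing on genome A and monotone on
genome B in either orientation; maximal chains are extracted greedily
(longest first, deterministic lexicographic tie-breaks, anchors removed
once used) and chains shorter than *s* (default 5) are discarded.
Measuring gaps in skipped *anchors* rather than raw gene ranks makes
chains robust to fractionation: a lost ortholog leaves no anchor and
therefore no gap, which matches how collinearity survives heavy gene
loss after polyploidy. The dynamic-programming chainer is verified
against exhaustive chain enumeration on instances up to 20 anchors.
E-values are taken from the input hit table, not recomputed.

Copy retention of an outgroup gene is the number of distinct target
block regions in which it anchors; blocks on one target chromosome whose
target gene sets overlap are merged first so fragmented chains cannot
double-count. Genes absent from all blocks score 0. Duplication origin
per gene: *TD* if in any tandem array, *WGT* if anchored in a block
whose outgroup partner retains ≥ 2 copies, *both*/*none* accordingly.

## Ka/Ks (Nei–Gojobori 1986)

Pairwise protein alignments are back-translated onto their CDSs (one
codon per residue, one codon gap per protein gap; terminal stop codons
trimmed; any codon/residue disagreement is an input error naming the
gene and column). Per ungapped codon column the synonymous site count of
each codon is Σ over positions of (synonymous non-stop changes)/(non-stop
changes) — the stop-excluding convention — averaged over the two
sequences, with N = 3·columns − S by construction. Differences are
averaged over all minimal substitution pathways avoiding stop codons;
when every pathway passes through a stop the non-stop steps are counted
and a warning logged. Ambiguous (N-containing) columns are void.
Proportions are Jukes–Cantor corrected; p ≥ 3/4 yields an undefined
rate, and Ks = 0 yields an undefined ratio — reported as such, never
forced into the positive class. Classification uses strict inequalities
to tolerance `tol` (default 1e−9). This counting estimator replaces
likelihood methods (codeml/yn00) deliberately: the studies it supports
report ratio summaries, for which NG86 is the standard counting analog;
numeric parity with ML estimates is not claimed. An AXT reader ingests
externally aligned pairs.

Stratified summaries report mean, median and n of defined ratios per
(population group × retention class) cell, with undefined pairs counted
separately; empty cells appear with n = 0 and a blank mean.

## Phylogeny

Neighbor joining follows Saitou–Nei with Studier–Keppler updates, ties
on the Q criterion broken by smallest label pair, and negative branch
lengths clamped to zero with the deficit moved to the sister branch so
path lengths are preserved. On additive matrices recovery is exact
(tested over 100 random 6-taxon trees). Trees are scikit-bio `TreeNode`
objects; Newick round-trips preserve topology and lengths to 1e−9.
Maximum-likelihood inference is out of scope — externally computed
Newick trees can be loaded and annotated. Clade summaries report, per
subfamily, the smallest clade containing all members and the monophyly
fraction; the tree should be sensibly rooted first (e.g.
`root_at_midpoint`), since on an unrooted tree the subfamily spanning
the arbitrary root dilutes its own clade.

## Expression

FPKM matrices are transformed as log₂(1 + x). Gene-gene distance is
1 − Spearman ρ with mid-ranked ties (so the dendrogram is invariant to
the transform); constant genes get distance 1 with a warning.
Agglomeration is complete linkage; genes are sorted by id first so leaf
order is deterministic. Replicates are averaged per (tissue, stage)
condition before clustering by default (per-sample mode available).
Dosage summaries report per-tissue means of each copy-set member and of
the member sum, flag the summed peak tissue, and attach a τ
tissue-specificity score (threshold 0.85 for the qualitative call).

## The synthetic pangenome

Defaults define the study conditions: 10 genomes in four ordered groups
(3 WDR / 2 SP / 2 SLC / 3 SLL), 50 base OGGs mixed 50% core / 20%
softcore / 20% dispensable / 10% private, 3 chromosomes, tandem arrays
of sizes 3/2/4 at rank spacings 1/1/2, an outgroup of 60 genes of which
60% were triplicated with retention probabilities (0.2, 0.3, 0.5) for
3/2/1 surviving copies, per-stratum Ka/Ks targets (0.1, 0.3, 0.6) for
1/2/3 retained copies, and a substitution density of 50 per kb.

Family structure is hierarchical: one 60-residue conserved domain;
subfamily ancestors diverge 15% from it (plus unique flanks); OGG
ancestors diverge 10% from their subfamily ancestor; per-genome copies
diverge 2%; tandem copies 1%. Intergenic gaps are geometric (mean ≈ 350
bp after a 50 bp floor). Every 20th locus emits a second, shorter mRNA
to exercise the isoform filter. Private OGGs go to one uniformly chosen
genome; dispensable presence counts are uniform on 2..N−2. Retained
triplication copies of each outgroup gene sit on up to three subgenome
chromosomes of the first genome, preserving ancestral order; their CDSs
are evolved by stop-avoiding point substitutions whose
synonymous/nonsynonymous split targets the stratum's Ka/Ks
(nonsynonymous with probability r·N/(S + r·N) from the sequence's NG86
site counts — the acceptance-style Monte-Carlo check at target 0.2
lands within ±0.03 in the mean). Expression archetypes cycle through
ubiquitous-high, tissue-specific, stage-ramp and silent with
multiplicative 2^N(0, 0.2) noise.

The similarity graph is idealised: strong intra-OGG edges (E = 1e−100),
weak same-subfamily edges (E = 1e−5, below any default cutoff), ideal
outgroup anchors (E = 1e−120). Real BLAST tables carry noisy scores,
partial-domain hits, and paralog cross-hits; passing truth-recovery here
therefore shows the graph algorithms are correct under clean separation,
not that any E-value cutoff is optimal for real data. Likewise the
simulator does not model chromosome-scale realism (sizes, GC, codon
bias, introns, inversions within subgenomes), so inverted-orientation
chaining is exercised by synthetic permutations in tests rather than by
the pangenome.

Known numerical caveats. (1) The Ka/Ks of an evolved pair is a ratio of
small counts; by Jensen's inequality the mean of per-pair ratios sits
above the target, noticeably so for the high-target strata (simulated
target 0.6 yields stratum means near 0.8 at ~15 substitutions per
pair). Stratum *ordering* is robust and is what the tests assert.
(2) NG86 site counts use the stop-excluding denominator stated above;
implementations that count stop neighbours in the denominator (e.g. some
reference libraries) differ on stop-adjacent codons — the cross-check
test against Biopython restricts itself to codons where the conventions
coincide. (3) All percentages are computed in exact rational arithmetic
before rounding, so printed values are reproducible bit-for-bit.

Problem sizes in the default test and acceptance runs — 10 genomes × 50
OGGs, 600 ancestors for retention sampling, 200 Monte-Carlo pairs, 100
random instances for each oracle suite — were chosen as the smallest
sizes at which the stochastic tolerances are meaningful.
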