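# Methods

`clonetracer` reconstructs immunoglobulin (Ig) clonality from single-cell
transcriptomes of plasma cells and profiles the identified clone against
the remaining cells. The motivating application is POEMS syndrome, where
the pathogenic plasma cell clone is small (a few percent of plasma
cells), carries a restricted lambda light chain (IGLV1-36/-40/-44/-47
rearranged to IGLJ3\*02) with characteristic amino-acid substitutions at
IMGT positions 38 and 40, and shows a CD19⁻ HLA-DR⁻/lo CD38-low surface
phenotype with low *MYC*/*CCND1*. All of these elements are exercised on
synthetic cohorts with planted ground truth, since the original patient
data are controlled-access.

## Repertoire model and annotation

**Germline model.** A `GermlineSegment` stores an IMGT-gapped nucleotide
sequence. For V segments the gapped string has 104 codon slots (IMGT
positions 1–104); a fixed subset of slots is gapped so every scaffold
has the same gapped length, as in a real IMGT alignment. Anchors are the
conserved Cys-104 (V) and the Phe/Trp-118 opening the F-G-X-G motif (J).
The IMGT position of any residue is recovered by codon counting in the
gapped string; no external numbering service is involved.

**Segment assignment.** Each transcript is aligned locally (affine gaps)
against every ungapped reference of a class; the scoring scheme is match
+2, mismatch −2, gap open −6, gap extend −1, with an 80% identity floor
below which the transcript is unassigned. Ties in score break
lexicographically by allele name. The alignment engine is Biopython's
`PairwiseAligner`; at cohort scale an edlib edit-distance prescreen
discards references that cannot win (any candidate within 20 edits of
the best is still affine-aligned) and identical transcripts are
annotated once. The reported score always comes from the affine
aligner and is checked in the tests against an exhaustive
dynamic-programming oracle.

**IMGT numbering and CDR3.** Each germline codon covered contiguously by
the V alignment donates its IMGT position to the transcript codon
aligned to it; insertions are excluded and deletions leave positions
absent. The CDR3 spans IMGT 105–117; the junction additionally includes
the Cys-104 and Phe-118 anchor codons, located by mapping the germline
anchor offsets through the V and J alignments. Clonotype identity uses
the junction *nucleotide* string — stricter than amino-acid identity and
immune to convergent recombination. A chain is productive when the
junction is in frame, translation is stop-free and position 104 is Cys.
Cells with two distinct productive light-chain junctions are flagged as
suspected doublets and excluded from clone-fraction denominators
(conservative; the alternative of keeping the higher-scoring chain would
inflate denominators with ambiguous cells).

## Clonotype grouping and clone calls

Cells sharing the exact light-chain key (V call, J call, junction nt)
form a clonotype; when heavy chains are present the heavy key must also
match, and cells lacking a heavy chain join a light-chain group only
when exactly one heavy variant exists (otherwise they stay separate). A
clonotype with ≥ `min_cells` members (default 2) is a clone; fractions
are computed over assignable non-doublet cells. Signature-positive
singletons can be promoted to putative clones afterwards (the
single-cell-clone case), reported at fraction 1/n.

Bulk repertoire reads are annotated with the same machinery; the clonal
read frequency is the key's share of all key-assignable reads, and
single-cell vs bulk concordance is summarized by Pearson r over paired
fractions (reported only for ≥ 3 pairs).

## Signature rule

A light chain is signature-positive when (i) its V gene is one of
IGLV1-36/-40/-44/-47 (gene level — alleles are not distinguished in the
evidence), (ii) its J call is exactly IGLJ3\*02, (iii) position 40 is
substituted to asparagine, and (iv) position 38 is substituted to a
nonpolar residue, taken as the standard set {G, A, V, L, I, P, F, M, W}
(the observed mutants G/P/A all belong). `strict` mode (default)
requires both positional criteria; `either` mode accepts one, since a
minimal rule was never defined by the observations the rule derives
from. Missing coverage at 38/40 leaves the flag false with a coverage
warning rather than guessing.

## Expression profiling

**Normalization.** Median-of-ratios size factors: the reference set is
genes with nonzero counts in every sample; on sparse matrices without
such genes, a fallback uses genes nonzero in ≥ 90% of cells with the
geometric mean over positive counts. Displayed values use
log2(normalized + 1).

**Differential expression.** Per gene, a Wald test on the log2 fold
change of normalized group means with NB variance μ + αμ², where α is a
method-of-moments estimate pooled across the two groups (df-weighted
mean, floored at 1e−8). A pseudo-mean of 0.5 keeps fold changes finite.
Genes with zero counts in both groups are excluded; BH adjustment runs
across the tested genes. This is deliberately *not* a port of DESeq2's
shrinkage estimators: a plain, fully specified NB test whose type-I
error is verified on 2000-gene null simulations (raw p < 0.05 rate
within 3 Monte-Carlo SD of 0.05). The second DE pass at a stricter
cutoff used for sorted populations is the same test with a different
threshold.

**Top-gene pooling and clustering.** For each disease contrast the top
30 up- and downregulated genes by p-value (among p < 0.01) are pooled;
duplicates collapse, which is why the pooled list is smaller than 6 × 30
when diseases share programs. K-means (scikit-learn, fixed seed, 10
restarts) runs on gene-standardized log2 normalized values of the
pooled genes.

**Pre-ranked GSEA.** Weighted Kolmogorov–Smirnov running sum (weight
p = 1 on |score|): set members step up by |s|/Σ|s|, non-members step
down by 1/(N−Nh); ES is the extremum. Genes with no reads in both
groups are excluded before ranking. The null is gene-set permutation
(random same-size sets), matching pre-ranked usage with small group
sizes; NES divides ES by the mean |permuted ES| of matching sign, and
FDR q across a collection is BH on the nominal p (a simplification of
the pooled-NES q; documented, not hidden). A set containing every
ranked gene is defined to score 0 (no discrimination is possible).

**Marker phenotype and gating.** Group means of log2(normalized + 1)
for the marker panel (CD19, SDC1, CD38, HLA-DRA/B1, MYC, CCND1, CCND2,
IRF4, VEGFA, IL6); "low/negative" flags fire when a group mean falls
more than a margin (default 1 log2 unit) below the reference group. The
in-silico gate is the expression-space analog of the
CD138⁺CD19⁻HLA-DR⁻/lo sort: a cell passes when *every* gating marker is
below threshold, default reference-group mean − 2 SD in log2 space
(flow gates do not translate directly to expression cutoffs; 2 SD is
the package's choice). Purity and recall are reported against truth or
clonotype labels.

## Synthetic cohorts

The generator plants everything downstream stages must recover:

- **Germline scaffolds** are random sequences with IMGT-conforming
  structure (shared gap slots, conserved Cys-23/Trp-41/Cys-104, J tail +
  F-G-X-G + FR4), *not* licensed IMGT database entries; only names and
  anchors follow the convention. Anchors suffice for every algorithm
  here. The four POEMS families carry fixed germline residues at 38/40
  matching the germline side of the reported substitutions.
- **Repertoires**: clone cells share one V-J recombination with a fixed
  CDR3 and the planted substitutions; nonclone cells draw independent
  V, J and random CDR3 (collisions are vanishingly rare at the default
  11-residue CDR3 and are anyway resolved by truth labels, which define
  ground truth). Heavy chains mirror the light-chain machinery with a
  random N-region and no D-segment model — the clone definition uses
  V-(D)-J + CDR3 identity, which this exercises fully. Substitution
  errors are injected last at 0.1% per base by default (Illumina-like;
  the platform's true per-cell error profile is not published, so this
  is a free parameter); truth is recorded pre-error.
- **Counts**: NB with log-normal base means, log-normal library-size
  multipliers (sdlog 0.3, exercising the size-factor estimator),
  dispersion 0.3, and clone-specific multiplicative marker shifts
  (defaults: CD19 −5, HLA-DRA/B1 −4, CD38 −1.5, MYC/CCND1 −1 log2).
- **Bulk reads** are 150 nt windows centred on the light-chain junction
  (a read must cover V anchor, junction and J anchor to be
  key-assignable), sampled uniformly across cells so the expected
  clonal read fraction equals the clone fraction.

What the simulation does **not** emulate: UMI/droplet chemistry,
realistic somatic hypermutation beyond the planted substitutions,
ambient RNA, batch effects, or dropout structure beyond NB sparsity.
Passing tests therefore demonstrate the correctness of the algorithms
under their stated model, not performance on any particular platform's
noise profile.

## Problem sizes and numerical choices

The test suite and the acceptance script run cohorts of 60–2000 cells,
bulk depth 10⁴, 2000-gene matrices and 5–20 replicate seeds — sizes at
which every planted effect is comfortably identifiable while the whole
suite completes in minutes on one CPU. Determinism: every generator and
stochastic algorithm takes an explicit seed; K-means uses a fixed
`random_state`; GSEA permutations are seeded. Degenerate inputs (empty
CDR3, all-zero genes, empty gates, single concordance pairs) return
flagged/absent values rather than raising, except where the input is
unusable (no assignable bulk reads, k > n cells, groups below 3 cells).

## Known limitations

- The DE test is asymptotic (Wald); at very small group sizes (< ~20
  cells) it can be anticonservative, and no independent filtering or
  dispersion shrinkage is applied.
- The heavy-chain model has no D segment, so IGH junction diversity is
  lower than real repertoires; this does not affect light-chain-driven
  analyses.
- `require_both_chains` strict grouping discards light-only cells; the
  default mode maximizes usable cells while still splitting groups on
  heavy-chain mismatches.
- The signature rule is a deterministic classifier of the reported
  pattern; it does not model somatic hypermutation rates and assigns no
  probability to a call.
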