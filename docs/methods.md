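# Methods

This note documents the models behind `opsinkit`, the choices made where
the design was genuinely open, and what the synthetic-data experiments do
and do not demonstrate.

## Species trees

`simulate_species_tree` samples from the reconstructed birth–death process
conditioned on the number of extant tips (Gernhard 2008): the n−1
speciation ages are i.i.d. with CDF
F(t) = λ(1 − e^{−rt}) / (λ − μ e^{−rt}) (r = λ − μ; the λ = μ limit is
F(t) = λt/(1+λt)), and the tree is assembled by joining uniformly chosen
lineage pairs in age order. This gives exact conditioning — the mean root
age is checked in the test suite against numerical integration of
E[root] = ∫ (1 − F(t)^{n−1}) dt — and makes sampling O(n).

The root age of this process is heavy-tailed. Pipelines that compare
sequence-derived quantities across replicate trees therefore **normalize
tree height to 1.0** (`opsinkit.pipeline.normalize_tree_height`), after
which the simulator's `rate_scale` parameter (default 0.4) is simply the
root-to-tip neutral divergence in substitutions/site. Without
normalization, deep replicates saturate nucleotide distances while shallow
ones carry too few substitutions to resolve recent events.

## Gene-family histories

Events (tandem duplication, same-chromosome dispersed duplication,
retrotransposition, loss, single-gene translocation, autosome–Z fusion)
occur along each species-tree branch as a Poisson process with per-lineage
rates, the affected gene copy chosen uniformly; events can also be
*planted* on named branches for experiments with deterministic truth.
Semantics:

- tandem copies sit adjacent to their parent and are emitted with ~6 kb
  spacing (uniform 0.8–1.2× of `tandem_spacing`), matching the close
  linkage of blue-opsin tandem pairs; all other intergenic gaps are
  exponential with mean 1.5 kb (a desk-scale compression of real gene
  density);
- retro copies are intronless and land on a uniformly chosen different
  chromosome (configurable), reflecting the hallmark of an LW retrogene:
  no introns, unlinked to the 7-intron parent;
- dispersed duplicates stay on the parent chromosome but at least two
  genes away (so they are never mistaken for tandem events);
- a chromosome fusion relabels an entire autosome onto the Z, preserving
  gene order after the native Z block (a neo-Z);
- every event is recorded in a ledger that replays exactly to the extant
  complement, and the true per-family genealogies are read off the same
  bookkeeping.

Ancestral opsins carry 7 introns (as the lepidopteran LW opsin does);
introns are GT..AG, fixed length (default 90 nt), placed at codon (phase-0)
boundaries with a 10-codon minimum exon size. Phase-0 placement keeps the
spliced-alignment search exact; sub-10-codon exons are both rare in real
genes and unresolvable in principle by alignment scoring (a 1–2 codon exon
scores less than an intron penalty).

## Codon sequences

Sequences evolve per codon by a continuous-time chain on the 61 sense
codons: single-nucleotide changes at rate ∝ κ for transitions (1 for
transversions), ×ω when nonsynonymous, 0 into stop codons; normalized so a
branch length of 1 is one expected neutral substitution per site. This is a
simplified MG94 analogue: ω has exactly the meaning the downstream
estimator measures. Defaults: κ = 2, background ω = 0.15 (purifying),
retrocopy ω = 0.5 (relaxed).

## Annotation

The annotation loop emulates an iterative tBLASTn + Exonerate protocol at
desk scale. Six conceptual translations of each genome are scanned with
exact amino-acid 5-mers shared with the queries (≥2 seeds per window),
seeded windows are extended by BLOSUM62 local alignment, and merged loci
are passed to a protein-to-genome dynamic program that aligns the full
query codon-by-codon, allowing GT..AG introns (≥30 nt) between query
codons at an intron penalty of 15. The model is substitution-only: with a
simulator that introduces no indels this recovers exact coordinates, and
the annotation tests verify 100% recall/precision with exact exon
boundaries at both zero and default divergence. On real data an in-exon
indel would force a locus-level failure rather than a frameshifted model —
a deliberate conservative choice.

Complete models (start codon, terminal stop, no internal stops) of 250–600
aa are promoted to seeds for the next round; the "appropriate protein
length" window is a configuration default (opsins run ~350–380 aa).
Classification assigns the class of the best-scoring labeled reference
only when its score margin over the best other class exceeds 5%; exact
ties are reported `unassigned` rather than guessed. When a gene tree is
available, the smallest reference-containing clade must be class-pure.

## Gene trees and reconciliation

LCA reconciliation maps each gene-tree node to the LCA of its children's
images; a node is a duplication iff it maps onto a child's image, the
event is assigned to the species branch above the image, and losses follow
the standard path-length count. Reconciling a species tree against itself
yields zero events, and on true genealogies every planted duplication maps
to exactly its branch of origin.

Estimated gene trees use JC-corrected nucleotide distances on the CDS
(under purifying selection most substitutions are synonymous, so protein
distances discard most of the signal) and neighbor joining with the usual
negative-branch-length fix. Because few-substitution branches are
frequently misresolved — inflating duplication counts — NJ topologies are
refined by reconciliation-guided rearrangement: steepest-descent NNI,
disjoint-subtree swaps, and subtree prune-regraft moves are accepted only
when they strictly lower the duplication+loss cost of the optimally rooted
reconciliation (the rearrangement idea of species-tree-aware gene-tree
correction tools such as Notung and TreeFix). A strict-improvement rule
protects well-supported duplication clades, whose cost no topology can
undercut. Cost over all rootings is computed by a directed-edge dynamic
program, so refinement is fast. Gene trees without an outgroup are rooted
at the minimum-cost position.

## Mechanistic classification

- **retro vs dna**: a single-exon duplicate of a parent with ≥2 introns is
  a retrogene; a single-exon parent makes the criterion inapplicable and
  the pair is conservatively classified `dna` with a note. Different-
  chromosome placement is recorded as supporting evidence only.
- **location**: different chromosome → `translocated`; ≤1 intervening gene
  → `tandem`; within 100 kb → `proximal`; else
  `dispersed_same_chromosome`. The tandem/proximal thresholds are
  configuration defaults; at the simulator's compressed genome scale the
  proximal/dispersed boundary is scale-dependent, so event-level scoring
  groups both as "dispersed" (same-chromosome, non-tandem).
- **fusion vs single-gene translocation**: after a fusion the duplicate's
  *neighborhood* moved with it, so its flanking genes sit, in a comparator
  genome lacking the event, together on a different chromosome in
  conserved order. Fusion is called when ≥5 of the 10 flanking genes
  co-migrated from one shared source chromosome (both thresholds
  configurable); otherwise the gene jumped alone. Ortholog identity comes
  from `ortholog_group` annotations; real-data use requires a genome-wide
  orthology map in that attribute.
- Classification never reads sequence content, only coordinates and exon
  structure (asserted by a scrambled-sequence test).

## Paralog linkage

Reciprocal best hits in an all-vs-all BLOSUM62 comparison, kept when on
the same chromosome with query coverage ≥ 0.70 and identity ≥ 65% (the
filters that make background pairs comparable to blue-opsin tandem pairs),
one pair per gene greedily by score. Intergenic distance is
max(0, downstream start − upstream end), strand-agnostic. The focal pair's
percentile in the background uses the mid-CDF with mid-ranked ties,
clamped to [100·0.5/n, 100·(1−0.5/n)] so values outside the background's
range report the resolution limit rather than 0 or 100 (the same
convention that keeps permutation p-values off zero). The synthetic
background is log-normal with median 16 kb and σ = 1.8, giving the
heavy-tailed median≪mean shape of genome-wide paralog spacing; focal
tandem distances are drawn uniformly from the observed 3–13 kb range.

## Selection analyses

**NG86 dN/dS.** Canonical Nei–Gojobori counting: per-position synonymous
fractions with stop mutations excluded from the possible-change set; site
counts averaged over the two sequences; differences averaged over all
shortest mutational pathways that avoid stops (all pathways if none
avoids); Jukes–Cantor correction. ω is flagged +∞ when dS = 0 < dN and
undefined when both are 0; pS or pN ≥ 0.74 flags saturation and excludes
the pair from group summaries. The implementation is checked to 1e−9
against a brute-force enumeration oracle, and estimator recovery is
validated at ω ∈ {0.1, 0.5, 1.0} under κ = 1 — the regime in which NG86's
equal-weight site counting is unbiased; with transition bias (κ > 1) the
estimator inherits NG86's well-known mild downward bias in ω.

**Group comparison.** Kruskal–Wallis H (tie-corrected) across diel-niche
groups with a label-permutation p-value, p = (b+1)/(n_perm+1); non-finite
ω values are excluded and counted. Null p-values are verified uniform.

**Relaxation proxy.** R = mean pairwise ω within the foreground clade over
the same for the background, with a leaf-partition permutation null
(one-sided for R > 1). This is an explicitly labelled proxy for
likelihood-based selection-intensity parameters such as RELAX's k — R > 1
with a purifying background is the relaxation signature — and no numeric
correspondence with k is claimed. Foreground and background must be clades
of one alignment; cross-clade pairs are what give the permutation null its
power.

**Trait association.** Two binary traits (diel niche, duplication
presence; "both"-niche species excluded by default) are fitted with
independent 2-state Markov chains (4 rates) versus a joint 4-state chain
with 8 single-trait transition rates, by pruning with uniform root
frequencies. LR = 2(lnL_dep − lnL_indep) is calibrated by parametric
bootstrap under the fitted independent model (p = (b+1)/(n_boot+1));
observed and bootstrap statistics use the identical single-start fitting
protocol so they remain exchangeable. Rates are bounded above at ~10
expected changes per root-to-tip path — beyond that they are
unidentifiable, and unbounded MLEs destabilize the bootstrap. The pruning
code is verified against exhaustive summation over ancestral states, and
type-I error is calibrated by simulation; the bootstrap is mildly
conservative away from the 5% tail, a known property of parametric
bootstraps built on small-sample Mk rate estimates.

**Tuning sites.** Known spectral-tuning positions (e.g. the blue-opsin
S116A substitution, or G175S/Y177F) are reported per taxon in 1-based
ungapped reference coordinates; gaps report "missing". Which reference
defines the numbering is a required user choice.

## Expression

TPM from counts and effective lengths (columns sum to 10⁶); stage means
over replicates; specificity by tau = Σ(1 − x_i/x_max)/(n−1) ∈ [0, 1];
parent/duplicate divergence as per-stage log₂((dup+1)/(parent+1)) with a
+1 pseudocount, classified "reciprocal stage bias" when dominant stages
differ and both tau ≥ 0.5. For larva-vs-adult questions the two adult head
samples should be mapped to a single "adult" stage in the sample-to-stage
table. Counts are negative-binomial (Gamma–Poisson, dispersion 10 by
default; Poisson in the large-dispersion limit) with configurable fold
changes; the 50-fold reciprocal fixture mirrors the magnitude of the
parent/retrocopy contrast between first-instar larvae and adult heads.

## Problem sizes and what the experiments show

The validation experiments run at desk scale: 12-species trees with five
planted events (20 replicates), 350-codon genes, 6 autosomes + Z with 12
background genes each, 500-codon pairs for estimator recovery, 100
replicates for calibration/power, 200 seeds for linkage and expression.
`scripts/acceptance.py` reports each number with the n used.

Passing these experiments shows the chain is *internally correct*: every
stage recovers a truth its own generator planted, under that generator's
assumptions. Real genome data differ in ways the generator deliberately
omits — indels and alignment uncertainty, assembly gaps and fragmented
scaffolds, pseudogenes, non-canonical splice sites, rate heterogeneity
across sites, incomplete lineage sorting, tissue-composition confounds in
whole-body RNA samples — so performance here is an upper bound, not a
field guarantee. The event-rate defaults are illustrative (no calibrated
estimates of per-mechanism duplication rates exist for this family), and
the λ_max metadata field is annotation only: nothing in the package
predicts absorbance from sequence.
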