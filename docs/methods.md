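# Methods

`irpdx` re-implements the computational core of an induced-recurrence
glioblastoma PDX (IR-PDX) study design: patient-derived glioma stem cells
(GIC) are xenografted, treated with a surgery-mimicking injury plus
radiotherapy and temozolomide, and allowed to recur; the induced
recurrence is then compared against the patient's true recurrence across
genomics, transcriptomics, methylation, histology and pharmacology.  This
note documents the models, parameter choices and numerical conventions of
each stage, what the synthetic data emulate, and the limits of what
passing tests demonstrate.

## Xenograft species deconvolution (`xenodeconv`)

Reads from PDX single-cell libraries are assumed to have been aligned to
both GRCh38 and Mm10; the module consumes the per-cell aligned-read counts.

- Per-cell filter: `logfc_hs_mm = log2((human + pc) / (mouse + pc))` with
  pseudocount `pc = 1`; cells with logFC < 1 are excluded.  The base-2
  log and unit pseudocount are conventions: threshold 1 then reads as "at
  least a two-fold human excess".  The boundary value logFC = 1 is kept.
- Per-cluster filter: clusters whose *mean of per-cell ratios*
  `(human + pc)/(mouse + pc)` is strictly below 3 are removed wholesale;
  a mean of exactly 3 is retained.  Mean-of-ratios (not ratio of summed
  counts) was chosen as the literal reading of a "mean ratio"; both
  boundary conventions are documented here precisely because they are
  conventions, not inferences.
- QC: cells need >= 500 detected genes, >= 1000 counts and <= 20%
  mitochondrial counts (gene-name prefix `MT-`, configurable); boundaries
  are kept.  Normalisation scales each cell to 10,000 counts and applies
  log1p; raw counts are preserved in `layers["counts"]`.

## Somatic filtering and phylogeny (`somatic`)

Call tables are long-form rows of (chrom, pos, ref, alt, sample, NR, NV,
GT, GQ, flag) with per-sample purities; NR is total depth, NV variant
reads.

1. **Candidate filter** (per-tumour vs matched normal): flag PASS, depth
   >= 10 in the calling tumour and the normal, NV >= 3 in the tumour,
   NV = 0 and genotype 0/0 in the normal, non-reference genotype in the
   tumour; candidates are merged across tumours.
2. **Joint filter** (all samples): flag in {PASS, alleleBias, QD, Q20},
   canonical chromosome (chr1-22, X, Y; configurable), NR > 10 and
   GQ > 10 in *all* samples (strict), normal 0/0, >= 1 tumour 0/1 or 1/1.
   The depth thresholds deliberately differ between stages (>= 10 vs
   strictly > 10), following the letter of each rule.
3. **Purity-adjusted VAF**: VAFadj = (NV/NR)/purity per sample; a variant
   is dropped when its maximum VAFadj across samples is < 0.05.  Samples
   with NR = 0 contribute no VAFadj.  Lowering purity can only increase
   VAFadj, so the surviving set is monotone in purity (property-tested).

The audit trail names, for every rejected variant, the rule at which its
best-supported record was eliminated, which for engineered single-rule
violations is the planted rule.

Binarisation scores a sample 1 for a variant if it has any variant read
(NV >= 1), and appends an all-zero outgroup row representing germline.

**Tree search.** Fitch small parsimony over binary characters scores
unrooted binary topologies.  For <= 6 leaves the search is exhaustive over
all (2n-5)!! topologies and returns every optimum; above that a parsimony
ratchet runs (default 50 iterations, 25% of characters up-weighted to
weight 2 per iteration) around a hill climb over subtree-prune-and-regraft
(SPR) moves.  SPR, a superset of nearest-neighbour interchange, was
adopted after NNI-only climbing measurably failed to reach the exhaustive
optimum on random matrices; with SPR the ratchet matched the exhaustive
oracle on hundreds of random 4-7 leaf instances.  Ties among equally
parsimonious trees are all returned together with their strict consensus
splits.

**acctran.** Ancestral states are computed per character by unit-cost
Sankoff dynamic programming on the tree rooted at the outgroup, followed
by a preorder pass in which ties between "keep the parent state" and
"change" are resolved in favour of changing — i.e. transformations are
accelerated towards the root.  Branch changes sum exactly to the
parsimony score (asserted in tests and in the acceptance script).

## Cell-state analysis (`cellstate`)

- **Variable genes**: expression is de-logged (expm1); per-gene dispersion
  (variance/mean) is z-scored within 20 equal-frequency bins of mean
  expression and genes are ranked by normalised dispersion with a
  lexicographic tie-break.  Equal-frequency bins avoid the degenerate
  single-gene bins that plain equal-width binning produces for extreme
  mean expression.
- **Embedding/clustering**: z-scaled (clipped at ±10) HVGs, full-SVD PCA
  (default 15 components), k-nearest-neighbour graph (k = 20), Louvain
  community detection (igraph multilevel) at resolution 0.25, seeded.
  Batch correction is an optional per-group centring of PCs
  (`center_by`); the synthetic fixtures carry no batch effect, so the
  default is none.
- **Markers**: one-vs-rest Wilcoxon rank-sum (scanpy) with BH adjustment;
  markers require adjusted p < 0.05, log2FC > 0.25 and expression in
  >= 10% of cluster cells (all configurable).  Cross-patient overlap is
  the Jaccard index of marker sets.
- **RAC signature**: given the intersection of the two patients' ciliated-
  cluster marker sets, the recurrence-associated cilia signature is the
  top 50 intersect genes by mean normalised expression within ciliated
  cells.  The ciliated cluster itself is a caller-supplied nomination
  (in the original analysis it was annotated manually from FOXJ1/RFX2
  and cilium-component markers).
- **Module score**: genes are binned into 25 equal-size bins of mean
  expression; for each signature gene 100 control genes are drawn without
  replacement from its bin (seeded; the pool is sorted so the draw is
  independent of gene order); score = mean signature expression − mean
  control expression per cell.  On a constant matrix the score is exactly
  zero.  Cell-cycle phases are assigned from S and G2M module scores
  (G1 when both are negative, otherwise the larger).
- **Cohort comparison**: the high-scorer threshold is mean + 2 SD of the
  pooled scored population (per-condition thresholds available by flag);
  per-tumour mean scores are compared between conditions by a two-sided
  rank-sum test.  With fewer than two tumours per condition the p-value
  is reported as undefined rather than computed.

## Concordance and capture (`concord`)

Differential tables carry (gene, effect, p, BH-adjusted p, contrast).
The built-in `simple_de` exists so synthetic fixtures flow end-to-end: it
applies the "< 1 count-per-million in all samples" prefilter, normalises
by median-of-ratios size factors (robust to library-composition shifts
that total-count scaling mishandles when many genes move one way), and
tests per gene with a two-sided Mann-Whitney.  It is plumbing, not a
DESeq2 replacement.

Concordant genes are those significant in both omics with opposite signs
(hypomethylated+up, or hypermethylated+down); the two sets are disjoint
by construction.  The capture fraction of a model contrast against a
truth contrast is |sig(model) ∩ sig(truth)| / |sig(truth)|, with effect-
sign matching on by default for expression and off for methylation; Venn
counts are emitted alongside.  Gene-level methylation takes each gene's
smallest-adjusted-p probe.  Subtype scoring applies the bin-matched
module score to pseudo-bulk profiles and reports the argmax (ties are
reported as ties).  Semi-supervised clustering selects the top features
by standard deviation (defaults 5000 genes / 10,000 probes), z-scores
them and clusters samples with complete linkage on Euclidean distance.

## Morphometry (`morpho`)

All structuring elements are Euclidean disks of the stated physical
radius; radii convert to pixels by round-half-up of radius/µm-per-pixel.
Erosion/dilation are computed from exact Euclidean distance transforms,
which is equivalent to disk-kernel morphology and fast at 75 px radii.

- Tissue is eroded by 35 µm.
- Tumour core: 10 µm opening of the tumour (hVim) mask, then connected
  components (8-connectivity) smaller than 10,000 µm² are removed.
- Gross tumour: 75 µm closing; component identity is assigned at the
  dilation stage, where objects within 150 µm merge — the following
  erosion restores borders but does not re-split a merged object (the
  geometric erosion of two bridged disks can disconnect even though the
  procedure treats them as one object).  Gross components containing no
  core component are excluded.
- Metrics: %hVim area = tumour/tissue area; invasiveness index =
  gross/core area; positive-cell density = cells per mm² of hVim area.
  Undefined ratios (empty core or tumour) are reported as NaN.

On rasterised disks, pixel-count areas agree with πr² to well under 1% at
the default 1 µm/px scale, and halving the pixel size moves areas by
< 1%.

## Pharmacology (`pharmaco`)

Viability is in % of vehicle control throughout.  Monotherapies are fitted
with the four-parameter Hill model E(d) = Einf + (E0−Einf)/(1+(d/EC50)^h)
by bounded least squares (tight tolerances recover exact generating
parameters to ~1e-6); its inverse D(E) is closed-form.  The Loewe-additive
expectation at (d1, d2) solves d1/D_a(E) + d2/D_b(E) = 1 by Brent root-
finding inside the jointly achievable effect range (relative tolerance
1e-9), clamping to the nearest achievable effect when no root exists and
collapsing to the active drug's monotherapy when the partner is inactive.
The synergy score is expected − observed viability, so positive scores
mean synergy; this sign convention is declared here because published
synergy matrices often omit it.  Sham self-combinations score < 1e-6 by
construction.  AUC comparisons use trapezoidal area over the dose axis on
survival fractions and unpaired two-sided t-tests on replicate AUCs.
Drug-candidate ranking intersects the significantly upregulated genes of
the model and truth contrasts, ranks by the mean of the two log2 fold
changes (log scale; a linear-scale flag exists), takes the top 10 and
joins a local drug-gene interaction snapshot (never a live query).

## Synthetic study conditions (`synthio`)

One seed expands into independent per-artifact NumPy PCG64 streams via
`SeedSequence(seed, spawn_key=(artifact_id,))` with documented artifact
ids, so a fixed seed gives byte-identical artifacts.  Counts are
negative-binomial (gamma-Poisson) with per-gene log-normal baseline means
(median 2 counts/gene) and log-normal dispersions; this matches the
overdispersion single-cell methods assume without copying any tool's
simulator.

Defaults (the study conditions; chosen once):

- dual-species: 2000 cells, 10% murine contamination, human depth
  NB(mean 5000, size 20), ambient cross-species reads Binomial(own reads,
  0.008) — so the minority-genome count never exceeds the majority count;
  contaminants are placed in their own cluster.
- state mixture: 1000 genes, four disjoint 60-gene marker blocks
  (AC-like, MES-like, NSC-ciliated, NPC-like), planted log2 effect 2,
  350 cells per condition × 3 conditions × 2 patients (two replicates
  each); ciliated proportion 0 in primary, 10%/15% in induced/recurrent.
  Cell-cycle S/G2M blocks are planted only when `cycle_effect > 0`.
- variants: tumours P, IR, R (purities 0.8/0.6/0.7) plus a normal; clonal
  history ((P,IR),R) with 30 trunk, 10 shared-P+IR and 4/4/8 private
  mutations at ~100x depth, clonal VAF 0.5 scaled by purity; one
  deterministic violation per filter rule with exact read counts so the
  ground-truth labels are certain.
- masks: 1 µm/px, tissue disk r = 1500 µm, core r = 500 µm, satellites of
  50/60/150 µm radius at 800/1000/760 µm — exercising island removal
  (7,854 µm² < 10,000), retention (11,310 µm²) and gap bridging
  (110 µm gap < 150 µm).
- dose grids: Hill parameters MBZ (100, 5, 120 nM, 1.5) and TMZ
  (100, 10, 900 µM, 1.2); combination doses include the assay design of
  50/250 nM MBZ against 500/1000/1500 µM TMZ, with extra monotherapy
  points because a 4-parameter fit needs more than three doses; planted
  Loewe offset +15% control on all combination cells; measurement noise
  SD 0.5% control with 3 replicates (luminescent viability assays are
  low-noise).
- differential tables: 5000 genes, 500 truth-significant, each captured
  by the model independently with probability 0.6 (expression) / 0.3
  (methylation) with matching sign, plus 200 model-only genes.

What the generators do *not* emulate: raw reads and UMIs, ambient RNA and
doublets, batch effects, spatially realistic histology textures, probe-
level methylation chemistry, or sequencing error in variant counts.
Passing tests therefore demonstrate correctness of the implemented
procedures and their recovery of planted structure under realistic
overdispersion — not robustness to every artefact of real PDX data.

## Problem sizes and determinism

Tests and the acceptance script run the full conditions at desk scale:
~2000-cell mixtures for clustering (ARI vs planted states), 10 × 2000
cells for species deconvolution, 100 random <= 6-leaf matrices for the
tree-search oracle, 500 truth-significant genes for capture fractions,
~3 megapixel rasters for morphometry.  Every stochastic step takes an
explicit seed; the end-to-end CLI chain is bit-reproducible at a fixed
seed (verified by hashing all outputs across two runs), which is why
intermediates are written as text (MTX/TSV/CSV/newick/TIFF) rather than
HDF5.

## Known limitations

- The ratchet is validated against the exhaustive oracle only up to 7
  leaves; WES studies of a few samples per patient sit well inside this,
  but large cohorts would need a dedicated phylogenetics package.
- `simple_de` (rank-sum on normalised counts) has no dispersion shrinkage
  and less power than negative-binomial GLMs at small n.
- The Loewe solver assumes monotone Hill monotherapies; strongly
  non-monotone data are flagged at fit time rather than modelled.
- The per-cell synergy score inherits Hill-fit uncertainty from noisy
  monotherapies (~±1% control at default noise); the planted offset is
  recovered to ±1 on the cell average.
- Cluster-level species filtering assumes contaminants co-cluster;
  isolated murine cells are caught by the per-cell logFC rule only.
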