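# Methods

This note records the models implemented in `gsckit`, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical conventions that matter for reproducing results.

## Peak catalog and region sets

Coordinates are 0-based half-open (BED convention). The catalog is the
union of all samples' peak calls with intervals merged on ≥ 1 bp overlap —
the simplest defensible overlap rule; it is also the overlap criterion for
mapping signal onto catalog regions and for promoter–region intersection.
Where several calls of one sample overlap one merged region, the minimum
q-value and the maximum fold enrichment are kept, so occupancy at any
threshold is monotone in q by construction.

State-exclusive regions use two thresholds: a strict call filter
(q ≤ 0.05) inside the state and a lenient absence filter (q > 0.2) in every
sample outside it. Exclusive sets are provably pairwise disjoint and this
is asserted at run time. Shared regions require occupancy in
≥ `min_samples` samples (default 15, i.e. a majority of a 27-sample
cohort). Differential state peaks use a Mann–Whitney rank-sum test per
region (asymptotic, tie-corrected — ATAC signal contains exact zeros),
Benjamini–Hochberg across regions, and a filter on the ratio of mean
signals (> 2). Ratio of means rather than medians: medians of
fold-enrichment vectors with many zeros are unstable at small n.

Promoter windows default to −2000/+500 bp around the TSS, strand-aware,
clipped at zero. The window size is a convention (common in regulatory
annotation), exposed as parameters.

## Saturation

The discovery curve is the cumulative count of distinct occupied regions
as samples are added in random order, averaged over permutations (default
10,000; tests use 200 with fixed seeds). The asymptotic regression is
y(n) = A·(1 − e^(−kn)) fitted by least squares with a self-start
(A₀ = 1.05·max y; k₀ from a log-linear regression of log(1 − y/A₀)), with
A bounded below by the observed total so the saturation fraction
y_obs(N)/A lies in (0, 1]. A flat curve short-circuits to A = y(N),
fraction 1. A Michaelis–Menten alternative (y = An/(K + n)) is available
via `model="michaelis_menten"` for sensitivity analysis; the model used is
recorded on the fit object.

## State discovery

Samples are compared by Pearson correlation of log2(signal + 1) rows
(affine-invariant on the log scale). The affinity is the
similarity-network-fusion scaled-exponential kernel: with mᵢ the mean
distance of sample i to its K nearest neighbors (K = min(20, n−1)),
ε(i,j) = (mᵢ + mⱼ + d(i,j))/3 and W(i,j) = exp(−d²/(μ·ε)), μ = 0.5.
With a single data type the fusion step reduces to this kernel; no
cross-modality diffusion is implemented. Spectral clustering follows
Ng–Jordan–Weiss: the k leading eigenvectors of D^(−1/2) W D^(−1/2),
row-normalized, partitioned by k-means with a fixed seed and 50 restarts,
so labels are deterministic given (W, k, seed). `select_k` sweeps k = 2–12
and takes the max mean silhouette (on the affinity converted to a
distance), ties to the smallest k; the Laplacian eigengap is reported
alongside as a diagnostic. New samples are mapped onto the reference
catalog and allocated by average-linkage hierarchical clustering on
correlation distance: the query takes the majority reference label of the
smallest merge cluster containing it, name-order tie-break, flagged.

## Single-cell signatures

The embedding is TF-IDF (term frequency per cell × inverse document
frequency per region, log1p-scaled ×10⁴) followed by truncated SVD; the
first component tracks sequencing depth and is dropped. Accessibility
modules are k-means clusters with the module count at the elbow of the
WSS curve, defined as the k maximizing the second difference of log(WSS)
(the point where relative improvement collapses); ties go to the smallest
k. The log transform makes the rule scale-free and reproduces the
intuitive elbow on curves like (100, 40, 20, 18, 17) → k = 3, where the
raw second difference would pick the first large drop instead.

Deviation scores follow the chromVAR construction: the expected signature
count of a cell is its depth times the signature's share of all counts;
raw = (obs − exp)/exp, which sums to zero over cells when weighted by
expectation. Each of `n_background` (default 50) background draws replaces
every signature region by one of its 50 nearest neighbors in standardized
(GC, mean accessibility) space, drawn uniformly; z standardizes raw
against the background mean and SD. Uniform k-NN sampling is a transparent
variant of chromVAR's Mahalanobis-based sampling; the matching features
are the same. "Significantly enriched" is defined as one-sided
(enrichment) normal-tail p from z, BH-corrected across cells, q ≤ 0.05 —
the package's own convention, applied uniformly to cellular-state, stem
and GSC-state signatures. Zero-depth cells are flagged invalid rather than
scored.

Module dominance at fold cut-off f (default 2): a single state dominates
when its cell count is ≥ f × every other state's; otherwise the top two
states dominate as a pair when their combined count is ≥ f × every
remaining state's count *and* each member exceeds every remaining count
(the second condition keeps uniform modules "mixed", which the bare
combined-count rule cannot); otherwise mixed.

## Motif enrichment

Scanning is a log-odds search (log2 p/0.25, pseudocount 10⁻³) over both
strands; a region hits a motif when its best window reaches
`rel_threshold` (default 0.8) of the motif's maximum attainable score; N
bases score as background. Enrichment of a target region set is measured
against the full catalog: FE = target hit rate / catalog hit rate, with an
upper-tail hypergeometric p and BH across motifs; motifs with zero catalog
hits are flagged rather than scored. Families (motif → DNA-binding-domain
family, supplied as a TSV) take the max FE among members with q ≤ 0.05 and
are retained at log2(FE) > 0.5. This scanner + hypergeometric model is a
deliberately simple, fully specified alternative to HOMER's ZOOPS/binomial
machinery; outputs carry a method tag so the two are never conflated.

## Essentiality

Per line, scaled score = (BF − line threshold)/sd(BF), mapping each line's
empirically determined threshold to exactly 0; SD scaling makes score
distributions comparable across lines (the particular scaling is a package
choice — only the zero-crossing is fixed by the construction). A gene is
essential in a line iff BF ≥ max(3, line threshold), boundary inclusive.
The per-line FDR-derived thresholds are inputs: they are produced upstream
of the BF tables this package consumes. State-exclusive essential genes
are essential in ≥ 1 line of one state and in no line of any other.

## Prognosis

DE genes per state: rank-sum of the state's samples against the rest on
log2(FPKM + 1), BH across genes, keep q ≤ 0.05 with mean-FPKM ratio ≥ 2
(boundary inclusive) and the higher mean in the state. This rank-based
test stands where a negative-binomial count model would be used on raw
counts; a precomputed DE table can be substituted by passing its gene sets
directly to the downstream steps. Centroids are mean log2(FPKM + 1) per
state over the DE-gene union.

The concordance index between a tumor and a centroid is pairwise rank
concordance over genes: over all gene pairs, count pairs ordered the same
way in both profiles, half-credit for pairs tied in either; C ∈ [0, 1],
invariant under strictly increasing transforms of either profile. This is
profile concordance — concordance between two expression vectors — not
Harrell's C against survival times; the stratification never sees survival
when scoring. Tumors are assigned to the argmax state (alphabetical
tie-break, flagged). Invasive bins use the cohort z-score of the Invasive
concordance column (sample SD): low < 1 ≤ mid < 1.65 ≤ high.

Survival statistics are implemented directly and cross-checked against
lifelines in the test suite: the Kaplan–Meier product-limit estimator
(median = smallest t with S(t) ≤ 0.5, "not reached" when S stays above ½);
the unweighted k-group log-rank test with the hypergeometric covariance
and a generalized inverse on the first k−1 groups; and Cox proportional
hazards by Newton–Raphson on the Breslow partial likelihood (step-halving;
convergence at gradient norm < 10⁻⁸; estimates diverging past |β| > 15
raise a monotone-likelihood error suggesting exact or penalized methods).
Breslow tie handling is the default for its simplicity; ties are rare to
absent for the continuous times used here. Xenograft-style inputs with
several mice per line are collapsed to one record per line by the lower
median (the lower middle observation for even counts); the event indicator
comes from the observation(s) at that time, censored if any of them is
censored.

## Synthetic data

The generators are pure functions of (config, seed) and emulate the shape
of the study's inputs at desk scale:

- **Bulk cohort**: 27 samples split 13 Reactive / 9 Constructive /
  5 Invasive over a latent catalog of 1,000 regions (chr1, 300 bp wide,
  1 kb apart, ±50 bp call jitter). Each state owns a 10% exclusive block
  (called at q ~ U(10⁻⁶, 0.04) in its samples, absent or weakly called at
  q ~ U(0.25, 1) elsewhere, so the 0.05/0.2 filters are unambiguous); 20%
  of regions are shared by all samples; the rest are present per sample
  with probability 0.6. Fold enrichment is log-normal (median 4).
- **Cells**: 1,000 cells over the same latent catalog; per-cell depth
  log-normal (median 2,000, log-SD 0.4, floor 100); counts multinomial
  given depth — chosen over independent Poisson so depths are conserved
  exactly and deviation-score expectations are exactly testable. Each of
  the four cellular states boosts its 50-region signature block by the
  effect size (default 2); a 10% stem minority boosts a 60-region stem
  block. Region GC ~ U(0.3, 0.7), independent of state; the `gc_bias`
  switch couples GC with accessibility to stress background matching.
- **Expression**: state centroids derive from the config seed (not the
  per-call seed), so reference and tumor cohorts generated under one
  config share planted structure; 10% of genes are shifted by 2 log2 units
  in exactly one state; samples add N(0, 0.5) log-noise.
- **Tumors**: 144 tumors mix the three centroids with an Invasive weight
  w ~ Beta(0.6, 2.5); hazard = 0.02 · HR_Invasive^(w/0.5) per month, so
  tumors differing by 0.5 in Invasive weight differ in hazard by the
  planted ratio (3.5 by default), censored administratively at 60.
- **Survival**: exponential times with group hazard = baseline × HR;
  default HRs Reactive 1.0 / Constructive 1.3 / Invasive 3.5.
- **Motif hits**: Bernoulli hit matrices over a 5,000-region universe;
  planted motifs hit 200 target regions at 4× the base rate 0.1. The
  universe is kept large relative to the target so the catalog-background
  fold enrichment approaches the planted rate ratio.

What the generators do **not** emulate: genome sequence and read-level
noise (peaks are abstract intervals; no FASTQ/BAM), chromosomal structure
beyond one chromosome, copy-number signal, batch effects, doublets and
ambient fragments in single-cell data, mean–variance relationships of
real RNA-seq counts, and dependence between censoring and covariates.
Passing tests therefore demonstrate the correctness and calibration of the
statistical machinery under the planted model, not robustness to the full
noise structure of real cohorts.

## Problem sizes and known limitations

Tests and examples run cohorts of 27 bulk samples × 1,000 regions, 1,000
cells, 2,000 genes, 144 tumors, and 100-replicate survival designs;
rarefaction uses 200–5,000 permutations with fixed seeds. These sizes were
chosen so every planted effect is comfortably detectable while the whole
suite stays interactive.

Known limitations: the Cox estimate of a 10-subject high-risk group (~7–9
events) carries the usual small-sample upward bias of the partial-likelihood
MLE — a few percent on the hazard-ratio scale — visible in the cohort-design
replicates; the hypergeometric motif model ignores sequence composition
beyond the catalog background; the concordance index treats genes
exchangeably (no weighting by effect size); and the null calibration of
rank-sum p-values is checked on 20-samples-per-state cohorts because the
discrete support of the statistic at 13/9/5 is too coarse for a
Kolmogorov–Smirnov uniformity check regardless of implementation.
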