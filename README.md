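# gsckit

Chromatin accessibility separates self-renewing, tumor-initiating cells from
their differentiated progeny. In adult IDH-wild-type glioblastoma (GBM),
patient-derived glioblastoma stem cells (GSCs) profiled by bulk ATAC-seq
fall into three chromatin-defined states — **Reactive**, **Constructive**
and **Invasive** — each with its own exclusively accessible regions,
enriched transcription-factor motif families, uniquely essential genes, and
prognostic weight: tumors most concordant with the Invasive expression
program carry the worst survival.

`gsckit` is a tested, reusable implementation of that analysis for anyone
working with ATAC peak sets, single-cell fragment counts, expression
matrices and survival tables: computational biologists who want to apply
the state-discovery and stratification machinery to their own cohorts, and
methodologists who want each statistic exposed as a plain function.

## What it computes

- **Peak catalog** — union of per-sample MACS2-style calls with ≥ 1 bp
  overlaps merged; per-sample q-value and fold-enrichment matrices over the
  merged regions. A region is **exclusive** to state *S* when called at
  q ≤ 0.05 in ≥ 1 sample of *S* and not called at q ≤ 0.2 in any other
  sample; **shared** regions are occupied by a majority of samples
  (> 14 of 27).
- **Saturation** — rarefaction of cumulative peak discovery over random
  sample orders (averaged over permutations), fitted by the asymptotic
  regression y(n) = A·(1 − e^(−kn)); the saturation fraction is
  y_obs(N) / A.
- **State discovery** — similarity-network-fusion scaled-exponential kernel
  on correlation distance of log2(signal + 1), normalized-Laplacian
  spectral clustering over k = 2–12 with silhouette-based selection, and
  hierarchical assignment of new catalog-mapped samples.
- **Single-cell signatures** — TF-IDF/LSI embedding and elbow-selected
  accessibility modules; chromVAR-style deviation z-scores of each cell
  against region-set signatures (cellular states NPC/OPC/AC/MES, stem
  signatures, GSC-state signatures), standardized against background
  region sets matched on GC content and mean accessibility; one-sided
  BH-corrected enrichment calls; module dominance at a twofold cut-off.
- **Motif enrichment** — log-odds PWM scanning (both strands), fold
  enrichment of a target set against the full catalog with hypergeometric
  tests, and family scores (max fold enrichment of significant members,
  retained at log2(FE) > 0.5).
- **Essentiality** — CRISPR-screen Bayes factors normalized per line to a
  common zero threshold; essential at BF ≥ max(3, line threshold);
  state-exclusive essential gene sets.
- **Prognosis** — per-state DE genes (rank-sum, BH, fold change ≥ 2),
  mean log2(FPKM + 1) state centroids, a pairwise rank **concordance
  index** C ∈ [0, 1] between each tumor and each centroid, Invasive
  z-score bins (< 1 / 1–1.65 / ≥ 1.65), and Kaplan–Meier / log-rank /
  Cox PH (Breslow ties) survival comparisons.
- **Synthetic data** — seeded generators for every input above with
  planted ground truth (states, exclusive blocks, stem cells, DE genes,
  hazard ratios), so the whole pipeline is testable without any download.

## Worked example

`examples/` contains one narrative script per capability. For instance:

```bash
python examples/01_bulk_states.py
```

```
catalog: 1000 regions x 27 samples
  Constructive:  100 exclusive regions (recovers 100% of planted)
  Invasive    :  100 exclusive regions (recovers 100% of planted)
  Reactive    :  100 exclusive regions (recovers 100% of planted)
saturation: predicted total 1000 regions, observed fraction 100.0%
spectral clustering: selected k=3, ARI vs planted states = 1.00
```

A 27-sample synthetic cohort is simulated with three planted states; the
catalog recovers every planted state-exclusive block under the 0.05/0.2
q-value rule, the saturation fit predicts the latent catalog size, and
spectral clustering of the fused affinity recovers the three states with
adjusted Rand index 1.0. `examples/05_prognosis.py` runs the survival arm:

```
DE genes per state: {'Constructive': 67, 'Invasive': 66, 'Reactive': 66}
tumors per dominant state: {'Reactive': 67, 'Constructive': 49, 'Invasive': 28}
invasive bins: {'low': 116, 'high': 15, 'mid': 13}
  low : n=116, KM median survival = 23.7
  mid : n= 13, KM median survival = 15.8
  high: n= 15, KM median survival = 11.3
log-rank across bins: chi2=17.3, df=2, p=0.00018
Cox high vs low: HR=2.75 (95% CI 1.56-4.85, p=0.00048)
```

The Invasive-high bin has the shortest median survival and a hazard ratio
close to the structure planted by the generator.

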