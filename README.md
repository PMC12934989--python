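# nichemet

Spatial + systemic metabolomics analysis of plasma-cell disorders — from
pixel-level mass-spectrometry-imaging (MSI) data of bone-marrow biopsies to
cohort-level inference about progression from MGUS (monoclonal gammopathy of
undetermined significance) to multiple myeloma (MM).

## Who this is for

Groups analyzing MALDI-MSI sections of bone marrow (or any tissue with a
tumor-niche / microenvironment split) together with matched bulk fluid
metabolomics.  The package covers the full analysis chain and ships a
synthetic cohort generator with known ground truth, so every stage is
testable without patient data.

## What it computes

* **Niche segmentation.**  Pixel spectra are TIC-normalized, log-transformed
  and z-scored, then partitioned by bisecting *k*-means with the
  largest-within-cluster-SSE split rule (`BisectingKMeans`, an
  sklearn-compatible clusterer that exposes the split tree).  Plasma-cell-rich
  clusters are called from a marker feature set; the resulting niche pixel
  fraction is validated against pathology plasma-cell percentages via
  Pearson correlation on transformed scales
  (x = log10(fraction + 1e−4), y = logit(PC%)) and Spearman on the original
  scales.
* **Routed differential statistics.**  Per metabolite: Shapiro–Wilk
  normality → Brown–Forsythe variance gate → Student *t* / Welch *t* /
  Mann–Whitney U, Benjamini–Hochberg correction, volcano flags, and the
  tissue × plasma FC–FC classification into eight directional classes at
  |log2FC| ≥ 0.58 (a 1.5-fold change), with pathway tallies.
* **Proliferation coupling.**  Per-group correlations of niche metabolite
  means with the S-phase proliferation score, the segmentation-gain
  statistic Δ|ρ| = |ρ_niche| − |ρ_whole-marrow|, anchor-metabolite
  correlation-partner sets (|r| > 0.30) with hypergeometric pathway
  over-representation, pairwise pathway networks, and per-pathway
  regression-slope summaries.
* **Hill-number diversity (q = 2).**  ²D = 1/Σp², evenness E = ²D/K_eff,
  paired two-community β = ²D_γ / ²D_α,w between niche and
  microenvironment, Mann–Whitney group tests, Cliff's δ effect sizes, and
  an HC3-robust OLS of logit(evenness) on logit(PC%).
* **Multivariate structure.**  PCA scores with a deterministic sign
  convention, seeded one-way PERMANOVA (pseudo-F, R², add-one permutation
  p), per-cluster PLS-VIP rankings, and a Spearman-based monotone
  stage-trend screen (MGUS non-progressive → progressive → MM).

## Worked example

```python
import numpy as np
from nichemet import default_params, simulate_cohort, segment_section, concordance
from nichemet.diversity import subject_diversity

params = default_params(seed=7)
sections, subjects, truth = simulate_cohort(params)

fractions, pc = [], []
for sec in sections:
    seg = segment_section(sec, K=4, seed=7, markers=params.marker_features)
    fractions.append(seg.niche_fraction)
    pc.append(truth.pc_percent[sec.subject_id])

res = concordance(np.array(fractions), np.array(pc))
print(f"Pearson R = {res.pearson_r:.3f} (p = {res.pearson_p:.2e})")
print(f"Spearman rho = {res.spearman_rho:.3f}")

seg = segment_section(sections[10], K=4, seed=7, markers=params.marker_features)
row = subject_diversity(sections[10], seg)
print(f"{sections[10].subject_id}: 2D_niche = {row['d2_niche']:.2f}, "
      f"evenness = {row['evenness_niche']:.3f}, beta = {row['beta']:.3f}")
```

prints

```
Pearson R = 0.994 (p = 1.81e-18)
Spearman rho = 1.000
MM01: 2D_niche = 10.60, evenness = 0.177, beta = 1.129
```

The marker-called niche fraction tracks the planted plasma-cell burden
essentially perfectly on the synthetic cohort (each subject's ground-truth
fraction is the exact niche pixel count over total pixels), and the first
MM subject's niche profile is strongly dominated by a few metabolites
(²D ≈ 10.6 effective features out of 60, evenness 0.18) while diverging
from its surrounding microenvironment (β > 1).

The same stages are scriptable from a shell:

```bash
nichemet simulate --outdir data --seed 7
nichemet segment --pixels data/pixels/MM01.tsv --k 4 \
    --markers data/markers.txt --seed 7 --out seg
nichemet run-all --simulate --seed 7 --outdir run
```

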