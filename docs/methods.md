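# Methods

This note records the models, defaults, numerical choices and known
limitations behind `nichemet`.  It is the companion to the API docs: the
code states *what* is computed, this note states *why it is computed that
way* and what the synthetic validation does and does not demonstrate.

## The analysis model

The package treats a bone-marrow section as a grid of pixels, each a
vector of metabolite intensities, and a cohort as paired (tissue section,
bulk plasma profile, clinical metadata) triples per subject.  Three
scientific claims structure the pipeline:

1. the marrow of plasma-cell disorders contains a metabolically coherent
   plasma-cell-rich **niche** separable from the microenvironment by
   unsupervised clustering of pixel spectra;
2. progression from MGUS to MM rewires metabolism both inside the niche
   (differential abundance, proliferation coupling, monotone stage
   trends) and systemically (bulk plasma), with partially concordant
   directions across compartments (the FC–FC classification);
3. progression reorganizes the marrow ecologically: the niche profile
   becomes dominated by fewer metabolites (lower Hill-number evenness)
   and diverges from the microenvironment (higher paired β diversity).

## Segmentation

Pixels are scaled to unit total ion current (TIC), log1p-transformed and
per-feature z-scored within each section.  Bisecting k-means starts from
one cluster and repeatedly 2-means-splits the cluster with the largest
within-cluster sum of squared Euclidean distances — the most heterogeneous
region is refined first, the variant commonly used for MSI data.  Each
split uses k-means++ with 10 restarts (best SSE kept); per-split seeds
derive from one `SeedSequence`, so a run is deterministic given its seed.
`K = 4` per section is the default: niche, microenvironment, and two
spare clusters for section-specific structure (hemorrhage-like artifacts,
niche substructure).  `K` is configurable; no claim is made that 4 is
optimal for real tissue.

**Niche calling.**  Marker features (a curated plasma-cell marker panel in
real use; the planted niche markers in simulation) are scored as
per-feature z-scores of **raw** log intensities, deliberately *not*
TIC-scaled: marker abundance is the biological signal, and dividing by
total ion current couples it to unrelated high-abundance features (in MM
niches the dominance metabolites inflate the TIC and would suppress the
marker share).  Cluster mean marker scores are sorted and cut at their
largest gap; clusters on the high side are niche, provided the top mean
is positive, otherwise the niche set is empty and flagged.  The gap rule
matters in majority-niche sections: there the z-score center lies inside
the niche, so a flat "mean > 0" cut would drop true niche subclusters
produced by the SSE-first splitting.

**Concordance.**  Niche pixel fraction vs pathology plasma-cell
percentage uses Pearson on x = log10(fraction + 1e−4), y = logit(PC%)
(variance stabilization; the offset keeps zero fractions finite, mapping
them to exactly −4) and Spearman on the original scales.  Proportions
entering any logit are clamped to [1e−6, 1 − 1e−6].

## Differential statistics

Routing per metabolite: Shapiro–Wilk on each group at α = 0.05 (constant
groups are routed non-parametrically, since normality is undefined);
if both pass, Brown–Forsythe (Levene, median-centered) at α = 0.05
chooses Student vs Welch t; otherwise a two-sided Mann–Whitney U, exact
when both groups have n ≤ 8 and no ties, normal approximation with tie
correction otherwise.  The gate α levels are conventions, exposed as an
argument.  Identical data in both groups returns p = 1 with a degeneracy
flag rather than an error.

Fold changes are log2 ratios of raw intensity means (not means of logs):
the FC–FC axes then read directly as abundance ratios.  Tissue values
entering group tests are per-subject niche means — one value per subject,
never pixels, avoiding pseudo-replication.  Volcano significance requires
*both* BH q < α and |log2FC| ≥ threshold (default 0.58 = log2(1.5)
rounded to two decimals; both knobs in `AnalysisConfig`).  The FC–FC
classes partition the plane with inclusive thresholds (|log2FC| = t
counts as changed); negating both axes maps each class to its mirror.

## Proliferation coupling

Correlations are computed per caller-supplied group (diagnosis group by
default; the progressive-MGUS stage alone has too few subjects for a
stable correlation), each group requiring ≥ 4 subjects.  β1 is the slope
of proliferation on the z-scored metabolite, so β1 = r·sd(sphase) and
sign(β1) = sign(r) exactly — the per-pathway slope summaries therefore
agree with the correlation summaries by construction.  Partner sets
around an anchor metabolite use the Pearson threshold alone (default
0.30), no p filter.  Over-representation is a one-sided hypergeometric
upper tail against a background of metabolites *detected in the same
compartment*, which controls detection bias; the pathway level defaults
to sub-pathways (KEGG-style maps), with super-pathways as an option.

## Diversity framework (Hill q = 2)

Abundance profiles are compartment means of TIC-normalized pixel
intensities, renormalized to sum to one over the feature panel — always
non-negative quantities, never z-scores.  ²D = 1/Σp²; E = ²D/K_eff with
K_eff the count of strictly positive features (richness; if K_eff were
read as the panel size instead, E rescales by a constant per panel —
both readings are available since K_eff is reported).  Paired β =
²D_γ/²D_α,w pools the two profiles with pixel-count weights.

Two α-mean options exist because the pixel-weighted *arithmetic* mean of
the two ²D values — the most literal reading of a "count-weighted mean" —
is not a true α diversity: when the compartments' ²D values differ
substantially and weights are uneven, β can fall below 1.  The package
logs such occurrences and offers the weighted *harmonic* mean
(equivalently, the reciprocal of the weighted mean Simpson
concentration, Jost's q = 2 form), for which ²D_γ ≥ ²D_α by Jensen's
inequality and hence β ≥ 1 always.  The arithmetic form is the default
for fidelity to the headline definition; the harmonic form is what we
recommend for interpretation, and the acceptance script reports both.

Cliff's δ is oriented MGUS-vs-MM: δ < 0 means higher values in MM.  The
evenness regression is OLS of logit(E) on logit(PC%) with HC3
heteroskedasticity-consistent covariance and a two-sided t test
(df = n − 2) on the slope.

## Multivariate

PERMANOVA uses Euclidean distances on z-scored log2 means by default
(Bray–Curtis available for non-negative matrices), the Gower-identity
sums of squares, and add-one permutation p-values ((1 + #{F* ≥ F}) /
(1 + n_perm), never zero) with a seeded generator — 999 permutations by
default.  PCA components carry a deterministic sign (largest-magnitude
loading positive).  VIP scores come from one-vs-rest PLS (NIPALS, 2
components by default; the count is a convention, not fitted) with
VIP_j = sqrt(p · Σ_a SSY_a w_ja² / Σ_a SSY_a); mean squared VIP is 1 by
construction, asserted in tests.  The stage-trend screen uses Spearman ρ
against stage codes {0, 1, 2} (spacing irrelevant to ranks), BH across
metabolites, flags only *increasing* trends (ρ > 0), and has a strict
variant additionally requiring non-decreasing stage medians.

## The synthetic cohort

The generator emulates the study design the analysis assumes: 10 MGUS-like
and 10 MM subjects, one 64×64 section each, 60 metabolites.  Niches are
unions of random discs hitting an exact target pixel count (ground-truth
plasma-cell fraction = realized niche fraction, by construction), drawn
per subject from stage-dependent ranges — 3–7% for MGUS-like, 50–90% for
MM, matching typical marrow plasma-cell burdens.  Three MGUS subjects are
"progressive" (plasmacytoma-like): MGUS-sized niches carrying
intermediate-to-MM-level niche effects.

Intensities are log-normal: baseline (one decade of spread across
features) × 2^(effect) × noise, with pixel noise σ = 0.5 log2 units and a
subject-level biological effect σ = 0.35 log2 units shared between
compartments.  Planted structure: five niche markers (+2 log2 in every
niche; one, 3-HK-like, additionally trends with stage), a
tryptophan-like metabolite enriched in the microenvironment, five
monotone stage-trend features (+1 log2 per stage step in the niche), four
proliferation-coupled features whose coupling sign flips from negative
(MGUS stages) to positive (MM) — the nucleotide-reversal motif — and four
MM-dominance features (+4 log2 in MM niches) that produce the evenness
deficit and β divergence.  The baseline spread and dominance magnitude
were chosen together so that profile concentration is controlled by the
planted effects rather than by baseline luck, while preserving marker
contrast for niche calling.  Bulk plasma profiles are a convex
combination (weight 0.8) of the subject's niche mean and independent
log-normal noise; with weight 1 and no noise the bulk equals the niche
mean exactly.

Replicated power analyses (stage-trend detection, evenness deficit) use a
subject-level draw from the same generative model — compartment means
with subject-level variability only — because at 100+ replicates the
pixel-level sampling noise of compartment means is negligible next to
the subject effect and full grids would add cost without information.

**What the synthetic validation does not show.**  Real MSI sections have
spatially correlated noise, matrix effects, isotope interference and
imperfect annotation; niches are not disc unions; microenvironments have
their own substructure.  In particular the generator does not emulate
per-patient variation in microenvironment heterogeneity, so Simpson
indices of K = 6 segmentations are similar across synthetic MGUS
subjects, unlike the wide spread real cohorts show; the
`spatial_heterogeneity` output is validated for correctness, not for
realistic between-patient dispersion.  Passing the recovery tests shows
the estimators are consistent under the stated model, not that real
tissue satisfies that model.

## Problem sizes and determinism

Default analyses run on 20 sections × 4,096 pixels × 60 features;
replicated checks use 100 subject-level replicates and the null
calibration 1,000 two-group draws — sizes chosen so a full validation
pass completes in well under a minute on a single core while keeping
Monte-Carlo error small relative to every asserted margin.  All
randomness flows from one seed; per-stage seeds derive from it by fixed
offsets, so stages re-run in isolation reproduce their outputs, and
identical configurations give bit-identical simulated data.

## Known limitations

* Niche calling needs a marker panel; there is no unsupervised fallback,
  by design (an unmarked "most distinct cluster" rule would silently
  latch onto artifacts).  A manual label override is available via the
  segmentation result.
* The arithmetic β default can undershoot 1 (see above); interpretation
  of between-group β differences should use the harmonic option.
* `spatial_heterogeneity` at K = 6 and the VIP rankings are descriptive;
  no inferential guarantees are attached to them.
* The imzML → pixel-table path is out of the core surface; pixel tables
  are the interchange format.
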