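# Methods

`gxeprot` re-implements, as a tested library, the quantitative analysis of a
genotype × environment (G×E) study of the transferred *Drosophila
melanogaster* ejaculate proteome: 12 isogenic lines ("isolines") reared on
high- and low-quality larval diets, three biological replicates per
isoline × diet cell, 72 samples quantified across five 16-plex TMT
(tandem mass tag) experiments.  Because the deposited raw spectra cannot be
re-searched at desk scale, every analysis is exercised on synthetic data
with known ground truth; this note records the models, the defaults, and
the limits of what the synthetic route can show.

## Simulation model

The generator (`gxeprot.synth`) draws protein-level log2 reporter
intensities additively:

    log2 y_ps = mu_p + g_pi + (d_p + gamma_pi) * x_s + b_pk + l_s + e_ps

with protein *p*, sample *s*, isoline *i(s)*, plex *k(s)*; diet coded
x = +1/2 (high) and −1/2 (low) so that `d_p` is directly the high−low log2
fold change; `g_pi` (isoline) and `gamma_pi` (G×E) centered over isolines
within protein; `b_pk` a plex batch offset; `l_s` a sample-loading offset;
`e_ps ~ N(0, sigma²)`.  Observed intensity is `2^log2y`.  Missingness is a
whole-plex event per protein, drawn to match an exact partition of proteins
into complete / single-missing / multi-missing (defaults 2547 / 445 / 1336
of 4328 — the deposited study's identification marginals).

Default effect scales (log2 units): baseline N(14, 2²), isoline s.d. 0.5,
diet s.d. 0.1, interaction s.d. 0.25, batch s.d. 0.5, loading s.d. 0.25,
residual s.d. 0.25.  These are invented magnitudes chosen to give
isoline-dominated biological variation, a weak diet main effect, and batch
structure large enough that uncorrected data cluster by plex — the
qualitative regime the real study reports.  Named presets freeze the
conditions used in tests: `batch_only` (pure plex structure),
`isoline_dominant` (isoline 1.0 > interaction 0.5 > diet 0.1),
`diet_null` (diet s.d. 0 with weak interaction 0.1: isolines respond to
diet in opposite directions with no consistent across-isoline effect — the
structure the study actually observed), and `null` (no biological signal).

What the generator does *not* emulate: reporter-ion interference and
channel leakage, peptide-to-protein rollup, intensity-dependent missingness
(dropout here is completely at random at the protein × plex level),
per-protein variance heterogeneity, and correlated protein modules.
Passing tests therefore demonstrate correctness of the statistical
machinery under the assumed additive model, not robustness to those
real-data features.

Design packing enumerates samples in (isoline, diet, replicate) order and
deals them round-robin over ⌈72/16⌉ = 5 plexes, which places the three
replicates of every cell in three distinct plexes; channel numbers within a
plex are a seeded permutation standing in for an interference-aware layout,
whose exact published scheme is not reproduced.  All draws derive from one
seed through a splittable generator, so every fixture is bit-reproducible.

## Harmonization

`normalize_pipeline` applies, in order:

1. **Imputation / exclusion.**  A protein missing in exactly one plex has
   each missing cell filled with the mean of its same-diet samples in the
   other plexes (falling back to the overall cross-plex mean if a diet
   level is unobservable, and logging the protein); proteins missing in
   more than one plex are excluded.  On the default fixture this yields
   445 imputed, 1336 excluded, 2992 retained.  Imputation operates on raw
   intensities, before any normalization, matching the processing order of
   the source protocol.
2. **Sample-loading (SL) normalization** — each column rescaled to the mean
   column total of its plex (channels of a plex received nominally equal
   material).
3. **TMM scaling** on intensity proportions: doubly trimmed log-ratios
   (M-trim 0.30, A-trim 0.05) against the column whose upper-quartile
   proportion is closest to the mean, precision-weighted by the asymptotic
   inverse variance, factors rescaled to geometric mean 1.
4. **log2.**
5. **ComBat** — parametric empirical-Bayes location/scale batch adjustment
   with diet and isoline retained as covariates, hyperparameters by method
   of moments, joint fixed-point iteration to 1e-8.  The implementation
   matches Bioconductor `sva::ComBat` to ~1e-6 on identical input (tested
   via Rscript).

The stage order SL → TMM → log2 → ComBat is a deliberate choice: the
empirical-Bayes adjustment assumes approximately normal log-scale input,
so it runs last even though the procedure is conventionally named with
ComBat first.  The TMM reference-column rule and the parametric (rather
than non-parametric) ComBat variant are likewise documented defaults where
the source procedure is unspecified.

**Known limitation.**  After ComBat, per-protein t statistics have mildly
inflated extreme tails under a global null (the scale adjustment removes
denominator noise that the numerator retains).  At the 0.05 level the
effect is negligible, but minimum p-values over hundreds of proteins can
be several-fold too small.  This is a property of the method, not of this
implementation (the reference implementation reproduces it exactly).  The
calibration tests of the contrast module therefore run on simulations that
are normalized by construction; the batch-removal property of the pipeline
is tested on the PCA/ANOVA side, where it is the scientifically relevant
claim.

## Annotation

`assemble_datasets` intersects the detected proteins with the published
sperm-proteome (SpP) and seminal-fluid-protein (SFP, high-confidence plus
candidate) lists, removes proteins shared with the female reproductive
tract (FRT), and classes the remainder as SFP-only, SpP-only or dual; called
candidates extend the working dataset.  On the default overlap fixture this
reproduces the published 1284 → 648 → 699 chain with classes
140/433/75/51.

`call_candidates` keeps genes whose male:female whole-body log-ratio lies
strictly above the empirical 0.90 quantile of all genes in the expression
table, then splits them by the accessory-gland:testis log-ratio (strictly
beyond the 0.10 tails): gland-biased → SFP candidates, testis-biased →
sperm candidates.  Quantiles are computed over every gene in the atlas,
zeros are replaced by a 0.5 pseudocount, and boundary ties are excluded.
Whether the tissue filter should compare accessory gland against testis or
each tissue against all male tissues is ambiguous in the source; the
gland-vs-testis ratio reading is implemented.

## Diet contrasts

Per protein, `fit_contrasts` fits

    abundance ~ diet + isoline + (1 | replicate)

with sum-coded isolines.  Because the design is identical for every
protein, the random intercept is profiled analytically: one
eigendecomposition of the replicate incidence matrix is shared across
proteins, and REML reduces to a 1-D bounded search over the variance ratio
θ = σ²_rep/σ²_res; θ̂ = 0 recovers OLS exactly and doubles as the
degenerate-fit fallback (logged).  The Wald t for the high−low contrast
uses residual degrees of freedom (no Satterthwaite correction — a
documented, simpler convention).  Constant proteins return logFC 0, p 1.
p-values are Benjamini–Hochberg adjusted across retained proteins.
Optional limma-style variance moderation (moment-matched scaled-inverse-χ²
prior on residual variances) is available but off by default.

`directional_bias` builds the 2×2 class × sign(logFC) table (zero-logFC
proteins excluded and counted) and reports Pearson's chi-square without
continuity correction.  On the published direction counts
(105/35 vs 308/125) this gives χ²₁ = 0.79, p = 0.375; the source prints
χ²₁ = 3.07 with p = 0.38, which are mutually inconsistent for those
counts — the recomputed statistic is reported, with the printed p-value
confirming the recomputation.

## Variance decomposition

PCA is the SVD of the column-centered sample × protein matrix (proteins
are not rescaled: they already share the log2 scale; scaling is an
option).  Component signs are fixed deterministically.  Type-III ANOVA of
a PC score on diet × isoline uses sum-to-zero contrasts (type III is
ill-defined under treatment coding) and is cross-checked against
`car::Anova` on the study design, where the degrees of freedom are
(1, 11, 11, 48).

Partial ε² is `df1(F−1)/(df1·F+df2)`, floored at 0.  The confidence
interval inverts the noncentral-F CDF at the (1−conf)/2 tails for the
noncentrality λ (bisection to 1e-8) and maps λ/(λ+df1+df2+1).  The
interval is two-sided; the source's printed intervals mix conventions
(some upper bounds are pinned at 1.00, one-sided style) and are not used
as reference values — the point estimates reproduce all six published
PC1/PC2 effect sizes to two decimals.

Per-protein contributions are `100·loading²/Σloading²` with the
above-average flag at the uniform share 100/n.  Ward clustering implements
the Lance–Williams recursion for both variants — `ward.D` (raw Euclidean
distances into the recursion) and `ward.D2` (squared distances,
square-root heights; the default, equivalent to scipy's `ward`) — with
ties broken toward the lowest cluster-index pair.

## Enrichment

`gsea` ranks proteins by the diet-contrast t statistic (ties broken by ID
so the order is strict), computes the weighted running-sum enrichment
score (hits weighted |t|^w normalized to one, misses −1/(N−n)), and draws
a gene-label permutation null — sample-level permutation is unavailable
when only a ranked list is supplied.  The nominal p compares |ES| against
same-signed null scores with floor 1/(n_perm+1); NES divides ES by the
mean |null ES| of matching sign; BH runs across sets so both enrichment
directions are reported on one scale.  Set-size filters default to
[5, 500].  Gene sets are plain ID collections (GMT files supported); real
GO hierarchies are out of scope and synthetic sets with planted rank bias
stand in for them.

`contribution_enrichment` regresses contributions on a binary type
indicator; the slope equals the group mean difference, with the usual
t-test on n−2 degrees of freedom.

## Problem sizes and numerical conventions

Simulation-based tests use 200–1000 proteins per replicate and the full
72-sample design — sizes at which every tested property (type-I error
within Monte-Carlo bands, variance-ordering recovery in ≥ 18/20 seeds,
CI coverage within ±3%) is already stable.  Tolerances: TMM geometric mean
to 1e-9; ComBat fixed point to 1e-8; noncentrality bisection to 1e-8;
oracle equivalences to ~1e-10 relative.  Degenerate inputs (constant
proteins, single batch, empty classes, sub-minimum gene sets) return the
documented neutral results or raise named errors rather than propagating
NaNs.
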