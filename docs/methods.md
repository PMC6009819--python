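# Methods

`tagdnl` implements an inference chain for direct-infusion mass-spectrometry
(DI-MS) lipidomics of blood plasma, centred on the observation that the
triacylglycerol (TAG) species of a plasma lipidome split into co-regulated
clusters, one of which — TAGs carrying saturated and monounsaturated
16–18-carbon fatty acids (≈46–52 total acyl carbons, 0–2 double bonds) — is
the signature of hepatic de novo lipogenesis (DNL) and of hepatic steatosis.
The package provides the full chain from raw intensity tables to that
conclusion: QC-pool batch normalization, clustering-tendency testing,
Bayesian hierarchical clustering, OPLS-DA discrimination with its validation
suite, clinical indices, deuterium-tracer DNL kinetics and covariate-adjusted
association scans, all exercised on a synthetic cohort generator that plants
the structure each stage is supposed to find.

## QC-pool normalization

DI-MS intensity drifts between analytical plates. Pooled-QC injections
(aliquots of one pool run repeatedly on every plate) carry only technical and
batch variation, so each plate is rescaled by

    factor(plate) = grand mean QC total intensity / plate mean QC total,

applied to all samples on the plate. The correction uses the *total* QC
intensity, not per-feature factors — a deliberately simple normalization that
preserves within-plate intensity ratios exactly and is idempotent. Precision
is reported as the per-feature coefficient of variation over QC rows
(sample SD / mean, n−1 denominator); features with any missing value are
dropped at ingestion rather than imputed, and a feature with zero QC mean has
undefined CV and is reported as such.

## Scaling

Multivariate models use mean-centring plus Pareto scaling
((x − mean)/√SD), the convention for MS intensities: it shrinks the dominance
of intense species without amplifying noise features the way unit-variance
scaling does. Scaling parameters are stored and re-applied to held-out data.
Zero-variance features are dropped (with a warning), not zero-filled, so the
NIPALS iterations stay well-posed.

## Clustering tendency (Hopkins statistic)

H = Σu / (Σu + Σw), where u are nearest-neighbour distances from m uniform
probes (drawn in the axis-aligned bounding box of the data) to the data and w
are nearest-neighbour distances of m sampled real points to the remaining
data (Euclidean metric, seeded sampling). H ≈ 0.5 indicates spatial
randomness; H → 1, clustering. The no-structure null is rejected for
H > 0.6799 (a conventional 95% threshold; it is approximate and applied
regardless of m). Defaults: m = min(⌈0.1·n⌉, 50). Per lipid class the
statistic is computed over *features*: species are points, Pareto-scaled
samples are dimensions, so it asks whether a class contains co-regulated
sub-groups. Classes with fewer than 5 species are reported "not testable".
Degenerate all-identical data return H = 1 with a warning. Complete-linkage
hierarchical clustering and seeded best-of-restarts k-means are provided as
conventional references (via scipy/scikit-learn).

## Bayesian hierarchical clustering (BHC)

Features are clustered by greedy agglomeration under a Dirichlet-process
mixture prior. For a candidate merge of subtrees i and j into k
(n_k members, concentration α):

    d_k  = α·Γ(n_k) + d_i·d_j              (leaves: d = α)
    π_k  = α·Γ(n_k) / d_k
    p(D_k|T_k) = π_k·p(D_k|H1) + (1−π_k)·p(D_i|T_i)·p(D_j|T_j)
    r_k  = π_k·p(D_k|H1) / p(D_k|T_k)

p(D|H1) is the marginal likelihood that all members form one Gaussian
cluster under a Normal-Inverse-Wishart prior. The pair with the highest
merge posterior r_k is merged at each step (ties broken on lowest feature
index, for determinism); everything is computed in log space. The root
p(D|T) provably equals the DP-weighted sum of marginal likelihoods over all
partitions *consistent with the tree*, which the tests verify by exhaustive
enumeration for n ≤ 5.

Hyperparameters are set by empirical Bayes: prior mean = data mean, prior
scatter = diagonal of the data covariance, κ₀ = 1, ν₀ = d + 2. When the
dimensionality (number of samples) is not below the item count — the usual
case when clustering a few dozen species over hundreds of subjects — the
full Wishart normalizer is ill-posed for an empirical scatter, and the prior
automatically switches to its diagonal Normal-Inverse-Gamma factorization
(per-dimension ν₀ = 3), flagged on the prior object. α defaults to 1.0;
increasing α raises the prior probability of many clusters (a tested
monotone trend).

Flat clusters come from descending from the root and splitting every node
with r_k < 0.5 — the point where the posterior favours a split. The input is
the TAG-percent matrix (each TAG as % of the sample's total TAG signal, so
profiles are compositional and not dominated by total lipemia), Pareto
scaled. Cluster summaries report mean carbons, mean double bonds and the
fraction of low-unsaturation species (total double bonds ≤ 2); the "DNL
cluster" label goes to the cluster with the lowest mean double-bond count
among clusters with mean carbons in 44–56 (all clusters as fallback).

## OPLS-DA and validation

Binary class membership (y ∈ {0,1}, centred) is modelled after Trygg–Wold
orthogonal filtering: per orthogonal component, with w ∝ X'y (unit norm),
p = X't/(t't), w_o ∝ p − (w'p)w; the orthogonal score t_o = X·w_o and its
loading are removed from X. A single predictive component is then fitted on
the filtered matrix. Reported statistics:

* R²X, R²Y — fractions of (scaled) X and y variation captured;
* Q² — predictive ability from k-fold cross-validation of the *entire*
  procedure, scaling re-estimated inside every training fold; folds are
  stratified venetian blinds on a seeded shuffle (deterministic per seed);
  default 7 folds. "Auto" component selection adds orthogonal components
  while Q² improves by > 0.01 (an explicit, documented stopping rule);
* random label-permutation test (default 200 permutations, identity
  permutations redrawn): passes when every permuted Q² falls below the true
  Q² and the intercept of permuted Q² regressed on |corr(y_perm, y)| stays
  below the true Q²;
* CV-ANOVA on the cross-validated residuals:
  F = ((SSY − PRESS)/A) / (PRESS/(n − A − 1)) with A = 1 + n_ortho model
  components. Degree-of-freedom conventions for CV-ANOVA differ between
  published descriptions; the one used is reported with the output, and
  PRESS ≥ SSY yields F ≤ 0 with p = 1.

S-plots report, per feature, cov(t, x_j) against corr(t, x_j) on the scaled
training matrix; features with zero variance are excluded with a note. New
samples are scaled with the training parameters, orthogonal-filtered with
the training loadings and scored; class calls use the midpoint of the
training class score means, and ROC/AUC are computed on the continuous
scores. Multi-class problems use standard PLS-DA (dummy-coded Y via
scikit-learn's NIPALS PLS) with VIP scores,
VIP_j = √(p·Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a), whose squared mean over
features is 1 by construction. PCA is NIPALS with deflation, truncating at
the matrix rank with a warning.

## Clinical indices

Fatty liver index (logistic score, 0–100):
L = 0.953·ln(TG mg/dL) + 0.139·BMI + 0.718·ln(GGT) + 0.053·waist − 15.745,
FLI = 100·eᴸ/(1+eᴸ); triglycerides in mmol/L are converted with
88.57 mg/dL per mmol/L, and FLI ≥ 60 labels steatosis. Ultrasound labelling
takes liver scores 5–10 as steatosis and 3–4 as none (scores outside 3–10
are rejected). HOMA-IR is the classic HOMA1 formula glucose(mmol/L) ×
insulin(mU/L)/22.5 with pmol/L → mU/L by ÷6.945; the calculator-based HOMA2
is out of scope and noted as such. Group summaries use the Welch
(unequal-variance) two-sided t-test — a deliberate choice where a plain
Student test would also be defensible.

## DNL kinetics

With drinking water enriched to a steady body-water deuterium fraction
(~1%), newly made palmitate incorporates deuterium at up to 22 exchangeable
positions (the standard mass-isotopomer convention for C16:0; exposed as a
parameter since laboratories differ). The precursor–product simplification
gives per timepoint

    fractional synthesis = palmitate enrichment
                           / (body-water enrichment × 22),

and FSR (%/h) is 100× the OLS slope of that fraction over the 1–4 h window
where incorporation is linear — a regression over the window rather than a
two-point difference, which is less noise-sensitive. Slope SE and R² are
reported; a negative estimate (possible under noise) is flagged rather than
clamped. De novo palmitate mass is fraction × pool size. The cluster–DNL
link is a simple OLS of the summed cluster signal on the DNL measure with a
two-sided slope test. Full mass-isotopomer distribution analysis (spectral
M+1/M+2 correction) is out of scope.

## Association scans

Individual TAG markers are tested against the ordinal ultrasound score by
proportional-odds (cumulative-logit) regression — statsmodels' OrderedModel
fitted by BFGS, convergence at relative log-likelihood change < 1e-8 within
500 iterations — or against the continuous FLI by OLS. Markers enter as
standardized log intensities, so estimates are per-SD log-odds (or betas).
Every model includes the base adjustment: analysis batch as a fixed
categorical (a modelling choice; a random effect would also be defensible)
plus total TAG. Additional adjustment sets (insulin resistance, adiposity,
lifestyle, genotype) are compared through the attenuation report,
(β_adj − β_base)/|β_base| × 100. Suspected separation is flagged, not fatal;
failed cells are flagged per cell. Nominal p-values are reported (no
correction is applied to the primary estimates) with a Benjamini–Hochberg
column alongside for transparency.

## The synthetic cohort generator

The generator is first-class, tested code: its defaults define the study
conditions every acceptance property is evaluated under.

* **Scale.** 1507 subjects on 19 plates with 5 pooled-QC injections per
  plate; ultrasound-steatosis prevalence 0.26.
* **Features.** 75 annotated species (6 LPC, 14 PC, 6 PE, 6 SM, 6 CE, 6
  DAG, 31 TAG) with log-normal intensities (DI-MS ion counts are positive
  and right-skewed); class-specific base log-means with per-feature jitter.
* **TAG clusters.** Three planted clusters — DNL (11 saturated/monounsat.
  46–52 C species), polyunsaturated (12 long-chain species), short-chain
  (8 species) — each driven by one latent factor per cluster (loading 0.8)
  plus feature log-noise of SD 0.35, giving within-cluster correlations
  near 0.84, a realistic figure for co-regulated plasma TAGs and the
  simplest structure both the Hopkins statistic and BHC can detect. Cluster
  shares of total TAG intensity are calibrated to their expected values
  (default 0.30/0.46/0.24; shares summing below 1 allocate the remainder to
  four unclustered background TAGs). DAGs co-vary with the TAG latents
  (loading 0.5).
* **Steatosis signal.** Steatotic subjects carry a 3.0-fold elevation of
  the DNL-cluster TAGs. The fold was derived from the cohort-description
  arithmetic: with the cluster at ~30% of TAG signal, 0.7 + 0.3×3.0 ≈ 1.6
  reproduces the observed fasting-TAG ratio between groups (1.70 vs
  1.03 mM). Steatosis also multiplies PC and CE intensities by 0.85 (their
  described relative decrease in fatty liver), parameterized as a power of
  the steatosis effect so the null case (effect = 1) removes every group
  difference. Part of the TAG elevation is mediated: the multiplier carries
  components in within-group-centred log-HOMA (0.30/SD), a risk-genotype
  dosage (0.15/allele) and free-sugar intake (0.08/SD), plus
  marker-specific components — TAG(46:1)/(46:2)/(48:2) load on insulin
  resistance and TAG(48:1)/(50:1)/(52:1) on waist (0.25/SD). Within-group
  centring makes effect = 1 an exact null while adjustment for a mediator
  still attenuates marker associations.
* **Covariates.** Age, sex, BMI, waist, glucose, insulin, total TAG and GGT
  are drawn from group-conditional distributions matching the cohort
  description table (log-normals for the right-skewed analytes); liver
  scores are 3–4 (non-steatotic, mean 3.66) or 5–10 (steatotic, mean ≈ 6.1);
  three binary SNP dosage columns and two dietary covariates are included.
* **Technical structure.** Mean-one log-normal plate factors (log-SD 0.13)
  and technical noise of CV 0.11 on every injection; QC rows are replicates
  of the pooled subject mean carrying only plate and technical variation.
  Together these reproduce a pre-normalization mean QC CV near 17% falling
  to ~11% after plate correction.
* **Tracer.** Palmitate enrichment = FSR/100 × body-water enrichment × 22 ×
  t plus Gaussian noise (SD 2e-4), 9 half-hour timepoints, body water
  steady at 1%, planted FSR 4.41 %/h.
* **Mouse livers.** Two diet groups (n = 8 default): each animal's de novo
  palmitate is log-normal with the western-diet group shifted by
  `diet_effect` (default 1.1 log units); DNL-cluster intensities scale
  proportionally with the animal's palmitate (animal-level log-noise 0.15,
  calibrated so the cluster-sum regression reproduces R² in the 0.8–0.95
  range at n = 16), the polyunsaturated cluster declines with DNL
  (slope −0.5 in logs) and the short cluster is unrelated. `diet_effect=0`
  removes all group structure.

What the generator does **not** emulate: raw spectra, isotope envelopes or
adduct structure; missingness and limit-of-detection censoring; correlated
technical drift within plates; non-Gaussian latent structure or more than
one factor per cluster; longitudinal sampling. Tests passing on this
generator therefore demonstrate that the estimators recover the structure
they target under a faithful but idealized noise model — not that any
particular clinical cohort will show the same effect sizes.

## Numerical choices and degenerate inputs

Log-space throughout BHC (logaddexp / log1mexp); merge posteriors can
round to 0 or 1 in double precision even though they are strictly interior,
so invariants are checked on the finite log posterior. Hopkins returns H = 1
with a warning for all-identical data and rejects m ≥ n. The OPLS auto rule
caps orthogonal components at 5; CV folds that would lose a class raise
immediately. OLS/ordinal fits flag rather than fail on separation;
convergence criteria are stated above. Seeds: every stochastic routine takes
an explicit integer seed and is bit-reproducible given it.

## Problem sizes in the test and acceptance runs

The test suite exercises the full default cohort (1507 × 75) where the
claim concerns the study scale (S-plot extremes, transfer AUC) and reduced
cohorts (200–600 subjects, 4–6 plates) for repeated-seed properties
(50-seed BHC recovery, 25-seed per-class Hopkins), chosen so the complete
suite runs in about a minute while keeping every Monte-Carlo margin wide.
`scripts/acceptance.py` regenerates everything at the default scale from a
single seed in a few seconds.

## Known limitations

* The Hopkins critical value 0.6799 is used verbatim irrespective of m and
  dimensionality; no null-distribution p-value is computed.
* BHC uses the greedy tree, not sampling over trees; the diagonal prior
  ignores inter-sample covariance when d ≥ n.
* CV-ANOVA degrees of freedom follow one of several published conventions.
* The FSR formula is the precursor–product simplification, not full MIDA.
* Cohort-scale multivariate statistics (R²/Q², AUC and the like) on
  synthetic data characterize the implementation, not any real population;
  only their qualitative regime is meaningful.
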