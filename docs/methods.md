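# Methods

This note documents the statistical model behind each stage of
`phenoscreen`, the defaults and why they were chosen, what the synthetic
data do and do not emulate, and the numerical conventions.

## Experimental design model

All analyses assume a factorial phenotyping design: *g* genotypes × *s*
watering environments (non-stressed, stressed) × *r* replicates, long-format
records `(genotype, environment, replicate, trait, value [, day])`. The
design summary reports the modal cell count as *r* (ties resolved toward the
larger count so short cells are flagged) and a `balanced` flag that is true
iff every genotype × environment × trait cell holds exactly *r* non-missing
values. The package's reference scale is g = 16, s = 2, r = 3 (96
observations per trait, 24 traits).

## Derived quantities

* Stress-response index: `(x̄_s − x̄_ns)/x̄_ns × 100` on population (or,
  via `genotype_stress_index`, per-genotype) means. Undefined for a zero
  control mean; full precision is kept internally and tabular output rounds
  to 2 d.p. only for presentation.
* PSII yield: `YII = (F_max − F_ground)/F_max`, the conventional Fv/Fm
  form, bounded in [0, 1]. Field instruments occasionally label the two
  fluorescence levels inconsistently; the implementation validates
  `0 ≤ F_ground ≤ F_max` rather than trusting labels.
* Soil volumetric water content is scaled m³/m³ → percent; peroxisome
  fluorescence is re-expressed per 1 mg extracted protein; time-course
  values are folds relative to a positive non-stressed baseline.

## ANOVA, variance components, heritability

Per trait, a balanced fixed-effects ANOVA is computed by mean
decomposition (genotype, environment, interaction, residual; every F tested
against the residual mean square). Variance components come from the
expected mean squares by the method of moments — the manual route used in
plant breeding rather than REML — because it is exactly testable against a
closed form and matches how broad-sense heritability is conventionally
derived from ANOVA tables:

    σ²e  = MS_res
    σ²ge = (MS_G×E − MS_res)/r
    σ²g  = (MS_G − MS_G×E)/(s·r)        (two-way)
    σ²g  = (MS_G − MS_res)/r            (one-way, single environment)

Negative moment estimates are truncated to zero and recorded in
`truncated`; truncation is what produces H = 0 entries for traits that
stress flattens (e.g. soil water at the wilting point). Heritability is
reported in percent on a genotype-mean basis:

    H = σ²g/(σ²g + σ²ge/s + σ²e/(s·r))   combined across environments
    H = σ²g/(σ²g + σ²e/r)                within one environment

Here *r* is replicates per environment. The per-environment formula is the
single-environment analogue needed to compare H under control vs stress;
the F-tests treat all factors as fixed while H treats genotype as random —
both uses are standard and are kept separate in the code. Missing-data
policy: a trait with unequal cell counts is analyzed on its largest
balanced subset (r reduced to the minimum cell count, lowest replicate
numbers kept, with a warning); below two replicates per cell the analysis
errors rather than guessing. H is invariant to affine rescaling of the
trait, which the suite checks.

## Correlation and PCA

Correlations are pairwise-complete Pearson coefficients over a wide
observations × traits matrix; the default observation unit is genotype ×
environment cell means (32 rows at reference scale) because replicate-level
rows mix within-cell noise into between-genotype structure; replicate level
is available. p-values use the t transform `t = r√((n−2)/(1−r²))` with
n − 2 df; |r| = 1 maps to p = 0; pairs with fewer than 3 complete
observations or a constant trait are reported missing, never 0. Signed r is
primary; an r² companion column is emitted for comparison with reports that
print squared (but signed) coefficients.

PCA is a classical eigendecomposition of the covariance matrix of
trait-mean-imputed, centered and (by default) z-scored data — standardizing
because the panel mixes cm, %, counts and fluorescence units. All
components are kept, so variance explained sums to 100 % and
`scores @ loadingsᵀ` reconstructs the processed data exactly; the sign
convention makes the largest-magnitude loading of each component positive.
No robust covariance pre-estimator is fitted by default; the decomposition
accepts any precomputed wide matrix, which is the hook for one.

## ROC sensitivity

The positive class is the stressed group. AUC is the midrank Mann–Whitney
statistic computed from ranks in O(n log n); the stepwise ROC curve over
unique thresholds starts at (0,0), ends at (1,1), and its trapezoidal area
equals the rank AUC exactly (ties contribute diagonal segments worth half
credit). Orientation defaults to `auto` — scores are flipped per trait so
the stressed empirical mean is the higher one — because a screen mixes
stress-suppressed and stress-induced traits; note `auto` fixes the sign of
the mean shift, not the rank order, so AUCs marginally below 0.5 remain
possible for skewed traits. Category-level AUC defaults to the AUC of the
first principal component of the member traits (z-scored, replicate level);
an arithmetic-mean alternative is provided. ROC observations default to
replicate level (48 per group at reference scale).

## Trait reduction

Each trait's robustness is a convex combination of four min-max-normalized
criteria: H under stress, AUC, |r| with a reference yield trait (default
grain weight), and the positive part of the H gain under stress (a trait
whose heritability rises under stress is especially selection-worthy).
Default weights 0.3/0.3/0.2/0.2 equalize the two dominant criteria
(heritability and sensitivity) and are fully configurable; they are
surfaced in output metadata because any such weighting is a modeling
choice, not an estimate. With internal min-max bounds the score depends on
the trait set; callers can fix external bounds per criterion to make scores
set-independent (the suite tests both behaviors). Pruning is greedy in
descending robustness: a trait is dropped if |r| with an already-kept trait
reaches the redundancy threshold (default 0.8), recording the kept proxy —
the "one representative per correlated yield cluster" practice. Ties in
robustness break alphabetically for determinism.

## Comparative-Ct expression

Fold changes use the 2^−ΔΔCt model with amplification efficiency fixed at
2 per cycle (no efficiency-corrected mode). Averaging order — technical
replicates on the Ct scale, biological replicates on the ΔCt scale — is the
common practice when three technical replicates nest in each biological
one. The calibrator is the same genotype, same day, non-stressed sample, so
calibrator cells are exactly 1 by construction; a shared housekeeping
offset cancels identically. Missing housekeeping or calibrator
measurements raise errors rather than propagating NaNs.

## Synthetic data

`simulate_trait` draws `y_ijk = μ + env_j + G_i + GE_ij + e_ijk` with
independent Gaussian components, so the implied heritability is known in
closed form and recovery is testable (the suite checks that over 500
Monte-Carlo replicates at g = 16, s = 2, r = 3 with σ²g = 4, σ²ge = 2,
σ²e = 6 the mean estimated H sits within 5 points of the true 66.67 %).
The environment effect is a fixed per-trait shift (no environment variance
term), mirroring a controlled withholding-water treatment.

The default catalogue (`data/trait_catalogue.yaml`) encodes the 24-trait
screen's published population means ± SDs per environment. Reported SDs
conflate genetic, G×E and residual variance; the catalogue splits the
pooled squared SD 50 % genetic / 10 % G×E / 40 % residual, a fixed choice
giving implied combined heritabilities near 81 %, in the range typically
reported for such panels. Tiller-count means are not reliably reported for
this design, so a count consistent with the spike-number scale and the
observed ~62 % reduction is used. Ordinal rating scales (survival,
recovery; 1–10) are clipped and rounded after noise; clipping and rounding
bias means and shrink variances slightly, which is why exact
mean-recovery checks use unbounded traits. Between-trait correlation is
injected through a single shared genotype latent factor with per-trait
loadings — enough to exercise redundancy pruning, not a full covariance
model. What the generator does not emulate: non-Gaussian trait
distributions, heteroscedasticity across genotypes, spatial/temporal
nuisance effects, genotype-specific stress trajectories in the population
table, or missing-data patterns of real screens; passing recovery tests
therefore demonstrate correctness of the estimators under the assumed
model, not robustness to real-data pathologies.

Time-course defaults encode two contrasting 14-day drought trajectories
(piecewise-linear anchors, multiplicative lognormal noise): a tolerant
genotype with early peroxisome proliferation (peak ×2 around day 4, phase
II) and stable water status, and a susceptible one with a late surge
(phase III) while relative water content, stomatal conductance and root
growth collapse. Phase boundaries default to I = days 1–2, II = 3–8,
III = 9–14. The qPCR generator inverts the comparative-Ct model
(`Ct = ct_base − log2(fold) + noise`), so zero-noise round-trips recover
folds exactly — bit-exactly for power-of-two folds, to 1e-12 otherwise.

## Numerical conventions

Balanced sums of squares are computed from cell/marginal means in float64;
the suite pins them to an explicit brute-force decomposition at 1e-9
relative tolerance and to an independent OLS ANOVA. Seeds are explicit
everywhere; multi-trait simulation derives per-trait child seeds from a
seed sequence so tables are bit-reproducible. Problem sizes used in the
test suite (500 ANOVA Monte-Carlo replicates, 100 random ANOVA tables, 200
ROC instances, 200 noisy qPCR round-trips) keep the full run under a
minute on one CPU while leaving Monte-Carlo error well inside the asserted
tolerances.

## Known limitations

Unbalanced designs beyond the largest-balanced-subset policy need a
mixed-model (REML) treatment that is deliberately out of scope, as are
narrow-sense heritability, post-hoc multiple comparisons, efficiency-
corrected qPCR, and plot rendering (all outputs are matrices/tables).
Category AUC composites and the robustness weighting are structural tools:
their absolute values depend on documented conventions (PC1 composite,
min-max bounds) and should be compared only within a fixed convention.
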