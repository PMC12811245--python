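# Methods

`dmnec` implements a complete analysis chain linking directed default-mode-
network (DMN) connectivity to antidepressant treatment response: synthetic
multi-site cohort generation, stationarity screening, order-1 Granger-causal
effective connectivity (EC), ComBat site harmonization, mixed-model group
contrasts, and SVM/SVR treatment-response prediction. This note records the
models, the parameters that matter, and the design choices made where the
design was genuinely open.

## Synthetic cohort generator

Real multi-site clinical rs-fMRI data are access-restricted, so every stage
runs against a generator that reproduces the statistical structure the
analysis assumes.

**ROI dynamics.** Each subject's 33-ROI signal is a first-order vector
autoregression

    x_t = Aᵀ x_{t−1} + drift·t + ε_t,   ε_t ~ N(0, σ²I),

simulated past a 100-step burn-in (any stationary initialization suffices;
the recorded series starts in the stationary regime). `A[i, j]` is the lag-1
influence of ROI i on ROI j. Defaults: 200 timepoints (a typical resting-
state acquisition length), unit noise SD, self-coupling 0.3 on the diagonal.
With zero drift the generator enforces spectral radius < 1 and refuses
explosive systems. A nonzero per-ROI `drift_slope` produces non-stationary
series for exercising the screening stage.

**Directed mPFC→PCC structure.** The 12×11 block of `A` from the medial-
prefrontal ROIs to the posterior-cingulate ROIs is set per subject to

    base (0.15) + group delta + covariate terms + γ_site
    + δ_site · η_subject,   η ~ N(0, 0.1),

plus N(0, 0.02) per-connection jitter. Because group, covariate and site
effects enter through the coupling itself, the *estimated* EC inherits them
— additive site shifts and multiplicative site scales on the EC scale, which
is exactly what the harmonization model assumes. Covariate slopes default to
−0.001/year of age, +0.01 for male sex, and −0.1 per mm of mean framewise
displacement. A group delta of `d × 0.1` injects approximately a Cohen's d
standardized difference on mean block EC (subject-level coupling dispersion
dominates the mean-EC variance; estimation noise biases the realized d
slightly toward zero, well inside the recovery bands used in testing).

**Site magnitudes are free parameters.** No per-site EC variance is
available to calibrate against; defaults (shifts of ±0.01–0.05, scale
factors 0.9–1.2) are chosen so that site structure is clearly detectable
before harmonization (site R² on mean EC of a few percent) without dwarfing
the biological effects.

**Treatment outcomes.** For treated subjects the HAMD-17 change
Δ = pre − post is generated by a Gaussian copula: baseline mean EC is rank-
transformed to normal scores z_e, and

    Δ = μ_Δ + σ_Δ (ρ z_e + √(1−ρ²) ζ),   ζ ~ N(0,1),

with σ_Δ = 6 (typical dispersion of HAMD change) and μ_Δ calibrated so that
P(Δ ≥ pre/2) equals the configured responder fraction (default 213/315)
under the baseline moments (pre ~ N(22, 5²), clipped to [5, 52]). Post
scores are clipped to [0, 52]. The rank link makes the construction
distribution-free in EC; clipping and the pre-score variability attenuate
the realized Pearson correlation to about 0.92·ρ (e.g. a configured ρ = 0.6
realizes r ≈ 0.55 at n = 300), which the testing bands account for.

**What the generator does not emulate:** hemodynamics and measurement
filtering, spatial ROI geometry, nonlinear or non-Gaussian dynamics,
site-specific acquisition artifacts beyond location/scale, longitudinal
post-treatment scans, and item-level HAMD structure. Tests passing on this
generator demonstrate correctness of the estimators under their assumed
model, not clinical validity on real data.

## Stationarity screening

Each ROI series is screened with an augmented Dickey-Fuller test (constant
term, augmentation order chosen by AIC up to the Schwert bound
⌊12(T/100)^¼⌋, candidate orders compared on a common sample, MacKinnon
response-surface p-values). The standard decision rule is used: rejecting
the unit-root null supports stationarity. Series failing the screen at
α = 0.05 are first-differenced and re-tested, up to twice; all series are
then truncated from the front to the common length (loss ≤ 2 timepoints).
A subject with a still-non-stationary series is excluded with a logged
reason. The implementation is self-contained so an independent reference
(statsmodels `adfuller`) can serve as a cross-implementation oracle in the
tests; the two agree to numerical precision on identical settings.

## Effective connectivity

EC from ROI x to ROI y is the signed lag-1 path coefficient b in the OLS
regression (both series demeaned, intercept retained)

    y_t = c + a·y_{t−1} + b·x_{t−1} + e_t.

Signed coefficients are the primary output because connectivity *reductions*
are meaningful signed effects; a restricted-vs-full variant — the log ratio
ln(RSS_r/RSS_f) with its F test on (1, T−4) df — is available for
significance-style analyses and is calibrated (null rejection ≈ 5 % at
α = 0.05). Bivariate rather than conditional multivariate estimation is
deliberate: the downstream summary is the arithmetic mean of the 132
individual mPFC→PCC path coefficients, so each connection is estimated
per pair. Constant and collinear inputs are rejected with named ROI pairs.

## ComBat harmonization

For subject j at site i, feature g:

    y_ijg = const_g + x_jᵀβ_g + γ_ig + δ_ig ε_ijg,

with covariates x = (age, sex, motion) — deliberately excluding diagnosis
and education, which belong to the inference stage. Location (γ) and scale
(δ) per site are stabilized by parametric empirical Bayes (normal prior on
γ, inverse-gamma on δ², prior moments pooled across features, fixed-point
iteration to 1e-6, ≤ 200 iterations), and the harmonized value is

    y* = (y − const − xᵀβ̂ − γ̂)/δ̂ + const + xᵀβ̂.

Defaults harmonize the 132 connections jointly (the prediction stage
consumes per-connection features; 132 features give the EB priors something
to pool over); a scalar-mean mode exists. With a single feature the
across-feature prior moments are degenerate, so the univariate path uses
the unshrunk per-site estimates. Identifiability: γ and δ are defined
relative to the pooled mean and variance, so γ̂ is reported in data units
(grand-mean-centred) and δ̂ as the site-to-pooled SD ratio; only contrasts
between sites — differences of γ̂, ratios of δ̂ — recover constructed site
effects. The implementation reproduces the reference Bioconductor
implementation (`sva::ComBat`, parametric priors) to ~1e-8 RMS; the test
suite asserts 1e-3.

## Group inference

The group contrast is the linear mixed model

    y ~ 1 + Group + Age + Sex + Education + Motion
        + (1 | Site) + (Group | Site),

fitted by maximum likelihood with a freely-estimated intercept–slope
covariance; the t statistic of the Group fixed effect is referenced to a
residual-df t distribution (df = n − 6) and converted to an effect size by

    d = T (n₁ + n₂) / (√df √(n₁ n₂)).

Two-group contrasts retain only sites with more than 10 subjects per group.
The subgroup contrasts (episode status, medication status, illness-duration
terciles at the fixed 3- and 24-month bounds, boundary values inclusive)
swap the Group variable in both the fixed and random parts. Fitting uses a
small multi-start over optimizers keeping the best converged likelihood;
without it, roughly a quarter of random-slope fits at 10 sites stall. On
non-convergence the random slope is dropped (flagged); single-site data
fall back to OLS (flagged).

**Known calibration properties.** With few sites and weak slope
heterogeneity, the ML estimate of the random-slope variance is boundary-
truncated and overshoots on average, inflating the Wald SE. Two measurable
consequences, both quantified by the test suite's simulations: the type-I
error rate sits at the conservative edge of nominal (≈ 0.026–0.033 at 10
sites, 40/site/group), and the recovered d is attenuated by roughly 8 %
toward zero at any n for fixed site count. Residual-based df (rather than
Satterthwaite) is retained deliberately — it mirrors the common default of
the mixed-model tooling this analysis emulates — and the attenuation is
small relative to the recovery tolerances used.

Also provided: classical paired pre/post t (df = n−1, d = mean/SD of the
differences; identical pairs return t = 0, p = 1, while a nonzero constant
difference is an error), Pearson correlation with t-based p, the responder
rule (reduction ≥ 50 % of the pre score; pre ≤ 0 is an error), and a Welch
two-sample test for responder vs non-responder EC changes (group sizes are
typically unequal).

## Treatment-response prediction

**Classification.** Within every training fold: z-scoring, recursive
feature elimination from 132 to 38 connections, linear SVM (C = 5, balanced
class weights). RFE refits an L1-regularized linear model each round
(logistic regression with the liblinear solver — deterministic and fast
enough for the ~94 refits per fold) and drops the single lowest-|weight|
feature, ties resolved by dropping the lowest column index. Stratified
5-fold splits, 100 repeats by default; accuracy, AUC (rank statistic over
decision scores), sensitivity, specificity, f1 and MCC (zero-denominator
convention: 0) are averaged over folds then repeats. The permutation test
shuffles labels and reruns the full pipeline — selection included — per
shuffle; p is the proportion of permuted accuracies strictly exceeding the
observed one (the strict-inequality convention, not (k+1)/(n+1)).

**Regression.** Linear-kernel SVR (C = 9, ε = 0.1) on the same within-fold
scaling and RFE (Lasso weights, α = 0.01); Pearson r, MAE and RMSE are
computed on pooled out-of-fold predictions (pooling is the stabler choice
at n ≈ 138).

**Per-fold vs global selection.** Selection inside the training fold is the
leakage-safe default. A "global" mode that selects the 38 connections once
on the full sample before cross-validation is kept as an explicit
replication flag, because the two variants differ dramatically in this
p ≈ n regime: on a synthetic treated cohort (n = 138, true EC↔ΔHAMD
correlation 0.6) the leakage-safe protocol recovers pooled r ≈ 0.0–0.35 —
the 37 selected-but-uninformative connections overwhelm the weakly
regularized SVR — while global selection yields r ≈ 0.64–0.73, at or above
the true correlation. Published performance levels in this regime are
characteristic of the global variant; the package defaults to the honest
one and the analysis scripts report both side by side. The chance-level
guard (signal-free data stays at accuracy ≈ 0.5, |MCC| ≈ 0) is asserted for
the default protocol.

## Numerical choices and degenerate inputs

- Time-series files round-trip at repr precision (< 1e-12); ragged rows,
  non-numeric cells and duplicate subject ids raise with row/column named.
- The default DMN partition (12 mPFC, 11 PCC, 6 LPC, 4 RPC named
  placeholder ROIs) is validated at load; custom partitions may have any
  sizes but must assign every ROI exactly once.
- Missing phenotype values are empty CSV cells; stages drop subjects
  missing a required field and report the count.
- All randomness flows from explicit integer seeds (`numpy` Generator /
  SeedSequence); identical config + seed reproduces byte-identical outputs,
  and the pipeline derives per-stage seeds as master + stage index.
- Simulation sizes in the test and acceptance suites are scaled for a
  single-CPU run: 10 CV repeats (100 in the pipeline default), 200 label
  permutations (1000 default), 500 mixed-model calibration replicates.

## Limitations

- Bivariate lag-1 Granger coefficients are not conditional effective
  connectivity; shared inputs inflate individual connections (the mean over
  the block is the analysis target).
- The generator's linear-Gaussian world cannot expose estimator failures
  specific to hemodynamic convolution, motion artifacts, or heavy-tailed
  noise.
- The mixed-model Wald test's mild conservatism and d attenuation at few
  sites are inherent to the ML + residual-df recipe (see above).
- Harmonization assumes location/scale site effects; interactions between
  site and biology are out of scope.
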