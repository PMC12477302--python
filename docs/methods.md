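# Methods

## The reciprocity (adaptive inaccuracy) statistic

Distylous populations carry two self-incompatible floral morphs whose sexual
organs occupy two height levels: the *high* level pairs S-morph anthers with
L-morph stigmas, the *low* level pairs L-morph anthers with S-morph stigmas.
Legitimate (intermorph) pollination depends on those pairings matching. The
package quantifies the match with the adaptive-accuracy framework: for a
level with anther mean/variance $(\bar A, V_A)$ and stigma mean/variance
$(\bar S, V_S)$ (mm, mm^2),

* maladaptive bias $= (\bar A - \bar S)^2$ — systematic departure of the
  organ means from co-location;
* imprecision $= V_A + V_S$ — flower-to-flower scatter of organ heights;
* inaccuracy $=$ bias $+$ imprecision; total inaccuracy $=$ high-level
  $+$ low-level inaccuracy.

With plants sampled in a burned and an unburned area, four legitimate morph
pairings exist — within no-fire, within fire, no-fire S x fire L, and
no-fire L x fire S — each drawing its four organ populations from specific
area x morph groups (every group contributes exactly one high and one low
organ across the set). The statistic is a plug-in estimator: group sample
means and sample variances (n−1 denominator; the convention is not fixed by
the framework, the unbiased variant was chosen) substituted into the
formulas. The decomposition identities (bias + imprecision = inaccuracy,
high + low = total, symmetry in the two organs, non-negativity) hold exactly
by construction and are property-tested.

**Variance level.** Flower-level variances pooled across individuals enter
the formulas (individual-mean-based variances would be an alternative; the
flower is the unit a pollinator encounters). The bootstrap therefore
resamples flowers within each area x morph group, keeping each flower's
stigma and anther paired; a cluster bootstrap resampling whole individuals
is available (`cluster_by_individual=True`) for designs with strong
individual effects.

**Uncertainty.** Nonparametric percentile intervals (2.5/97.5%) from B
seeded resamples (B >= 100 enforced; 1000 by default in the pipeline). In
simulation at 200 flowers per group the 95% interval for total inaccuracy
covers the generating-population value ~91% of the time: percentile
intervals mildly undercover variance-dominated statistics at this n, which
is expected behaviour, not a defect of the implementation; coverage
approaches nominal as n grows. An opt-in size-standardised variant (each
level divided by its squared mean organ height) is provided for cross-study
comparison and clearly labelled; the reference analysis uses raw mm^2.

## Factorial trait models

Every trait is modelled as `trait ~ area + morph + area:morph` (treatment
coding; no-fire and L are the reference levels) with the family fitting its
support:

| family | link | used for |
|---|---|---|
| gaussian | identity | inflorescence length, corolla diameter, stigma height, nectar volume, nectar calories |
| gamma | log | plant height, stem diameter, corolla/anther/stigma length, anther height |
| NB1 negative binomial | log | inflorescence, bud, fruit and pollen-grain counts |
| beta | logit | nectar concentration (proportion scale) |
| binomial | logit | pollen presence/absence (alternative view of deposition) |

NB1 means the linear-parameterisation negative binomial,
$\mathrm{Var} = \mu(1+\alpha)$; the pollen-grain model adds a constant
structural-zero probability $\pi$ (zero inflation is intercept-only — no
covariate structure for $\pi$ is assumed). The registry of sixteen default
models records which traits carry a group-wise dispersion flag and which are
repeated measures.

**Individual-level clustering.** Traits measured on several units of the
same plant are not independent. Gaussian models absorb this with a
maximum-likelihood random intercept (MixedLM); when the intercept variance
sits on the zero boundary and the default optimizer stalls, the fit retries
with derivative-free optimizers and, failing that, falls back to a
cluster-robust OLS — the marginal equivalent. statsmodels offers no
joint-likelihood GLMM for the remaining families, so the package uses
cluster-aware marginal inference instead: GEE with an exchangeable working
correlation for gamma and binomial models, and maximum likelihood with a
cluster-robust (score-based sandwich) covariance grouped by individual for
NB1, zero-inflated NB1 and beta models. The handling actually used is
recorded machine-readably in every `ModelFit.re_handling` and in the run
report, because marginal and conditional coefficients are not identical for
nonlinear links.

**Group-wise dispersion.** Models flagged for heteroscedasticity
accommodate cell-wise dispersion through robust sandwich covariances (HC3
for independent fits, the cluster/GEE sandwich otherwise) rather than an
explicit dispersion submodel in the likelihood. In a 2x2 design the sandwich
estimator is consistent under arbitrary cell-wise heteroscedasticity, so
Wald inference — the quantity of interest here — is protected; what is given
up is likelihood-based efficiency and an explicit dispersion estimate per
cell.

**Type-II Wald tests.** Each term is tested with a Wald chi-square (df = 1
throughout in the 2x2 design) built from the single full-model coefficient
covariance: a main effect is adjusted for the other main effect while
ignoring the interaction, the interaction is tested last. The hypothesis
matrix construction follows the conjugate-complement algorithm of the
standard analysis-of-deviance implementation; on fixed datasets the
statistics agree with an independent R `car::Anova(type = 2, test = "Wald")`
run to all printed digits (frozen in the test suite). Under the null the
empirical size per term is 0.04–0.07 at alpha = 0.05 (1000 simulated
datasets, gaussian and NB1, 25 units/cell).

**Marginal means and contrasts.** Predicted group means average the linear
predictor over the factor grid (each cell weighted equally — not
observation-weighted), then back-transform through the inverse link, with
delta-method SEs; with an identity link and balanced data they reduce
exactly to arithmetic group means. Morph-conditioned contrasts compare fire
vs no-fire within each morph on the link scale with Wald z tests; for log
links the back-transformed contrast is a mean ratio. The pipeline computes
contrasts only when the interaction term is significant (alpha = 0.05),
mirroring the usual post-hoc workflow.

## Percent effects and nectar energetics

Percent effects are $100(\bar y_f - \bar y_r)/\bar y_r$ reported to two
decimals, focal vs reference. Conventions: for area comparisons the
unburned group is always the reference; for morph comparisons the
second-named group is the reference. The antisymmetry identity
$p_{BA} = -100\,p_{AB}/(100 + p_{AB})$ is property-tested.

Refractometer concentrations (% w/w) convert to sucrose equivalents as
$10\,C\,\rho(C)$ ug sucrose per uL, with $\rho(C)$ the 20 C density of a C%
w/w aqueous sucrose solution linearly interpolated from the standard
concentrative-properties table embedded in `effects.py` (15 nodes, 0–70%).
No temperature correction is applied to readings. Energy content uses the
standard 4 cal per mg sugar. Per-flower calories are derived from volume x
concentration before model fitting.

## The synthetic-data generator

The generator emulates the study design the analysis assumes: 17 individuals
per morph per area (individual traits); 10 flower-sampled individuals x 8
flowers per cell (~320 flowers of morphometry); ~22 inflorescences per cell
for length/bud counts; ~36 infructescences per cell from ~11 individuals for
fruit counts; ~10 nectar flowers and ~96 pollen-scored flowers per cell.
Distributions mirror the model families: truncated-at-zero normals for
lengths/heights (truncation is >10 SD from zero at the default CVs, so the
induced bias is negligible), gamma–Poisson NB1 for counts (exact NB1
moments; alpha = 0 short-circuits to Poisson), a mean/precision beta for
concentration, and structural zeros for pollen. Individual intercepts
(additive for continuous traits; mean-one log-normal for counts) give the
cluster-aware machinery real signal. Fire acts multiplicatively on cell
means with per-morph overrides.

Default parameter values are anchored to the published results of the
source study wherever it reports them: organ-height means (L stigma
16.46 mm, S anther 16.51 mm, S stigma 10.42 mm, L anther 10.83 mm,
unchanged by fire), the multiplicative fire effects on inflorescence length
(x0.906), corolla length (x0.953), anther length (x0.941), L-morph stigma
length (x0.665) and S-morph fruit set (x1.353). Where only precision is
published, noise parameters were back-calculated from it: the printed
marginal-mean SEs for flower traits imply flower SDs of ~0.2–0.4 mm and a
small between-individual SD (0.05 mm default), and the reported fruit-count
interaction chi-square implies an NB1 dispersion near 7 by SE inversion.
Organ-height SDs default to 1.1 mm, which keeps total inaccuracy dominated
by imprecision rather than bias, as reported. Remaining free parameters
(bud/inflorescence count means, pollen mean 60 with alpha 8 and pi 0.3,
nectar volumes ~14–16 uL at 20% w/w) are field-realistic choices fixed once.

What the generator does **not** emulate: pollinator behaviour and the
mechanics of pollen transfer, spatial structure within areas, fire-intensity
gradients, temporal (within-season) variation, and any correlation between
traits beyond the shared individual intercept. Passing tests therefore
demonstrate that the statistical machinery recovers known structure from
data with the study's design and noise levels — not that the biological
conclusions would survive features of real data the generator omits.

## Numerical choices

* ML fits retry from up to three seeded jittered starts on non-convergence;
  non-convergence is flagged in the result and downstream operations refuse
  to run on unconverged fits rather than returning silent numbers.
* Cluster sandwich covariances use the conventional
  $G/(G-1)\cdot(n-1)/(n-p)$ small-sample factor and agree with the
  statsmodels cluster covariance where both exist.
* Zero-variance groups are legal inputs to the reciprocity statistic and
  propagate exactly (degenerate bootstrap intervals equal the point
  estimate).
* All randomness flows from explicit seeds; the pipeline derives per-stage
  substreams from one global seed via `SeedSequence`, so stages can be
  re-run in isolation and full runs are reproducible byte-for-byte.
* Tidy long format (`area, morph, individual_id, unit_id, trait, value`) is
  the single interchange schema for all tables, CSV on disk.

## Simulation problem sizes

Calibration and recovery experiments in the test suite use: 1000 simulated
datasets (25 units/cell) per family for test size; 20 seeds at 500
units/cell for coefficient and NB1-dispersion recovery; 500 units/cell for
zero-inflation recovery; 10^4 flowers/group for inaccuracy consistency
(relative error < 5%); 60 repetitions at 200 flowers/group for bootstrap
coverage; and 20 seeded end-to-end runs of the default configuration for
the scenario-level significance pattern. The morph-conditioned contrast
recovery experiment injects the S-morph-only fruit effect at its reported
magnitude (+35.3%) into 100 infructescences per cell across 25 individuals
— a size at which nominal power exceeds 95%, so the experiment measures the
method rather than the sampling design (at the field design of ~36 per cell
the same effect is detected in ~85% of runs, a power statement about the
design).

## Known limitations

* Non-gaussian repeated-measures models use marginal (GEE / cluster-robust
  ML) inference, not joint-likelihood GLMMs; with log/logit links marginal
  and conditional effects differ, and with few clusters (10–17 individuals
  per cell) robust Wald tests can be mildly liberal.
* The beta and zero-inflated fits have no working-correlation analogue here;
  their cluster adjustment is the sandwich covariance only.
* Percentile bootstrap intervals undercover slightly at small flower counts
  (see above); BCa intervals were not implemented.
* The sucrose density table is pinned at 20 C; refractometer temperature
  correction is out of scope.
* Multivariate ordination (PCA, distance-based RDA), residual-simulation
  diagnostics and multiple-testing correction across models are outside the
  package's scope.
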