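# Methods

This note documents the statistical models implemented in
`pedexpress`, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
choices that affect results.

## Kinship

The kinship coefficient Φ(i,j) is the probability that single alleles
drawn at random from i and j are identical by descent; 2Φ scales the
additive genetic covariance between relatives.  It is computed by the
exact recursion on a parents-before-children ordering —
Φ(i,i) = ½(1+Φ(f,m)), Φ(i,j) = ½(Φ(f,j)+Φ(m,j)), founders mutually
unrelated — with no non-inbred shortcut, so marriage loops and inbred
individuals are handled exactly (verified against a gene-dropping
Monte-Carlo oracle in the test suite).  Pedigree files are PED-style;
parental sex is *not* cross-validated against the father/mother
columns by default because real files are messy (a `strict_sex` mode
enables the check).  Singletons form 1×1 blocks: they inform fixed
effects and total variance but carry no between-individual genetic
covariance.

## Detection above the control null

Each array carries embedded control probes measuring background.  The
per-sample detection threshold is the empirical 95th percentile of the
sample's control signals, interpolated at plotting position (n+1)q
("weibull" convention).  The convention matters: with a finite control
pool (hundreds of probes) the common (n−1)q+1 linear rule is exceeded
by a fresh background draw with probability ≈0.053 rather than 0.05,
which propagates into every probe's tail count and inflates the
realized false-detection rate; the (n+1)q position makes the
exceedance probability unbiased.  A pooled-across-samples null is
available behind a flag but is less robust to per-sample scale
artifacts; per-sample thresholds make the 5% null fraction exact per
sample under the artifact model.

For each non-control probe the tail count k (samples above threshold)
is tested for excess over E = 0.05·n.  The reported statistic is the
one-cell χ² (k−E)²/(n·0.05·0.95) — the squared binomial z — with a
one-sided alternative, since depletion below background is not
evidence of expression.  Default p-values are the exact binomial tail
sum P(X ≥ k): at the relevant scales (E in the tens) the continuous
normal tail overstates significance enough to push the realized
false-detection proportion above the nominal FDR, while the exact tail
keeps it controlled.  The normal approximation remains available
(`exact=False`) and agrees with the exact tail within 10% relative
error for n ≥ 1000 and k within ±5 of E; outside that regime use the
exact mode.  Benjamini–Hochberg step-up q-values are applied across
probes; "FDR" is read as BH throughout the package — the
smoother/estimator variants of FDR control are deliberately out of
scope.

## Standardization

Three fixed stages, in this order, with no re-binning:

1. **Within-individual z-scores in decile bins.**  Transcripts are
   ranked by mean log raw signal across individuals (ties broken by
   transcript id) and split into 10 equal-count bins, the remainder
   spread one-per-bin from the lowest bin.  Within each sample and
   bin, log signals are z-scored (n−1 denominator).  This removes
   per-sample offset and scale artifacts exactly (a sample-wise
   rescaling of raw signals cancels).
2. **Regression on mean signal.**  Each transcript's z-scores are
   regressed (OLS) on the individual-specific mean log raw signal and
   its square, per transcript across individuals; residuals proceed.
   A constant mean-signal vector makes the design rank-deficient and
   is reported as an error with advice to skip the stage.
3. **Rank-based inverse normal.**  Per transcript, values map to
   Φ⁻¹((r−3/8)/(n+1/4)) of their average ranks (Blom offset; the
   (r−½)/n alternative is a config option).  Ties share a value.  The
   output margins are exactly standard-normal in quantile positions,
   which is what the variance-components likelihoods assume.

Natural log is used throughout; the base is consequence-free because a
change of base rescales all log signals by a common factor that the
z-scoring absorbs (property-tested).  Transcripts with zero variance
across samples are dropped with a warning before binning.

One caveat documented deliberately: with *few transcripts per bin* and
a large fraction of strongly affected transcripts of one sign, the bin
means absorb part of the signal and push a small opposite-sign
artifact into null transcripts of the same bin.  At realistic scale
(hundreds of transcripts per bin, a few percent affected) the effect
is negligible — the FDR acceptance test runs at that scale — but the
generator makes it easy to reproduce the pathology.

## Polygenic association model

For phenotype vector y (inverse-normalized expression) with covariates
X (intercept, sex, age, age×sex; age² terms behind a flag, default
off), each pedigree block contributes

    y_b ~ N(X_b β, σ²(h²·2Φ_b + (1−h²) I)).

Per block, 2Φ is eigendecomposed once; in the rotated basis the
covariance is diagonal, β and σ² are profiled analytically by GLS, and
the likelihood is maximized over h² ∈ [0,1] by a coarse grid
(0, 0.25, 0.5, 0.75, 0.99, 1) followed by bounded Brent refinement
(xatol 1e−7).  Because the eigendecomposition is shared, a
transcriptome scan costs one cheap 1-D search per transcript per
model.  When 2Φ = I everywhere (all singletons) h² is unidentifiable
and reported as NaN with a flag; the likelihood then equals the
ordinary linear model's.

The exposure is tested by LRT between nested fixed-effect models with
variance parameters re-estimated under each — maximum likelihood, not
REML, because REML likelihoods are not comparable across fixed-effect
structures.  The reference is χ²₁ (the exposure coefficient is
unconstrained; no boundary mixture is involved — that mixture,
½χ²₀+½χ²₁, applies only to variance-component tests such as h² = 0).
LRT values in (−1e−6, 0) are clamped to zero; anything more negative
raises an optimization-failure error.

For the transcriptome scan the default p-value reference is the
finite-sample form of the same statistic: in the no-genetic-variance
limit LRT = n·log(RSS₀/RSS₁) corresponds exactly to an F(1, n−p)
statistic, so the scan maps the LRT through
(e^{LRT/n}−1)(n−p) ~ F(1, n−p).  At transcriptome scale the BH cutoff
sits at p ≈ 10⁻³, where the asymptotic χ²₁ tail is measurably
anticonservative at cohort sizes in the hundreds (ratio ≈1.15 at
p ≈ 0.0025 in null simulation on the reference design) — enough to
push the realized FDR above nominal; the F calibration removes most of
that and brings the realized false-discovery proportion to the nominal
0.05.  The classic χ²₁ reference remains available
(`reference="chi2"`) and is what the single-test `lrt_covariate`
returns.  BH q-values are computed across transcripts, and the scan
summary reports the implied nominal p threshold (largest p among
rejections) and the direction split.

No household/shared-environment variance component is fitted by
default; nothing in the target analysis calls for one, and the
association model exposes the residual structure needed to add one as
a sensitivity analysis.

## Bivariate liability model

Smoking is modeled as a latent standard-normal liability ℓ = g_l + e_l
with Var(g_l) = h²ₗ·2Φ, Var(e_l) = (1−h²ₗ)I, observed as
smoker = 1{ℓ > t}.  Jointly with expression y (variance σ², additive
fraction h²ₑ), the cross-covariance is
Cov(y, ℓ) = σ(ρg√(h²ₑh²ₗ)·2Φ + ρe√((1−h²ₑ)(1−h²ₗ))·I).  The implied
phenotypic correlation ρp = ρg√(h²ₑh²ₗ) + ρe√((1−h²ₑ)(1−h²ₗ)) cannot
exceed 1 in magnitude when |ρg|,|ρe| ≤ 1 (Cauchy–Schwarz), so the box
bounds are sufficient for a valid joint covariance.

The block likelihood uses a conditional decomposition: the exact MVN
density of the expression sub-vector times the orthant probability of
the conditional liability (mean C'V_y⁻¹(y−Xβ), covariance
V_l − C'V_y⁻¹C) over the rectangle dictated by the block's smoker
pattern and threshold.  This keeps the continuous part exact and
reduces the integral's dimension to the block size (capped at 20 by
default; larger blocks raise an error rather than silently degrade).

Orthant probabilities use Genz's sequential-conditioning estimator on
a scrambled Sobol point set with a fixed seed — fixed so that repeated
likelihood evaluations see identical points and the objective is
smooth and deterministic, hence optimizable.  256 points per block
(128–64 in bulk recovery runs) give ~1e−4 relative accuracy at block
size ≤ 8; 2-member blocks reproduce the closed-form bivariate normal
CDF to 1e−5 (tested), and a 10⁷-draw Monte-Carlo integration of the
same integral — conditioning the opposite way — agrees within MC error
(tested).

Fitting maximizes over (h²ₑ, h²ₗ, ρg, ρe, t, log σ, β) by L-BFGS-B
with box bounds, warm-started from the univariate polygenic fit, the
observed prevalence (t = Φ⁻¹(1−p̂)) and a point-biserial hint for ρe;
the finite-difference step is 1e−5 (smaller steps make the gradient
noisy near the optimum and waste iterations).  The threshold t is a
free parameter rather than being fixed at the sample prevalence,
matching standard discrete-trait variance-components practice; fixing
it (or any other parameter) is supported via `fix=`.  ρg = 0 and
ρe = 0 are each tested by LRT against the constrained fit (χ²₁),
warm-started from the full optimum; if a constrained fit ends above
the full fit, the full fit is restarted from it.  Standard errors come
from the numerical observed information (full Hessian by central
differences), and can be skipped in bulk runs.  When ĥ²ₗ ≈ 0, ρg is
unidentifiable and reported as NaN with a flag and warning.

Covariates: the expression trait carries {sex, age, age×sex} by
default.  The liability side carries only the threshold by default —
liability covariates (shifting the liability mean per individual) are
supported via `liability_covariates=` but off by default, since the
exposure model has no stated covariate structure and the extra
parameters are pure optimization cost when their true effects are
absent.  By convention the bivariate stage runs on the top 50 scan
hits; a full-transcriptome run is allowed but warned as expensive.

## Exposure-measure validation

The tetrachoric correlation of a 2×2 table is the ML ρ of a standard
bivariate normal dichotomized at thresholds fixed from the margins
(the standard two-step estimator); the bivariate normal CDF is
evaluated by Gauss–Legendre quadrature of dΦ₂/dρ = φ₂ from ρ = 0,
accurate to ~1e−12 for |ρ| ≤ 0.99.  The SE is the inverse square root
of the numerical second derivative of the profile log-likelihood.  A
zero cell drives ρ̂ to the boundary, which is reported with a warning
rather than masked.  Cotinine classification uses right-inclusive
cuts: < 20 non-smoker, [20, 300) smoker, ≥ 300 heavy smoker; missing
stays missing, and the conflict count against self-report considers
only the smoker/non-smoker distinction.

## Enrichment

Right-tailed Fisher's exact p = P(X ≥ k), X ~ hypergeometric(N, K, n),
via `scipy.stats.hypergeom.sf` (tail summed at full precision), with
the *detected transcriptome* as the reference universe N — using the
whole genome would overstate enrichment of anything expression-biased.
Categories are intersected with the reference before counting;
significant genes outside the reference are dropped with a warning.
Testing is at the gene level: multiple significant transcripts of one
gene count once, and transcripts without a symbol are excluded with a
logged count.  BH q-values across categories are reported alongside
the raw p-values.

## Synthetic data: what it emulates, and what it does not

The generator produces (i) three-generation families drawn to sizes
5-8 (a founder couple, children, and one married child with
grandchildren; a free-form branching process is available) plus
singletons; (ii) liability-threshold smoking at 24% prevalence with
liability heritability 0.5 by default, reported status flipped at rate
0.017, cigarettes/day as a discretized lognormal for reported smokers,
and cotinine as class-specific lognormals keyed to *true* status
(medians 3 and 150, log-sd 0.6/0.7) — so with the default noise about
17 per 1,000 reported statuses conflict with the cotinine
classification; (iii) per-transcript expression
y = β·smoker + γ·covariates + g + e with h² ~ U[0.1, 0.8], a 5%
affected fraction with |β| ~ U[0.4, 0.8] (random sign), and optional
(ρg, ρe) coupling of g and e to the liability's components; (iv) raw
signals exp(a_s + b_s·(μ_t + 0.5·y)) with per-sample offset/scale
artifacts, plus control and unexpressed probes drawn i.i.d. from one
background mixture — i.i.d. across probes *and* samples, which is what
makes the per-probe 5% tail null exact for the detection stage.  Ages
are uniform on [16, 94]; no cohort structure.  The expression model
responds to true (pre-misclassification) smoking, the scan uses
reported smoking: self-report noise attenuates, as in real data.

Not emulated: bead-level array physics, probe cross-hybridization,
batch layout, cessation dynamics, population structure or genotype
data.  Passing tests therefore demonstrate the statistical machinery
under the assumed generative model — heritable liability, polygenic
expression, multiplicative signal artifacts — not robustness to
failure of those assumptions.

All randomness flows from one seed expanded per stage as
`default_rng([seed, stage_index])`, so every stage is independently
reproducible and equal seeds give bit-identical outputs.

## Scales used by the replicated calibration runs

The repository's calibration experiments use problem sizes chosen to
estimate each quantity with useful precision: 20-40 replicates of the
reference design (~600 individuals, 2,000 transcripts) for the scan
false-discovery proportion; 20-40 replicates of 400 samples × 1,500
probes for detection; 200 traits on 50 five-member families for h²
recovery; 100 bivariate fits on 60 six-member families, each replicate with
its own liability draw, for (ρg, ρe) recovery and the ρg = 0 test
size; 2,000 null traits for LRT calibration; 10⁵ draws for the
tetrachoric check; 10⁷ draws for the Monte-Carlo likelihood oracle.
Mean absolute artifact correlations are checked on a ~2,500-sample
cohort because the pure-noise floor of that statistic, ≈0.8/√n, must
sit below the 0.02 contract.

## Known limitations

* The detection χ² statistic's normal tail is only trustworthy near
  the null (documented regime above); the exact tail is the default.
* BH is applied under the usual positive-dependence reading; the
  mild within-bin dependence induced by standardization is covered
  empirically by the FDR acceptance runs, not theoretically.
* The bivariate model assumes the liability threshold is constant
  across individuals unless liability covariates are supplied.
* Tetrachoric SEs use observed information; tables with zero cells
  report boundary estimates with warnings, not finite SEs.
* ML variance components are biased low in small samples (no REML
  mode); the h² recovery test quantifies the bias at its design scale.
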