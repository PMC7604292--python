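# Methods

## The model

Each response — a standardized NMR bucket intensity ("metabolomic
feature") or a malting-quality trait measured on the same wort sample —
is modeled at the level of the individual field plot:

    y = X b + Z_g g + Z_l l + Z_ig ig + Z_il il + Z_t t + e

* `b` — fixed location x year x trial cell effects (the fixed part is
  reduced to full column rank by dropping trailing collinear columns in
  data order, deterministically).
* `g ~ N(0, G sigma_g^2)` — additive genomic line effects, with `G` the
  VanRaden method-1 genomic relationship matrix built from SNP dosages:
  `G = ZZ' / (2 sum_j p_j (1 - p_j))`, dosages centred by twice the
  in-sample allele frequency.  Markers pass QC when MAF is strictly above
  5% and missingness strictly below 20%; missing dosages are mean-imputed
  before centring.
* `l ~ N(0, I sigma_l^2)` — line effects not captured by the markers.
* `ig ~ N(0, diag(G,...,G) sigma_ig^2)` — genomic line x environment
  interactions, one G block per location x year environment.
* `il ~ N(0, I sigma_il^2)` — non-genomic line x environment interactions.
* `t ~ N(0, I sigma_t^2)` — malting-batch effects (samples malted and
  mashed together).
* `e ~ N(0, I sigma_e^2)` — residual.

The phenotypic variance of a single plot and the plot-level genomic
heritability are

    sigma_P^2 = Gbar sigma_g^2 + sigma_l^2 + Gbar sigma_ig^2
                + sigma_il^2 + sigma_t^2 + sigma_e^2
    h2 = Gbar sigma_g^2 / sigma_P^2

with `Gbar` the average diagonal of G.  Relative variance components
(RVCs) are the Gbar-weighted shares of sigma_P^2; they sum to one.  This
is the heritability of one plot measurement, deliberately not of a line
mean.

The bivariate model expands every dispersion parameter to a 2x2
covariance block (the univariate model is the sub-model per response).
From the fitted blocks the additive genetic correlation is
`r_g = c_g / sqrt(v_g1 v_g2)` and the phenotypic correlation is the
Gbar-weighted sum of all covariance entries over the product of the two
phenotypic standard deviations — the same weighting as the univariate
sigma_P^2 identity, so the two definitions are mutually consistent.
Standard errors of h2, r_g and r_p come from the delta method on the
inverse average-information (AI) matrix; the h2 SE is an extension beyond
the core point estimate, kept for diagnostics.

## REML estimation

Variance components maximize the restricted log-likelihood

    l_R = -1/2 [ log|V| + log|X'V^-1 X| + y'Py ] + const,
    V = sum_k sigma_k^2 Z_k A_k Z_k' + I sigma_e^2

over nonnegative components.  The implementation materializes each term's
covariance structure `Z_k A_k Z_k'` as a dense n x n matrix (gathers of G
for the genomic terms, equality indicators otherwise), which keeps every
gradient and AI entry an elementwise product or matrix-vector product
once `P` is formed.  The update strategy:

1. five expectation-maximization warm-start iterations
   (`sigma_k^2 += sigma_k^4 / q_k (y'P V_k P y - tr(P V_k))`, floored at
   a small positive value);
2. average-information (Newton-type) updates with step-halving, Newton
   directions rescaled to parameter magnitude when the AI matrix is
   near-singular;
3. active-set handling of the nonnegativity bounds: a component whose
   update goes negative is pinned at exactly zero and freed again when
   its gradient turns positive.  Exact zeros are representable on
   purpose — the null distribution of h2 has an atom at 0;
4. convergence when the relative log-likelihood change is below 1e-8 and
   the scale-invariant gradient norm (gradient times var(y)/n) of the
   free components is below 1e-6, with an iteration cap of 200.  When a
   solution sits on a constraint boundary the gradient need not vanish;
   the fitter then stops once neither the AI direction nor an EM step
   (a guaranteed-ascent direction) improves the restricted likelihood
   beyond tolerance — a no-feasible-ascent stopping rule.

The bivariate fitter parameterizes each 2x2 block by its Cholesky factor
`L = [[a, 0], [b, c]]` (block = LL'), which turns the
positive-semidefinite constraint into the simple bounds a, c >= 0 and
makes the restricted likelihood smooth in the parameters; it is then
maximized by L-BFGS-B with the analytic gradient (chain rule through the
Cholesky map).  Correlations never leave [-1, 1] by construction;
boundary solutions (|r| = 1, i.e. c = 0) and pinned zero variances
(a = 0) are exactly representable, and they do occur in this class of
data.  An earlier projected-Newton scheme (AI steps with per-block
eigenvalue projection) was abandoned: near the |r| = 1 ridge the
projection makes ascent directions nearly infeasible and convergence
creeps.  The residual block's diagonal Cholesky entries are bounded
below at 1e-3 response-SDs so the stacked covariance matrix stays
invertible even for (nearly) identical responses.  Warm start: variance
entries from the two univariate fits, covariances from the observed
cross-correlation of the responses shrunk by half.  Standard errors come
from the inverse AI matrix evaluated in the block parameterization at
the solution; rows of pinned parameters are zeroed and |r| = 1
covariances carry a boundary flag because their delta-method SE is not
meaningful there.

Responses missing on some plots (trait records) are handled by unequal
row sets per response; the residual cross-block links only plots carrying
both measurements.

## Significance calibration

Because h2 estimates pile up at zero, nominal asymptotic tests are
useless near the boundary.  Significance is instead calibrated
empirically: i.i.d. standard-normal responses are simulated on the exact
experimental design (all components null except the residual), the full
model is refitted per replicate, and the empirical upper 1% quantile
(linear interpolation) of the null h2 values is the cutoff.  A feature is
significant when its h2 exceeds the cutoff strictly.  The desk default is
1,000 replicates (configurable; the replicate count is recorded with the
output); failed replicate fits are retried on the next random substream
and more than 5% failures abort.  Correlations are tested with
z = estimate/SE against the two-sided 1% normal threshold 2.326, again
with a strict inequality.

## Preprocessing

The pipeline starts from a frequency-domain bucket table (plot x ppm).
Steps: (1) closed-interval exclusion of the residual-water window
(4.7-4.9 ppm) and the DSS reference window (-0.2-0.2 ppm; outside a
0.70-9.00 ppm grid this second window is a no-op); (2) probabilistic
quotient normalization against the bucket-wise median spectrum — each
spectrum is divided by the median of its bucket-wise quotients to the
reference, which removes per-sample dilution exactly when dilution is a
common factor; (3) optional segment-wise alignment: each segment is
shifted by the integer bucket offset within ±max_shift maximizing
cross-correlation with the reference, vacated positions filled with the
segment's edge value.  Integer-shift cross-correlation is the core of
interval-correlation-shifting alignment and is verifiable by brute force;
sub-bucket interpolation is deliberately out of scope.  (4) per-bucket
centring and standardization to mean 0, SD 1 (divisor n-1, matching the
downstream variance conventions); constant buckets are dropped and
recorded.  The ppm grid is stored ascending internally — one canonical
orientation avoids sign errors; writers may emit the conventional
descending display order.

Raw FID processing (apodization, Fourier transform, phasing, baseline,
chemical-shift referencing) happens instrument-side and is out of scope.

## Synthetic data

The generator emulates a multi-environment barley breeding trial.
Genotypes: founder haplotypes drawn in Hardy-Weinberg proportions at
allele frequencies from `maf_range`, lines formed by founder crosses
followed by recombination-free selfing generations (default 4,
emulating single-seed-descent inbreds); this induces realistic
off-diagonal relationship and an inflated G diagonal (~1.9) without
modeling a genetic map.  Design: lines are split into year cohorts
(lines are not repeated across years in such programs), grown in every
location of their year, trials nested per environment, consecutive plots
grouped into equal-size malting batches (batch layout is not constrained
by any published description, so grouping by order is the simple
default).  Defaults mirror the motivating study's scale: 565 lines,
3,889 markers with MAF >= 5%, 2 locations x 3 years, ~4.65 plots per
line, a 0.70-9.00 ppm grid, trait missingness ~2%, feature
heritabilities in [0, 0.4].

All configured variances are **plot-level** variances: genomic effects
are drawn with covariance `(G/Gbar) sigma^2`, so the average variance of
a plot's genomic value equals sigma_g^2 regardless of the population's
inbreeding, the true plot h2 is sigma_g^2 over the plain component sum,
and the REML estimate of `Gbar sigma_g_hat^2` targets the configured
value.  The alternative (literal `G sigma^2` sampling) ties the meaning
of every configured h2 to the realized inbreeding level, which would
make "a feature with true h2 = 0.3" an ill-defined request; the
plot-scale convention keeps simulation targets and estimates on one
scale.

Trait-feature covariance is imposed by building the trait's genomic
effect as a linear combination of feature genomic effects plus an
independent remainder (exact for mutually independent features; requested
blocks are validated for positive semi-definiteness and infeasible
combinations are rejected naming the offending block).  Residual
covariance is imposed the same way.  Bucket intensities add a positive
baseline (10 feature-SDs) and a per-plot log-normal dilution factor
(sigma = 0.1), both removed again by PQN and standardization — this
exercises the preprocessing without changing the downstream truth.

What the generator does **not** emulate: peak shapes and chemical-shift
drift (buckets are generated on a common grid; alignment is therefore
exercised by dedicated shifted fixtures, not by the generator), spectral
overlap between metabolites, heteroscedastic technical noise, spatial
field trends within trials, and linkage/QTL architecture (genomic values
are drawn from G directly).  Passing recovery tests therefore shows the
estimation chain is correct and calibrated for data satisfying the
model's covariance assumptions — not that real spectra meet them.

## Quality-control experiments (problem sizes)

The experiment battery (`nmrherit.experiments`, also driven by
`scripts/acceptance.py`) uses sizes chosen for desk-scale runtime, as the
package's own reference conditions:

* oracle checks: closed-form balanced ANOVA (6 plots) and grid-search
  maximization on a 12-plot instance;
* h2 recovery: 50 fully independent replicates (own genotypes, design
  and G each, so the Monte-Carlo SE of the mean is honest), 200 lines x
  ~3 plots in 6 environments, true components (0.3, 0.1, 0.1, 0.1, 0.1,
  0.3);
* genetic-correlation recovery: independent feature-trait pairs at true
  r_g = -0.6 on the same design scale;
* null calibration: cutoff from 500 pure-noise refits on a 100-line
  design, tested on 500 fresh null features against the binomial 95%
  band around 1%.  Every recovery target feature is simulated alongside
  127 pure-noise buckets so PQN sees a realistic quotient distribution
  (a one-bucket spectrum would be normalized onto itself, and the PQN
  factor's estimation error injects plot variance of order 1/n_buckets).

At the 200-line scale the constrained REML estimator of plot h2 carries
a small negative finite-sample bias (~0.02 at truth 0.3, measured with
preprocessing disabled, so it is an estimator property, not a pipeline
artifact); it sits within the two-Monte-Carlo-SE tolerance the recovery
experiments use and shrinks with design size.

## Known limitations

* The AI-REML fitter is dense (O(n^2) memory, O(n^3) per iteration); it
  is sized for thousands of plots, not hundreds of thousands.
* Near PSD boundaries the bivariate likelihood can be extremely flat;
  reported boundary correlations (|r| = 1) are constrained optima and
  their delta-method SEs are not trustworthy there (the boundary flag is
  set for exactly this reason).
* The null-calibration cutoff is an empirical quantile; with R
  replicates its own Monte-Carlo error is O(1/sqrt(R alpha)), which is
  why the replicate count is configurable and recorded.
* Undefined correlations (a genomic variance pinned at zero) are
  reason-coded and excluded from summary denominators rather than
  coerced to zero; summary percentages report their denominator.
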