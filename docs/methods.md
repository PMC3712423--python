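# Methods

## The statistical problem

Behavioural-syndrome studies measure a handful of inter-correlated traits
per breeding pair — behavioural assay scores, breeding decisions,
parental effort, components of reproductive success — each on a different
subset of pairs. Simple bivariate correlations confound direct and
indirect effects, so the analysis fits an *a priori* recursive path model
(a DAG of hypothesized causal links) and asks which direct and compound
paths the data support. Because per-pair sample sizes are small and
pairwise-varying, the uncertainty in the trait covariance matrix is the
dominant source of uncertainty, and it is propagated exactly: the path
model is refitted to each of 1000 posterior covariance draws rather than
to a single point estimate.

## Covariance posterior with missing data

Model: rows x_i ∈ R^p are iid N(μ, Σ); missingness is assumed ignorable
(missing at random). Variables are standardized to observed mean 0, SD 1
before sampling, so draws are covariance matrices on a correlation-like
scale; `to_correlation` rescales each draw to exact unit diagonal.

Gibbs sweep: (1) missing cells given observed cells from the conditional
Gaussian, vectorized over rows sharing a missingness pattern; (2) μ given
completed data and Σ, under a near-flat N(0, 10⁸·I) prior; (3) Σ given
completed data and μ from inverse-Wishart(ν₀ + n, S₀ + Σᵢ(xᵢ−μ)(xᵢ−μ)ᵀ)
with ν₀ = p + 1 and S₀ = I — on the standardized scale this prior puts
near-uniform mass on each marginal correlation. Chain defaults are 13 000
iterations, 3 000 burn-in, thinning 10, leaving exactly 1000 retained
matrices. Augmentation (rather than pairwise-complete estimation) is what
guarantees every draw is symmetric positive definite while still letting
the pairwise-varying sample sizes drive the per-path uncertainty.

A `known_mean` option skips the μ-update; with complete data the sampler
is then exactly conjugate, which the tests exploit to compare draws
against the closed-form inverse-Wishart posterior (Kolmogorov–Smirnov
checks per entry).

Degenerate inputs: variables observed on fewer than 3 rows or with zero
variance are rejected; variable pairs with no jointly observed rows only
raise a warning, since augmentation still identifies their covariance
through the other variables.

## Recursive path fitting

For a DAG on standardized variables the maximum-likelihood fit is exact
and non-iterative: each endogenous variable's coefficients solve the
normal equations on the correlation matrix, β = R[P,P]⁻¹R[P,y], with
residual variance ψ = 1 − R[y,P]β = 1 − R². No fit indices are computed —
the model is saturated in the relevant sense and all hypothesized paths
are reported. The model-implied matrix is (I − B)⁻¹Ψ(I − B)⁻ᵀ; tests pin
it to an independent exhaustive path-enumeration (tracing-rule) oracle
and to the round-trip identity (fitting an implied matrix recovers the
coefficients to 10⁻¹⁰).

Compound paths are products of coefficients along a declared chain of
edge labels, computed within each posterior draw; summaries of compounds
are therefore summaries of per-draw products, never products of
summaries (the two provably differ for skewed posteriors, and a test
constructs such a case). Chains are validated as admissible treks: the
walk may move against arrows first (through a common cause) and with
arrows after, but never through a collider. Pure head-to-tail chains are
the common special case; the trek form is needed because one published
compound (exploration ← aggression → own feeding rate) passes through
the syndrome's common cause.

Per draw, the covariance draw is converted to a correlation matrix and,
if numerically indefinite, repaired by clipping eigenvalues at 10⁻⁸ and
re-normalizing the diagonal; draws with minimum eigenvalue below −10⁻⁴
are rejected and logged, and more than 5% rejections abort the analysis.
This keeps well-conditioned draws bit-unchanged while tolerating harmless
rounding at the PD boundary.

## Summaries and support classes

Each coefficient's posterior sample is summarized by (a) the mode of a
Gaussian kernel density (Silverman bandwidth, 512-point grid) — the
"most likely" value; (b) the posterior mean, reported alongside because
KDE modes are bandwidth-sensitive; (c) the 2.5%/97.5% empirical
quantiles; (d) a tail probability p = 2·min(fraction > 0, fraction < 0),
floored at 1/n_draws. The doubling makes p two-sided; since "how often
the estimate was positive or negative" is one-sided-ambiguous, the raw
positive fraction is also emitted. Support classes: **strong** if the
interval excludes zero, *some* if it overlaps zero but p < 0.05 (no
extra "slightly overlapping" width criterion is imposed — none is
defined), none otherwise. The DOT export draws strong paths solid, some
paths dashed, and omits unsupported ones.

## Repeatability

R = σ²_ind/(σ²_ind + σ²_res) from a Gaussian random-intercept model with
optional fixed effects (sex, test sequence, year), fitted by Gibbs:
flat prior on fixed effects, inverse-gamma(0.001, 0.001) on both
variances — a conventional weakly informative choice for this model
family. Same chain defaults as above (1000 retained draws). R is formed
per draw, so the point estimate (KDE mode), mean and interval all respect
the posterior dependence between the two variances. Recovery tests cover
intraclass correlations from 0 to 0.78; the balanced no-covariate case is
checked against one-way ANOVA method-of-moments estimators.

## Preprocessing

Aggression: approach latency is box-cox transformed (λ chosen on a grid
over [−2, 2] in steps of 0.01 by profile likelihood, ties broken toward
0, i.e. preferring the log), multiplied by −1 so higher = more
aggressive, and centred on the per-stage mean of observed scores because
nest stage affects latency. The transform must precede negation (box-cox
needs positive input); only the monotone ordering of latencies matters
downstream. Exclusion of birds not confirmed as the feeding male is a
data-collection rule applied upstream by the caller, not a computation.

Feeding rate: visits per 90-minute window scale to feeds/hour by 60/90;
the trait is the mean of the two daily rates, falling back to the single
observed day, NaN if both are missing.

## Synthetic-data generator

The generator is the package's ground-truth instrument: exogenous latents
are jointly Gaussian with the configured correlations; each endogenous
latent is Σβ·parent plus a Gaussian residual with variance 1 − βᵀR_Pβ, so
all latents have unit variance and the configured β are exactly the
standardized path coefficients a correct analysis should recover.
Configurations implying non-positive residual variance or a non-PD
exogenous block are rejected. Repeated assays are latent + Gaussian noise
with noise variance (1−R)/R, giving intraclass correlation R exactly.

Default study conditions mirror the motivating field season: ~73
monitored nests, published male/female coefficients as effect sizes,
repeatabilities 0.66 (exploration) and 0.78 (feeding), per-column MCAR
rates chosen so pairwise sample sizes land in the published 33–73 range.
Observation-scale transforms (optional, off for recovery analyses) use
blue-tit-plausible constants: latency = exp(stage offset − 0.5·latent)·60
seconds — an arbitrary monotone map, since preprocessing inverts it up to
rank; feeds/hour ≈ 15 ± 4 rounded to visit counts per 90-minute window;
lay dates ≈ day 20 ± 8 after March 1; brood sizes ≈ 9 ± 2.5 with
fledgling number capped at brood size; fledgling mass ≈ 11.2 ± 0.9 g.

What the generator does *not* emulate: non-Gaussian marginals of count
data (rounding is optional precisely because it attenuates correlations),
missingness that depends on the data (MAR/MNAR), assortative mating,
territory quality, year effects, or within- vs between-individual
decomposition of the path structure. Passing recovery tests therefore
demonstrates the inference machinery is correct under the model's own
assumptions, not that those assumptions hold in any particular field
dataset.

## Problem sizes and numerical choices

Parameter-recovery analyses use 5000 pairs and the default 1000-draw
chains, sizes at which posterior means sit well within ±0.05 of
generating values while a full run stays in the tens of seconds;
repeatability recovery uses 500 individuals × 2 assays (±0.04). All
randomness flows through numpy `SeedSequence`, so identical seeds are
bit-reproducible. Quantiles use numpy's default linear interpolation;
degenerate (constant) posterior samples short-circuit the KDE and return
the constant.

## Known limitations

Single-level residual structure only (no random effects inside the
multivariate model — stage/centring adjustments happen in preprocessing);
Gaussian likelihoods throughout; recursive (acyclic) diagrams only; the
KDE mode is bandwidth-dependent, which is why the mean is always reported
next to it; convergence reporting is limited to the fixed chain defaults,
which are generous for these conjugate-style samplers but not adaptive.
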