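# Methods

## Model

`jmr` tests, taxon by taxon, whether a microbe's longitudinal
relative-abundance trajectory signals the host's binary disease outcome in
a matched case-control cohort. Participants j = 1..J in matched set
s = 1..S share latent exposures; each contributes samples at ages
t = 1..T_sj. Two latent factors, a subject effect a_sj ~ N(0, σ_a²) and a
set effect b_s ~ N(0, σ_b²), are shared across three submodels:

    logit P(O_sj = 1)   = u_sj α + a_sj + b_s
    logit μ_sjt         = x1_sjt β11 + z_sjt β12 + z̃_sjt (λ_r a_sj + γ_r b_s)
    logit π_sjt         = x2_sjt β21 + z_sjt β22 + z̃_sjt (λ_p a_sj + γ_p b_s)

O_sj is the disease outcome with time-invariant covariates u_sj
(intercept first); the target taxon's relative abundance y_sjt follows a
two-part zero-inflated Beta law — presence probability π_sjt and, given
presence, a Beta density with mean μ_sjt and precision φ (shapes μφ and
(1−μ)φ). x1/x2 are relative abundances and presence indicators of
pre-selected covariate taxa; z holds the shared longitudinal covariates
(intercept, age rescaled to [0, 1], any extras). The design vector z̃ is 1
for the intercept test and the scaled age for the slope test; the
intercept and slope analyses are two separate fits.

The association of interest is carried by the scaling parameters λ_r
(abundance) and λ_p (presence): under H0: λ_r = λ_p = 0 the taxon's
trajectory is independent of the disease-bearing subject effect. The test
statistic is the joint Wald sum W = λ̂_r²/SE² + λ̂_p²/SE², referred to
χ²(2) (χ²(1) when the presence part is degenerate, see below). No
cross-covariance term enters W; this matches the statistic as originally
defined, and the resulting conservatism is documented rather than
corrected. Across taxa, p-values are Benjamini-Hochberg adjusted.

Model variants: **JMR** (full, with covariate taxa), **JMR-NC** (no
covariate taxa) and **JR-NC** (additionally drops the set-level effect b_s
from all three submodels).

## Estimation

The marginal likelihood of a matched set integrates the J+1 random
effects. The integral is approximated by nested Gauss-Hermite quadrature:
the set effect b on the outer nodes, and — because subjects are
conditionally independent given b — a one-dimensional inner rule per
subject, giving O(Q² · J · ΣT) cost instead of O(Q^(J+1)). All sums are
accumulated in log space (log-sum-exp). The default is Q = 5 nodes per
dimension; quadrature accuracy is verified against a dense trapezoid
integrator in the test suite, and Q is configurable (more nodes reduce
the small attenuation of λ̂ visible at Q = 5).

All free parameters are estimated by maximizing the ridge-penalized
marginal log-likelihood ln L − ρ‖θ‖². The penalty excludes the intercepts
of α, β12 and β22 (penalizing intercepts would distort baseline
prevalence and abundance) and includes every slope, the covariate-taxa
coefficients, λ's, γ's and log φ. The default ρ = 0.1 sits in the lower
half of the cross-validation grid and is small relative to the
information content of typical data sets; `cv_rho` selects ρ from a
log-spaced grid in [1e-3, 10] (8 points) by 5-fold matched-set
cross-validation, scoring held-out sets by the negative penalized
log-likelihood and choosing the elbow (maximum discrete second difference
of the loss over log ρ, arg-min fallback for monotone curves). The
cross-validation loss is evaluated on a panel of P0 = 12 representative
taxa drawn stratified across abundance decades.

Identifiability: σ_a = σ_b = 1 are fixed. The longitudinal submodels
absorb scale through λ/γ, and a single Bernoulli outcome per subject
identifies the disease-side variance only weakly; fixing the scale also
matches the model-based simulator, which draws a, b from N(0, 1).

Optimization is L-BFGS-B with the exact analytic gradient of the
quadrature approximation (the posterior-node-weighted conditional score),
with φ optimized on the log scale. Initialization: α and β21/β22 from
quick ridge-stabilized logistic fits, β11/β12 from least squares on
logit y over the positive samples, φ by method of moments on the
residuals, λ = γ = 0.1. Two random restarts (fixed internal seed, so
refits are bit-reproducible) are attempted on non-convergence; tolerance
is 1e-11 on the relative objective change. Standard errors are square
roots of the diagonal of the inverse observed information of the
penalized objective, computed by central finite differences of the
analytic gradient at the optimum.

Degenerate taxa: an all-zero taxon is skipped (`no_presence`); a
never-absent taxon is fit without the presence part (λ_p fixed at 0) and
tested on one degree of freedom; y = 1 is clipped to 1 − 1e-6 with a
warning and y in (0, 1e-12) is clipped up. Missing time points are
simply absent from the likelihood (random missingness).

## Covariate-taxa pre-selection

For each target taxon a two-stage screen picks x1 and x2, treating all
longitudinal samples as independent. Stage 1 computes Bray-Curtis
distance from the target's across-sample profile (relative abundance for
the abundance part; 0/1 presence for the presence part, where the same
formula equals one minus the Sørensen-Dice overlap) to every candidate
taxon and keeps candidates strictly below the empirical 0.1 quantile
(type-7) of the distance-to-target vector; with fewer than 10 candidates
the single nearest is kept. Stage 2 refines by elastic net (mixing 0.5,
penalty by seeded 5-fold CV): linear on the target's non-zero abundance
against candidate abundances, logistic on the presence indicator against
candidate presences; taxa with non-zero coefficients survive. The target
is never its own covariate, and candidates can be restricted to a named
sub-community.

The quantile is taken over distances to the target (not all pairwise
distances), and the elastic-net mixing and CV design are fixed choices
documented here because no canonical values exist for this screen.

## Synthetic cohorts

`stat_sim` draws a_sj, b_s ~ N(0,1), binarizes each at its median into
high-risk indicators A_sj, B_s (exactly half high-risk for even counts),
draws a genotype G ~ Bernoulli(0.5), and generates outcomes from
logit p = α0 + α1 G + α2 A + α3 B with (α0, α1, α3) = (0.5, −2, 1) and
α2 configurable (default 1).

**Scenario A** (single taxon, Beta-Binomial): the study-level mean at
t = 1 is μ1 ~ Beta(μ0, φ0) rising linearly by 50% across the study
window; set means are Beta(μ_t, φ_t), subject means Beta(μ_st, φ_st),
with additive shifts ±Δμ for high-risk sets/subjects; library sizes are
Poisson(1e5) and counts Binomial. Defaults μ0 = 0.005, φ0 = 200,
φ_t = 50, φ_st = 100 describe a mid-abundance taxon (−log10 y between 2
and 3) whose observed zero fraction is about 0.4 on average but varies
widely across replicates — the regime where a two-part model is most
relevant. Setting both Δ's to 0 gives the null configuration.

**Scenarios B1/B2/C** (count tables with compositional coupling): a
baseline composition spanning six abundance decades (normalized
10^−U(0,6) profile — a synthetic stand-in for a cohort-estimated
baseline) is evolved through a Dirichlet hierarchy: study level
(overdispersion ξ0 = 0.04), an age shift moving mass between two fixed
halves of the community, set level (ξ_t from 0.05 decreasing linearly to
0.03) with a γ-scaled shift for high-risk sets, and subject level
(ξ* = 0.03) with a λ-scaled disease shift for high-risk subjects:
M+ (15% of taxa) gains Δ, M− (15%) loses dΔ and the pseudo-biomarker set
M0 loses (1−d)Δ, d = 0.5 by default and |M0| = 15% of taxa. Δ is a
fraction (γ or λ) of the largest shift compatible with nonnegativity;
mass moves proportionally to current frequencies within each subset
(uniform fallback when a subset's mass vanishes). Scenario B2 ramps the
subject shift linearly with age (slope signal); scenario C partitions
taxa 50% null / 10% M+ / 40% M− with no M0. Library sizes are
Poisson(1e5) truncated at 10,000; counts are Multinomial. Dirichlet
draws with mean m and overdispersion ξ use concentration m(1−ξ)/ξ.

`sim_joint_model` draws data from the fitted model family itself (shared
random effects, ZIB observations, an observed set-level binary covariate
H standing in the α3 position) and is the generator for parameter
recovery checks — it is the only generator in which λ_r is a true
parameter.

What the simulator does not emulate: real taxonomic correlation
structure beyond sum-to-one coupling, time-varying library-size artifacts,
batch effects, and the TEDDY-estimated baseline composition and effect
schedules (controlled-access data; replaced by the synthetic profiles
above). Passing tests therefore demonstrate internal statistical
correctness and the compositional mechanism, not performance on any
specific real cohort.

## Benchmark and metrics

The baseline is the field-standard linear mixed model on
arcsin-square-root transformed abundance (LMM-S: subject intercept;
LMM-N: subject nested in set), fixed effects age, genotype, disease and
genotype×disease, Wald test on the disease main effect (intercept) or a
disease×age term (slope). Metrics per replicate: sensitivity on M+ ∪ M−,
FPR/type I error on null taxa, FDR among calls (0 when none), and FPPR —
positives outside M+ ∪ M− divided by the number of taxa outside M+ ∪ M−
(false and pseudo positives are indistinguishable under compositional
shifts). High-dimensional scenarios call at BH q < 0.15; scenario A at
p < 0.05. Tables are filtered to taxa with mean relative abundance
> 1e-6 and prevalence > 5% before testing; filtered taxa count as not
called.

## Problem sizes and numerical choices

The test suite exercises the pipeline at reduced dimension chosen so the
statistical properties are measurable while a full run stays desk-sized:
500 null replicates at S = 50 pairs for type I error and Wald
calibration, 100 replicates at S = 200 for recovery, and 10 scenario-B1
replicates at P = 120, S = 100 for the FPPR comparison; the published
analyses of this design family use 10,000 single-taxon replicates and
P ≈ 1000-taxon tables, reachable through the same configuration
parameters. Logits are clamped at ±30 inside the likelihood kernel;
non-finite objective values are mapped to a large penalty; Hessian steps
are 1e-5 relative.

## Known limitations

* λ̂_r/λ̂_p are attenuated by the ridge penalty and by coarse quadrature
  (about 15% at Q = 5, under 3% at Q = 15 in model-based recovery runs);
  the Wald test inherits this conservatism.
* Under misspecified generators (Beta-Binomial hierarchy, scenario A) the
  null W is markedly conservative relative to χ²(2) — information-based
  SEs overstate the sampling variance of λ̂ — so type I error is
  controlled but below nominal, and power is correspondingly reduced.
* The Bray-Curtis screen selects profile-similar taxa; for a
  pseudo-biomarker these are typically other co-depleted taxa rather than
  the oppositely-moving drivers. The adjustment still absorbs the shared
  compositional signal (the end-to-end FPPR comparison is the operative
  check), but the covariate list should not be read as a causal driver
  set.
* One global ρ is used for all taxa; per-taxon tuning is out of scope.
* The disease submodel is cross-sectional logistic; no time-to-event
  structure.
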