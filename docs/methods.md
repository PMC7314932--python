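# Methods

This note documents the statistical content of `elicitlgm`: the models and
procedures, the defaults and why they were chosen, the numerical choices,
and what the synthetic-data based tests do and do not establish.

## The latent growth curve model

Three waves of a standardized 0–100 symptom score (at ~1, 3 and 12 months
post-event) are modelled linearly: subject *i* has a latent intercept *Iᵢ*
(expected score at the first wave) and a latent slope *Sᵢ* (expected change
over the full year),

    y_it = I_i + λ_t · S_i + ε_it,        ε_it ~ N(0, θ),
    (I_i, S_i) ~ N₂((α₁, α₂), Ψ),         Ψ = [[ψ₁₁, ψ₂₁], [ψ₂₁, ψ₂₂]].

Slope loadings are fixed at λ₁ = 0 and λ₃ = 1, so α₂ is on a
score-per-year scale. The middle loading is not uniquely determined by the
design; the default is λ₂ = 0.25 (3 of 12 months, linear time). The
alternative reading 2/11 (months 1→12 span 11 months, wave 2 sits 2 months
in) shifts the posterior means for α₁, α₂ by well under one posterior SD on
n = 100 data; a sensitivity test in the suite documents this. Residual
variance θ is shared across waves by default.

The latent variables are marginalized analytically, y_i ~ N₃(Λα, ΛΨΛ′ + θI)
with Λ = [1 | λ], so the likelihood is a 3-dimensional multivariate normal
and the posterior has six free parameters: α₁, α₂, ψ₁₁, ψ₂₂, ρ, θ, where
ψ₂₁ = ρ·√(ψ₁₁ψ₂₂). Parameterizing the covariance through the correlation ρ
keeps Ψ positive definite for any ρ ∈ (−1, 1) and matches the U(−1, 1)
prior, whose support is that of a correlation, not a covariance.

### Benchmark priors and the reference posterior

Two deliberately uninformative prior sets define the *reference posterior*
("what the data say"):

| parameter | benchmark 1 | benchmark 2 |
|---|---|---|
| α₁ | U(0, 100) | N(0, 10⁸) |
| α₂ | U(−100, 100) | N(0, 10⁸) |
| ψ₁₁, ψ₂₂, θ | half-t(3, 196) | same |
| ρ | U(−1, 1) | same |

Benchmark 1 encodes only the instrument's range; benchmark 2 mirrors the
near-flat defaults of common SEM software. The half-t(3, 196) prior is
applied on the variance scale as printed (196 = 14² suggests an SD-scale
convention with scale 14; `LGMSpec(half_t_on_sd=True)` switches to that
reading, with the Jacobian handled internally). The benchmark divergence
reproductions do not depend on this choice. At n ≥ 100 the two benchmarks
give posterior means for α₁, α₂ that agree to a small fraction of a
posterior SD — stable estimation: the priors are overwhelmed by the data.

### Sampling and diagnostics

The posterior is sampled with the affine-invariant ensemble sampler
(emcee) on the natural parameter scale, with out-of-support proposals
rejected through a −∞ log-prior. Walkers start from a method-of-moments
estimate (per-subject OLS intercept/slope; the OLS sampling covariance is
subtracted from the between-subject coefficient covariance to initialize
Ψ) with 2% multiplicative jitter. Defaults: 4 independent ensembles × 32
walkers, 2000 warmup + 2000 retained steps, all randomness derived from a
single user seed (runs are bit-reproducible per platform). Simulation
studies in the test suite use 2 ensembles × 24 walkers with 1000 + 1000
steps, which keeps a twenty-replication recovery study to a few minutes on
one CPU while holding effective sample sizes for the latent means in the
several-hundreds.

Convergence is summarized by split-R̂ computed *across independent
ensembles* (and the early/late halves of each): walkers within an ensemble
interact and are not independent chains, so per-walker R̂ would conflate
walker autocorrelation with non-convergence. Effective sample size is
computed per walker trajectory, which *does* account for that
autocorrelation. A fit with R̂ ≥ 1.01 on either latent mean is flagged
(`converged=False`), never silently returned. Exactly-zero-variance data
are rejected: the likelihood is unbounded there and the posterior
degenerate.

Marginal posteriors for α₁ and α₂ are carried forward as moment-matched
normal approximations (the draws remain available; the agreement module
accepts any density, so a KDE could be substituted by the caller).

## Skew-normal priors from point + bounds

A judgment (point, lower, upper, coverage) is represented as a skew normal
in the direct parameterization SN(ξ, ω, α) such that

* CDF(lower) = (1 − coverage)/2 and CDF(upper) = 1 − (1 − coverage)/2,
* the *mode* equals the point estimate.

Bounds default to a central 98% interval (1st/99th percentiles): "reasonable
bounds" are near-extreme but not absolute limits. The mode (not the median)
is matched because the feedback plot is a density and experts anchor on its
peak; a median-matching variant would be a small change to one residual.

Fitting exploits the structure of the problem rather than a generic
optimizer: given the shape α, the two quantile conditions determine ω and ξ
*exactly* (linearly, from the standard skew-normal quantiles), leaving a
single monotone equation in α — the mode's relative position between the
bounds. That equation is solved by bisection (Brent) on α ∈ [0, 60], with
left-skewed judgments handled by reflection, so symmetric judgments return
α = 0 exactly and mirrored judgments return exactly opposite shapes. A 3-D
least-squares fit over (ξ, ω, α) was evaluated first and abandoned: beyond
|α| ≈ 5 it collapses into zero-gradient regions and misses the required
tolerances. The profiled solve satisfies the quantile conditions to
~1e−12 and the mode to ~1e−8 of the bound width across the feasible range.

Feasibility: the skew-normal family cannot place its mode arbitrarily close
to a bound. With 98% coverage, shapes up to |α| = 60 cover mode positions
from about 2% to 98% of the bound width; judgments outside that range raise
a `FitError` reporting the residuals instead of returning a silently bad
fit. Priors are *not* truncated to the 0–100 instrument range (elicited
densities are displayed unbounded); a warning is emitted when more than 1%
of a fitted prior's mass falls outside it.

The standard skew-normal mode has no closed form; it is computed by bounded
scalar minimization of −pdf on (−1, 1) to 1e−12, which is exact to solver
tolerance.

## Pooling

Group priors are equal-weight *linear* (arithmetic) mixtures: density
Σ wᵢ fᵢ, CDF Σ wᵢ Fᵢ. Linear pooling preserves multimodality, which is the
point when expert groups genuinely disagree; logarithmic pooling would
average disagreement away. The all-experts pool weights every expert
equally (1/K over all K experts) rather than re-weighting groups.
Performance-based weights (Cooke's classical model) are deliberately not
implemented: calibrating experts against the same data they are compared
with would count those data twice.

## Prior–data (dis)agreement

Disagreement is KL(p ‖ q) in nats with p the (normal-approximated)
reference-posterior marginal and q the candidate prior — the information
lost approximating the posterior by the prior. Closed forms are used for
normal–normal and normal–uniform pairs; everything else goes through
adaptive quadrature of p·log(p/q) over p's effective support (±12 SD for a
normal p) to absolute tolerance 1e−8, with the closed forms serving as an
independent cross-check (agreement to 1e−6 nats over a 100-case grid is
asserted in the suite). If the prior's support misses more than 1e−12 of
the posterior's mass the divergence is reported as +∞; below that
threshold the missing tail is ignored — this is what makes
KL(N(22.7, 1.3) ‖ U(0, 100)) finite, as published, despite the normal's
(astronomically small, ~1e−88) mass outside [0, 100]. Natural logs
throughout: the published benchmark rows are only reproduced in nats.

Tables display 2 decimals; companion JSON keeps full precision.

## Synthetic data: what it emulates and what it does not

`TruthConfig` defaults: α₁ = 22.7, α₂ = −14.6, ψ₁₁ = 110, ψ₂₂ = 150,
ρ = −0.3, θ = 60, n = 100, λ = (0, 0.25, 1). The latent means mirror the
published reference posterior; the (co)variances and noise were fixed once
so that an n = 100 benchmark fit yields posterior SDs for the latent means
of ≈ 1.1–1.4 score points (the published magnitudes), with between-subject
SDs (~10–12 points) and measurement noise (~7.7 points) plausible for a
0–100 symptom scale. Scores are clipped to [0, 100] by default, honoring
the instrument.

Clipping matters: under the default truth roughly a quarter of wave-3
scores hit the floor, which biases the fitted slope toward zero — a floor
effect real questionnaire data share but the linear-normal LGM does not
model. Moment checks and parameter-recovery studies therefore run with
`clip=False` (model-consistent draws; `ScoreDataset` relaxes its range
check for such data): recovery is a property of the estimator under the
model. Consequently, passing recovery tests say nothing about robustness
to floor censoring, skewness, dropout, or informative missingness in real
scores — only that the sampler and model are correct under their own
assumptions.

Synthetic experts draw their 10 fictive trajectories from the truth's
individual-level distribution, derive point estimates through the actual
elicitation code path, and place bounds of half-width
z·√(ψ/10)/κ around the (optionally biased) points — an honest expert
(bias 0, κ = 1) states the sampling uncertainty of a 10-person average;
κ > 1 produces overconfidently narrow priors. This emulates the location
and dispersion biases discussed in the elicitation literature, not the
richer cognitive phenomena (anchoring dynamics, availability of severe
cases, nonlinear beliefs).

## Degenerate inputs and edge cases

* Empty trajectory lists, inverted bounds, points outside bounds, empty
  pools, negative weights, invalid coverage/levels: immediate `ValueError`s
  naming the offending item.
* Fewer than 3 trajectories: warning (weak averaging), not an error.
* Missing waves: listwise deletion with a log record.
* Trajectory bands with both priors use ≥ 100,000 seeded Monte Carlo draws;
  at λ = 0 they agree with the intercept-only closed-form band to MC error.

## Known limitations

* Linear growth only; no covariates, no per-wave residual variances beyond
  a config option, no fit indices beyond convergence diagnostics.
* The skew-normal is the only elicitation family (no beta/t alternatives).
* The reference posterior enters KL as a normal approximation; for
  strongly non-normal posteriors (tiny n) the reported divergences inherit
  that approximation error — the ~0.02-nat gap between the closed-form
  reproductions and the published benchmark values is of exactly this kind.
* emcee walker ensembles mix slowly relative to gradient-based samplers;
  the defaults compensate with steps, which is adequate for this six-parameter
  problem but would not scale to many more parameters.
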