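# elicitlgm

Expert elicitation for Bayesian latent growth curve models (LGMs), with
prior–data (dis)agreement diagnostics.

When longitudinal samples are small — the motivating case is posttraumatic
stress symptom (PTSS) development in children after burn injuries, measured
on a standardized 0–100 questionnaire scale at roughly 1, 3 and 12 months —
clinical experts are an alternative source of information. This package
implements a multi-parameter Five-Step elicitation workflow and the
machinery to compare what experts believe with what the data say:

1. **Indirect elicitation** — an expert sketches 10 fictive individual
   trajectories (score at first month, score at 12 months); their averages
   give point estimates for the group mean intercept α₁ and yearly slope α₂.
2. **Feedback** on the implied average trajectory.
3. **Direct elicitation** — a reasonable lower/upper bound around each point
   estimate (read as a central 98% interval by default).
4. **Distribution fitting & feedback** — each judgment becomes a skew-normal
   prior SN(ξ, ω, α) whose tail quantiles hit the bounds and whose mode is
   the point estimate; credible bands for the implied trajectory are shown.
5. **Aggregation** — experts are pooled by equal-weight linear opinion
   pooling into group mixture priors.

On the data side, the three-wave linear LGM

    y_it = I_i + λ_t·S_i + ε_it,   (I_i, S_i) ~ N₂((α₁, α₂), Ψ),   ε_it ~ N(0, θ),

with λ = (0, 0.25, 1), is fitted by MCMC under deliberately uninformative
*benchmark* priors — either U(0,100)/U(−100,100) on the latent means
(benchmark 1) or N(0, 10⁸) (benchmark 2), with half-t(3, 196) priors on
ψ₁₁, ψ₂₂, θ and U(−1,1) on the intercept–slope correlation — yielding the
*reference posterior*. Each candidate prior q is then scored by the
Kullback–Leibler divergence KL(posterior ‖ q) in nats: the information lost
when the data-driven posterior is approximated by that prior. Larger KL =
stronger prior–data disagreement; overconfident priors in the wrong place
are penalized heavily.

A seeded synthetic-data module simulates both patient score datasets from a
known truth and expert judgments with controllable bias and overconfidence,
so the complete pipeline is testable end to end without any external data.

## Worked example

```python
import elicitlgm as el

# what the data say: simulate 100 children from a known truth and fit the
# reference posterior under benchmark-2 priors
data = el.simulate_scores(el.TruthConfig(seed=3, clip=False))
model = el.LatentGrowthModel(data, el.default_benchmark_spec("benchmark2"))
result = model.fit(seed=1, config=el.MCMCConfig(chains=2, walkers=24,
                                                warmup=1000, draws=1000))
print(result.summary())

# what an expert says: point 30 with bounds (25, 45) -> right-skewed prior
prior = el.fit_skew_normal(el.BoundJudgment(point=30, lower=25, upper=45))
print(prior)

# how far apart they are
print(el.kl_divergence(result.marginal("alpha1"), prior))
```

prints (abridged):

```
Latent growth curve model — reference posterior
  spec: benchmark2   n subjects: 100   loadings: (0.0, 0.25, 1.0)
  sampler: emcee, 2 ensembles x 24 walkers, 1000+1000 steps, seed 1
  converged: True

  param         mean       sd     2.5%    97.5%   R-hat     ESS
  alpha1      23.044    1.260   20.516   25.482   1.001     584
  alpha2     -12.670    1.616  -15.833   -9.486   1.002     538
  psi11      115.502   22.740   75.458  164.017   1.001     419
  psi22      151.879   39.837   81.402  238.587   1.003     487
  rho         -0.359    0.130   -0.583   -0.077   1.003     448
  theta       56.241    8.653   42.075   75.884   1.004     544
SkewNormalPrior(location=27.1039..., scale=6.9477..., shape=4.0026..., label='')
5.5772...
```

The posterior mean intercept ≈ 23.0 (true 22.7) with SD ≈ 1.3: at n = 100
the benchmark priors are overwhelmed by the data. The elicited prior peaks
at 30 with a right skew (shape ≈ 4) but is visibly too high and too
confident relative to the posterior: its divergence (≈ 5.6 nats) exceeds
even the uninformative uniform benchmark's (≈ 3.1 nats) — exactly the kind
of overconfidence penalty the KL diagnostic is designed to expose.

The same pipeline is scriptable from the shell via the `elicit` command
(`simulate`, `derive`, `fit-prior`, `pool`, `fit-lgm`, `agreement`).

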