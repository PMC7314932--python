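"""Bayesian linear latent growth curve model for three-wave score data.

The model: subject i carries a latent intercept Iᵢ and slope Sᵢ,

    (Iᵢ, Sᵢ) ~ N₂((α₁, α₂), Ψ),      Ψ = [[ψ₁₁, ψ₂₁], [ψ₂₁, ψ₂₂]],
    y_it = Iᵢ + λ_t·Sᵢ + ε_it,        ε_it ~ N(0, θ),

with slope loadings λ fixed at 0 for the first wave and 1 for the last, so
α₂ is the expected change over the full follow-up (one year).  The latent
variables are marginalized analytically: y_i ~ N₃(Λα, ΛΨΛ' + θI), which
makes the likelihood a three-dimensional multivariate normal and the
posterior a six-parameter problem (α₁, α₂, ψ₁₁, ψ₂₂, ρ, θ), with ψ₂₁
parameterized through the correlation ρ = ψ₂₁/√(ψ₁₁ψ₂₂).

The reference posterior is obtained under deliberately uninformative
benchmark priors — either uniforms that encode only the instrument's range
(benchmark 1) or near-flat normals (benchmark 2) — and sampled with the
affine-invariant ensemble sampler (emcee), run as several independent
ensembles so that split-R̂ across ensembles is a valid convergence check.

Shape of the API follows the statsmodels convention: build a
:class:`LatentGrowthModel` from data, call :meth:`~LatentGrowthModel.fit`,
receive :class:`LGMResults` carrying draws, moment-matched marginal normal
approximations, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy import linalg

from .densities import Density, HalfT, Normal, Uniform

__all__ = [
    "ScoreDataset",
    "LGMSpec",
    "MCMCConfig",
    "PosteriorSummary",
    "LGMResults",
    "LatentGrowthModel",
    "default_benchmark_spec",
    "fit_reference_posterior",
    "PARAM_NAMES",
]

logger = logging.getLogger(__name__)

PARAM_NAMES = ("alpha1", "alpha2", "psi11", "psi22", "rho", "theta")

DEFAULT_LOADINGS = (0.0, 0.25, 1.0)  # waves at ~1, 3 and 12 months
CLINICAL_CUTOFF = 42.0


@dataclass(frozen=True)
class ScoreDataset:
    """n subjects × 3 waves of standardized 0-100 symptom scores.

    ``enforce_range`` may be disabled for model-consistent simulated data
    whose latent-normal draws are deliberately left unbounded.
    """

    scores: np.ndarray  # shape (n, n_waves)
    subject_ids: Tuple[str, ...] = ()
    wave_months: Tuple[float, ...] = (1.0, 3.0, 12.0)
    clinical_cutoff: float = CLINICAL_CUTOFF
    enforce_range: bool = True

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2 or scores.shape[0] < 1:
            raise ValueError("scores must be a non-empty (n, waves) matrix")
        if np.isnan(scores).any():
            keep = ~np.isnan(scores).any(axis=1)
            logger.info(
                "listwise deletion: dropping %d of %d subjects with missing waves",
                int((~keep).sum()), scores.shape[0],
            )
            scores = scores[keep]
            object.__setattr__(self, "scores", scores)
            if scores.shape[0] < 1:
                raise ValueError("no complete cases remain after listwise deletion")
        if self.enforce_range and (scores.min() < 0.0 or scores.max() > 100.0):
            raise ValueError("scores must lie within [0, 100]")
        if not self.subject_ids:
            object.__setattr__(
                self, "subject_ids", tuple(f"s{i+1}" for i in range(scores.shape[0]))
            )

    @property
    def n_subjects(self) -> int:
        return self.scores.shape[0]

    @property
    def n_waves(self) -> int:
        return self.scores.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ScoreDataset":
        """Build from a DataFrame with columns id, t1, t2, t3."""
        cols = [c for c in df.columns if c.lower().startswith("t") and c[1:].isdigit()]
        cols = sorted(cols, key=lambda c: int(c[1:]))
        if len(cols) < 3:
            raise ValueError(f"need wave columns t1..t3, found {list(df.columns)}")
        ids = tuple(str(v) for v in df["id"]) if "id" in df.columns else ()
        return cls(df[cols].to_numpy(dtype=float), subject_ids=ids, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ScoreDataset":
        return cls.from_dataframe(pd.read_csv(path), **kwargs)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores, columns=[f"t{j+1}" for j in range(self.n_waves)]
        )
        df.insert(0, "id", list(self.subject_ids))
        return df


@dataclass(frozen=True)
class LGMSpec:
    """Model definition: slope loadings plus priors for the six parameters.

    ``prior_psi21`` is a prior on the intercept-slope *correlation*
    (support within [-1, 1]); the covariance is derived as ρ·√(ψ₁₁ψ₂₂).
    ``half_t_on_sd`` switches the half-t variance priors to the SD scale
    (scale √196 = 14) for users who read the prior's scale parameter as an
    SD convention.
    """

    loadings: Tuple[float, ...] = DEFAULT_LOADINGS
    prior_alpha1: Density = field(default_factory=lambda: Uniform(0.0, 100.0))
    prior_alpha2: Density = field(default_factory=lambda: Uniform(-100.0, 100.0))
    prior_psi11: Density = field(default_factory=lambda: HalfT(3.0, 196.0))
    prior_psi22: Density = field(default_factory=lambda: HalfT(3.0, 196.0))
    prior_psi21: Density = field(default_factory=lambda: Uniform(-1.0, 1.0))
    prior_theta: Density = field(default_factory=lambda: HalfT(3.0, 196.0))
    half_t_on_sd: bool = False
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(self.loadings) < 3:
            raise ValueError("need at least three waves of loadings")
        if self.loadings[0] != 0.0 or self.loadings[-1] != 1.0:
            raise ValueError("slope loadings must start at 0 and end at 1")
        lo, hi = self.prior_psi21.support
        if lo < -1.0 or hi > 1.0:
            raise ValueError("psi21 prior must be supported within [-1, 1] (correlation)")

    def _variance_logprior(self, prior: Density, value: float) -> float:
        if self.half_t_on_sd:
            # prior placed on the SD; scale 196 on the variance corresponds
            # to scale 14 on the SD.  Includes the Jacobian of v -> sqrt(v).
            sd_prior = HalfT(prior.df, float(np.sqrt(prior.scale)))  # type: ignore[attr-defined]
            sd = np.sqrt(value)
            return float(sd_prior.logpdf(sd) - np.log(2.0 * sd))
        return float(prior.logpdf(value))

    def log_prior(self, params: np.ndarray) -> float:
        a1, a2, p11, p22, rho, th = params
        if p11 <= 0 or p22 <= 0 or th <= 0 or not (-1.0 < rho < 1.0):
            return -np.inf
        lp = 0.0
        for prior, value in ((self.prior_alpha1, a1), (self.prior_alpha2, a2),
                             (self.prior_psi21, rho)):
            v = prior.logpdf(value)
            if not np.isfinite(v):
                return -np.inf
            lp += float(v)
        for prior, value in ((self.prior_psi11, p11), (self.prior_psi22, p22),
                             (self.prior_theta, th)):
            v = self._variance_logprior(prior, value)
            if not np.isfinite(v):
                return -np.inf
            lp += v
        return lp


def default_benchmark_spec(which: str) -> LGMSpec:
    """Benchmark prior sets for the reference posterior.

    ``benchmark1`` encodes only the instrument: U(0, 100) on the group mean
    intercept and U(-100, 100) on the group mean slope.  ``benchmark2``
    uses the near-flat N(0, 10⁸) defaults common in SEM software for both
    latent means.  Both share half-t(3, 196) priors on the variance
    components and U(-1, 1) on the intercept-slope correlation.
    """
    which = which.lower().replace(" ", "")
    if which in ("benchmark1", "1", "b1"):
        return LGMSpec(name="benchmark1")
    if which in ("benchmark2", "2", "b2"):
        return LGMSpec(
            prior_alpha1=Normal(0.0, 1e8),
            prior_alpha2=Normal(0.0, 1e8),
            name="benchmark2",
        )
    raise ValueError(f"unknown benchmark {which!r}; expected 'benchmark1' or 'benchmark2'")


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings: independent ensembles ('chains') of emcee walkers."""

    chains: int = 4
    walkers: int = 32
    warmup: int = 2000
    draws: int = 2000

    def __post_init__(self) -> None:
        if self.chains < 1 or self.walkers < 12 or self.warmup < 1 or self.draws < 1:
            raise ValueError("invalid MCMC configuration")


def _reduced_config() -> MCMCConfig:
    """Lighter settings for simulation studies (many repeated fits)."""
    return MCMCConfig(chains=2, walkers=24, warmup=1000, draws=1000)


def _fast_logpdf(prior: Density):
    """Closed-form scalar log-density closure (the MCMC hot path).

    Equivalent to ``prior.logpdf`` but avoids scipy's per-call machinery;
    equality with the generic path is asserted in the test suite.
    """
    import math

    if isinstance(prior, Uniform):
        lo, hi, c = prior.low, prior.high, -math.log(prior.width)
        return lambda x: c if lo <= x <= hi else -np.inf
    if isinstance(prior, Normal):
        mu, var = prior.mean, prior.variance
        c = -0.5 * math.log(2.0 * math.pi * var)
        return lambda x: c - 0.5 * (x - mu) ** 2 / var
    if isinstance(prior, HalfT):
        df, scale = prior.df, prior.scale
        c = (
            math.log(2.0)
            + math.lgamma((df + 1.0) / 2.0)
            - math.lgamma(df / 2.0)
            - 0.5 * math.log(df * math.pi)
            - math.log(scale)
        )
        e = -(df + 1.0) / 2.0
        return lambda x: (c + e * math.log1p((x / scale) ** 2 / df)) if x >= 0 else -np.inf
    return lambda x: float(prior.logpdf(x))


class _LogPosterior:
    """Marginal MVN log-posterior; per-call cost independent of n.

    With S = Σᵢ yᵢyᵢ' and ȳ precomputed, the Gaussian exponent
    Σᵢ (yᵢ-μ)'Σ⁻¹(yᵢ-μ) reduces to tr(Σ⁻¹·[S - n(ȳμ'+μȳ') + nμμ']).
    """

    def __init__(self, data: ScoreDataset, spec: LGMSpec):
        self.spec = spec
        Y = data.scores
        self.n = Y.shape[0]
        self.ybar = Y.mean(axis=0)
        self.S = Y.T @ Y
        lam = np.asarray(spec.loadings, dtype=float)
        self.Lambda = np.column_stack([np.ones_like(lam), lam])
        self.n_waves = len(lam)
        self._lp_a1 = _fast_logpdf(spec.prior_alpha1)
        self._lp_a2 = _fast_logpdf(spec.prior_alpha2)
        self._lp_rho = _fast_logpdf(spec.prior_psi21)
        if spec.half_t_on_sd:
            self._lp_var = lambda prior, v: spec._variance_logprior(prior, v)
        else:
            fasts = {
                id(spec.prior_psi11): _fast_logpdf(spec.prior_psi11),
                id(spec.prior_psi22): _fast_logpdf(spec.prior_psi22),
                id(spec.prior_theta): _fast_logpdf(spec.prior_theta),
            }
            self._lp_var = lambda prior, v: fasts[id(prior)](v)

    def log_prior(self, params: np.ndarray) -> float:
        a1, a2, p11, p22, rho, th = params
        if p11 <= 0 or p22 <= 0 or th <= 0 or not (-1.0 < rho < 1.0):
            return -np.inf
        lp = (
            self._lp_a1(a1)
            + self._lp_a2(a2)
            + self._lp_rho(rho)
            + self._lp_var(self.spec.prior_psi11, p11)
            + self._lp_var(self.spec.prior_psi22, p22)
            + self._lp_var(self.spec.prior_theta, th)
        )
        return lp if np.isfinite(lp) else -np.inf

    def __call__(self, params: np.ndarray) -> float:
        lp = self.log_prior(params)
        if not np.isfinite(lp):
            return -np.inf
        a1, a2, p11, p22, rho, th = params
        psi21 = rho * np.sqrt(p11 * p22)
        Psi = np.array([[p11, psi21], [psi21, p22]])
        Sigma = self.Lambda @ Psi @ self.Lambda.T + th * np.eye(self.n_waves)
        try:
            cho = linalg.cho_factor(Sigma, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return -np.inf
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        mu = self.Lambda @ np.array([a1, a2])
        M = (
            self.S
            - self.n * (np.outer(self.ybar, mu) + np.outer(mu, self.ybar))
            + self.n * np.outer(mu, mu)
        )
        quad = np.trace(linalg.cho_solve(cho, M, check_finite=False))
        ll = -0.5 * (self.n * (self.n_waves * np.log(2.0 * np.pi) + logdet) + quad)
        return lp + ll


def _moment_start(data: ScoreDataset, spec: LGMSpec) -> np.ndarray:
    """Method-of-moments start from per-subject OLS intercepts/slopes."""
    lam = np.asarray(spec.loadings, dtype=float)
    X = np.column_stack([np.ones_like(lam), lam])
    pinv = np.linalg.pinv(X)
    betas = data.scores @ pinv.T  # (n, 2)
    resid = data.scores - betas @ X.T
    dof = max(len(lam) - 2, 1)
    theta = float(np.mean(np.sum(resid**2, axis=1)) / dof)
    theta = max(theta, 1e-2)
    alpha = betas.mean(axis=0)
    B = np.cov(betas.T) if data.n_subjects > 1 else np.eye(2)
    # sampling noise of the OLS coefficients inflates cov(betas); remove it
    Psi = B - theta * pinv @ pinv.T
    p11 = max(float(Psi[0, 0]), 1e-2)
    p22 = max(float(Psi[1, 1]), 1e-2)
    rho = float(np.clip(Psi[0, 1] / np.sqrt(p11 * p22), -0.9, 0.9))
    a1 = float(np.clip(alpha[0], *_clip_interval(spec.prior_alpha1)))
    a2 = float(np.clip(alpha[1], *_clip_interval(spec.prior_alpha2)))
    return np.array([a1, a2, p11, p22, rho, theta])


def _clip_interval(prior: Density) -> Tuple[float, float]:
    lo, hi = prior.support
    eps = 1e-6
    lo = lo + eps if np.isfinite(lo) else -1e12
    hi = hi - eps if np.isfinite(hi) else 1e12
    return lo, hi


@dataclass
class PosteriorSummary:
    """Marginal normal approximations plus diagnostics for each parameter."""

    means: Dict[str, float]
    variances: Dict[str, float]
    rhat: Dict[str, float]
    ess: Dict[str, float]
    converged: bool
    n_subjects: int
    spec_name: str

    def marginal(self, name: str) -> Normal:
        if name not in self.means:
            raise KeyError(f"no marginal for parameter {name!r}")
        return Normal(self.means[name], self.variances[name], label=name)

    def to_dict(self) -> dict:
        return {
            "params": {
                k: {"mean": self.means[k], "var": self.variances[k]} for k in self.means
            },
            "diagnostics": {
                "rhat": self.rhat,
                "ess": self.ess,
                "converged": self.converged,
            },
            "n_subjects": self.n_subjects,
            "spec": self.spec_name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PosteriorSummary":
        params = d["params"]
        diag = d.get("diagnostics", {})
        return cls(
            means={k: float(v["mean"]) for k, v in params.items()},
            variances={k: float(v["var"]) for k, v in params.items()},
            rhat={k: float(v) for k, v in diag.get("rhat", {}).items()},
            ess={k: float(v) for k, v in diag.get("ess", {}).items()},
            converged=bool(diag.get("converged", True)),
            n_subjects=int(d.get("n_subjects", 0)),
            spec_name=str(d.get("spec", "unknown")),
        )


class LGMResults:
    """Posterior sample and summaries from a fitted latent growth model."""

    def __init__(
        self,
        model: "LatentGrowthModel",
        chains: np.ndarray,  # (ensemble*walker, step, param), walker-major
        seed: int,
        config: MCMCConfig,
    ):
        self.model = model
        self.chains = chains
        self.seed = seed
        self.config = config
        flat = chains.reshape(-1, chains.shape[-1])
        self._flat = flat
        # ESS at walker granularity: each walker's trajectory is autocorrelated
        ess = az.ess(az.from_dict(
            posterior={name: chains[..., k] for k, name in enumerate(PARAM_NAMES)}
        ))
        # R-hat at ensemble granularity: independent ensembles must agree, and
        # so must the early and late halves of each (split-R-hat); individual
        # walkers within an ensemble are not independent chains
        by_ensemble = (
            chains.reshape(config.chains, config.walkers, config.draws, -1)
            .transpose(0, 2, 1, 3)  # step-major flattening within ensemble
            .reshape(config.chains, config.walkers * config.draws, -1)
        )
        rhat = az.rhat(az.from_dict(
            posterior={name: by_ensemble[..., k] for k, name in enumerate(PARAM_NAMES)}
        ))
        self.rhat = {name: float(rhat[name].values) for name in PARAM_NAMES}
        self.ess = {name: float(ess[name].values) for name in PARAM_NAMES}
        self.converged = all(self.rhat[p] < 1.01 for p in ("alpha1", "alpha2"))
        if not self.converged:
            logger.warning(
                "reference posterior flagged non-converged: R-hat alpha1=%.3f alpha2=%.3f",
                self.rhat["alpha1"], self.rhat["alpha2"],
            )

    # -- accessors ----------------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(self._flat.mean(axis=0), index=PARAM_NAMES)

    @property
    def draws(self) -> pd.DataFrame:
        return pd.DataFrame(self._flat, columns=PARAM_NAMES)

    def posterior_mean(self, name: str) -> float:
        return float(self._flat[:, PARAM_NAMES.index(name)].mean())

    def posterior_var(self, name: str) -> float:
        return float(self._flat[:, PARAM_NAMES.index(name)].var(ddof=1))

    def posterior_sd(self, name: str) -> float:
        return float(np.sqrt(self.posterior_var(name)))

    def credible_interval(self, name: str, level: float = 0.95) -> Tuple[float, float]:
        if not (0.0 < level < 1.0):
            raise ValueError("level must be in (0, 1)")
        x = self._flat[:, PARAM_NAMES.index(name)]
        p = (1.0 - level) / 2.0
        lo, hi = np.quantile(x, [p, 1.0 - p])
        return float(lo), float(hi)

    def marginal(self, name: str) -> Normal:
        """Moment-matched normal approximation of one marginal posterior."""
        return Normal(self.posterior_mean(name), self.posterior_var(name), label=name)

    def summarize(self) -> PosteriorSummary:
        return PosteriorSummary(
            means={p: self.posterior_mean(p) for p in PARAM_NAMES},
            variances={p: self.posterior_var(p) for p in PARAM_NAMES},
            rhat=self.rhat,
            ess=self.ess,
            converged=self.converged,
            n_subjects=self.model.data.n_subjects,
            spec_name=self.model.spec.name,
        )

    def summary(self) -> str:
        lines = [
            "Latent growth curve model — reference posterior",
            f"  spec: {self.model.spec.name}   n subjects: {self.model.data.n_subjects}"
            f"   loadings: {tuple(self.model.spec.loadings)}",
            f"  sampler: emcee, {self.config.chains} ensembles x {self.config.walkers}"
            f" walkers, {self.config.warmup}+{self.config.draws} steps, seed {self.seed}",
            f"  converged: {self.converged}",
            "",
            f"  {'param':<8}{'mean':>10}{'sd':>9}{'2.5%':>9}{'97.5%':>9}"
            f"{'R-hat':>8}{'ESS':>8}",
        ]
        for p in PARAM_NAMES:
            lo, hi = self.credible_interval(p, 0.95)
            lines.append(
                f"  {p:<8}{self.posterior_mean(p):>10.3f}{self.posterior_sd(p):>9.3f}"
                f"{lo:>9.3f}{hi:>9.3f}{self.rhat[p]:>8.3f}{self.ess[p]:>8.0f}"
            )
        return "\n".join(lines)


class LatentGrowthModel:
    """Three-wave linear latent growth model, fitted by MCMC.

    Parameters
    ----------
    data : ScoreDataset or DataFrame
        n × 3 score matrix on the 0-100 scale (columns t1..t3 if a frame).
    spec : LGMSpec, optional
        Priors and loadings; defaults to the benchmark-2 reference priors.
    """

    def __init__(self, data, spec: Optional[LGMSpec] = None):
        if isinstance(data, pd.DataFrame):
            data = ScoreDataset.from_dataframe(data)
        if not isinstance(data, ScoreDataset):
            data = ScoreDataset(np.asarray(data, dtype=float))
        self.data = data
        self.spec = spec if spec is not None else default_benchmark_spec("benchmark2")
        if len(self.spec.loadings) != data.n_waves:
            raise ValueError(
                f"spec has {len(self.spec.loadings)} loadings but data has "
                f"{data.n_waves} waves"
            )
        if float(np.var(data.scores)) == 0.0:
            raise ValueError("degenerate data: all scores identical (zero variance)")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec: Optional[LGMSpec] = None):
        return cls(ScoreDataset.from_dataframe(df), spec)

    @classmethod
    def from_csv(cls, path, spec: Optional[LGMSpec] = None):
        return cls(ScoreDataset.from_csv(path), spec)

    def fit(self, seed: int = 0, config: Optional[MCMCConfig] = None) -> LGMResults:
        """Sample the posterior; seeded and reproducible given (seed, config)."""
        config = config or MCMCConfig()
        log_prob = _LogPosterior(self.data, self.spec)
        start = _moment_start(self.data, self.spec)
        ndim = len(PARAM_NAMES)
        child_seeds = np.random.SeedSequence(seed).generate_state(config.chains)

        chain_draws = []
        for c in range(config.chains):
            rs = np.random.RandomState(int(child_seeds[c] % (2**31 - 1)))
            p0 = start[None, :] * (1.0 + 0.02 * rs.randn(config.walkers, ndim))
            p0[:, 4] = np.clip(start[4] + 0.05 * rs.randn(config.walkers), -0.95, 0.95)
            p0[:, 2:4] = np.abs(p0[:, 2:4]) + 1e-3
            p0[:, 5] = np.abs(p0[:, 5]) + 1e-3
            # keep means inside bounded prior support
            p0[:, 0] = np.clip(p0[:, 0], *_clip_interval(self.spec.prior_alpha1))
            p0[:, 1] = np.clip(p0[:, 1], *_clip_interval(self.spec.prior_alpha2))
            sampler = emcee.EnsembleSampler(config.walkers, ndim, log_prob)
            state = emcee.State(p0, random_state=rs.get_state())
            state = sampler.run_mcmc(state, config.warmup, progress=False)
            sampler.reset()
            sampler.run_mcmc(state, config.draws, progress=False)
            # (steps, walkers, ndim) -> per-walker chains (walkers, steps, ndim)
            chain_draws.append(sampler.get_chain().transpose(1, 0, 2))
        # every walker of every ensemble is one chain for the diagnostics
        chains = np.concatenate(chain_draws, axis=0)
        return LGMResults(self, chains, seed, config)


def fit_reference_posterior(
    data: ScoreDataset,
    spec: LGMSpec,
    mcmc_config: Optional[MCMCConfig] = None,
    seed: int = 0,
) -> PosteriorSummary:
    """One-call reference posterior: fit the LGM and summarize marginals."""
    return LatentGrowthModel(data, spec).fit(seed=seed, config=mcmc_config).summarize()
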