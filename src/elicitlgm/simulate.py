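"""Synthetic longitudinal scores and synthetic expert judgments.

Everything downstream of data collection is testable without any external
download: this module draws patient score datasets from a known linear
latent growth process on the 0-100 instrument scale, and fabricates expert
judgments with controllable location bias and overconfidence so the whole
elicitation → pooling → agreement pipeline can be exercised end to end.

The default truth places the group mean intercept at 22.7 and the yearly
change at −14.6 (a clear average recovery that most individuals, but not
all, follow), with between-subject SDs around 10-12 score points, a mild
negative intercept-slope correlation, and measurement noise of SD ≈ 7.7 —
magnitudes a three-wave questionnaire study of ~100 children would
plausibly produce.  At n = 100 these settings give reference-posterior SDs
for the latent means close to 1.1-1.4 score points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from .lgm import DEFAULT_LOADINGS, ScoreDataset
from .pooling import ExpertGroup, ExpertJudgment
from .skewnorm import BoundJudgment, fit_skew_normal
from .trajectories import Trajectory, derive_point_estimates

__all__ = ["TruthConfig", "ExpertProfile", "simulate_scores", "simulate_expert"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TruthConfig:
    """True data-generating latent growth process."""

    alpha1: float = 22.7
    alpha2: float = -14.6
    psi11: float = 110.0
    psi22: float = 150.0
    corr: float = -0.3
    theta: float = 60.0
    n: int = 100
    loadings: Tuple[float, ...] = DEFAULT_LOADINGS
    seed: int = 0
    clip: bool = True  # honor the instrument's [0, 100] range

    def __post_init__(self) -> None:
        if self.psi11 <= 0 or self.psi22 <= 0 or self.theta <= 0:
            raise ValueError("variances must be positive")
        if not (-1.0 < self.corr < 1.0):
            raise ValueError("correlation must lie in (-1, 1)")
        if self.n < 1:
            raise ValueError("need at least one subject")

    @property
    def latent_mean(self) -> np.ndarray:
        return np.array([self.alpha1, self.alpha2])

    @property
    def latent_cov(self) -> np.ndarray:
        c = self.corr * np.sqrt(self.psi11 * self.psi22)
        return np.array([[self.psi11, c], [c, self.psi22]])

    def wave_means(self) -> np.ndarray:
        lam = np.asarray(self.loadings)
        return self.alpha1 + lam * self.alpha2

    def wave_cov(self) -> np.ndarray:
        lam = np.asarray(self.loadings)
        L = np.column_stack([np.ones_like(lam), lam])
        return L @ self.latent_cov @ L.T + self.theta * np.eye(len(lam))


@dataclass(frozen=True)
class ExpertProfile:
    """How a synthetic expert deviates from the truth.

    ``bias`` shifts the expert's beliefs about both latent means (score
    units); ``overconfidence`` κ divides the honest bound width, so κ > 1
    produces too-narrow priors and κ < 1 too-wide ones.
    """

    bias: float = 0.0
    overconfidence: float = 1.0
    group: ExpertGroup = ExpertGroup.OTHER
    expert_id: str = "synthetic-expert"
    n_trajectories: int = 10
    coverage: float = 0.98

    def __post_init__(self) -> None:
        if self.overconfidence <= 0:
            raise ValueError("overconfidence factor must be positive")
        if self.n_trajectories < 1:
            raise ValueError("need at least one trajectory")


def simulate_scores(cfg: TruthConfig) -> ScoreDataset:
    """Draw an n × waves score dataset from the true growth process.

    Subject latents (Iᵢ, Sᵢ) are bivariate normal; observed scores add
    N(0, θ) noise per wave.  With ``clip`` the scores are truncated to the
    instrument range and the clipped fraction is logged.
    """
    rng = np.random.default_rng(cfg.seed)
    latents = rng.multivariate_normal(cfg.latent_mean, cfg.latent_cov, size=cfg.n)
    lam = np.asarray(cfg.loadings)
    scores = latents[:, [0]] + np.outer(latents[:, 1], lam)
    scores = scores + rng.normal(0.0, np.sqrt(cfg.theta), size=scores.shape)
    if cfg.clip:
        clipped = np.mean((scores < 0.0) | (scores > 100.0))
        if clipped > 0:
            logger.info("clipped %.2f%% of simulated scores to [0, 100]", 100 * clipped)
        scores = np.clip(scores, 0.0, 100.0)
        return ScoreDataset(scores)
    # unbounded draws stay exactly model-consistent (moment and recovery checks)
    return ScoreDataset(scores, enforce_range=False)


def simulate_expert(
    truth: TruthConfig,
    profile: ExpertProfile,
    seed: Optional[int] = None,
) -> ExpertJudgment:
    """Fabricate one expert's full elicitation product.

    The fictive trajectories are genuine draws from the truth's
    individual-level latent distribution (start = I, end = I + S, clipped
    to the instrument range).  The bound judgments are centred on the
    trajectory-derived point estimates shifted by the profile's bias; an
    honest expert's bound half-width is the coverage-level quantile of the
    sampling uncertainty of a 10-trajectory average, and the profile's
    overconfidence factor divides that width.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    latents = rng.multivariate_normal(
        truth.latent_mean, truth.latent_cov, size=profile.n_trajectories
    )
    starts = np.clip(latents[:, 0], 0.0, 100.0)
    ends = np.clip(latents[:, 0] + latents[:, 1], 0.0, 100.0)
    trajectories = tuple(
        Trajectory(f"fictive-{i+1}", float(s), float(e))
        for i, (s, e) in enumerate(zip(starts, ends))
    )
    points = derive_point_estimates(trajectories)

    z = stats.norm.ppf((1.0 + profile.coverage) / 2.0)
    k = profile.n_trajectories

    def judgment(point: float, psi: float) -> BoundJudgment:
        half_width = z * np.sqrt(psi / k) / profile.overconfidence
        return BoundJudgment(
            point=point,
            lower=point - half_width,
            upper=point + half_width,
            coverage=profile.coverage,
        )

    j_int = judgment(points.intercept_point + profile.bias, truth.psi11)
    j_slo = judgment(points.slope_point + profile.bias, truth.psi22)
    prior_int = fit_skew_normal(j_int, label=f"{profile.expert_id}-intercept")
    prior_slo = fit_skew_normal(
        j_slo, label=f"{profile.expert_id}-slope", instrument_range=(-100.0, 100.0)
    )
    return ExpertJudgment(
        expert_id=profile.expert_id,
        group=profile.group,
        intercept_prior=prior_int,
        slope_prior=prior_slo,
        trajectories=trajectories,
        intercept_judgment=j_int,
        slope_judgment=j_slo,
    )
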