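"""Skew-normal representation of an elicited belief.

The direct stage of the elicitation asks the expert for a reasonable lower
and upper bound around the point estimate obtained from the trajectories.
The three numbers are translated into a skew-normal distribution in the
location-scale-shape (direct) parameterization: the bounds are read as the
tails of a central credible interval (98% by default, i.e. the 1st/99th
percentiles) and the point estimate as the mode — the visually dominant
feature of the density plot the expert is shown as feedback.

Asymmetric bounds therefore produce skewed beliefs; symmetric bounds
recover an ordinary normal (shape 0).  Given the shape, the quantile
conditions determine location and scale exactly, so fitting reduces to a
single monotone root-find in the shape parameter.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

__all__ = [
    "SkewNormalPrior",
    "BoundJudgment",
    "fit_skew_normal",
    "credible_interval",
    "band_for_trajectory",
]

_SQRT_2_OVER_PI = np.sqrt(2.0 / np.pi)


def _standard_mode(shape: float) -> float:
    """Mode of the standard skew normal SN(0, 1, shape), numerically.

    No closed form exists for shape ≠ 0; the mode always lies in (-1, 1).
    """
    if shape == 0.0:
        return 0.0
    res = optimize.minimize_scalar(
        lambda x: -stats.skewnorm.pdf(x, shape),
        bounds=(-1.0, 1.0),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


@dataclass(frozen=True)
class SkewNormalPrior:
    """Skew-normal belief in direct (location ξ, scale ω, shape α) form.

    shape = 0 recovers Normal(ξ, ω²).  Score units for ξ and ω.
    """

    location: float
    scale: float
    shape: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    # -- distribution services (scipy skewnorm backend) -------------------
    def _dist(self):
        return stats.skewnorm(self.shape, loc=self.location, scale=self.scale)

    @property
    def support(self) -> Tuple[float, float]:
        return (-np.inf, np.inf)

    def pdf(self, x):
        return self._dist().pdf(x)

    def logpdf(self, x):
        return self._dist().logpdf(x)

    def cdf(self, x):
        return self._dist().cdf(x)

    def ppf(self, q):
        return self._dist().ppf(q)

    def rvs(self, size, rng: np.random.Generator):
        return self._dist().rvs(size=size, random_state=rng)

    def mean(self) -> float:
        """Analytic mean ξ + ω·δ·√(2/π) with δ = α/√(1+α²)."""
        delta = self.shape / np.sqrt(1.0 + self.shape**2)
        return float(self.location + self.scale * delta * _SQRT_2_OVER_PI)

    def mode(self) -> float:
        return self.location + self.scale * _standard_mode(self.shape)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "family": "skew-normal",
            "xi": self.location,
            "omega": self.scale,
            "alpha": self.shape,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SkewNormalPrior":
        if d.get("family", "skew-normal") != "skew-normal":
            raise ValueError(f"unsupported family {d.get('family')!r}")
        return cls(
            location=float(d["xi"]),
            scale=float(d["omega"]),
            shape=float(d["alpha"]),
            label=d.get("label", ""),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "SkewNormalPrior":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class BoundJudgment:
    """Point estimate with reasonable lower/upper bounds.

    ``coverage`` is the central probability mass the bounds are taken to
    span; the default 0.98 reads them as 1st/99th percentiles.
    """

    point: float
    lower: float
    upper: float
    coverage: float = 0.98

    def __post_init__(self) -> None:
        if self.lower >= self.upper:
            raise ValueError(f"need lower < upper, got [{self.lower}, {self.upper}]")
        if not (self.lower < self.point < self.upper):
            raise ValueError(
                f"point {self.point} must lie strictly inside ({self.lower}, {self.upper})"
            )
        if not (0.0 < self.coverage < 1.0):
            raise ValueError(f"coverage must be in (0, 1), got {self.coverage}")


class FitError(RuntimeError):
    """Raised when the skew-normal fit fails to reach the requested accuracy."""


_ALPHA_MAX = 60.0


def _mode_fraction(alpha: float, p_lo: float, p_hi: float) -> float:
    """Position of the mode between the p_lo and p_hi quantiles, in [0, 1]-ish.

    Location- and scale-free, so it depends on the shape alone; strictly
    decreasing in alpha (a right skew pushes the mode toward the lower
    bound).  0.5 at alpha = 0.
    """
    q_lo = stats.skewnorm.ppf(p_lo, alpha)
    q_hi = stats.skewnorm.ppf(p_hi, alpha)
    return (_standard_mode(alpha) - q_lo) / (q_hi - q_lo)


def fit_skew_normal(
    judgment: BoundJudgment,
    label: str = "",
    instrument_range: Optional[Tuple[float, float]] = (0.0, 100.0),
) -> SkewNormalPrior:
    """Fit a skew normal whose tails hit the bounds and whose mode is the point.

    The fitted distribution satisfies, within 1e-4 on the probability scale,
    CDF(lower) = (1-coverage)/2 and CDF(upper) = 1-(1-coverage)/2, and
    places its mode at the point estimate (within 1e-3 of the bound width).

    Given the shape α, the two quantile conditions pin down scale and
    location exactly, so the fit profiles out (ξ, ω) and solves a single
    monotone equation in α: the mode's relative position between the
    bounds.  Symmetric judgments short-circuit to shape exactly 0, and a
    left-skewed judgment is fitted as the mirror image of a right-skewed
    one, so reflection symmetry is exact.  Judgments whose point estimate
    sits too close to a bound for any skew normal (|α| beyond 60) raise
    :class:`FitError` with the residuals rather than returning a bad fit.

    A warning is emitted when more than 1% of the fitted prior's mass falls
    outside ``instrument_range`` (the belief is kept unbounded regardless).
    """
    width = judgment.upper - judgment.lower
    p_lo = (1.0 - judgment.coverage) / 2.0
    p_hi = 1.0 - p_lo
    target = (judgment.point - judgment.lower) / width

    # mirror left-skewed judgments (mode above the midpoint) to the
    # right-skewed half problem
    mirrored = target > 0.5
    t = 1.0 - target if mirrored else target

    if abs(t - 0.5) < 1e-12:
        alpha = 0.0
    else:
        g = lambda a: _mode_fraction(a, p_lo, p_hi) - t
        g_max = g(_ALPHA_MAX)
        if g_max > 0.0:
            raise FitError(
                f"no skew normal places its mode at {target:.3f} of the bound "
                f"width for coverage {judgment.coverage}: requires shape beyond "
                f"{_ALPHA_MAX:.0f} (residual at the boundary: "
                f"{g_max * width:+.2e} score units)"
            )
        alpha = float(optimize.brentq(g, 0.0, _ALPHA_MAX, xtol=1e-12, rtol=1e-14))
    if mirrored:
        alpha = -alpha

    q_lo = stats.skewnorm.ppf(p_lo, alpha)
    q_hi = stats.skewnorm.ppf(p_hi, alpha)
    omega = width / (q_hi - q_lo)
    xi = judgment.lower - omega * q_lo
    prior = SkewNormalPrior(float(xi), float(omega), float(alpha), label=label)

    resid_lo = float(prior.cdf(judgment.lower)) - p_lo
    resid_hi = float(prior.cdf(judgment.upper)) - p_hi
    resid_mode = (prior.mode() - judgment.point) / width
    if max(abs(resid_lo), abs(resid_hi)) > 1e-4 or abs(resid_mode) > 1e-3:
        raise FitError(
            "skew-normal fit did not converge: residuals "
            f"cdf(lower)={resid_lo:+.2e}, cdf(upper)={resid_hi:+.2e}, "
            f"mode={resid_mode * width:+.2e} (score units)"
        )

    if instrument_range is not None:
        lo, hi = instrument_range
        outside = prior.cdf(lo) + (1.0 - prior.cdf(hi))
        if outside > 0.01:
            warnings.warn(
                f"prior {label or '(unlabelled)'}: {outside:.1%} of its mass lies "
                f"outside the instrument range [{lo}, {hi}]",
                UserWarning,
                stacklevel=2,
            )
    return prior


def credible_interval(prior, level: float) -> Tuple[float, float]:
    """Central credible interval: quantiles at (1±level)/2."""
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    p = (1.0 - level) / 2.0
    return float(prior.ppf(p)), float(prior.ppf(1.0 - p))


def band_for_trajectory(
    intercept_prior: SkewNormalPrior,
    slope_prior: Optional[SkewNormalPrior],
    loadings: Sequence[float],
    level: float = 0.95,
    n_draws: int = 100_000,
    seed: int = 0,
) -> list:
    """Credible band for the average trajectory at each slope loading.

    With only the intercept belief, the band is its central interval,
    constant across loadings.  With both beliefs, the band at loading λ is
    the central interval of I + λ·S for independent draws I, S (Monte
    Carlo, seeded).
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    loadings = [float(l) for l in loadings]
    if any(not (0.0 <= l <= 1.0) for l in loadings):
        raise ValueError("loadings must lie in [0, 1]")

    if slope_prior is None:
        lo, hi = credible_interval(intercept_prior, level)
        return [(lam, lo, hi) for lam in loadings]

    rng = np.random.default_rng(seed)
    draws_i = intercept_prior.rvs(n_draws, rng)
    draws_s = slope_prior.rvs(n_draws, rng)
    p = (1.0 - level) / 2.0
    out = []
    for lam in loadings:
        combined = draws_i + lam * draws_s
        lo, hi = np.quantile(combined, [p, 1.0 - p])
        out.append((lam, float(lo), float(hi)))
    return out
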