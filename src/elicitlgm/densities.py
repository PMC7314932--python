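"""One-dimensional densities used as priors and posterior approximations.

Every elicited or benchmark belief in this package is, operationally, a
one-dimensional density: it can be evaluated, integrated, inverted and
sampled.  This module defines the small interface the rest of the package
relies on (:class:`Density`) together with the closed-form families needed
for benchmark priors and moment-matched posterior approximations.  The
skew-normal and mixture families live in :mod:`elicitlgm.skewnorm` and
:mod:`elicitlgm.pooling` and implement the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Tuple, runtime_checkable

import numpy as np
from scipy import stats

__all__ = ["Density", "Normal", "Uniform", "HalfT"]


@runtime_checkable
class Density(Protocol):
    """Minimal protocol for a univariate probability density."""

    def pdf(self, x):  # pragma: no cover - protocol
        ...

    def cdf(self, x):  # pragma: no cover - protocol
        ...

    @property
    def support(self) -> Tuple[float, float]:  # pragma: no cover - protocol
        ...


@dataclass(frozen=True)
class Normal:
    """Normal density parameterized by mean and *variance*."""

    mean: float
    variance: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise ValueError(f"variance must be positive, got {self.variance}")

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))

    @property
    def support(self) -> Tuple[float, float]:
        return (-np.inf, np.inf)

    def pdf(self, x):
        return stats.norm.pdf(x, self.mean, self.sd)

    def logpdf(self, x):
        return stats.norm.logpdf(x, self.mean, self.sd)

    def cdf(self, x):
        return stats.norm.cdf(x, self.mean, self.sd)

    def ppf(self, q):
        return stats.norm.ppf(q, self.mean, self.sd)

    def rvs(self, size, rng: np.random.Generator):
        return rng.normal(self.mean, self.sd, size=size)

    def entropy(self) -> float:
        """Differential entropy in nats: ½·log(2πe·σ²)."""
        return 0.5 * float(np.log(2.0 * np.pi * np.e * self.variance))


@dataclass(frozen=True)
class Uniform:
    """Uniform density on [low, high]."""

    low: float
    high: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.high > self.low:
            raise ValueError(f"need low < high, got [{self.low}, {self.high}]")

    @property
    def width(self) -> float:
        return self.high - self.low

    @property
    def support(self) -> Tuple[float, float]:
        return (self.low, self.high)

    def pdf(self, x):
        return stats.uniform.pdf(x, self.low, self.width)

    def logpdf(self, x):
        return stats.uniform.logpdf(x, self.low, self.width)

    def cdf(self, x):
        return stats.uniform.cdf(x, self.low, self.width)

    def ppf(self, q):
        return stats.uniform.ppf(q, self.low, self.width)

    def rvs(self, size, rng: np.random.Generator):
        return rng.uniform(self.low, self.high, size=size)


@dataclass(frozen=True)
class HalfT:
    """Half-t density on [0, ∞) with ``df`` degrees of freedom and ``scale``.

    Used as the weakly informative prior on variance components.  The density
    is that of |T| where T ~ t(df) scaled by ``scale``.
    """

    df: float
    scale: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.df > 0 and self.scale > 0):
            raise ValueError("df and scale must be positive")

    @property
    def support(self) -> Tuple[float, float]:
        return (0.0, np.inf)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.where(x < 0, 0.0, 2.0 * stats.t.pdf(x / self.scale, self.df) / self.scale)
        return out if out.ndim else float(out)

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore"):
            out = np.where(
                x < 0,
                -np.inf,
                np.log(2.0) + stats.t.logpdf(x / self.scale, self.df) - np.log(self.scale),
            )
        return out if out.ndim else float(out)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.where(x < 0, 0.0, 2.0 * stats.t.cdf(x / self.scale, self.df) - 1.0)
        return out if out.ndim else float(out)

    def ppf(self, q):
        return self.scale * stats.t.ppf((1.0 + np.asarray(q, dtype=float)) / 2.0, self.df)

    def rvs(self, size, rng: np.random.Generator):
        return np.abs(self.scale * rng.standard_t(self.df, size=size))
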