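"""Linear opinion pooling of expert priors into group mixtures.

Individual experts' skew-normal beliefs are aggregated by equal-weight
linear (arithmetic) pooling: the group density is the weighted average of
the component densities, and likewise for the CDF.  Linear pooling is the
only pooling rule that preserves the multimodality of genuinely divergent
expert groups, which is exactly the feature of interest when contrasting,
say, nurses with psychologists.  Weights are 1/K by default; performance
weighting (e.g. Cooke's classical model) is an extension point, not
implemented.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .skewnorm import BoundJudgment, SkewNormalPrior
from .trajectories import Trajectory

__all__ = ["ExpertGroup", "ExpertJudgment", "MixturePrior", "pool", "mixture_cdf"]


class ExpertGroup(str, Enum):
    PSYCHOLOGIST = "psychologist-group"
    NURSE = "nurse-group"
    OTHER = "other"


@dataclass(frozen=True)
class ExpertJudgment:
    """One expert's complete elicitation product.

    Carries the fitted intercept and slope priors plus the raw inputs
    (trajectories and bound judgments) that produced them.  Group
    membership is metadata; pooling never infers it.
    """

    expert_id: str
    group: ExpertGroup
    intercept_prior: SkewNormalPrior
    slope_prior: SkewNormalPrior
    trajectories: Tuple[Trajectory, ...] = ()
    intercept_judgment: Optional[BoundJudgment] = None
    slope_judgment: Optional[BoundJudgment] = None


@dataclass(frozen=True)
class MixturePrior:
    """Equal- or given-weight arithmetic mixture of skew-normal components."""

    components: Tuple[SkewNormalPrior, ...]
    weights: Tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.components) != len(self.weights):
            raise ValueError("components and weights must have equal length")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")

    @property
    def support(self) -> Tuple[float, float]:
        return (-np.inf, np.inf)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        out = sum(w * c.pdf(x) for w, c in zip(self.weights, self.components))
        return out if np.ndim(x) else float(out)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        out = sum(w * c.cdf(x) for w, c in zip(self.weights, self.components))
        return out if np.ndim(x) else float(out)

    def sf(self, x):
        """Pr(X > x) = Σ wᵢ·(1 − Fᵢ(x))."""
        return 1.0 - self.cdf(x)

    def mean(self) -> float:
        return float(sum(w * c.mean() for w, c in zip(self.weights, self.components)))

    def ppf(self, q):
        scalar = np.ndim(q) == 0
        qs = np.atleast_1d(np.asarray(q, dtype=float))
        lo = min(c.ppf(1e-12) for c in self.components)
        hi = max(c.ppf(1.0 - 1e-12) for c in self.components)
        out = np.array(
            [optimize.brentq(lambda x, p=p: self.cdf(x) - p, lo, hi, xtol=1e-12) for p in qs]
        )
        return float(out[0]) if scalar else out

    def rvs(self, size, rng: np.random.Generator):
        idx = rng.choice(len(self.components), size=size, p=np.asarray(self.weights))
        draws = np.empty(size, dtype=float)
        for k, c in enumerate(self.components):
            mask = idx == k
            n_k = int(mask.sum())
            if n_k:
                draws[mask] = c.rvs(n_k, rng)
        return draws

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "components": [c.to_dict() for c in self.components],
            "weights": list(self.weights),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixturePrior":
        return cls(
            components=tuple(SkewNormalPrior.from_dict(c) for c in d["components"]),
            weights=tuple(float(w) for w in d["weights"]),
            label=d.get("label", ""),
        )


def pool(
    priors: Sequence[SkewNormalPrior],
    weights: Optional[Sequence[float]] = None,
    label: str = "",
) -> MixturePrior:
    """Linear opinion pool: density Σ wᵢ·fᵢ, weights defaulting to 1/K."""
    priors = list(priors)
    if not priors:
        raise ValueError("cannot pool an empty list of priors")
    if weights is None:
        weights = [1.0 / len(priors)] * len(priors)
    else:
        weights = [float(w) for w in weights]
        if len(weights) != len(priors):
            raise ValueError("weights must match the number of priors")
        if any(w < 0 for w in weights):
            raise ValueError("weights must be non-negative")
        total = sum(weights)
        if total <= 0:
            raise ValueError("weights must sum to a positive value")
        weights = [w / total for w in weights]
    return MixturePrior(tuple(priors), tuple(weights), label=label)


def mixture_cdf(m: MixturePrior, x) -> float:
    """CDF of a mixture prior at x (Σ wᵢ·Fᵢ(x))."""
    return m.cdf(x)
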