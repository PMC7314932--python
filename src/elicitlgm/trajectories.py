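"""Indirect elicitation from fictive individual trajectories.

The first stage of the elicitation asks an expert not for parameters but for
a handful of fictive individuals: for each, the symptom score shortly after
the event and the score one year later, on the instrument's 0-100 scale.
Because the growth model is linear with the slope scaled per year, each
fictive individual carries an intercept (the start value) and a slope (end
minus start), and the group-mean point estimates are simply the averages.
The implied average trajectory is fed back to the expert, who may revise the
trajectories and re-derive; this module is stateless per call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np

__all__ = ["Trajectory", "PointEstimates", "derive_point_estimates", "average_trajectory"]

SCORE_MIN = 0.0
SCORE_MAX = 100.0


@dataclass(frozen=True)
class Trajectory:
    """One fictive individual's linear score path.

    ``start_value`` is the score at the first time point (intercept scale),
    ``end_value`` the score at 12 months, one slope-unit later.
    """

    subject_label: str
    start_value: float
    end_value: float

    def __post_init__(self) -> None:
        for name in ("start_value", "end_value"):
            v = getattr(self, name)
            if not (SCORE_MIN <= v <= SCORE_MAX):
                raise ValueError(
                    f"trajectory {self.subject_label!r}: {name}={v} outside [0, 100]"
                )

    @property
    def slope(self) -> float:
        return self.end_value - self.start_value


@dataclass(frozen=True)
class PointEstimates:
    """Point values for the group mean intercept and slope (score units / year)."""

    intercept_point: float
    slope_point: float


def derive_point_estimates(trajectories: Sequence[Trajectory]) -> PointEstimates:
    """Reduce fictive individual trajectories to group-mean point estimates.

    The intercept point estimate is the arithmetic mean of the start values;
    the slope point estimate is the mean of the per-individual changes over
    one year.  Deterministic and order-invariant.

    Raises
    ------
    ValueError
        If the list is empty.  Out-of-range scores are rejected by
        :class:`Trajectory` itself, naming the offending trajectory.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("no trajectories")
    if len(trajectories) < 3:
        warnings.warn(
            f"only {len(trajectories)} trajectories: averaging is weak; "
            "10 is the recommended number",
            UserWarning,
            stacklevel=2,
        )
    starts = np.array([t.start_value for t in trajectories])
    slopes = np.array([t.slope for t in trajectories])
    return PointEstimates(float(starts.mean()), float(slopes.mean()))


def average_trajectory(
    estimates: PointEstimates, times: Iterable[float]
) -> List[Tuple[float, float]]:
    """Evaluate the implied average trajectory at the given slope loadings.

    A loading of 0 is the first measurement, 1 the 12-month measurement; the
    score at loading λ is ``intercept + λ·slope``.
    """
    out: List[Tuple[float, float]] = []
    for lam in times:
        if not (0.0 <= lam <= 1.0):
            raise ValueError(f"loading {lam} outside [0, 1]")
        out.append((float(lam), estimates.intercept_point + lam * estimates.slope_point))
    return out
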