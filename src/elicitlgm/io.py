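"""File formats and run configuration.

Beliefs travel as JSON (nested and typed), tabular data as CSV.  Judgment
files are validated with pydantic at load time so schema violations name
the offending expert and field; fitted priors round-trip losslessly.
Every CLI run writes its resolved configuration next to its outputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .agreement import AgreementTable
from .pooling import ExpertGroup, ExpertJudgment, MixturePrior
from .skewnorm import BoundJudgment, SkewNormalPrior, fit_skew_normal
from .trajectories import Trajectory

__all__ = [
    "RunConfig",
    "read_judgments",
    "write_judgments",
    "read_trajectories_csv",
    "write_table",
    "read_prior",
    "write_prior",
]


# ---------------------------------------------------------------------------
# judgment schema


class _TrajectoryModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    subject_label: str = ""
    start_value: float = Field(ge=0.0, le=100.0)
    end_value: float = Field(ge=0.0, le=100.0)


class _BoundModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    point: float
    lower: float
    upper: float
    coverage: float = 0.98


class _ExpertModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    expert_id: str
    group: Literal["psychologist-group", "nurse-group", "other"] = "other"
    trajectories: List[_TrajectoryModel] = []
    intercept: _BoundModel
    slope: _BoundModel


class _JudgmentFile(BaseModel):
    model_config = ConfigDict(extra="forbid")
    experts: List[_ExpertModel]


def read_judgments(path) -> List[ExpertJudgment]:
    """Load expert judgments from a JSON file, fitting priors on load.

    All type invariants are enforced; a violation raises ``ValueError``
    naming the expert and field.
    """
    path = Path(path)
    raw = json.loads(path.read_text())
    try:
        parsed = _JudgmentFile.model_validate(raw)
    except ValidationError as e:
        first = e.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ValueError(f"{path.name}: invalid judgment file at {loc}: {first['msg']}") from e

    out: List[ExpertJudgment] = []
    for ex in parsed.experts:
        try:
            trajectories = tuple(
                Trajectory(t.subject_label, t.start_value, t.end_value)
                for t in ex.trajectories
            )
            j_int = BoundJudgment(**ex.intercept.model_dump())
            j_slo = BoundJudgment(**ex.slope.model_dump())
            prior_int = fit_skew_normal(j_int, label=f"{ex.expert_id}-intercept")
            prior_slo = fit_skew_normal(
                j_slo, label=f"{ex.expert_id}-slope", instrument_range=(-100.0, 100.0)
            )
        except ValueError as e:
            raise ValueError(f"{path.name}: expert {ex.expert_id!r}: {e}") from e
        out.append(
            ExpertJudgment(
                expert_id=ex.expert_id,
                group=ExpertGroup(ex.group),
                intercept_prior=prior_int,
                slope_prior=prior_slo,
                trajectories=trajectories,
                intercept_judgment=j_int,
                slope_judgment=j_slo,
            )
        )
    return out


def write_judgments(judgments: Sequence[ExpertJudgment], path) -> None:
    """Serialize raw judgments (trajectories + bounds) to JSON."""
    payload = {
        "experts": [
            {
                "expert_id": j.expert_id,
                "group": j.group.value,
                "trajectories": [
                    {
                        "subject_label": t.subject_label,
                        "start_value": t.start_value,
                        "end_value": t.end_value,
                    }
                    for t in j.trajectories
                ],
                "intercept": _bound_dict(j.intercept_judgment, j.intercept_prior),
                "slope": _bound_dict(j.slope_judgment, j.slope_prior),
            }
            for j in judgments
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def _bound_dict(judgment: Optional[BoundJudgment], prior: SkewNormalPrior) -> dict:
    if judgment is None:
        raise ValueError(
            f"prior {prior.label!r} has no raw bound judgment; cannot serialize"
        )
    return {
        "point": judgment.point,
        "lower": judgment.lower,
        "upper": judgment.upper,
        "coverage": judgment.coverage,
    }


def read_trajectories_csv(path) -> Dict[str, List[Trajectory]]:
    """CSV trajectories (columns expert_id, subject_label, start, end) by expert."""
    df = pd.read_csv(path)
    required = {"expert_id", "subject_label", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV is missing columns: {sorted(missing)}")
    out: Dict[str, List[Trajectory]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["expert_id"]), []).append(
            Trajectory(str(row["subject_label"]), float(row["start"]), float(row["end"]))
        )
    return out


# ---------------------------------------------------------------------------
# priors and tables


def write_prior(prior, path) -> None:
    """Write a skew-normal or mixture prior as JSON (lossless round trip)."""
    Path(path).write_text(json.dumps(prior.to_dict(), indent=2))


def read_prior(path):
    d = json.loads(Path(path).read_text())
    if "components" in d:
        return MixturePrior.from_dict(d)
    return SkewNormalPrior.from_dict(d)


def write_table(table: AgreementTable, path) -> None:
    """Write an agreement table as CSV (2 decimals) + full-precision JSON.

    Column order is fixed: label, kl_intercept, kl_slope.  The companion
    ``<path>.json`` keeps full precision.
    """
    path = Path(path)
    df = table.to_dataframe()
    df.to_csv(path, index=False, float_format="%.2f")
    companion = path.with_suffix(path.suffix + ".json")
    companion.write_text(
        json.dumps(
            {
                "reference": table.reference,
                "rows": [
                    {"label": l, "kl_intercept": ki, "kl_slope": ks}
                    for l, ki, ks in table.rows
                ],
            },
            indent=2,
        )
    )


# ---------------------------------------------------------------------------
# run configuration


class RunConfig(BaseModel):
    """Resolved configuration written next to every run's outputs."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    coverage: float = 0.98
    loadings: Tuple[float, ...] = (0.0, 0.25, 1.0)
    benchmark: Literal["benchmark1", "benchmark2"] = "benchmark2"
    mcmc_chains: int = 4
    mcmc_walkers: int = 32
    mcmc_warmup: int = 2000
    mcmc_draws: int = 2000
    out_dir: str = "."

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))

    def to_json_file(self, path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))

    @classmethod
    def from_json_file(cls, path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())
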