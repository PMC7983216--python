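"""Plan Quality Metric: per-criterion sub-scores and the 100-point total.

Each criterion awards points for one dosimetric endpoint of one
structure.  Threshold criteria carry an *acceptable* and an *excellent*
level: a value worse than acceptable scores 0, exactly acceptable scores
60% of the criterion's points, and scores rise linearly to the full
points at the excellent level.  Conformity and homogeneity of the two
targets are scored continuously as ``max_points * CI`` and
``max_points * (1 - HI)``.  The default criteria set has 19 rows whose
points sum to exactly 100.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from . import structures as st
from .dvh import (
    DoseMetricSpec,
    MetricKind,
    PlanRecord,
    ci_inputs_from_plan,
    conformity_index,
    evaluate_metric,
    homogeneity_index,
)

__all__ = [
    "Direction",
    "ScoreMode",
    "Criterion",
    "CriteriaSet",
    "CriterionScore",
    "ScoreReport",
    "default_criteria",
    "score_criterion",
    "score_plan",
]

#: fraction of max_points awarded at exactly the acceptable level
ACCEPTABLE_FRACTION = 0.6


class Direction(str, enum.Enum):
    HIGHER_BETTER = "higher_better"
    LOWER_BETTER = "lower_better"


class ScoreMode(str, enum.Enum):
    THRESHOLD = "threshold"
    CI_LINEAR = "ci_linear"
    HI_LINEAR = "hi_linear"


@dataclass(frozen=True)
class Criterion:
    """One scoring row: a structure endpoint with its point schedule."""

    cid: str
    structure: str
    metric: Union[DoseMetricSpec, str]  # DoseMetricSpec, or "CI" / "HI"
    direction: Direction
    max_points: float
    acceptable: Optional[float] = None
    excellent: Optional[float] = None
    mode: ScoreMode = ScoreMode.THRESHOLD

    def __post_init__(self) -> None:
        if self.max_points <= 0:
            raise ValueError(f"{self.cid}: max_points must be > 0")
        if self.mode == ScoreMode.THRESHOLD:
            if self.acceptable is None or self.excellent is None:
                raise ValueError(f"{self.cid}: threshold mode needs both levels")
            if self.direction == Direction.LOWER_BETTER:
                ok = self.excellent <= self.acceptable
            else:
                ok = self.excellent >= self.acceptable
            if not ok:
                raise ValueError(
                    f"{self.cid}: excellent must be on the better side of acceptable"
                )
        elif not isinstance(self.metric, str):
            raise ValueError(f"{self.cid}: CI/HI modes take a 'CI' or 'HI' metric")

    @property
    def metric_label(self) -> str:
        return self.metric if isinstance(self.metric, str) else self.metric.label


@dataclass(frozen=True)
class CriteriaSet:
    name: str
    criteria: tuple[Criterion, ...]

    def __post_init__(self) -> None:
        ids = [c.cid for c in self.criteria]
        if len(set(ids)) != len(ids):
            raise ValueError("criterion ids must be unique")

    @property
    def max_total(self) -> float:
        return float(sum(c.max_points for c in self.criteria))

    def __len__(self) -> int:
        return len(self.criteria)


@dataclass(frozen=True)
class CriterionScore:
    cid: str
    structure: str
    metric_label: str
    value: float
    points: float
    max_points: float


@dataclass(frozen=True)
class ScoreReport:
    per_criterion: tuple[CriterionScore, ...]
    total: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "criterion": s.cid,
                    "structure": s.structure,
                    "metric": s.metric_label,
                    "value": s.value,
                    "points": s.points,
                    "max_points": s.max_points,
                }
                for s in self.per_criterion
            ]
        )


def _m(kind: MetricKind, parameter: float = 0.0) -> DoseMetricSpec:
    return DoseMetricSpec(kind, parameter)


def default_criteria() -> CriteriaSet:
    """The default 100-point pelvic criteria set (19 rows).

    Targets: coverage, hot-spot volume, minimum dose, CI and HI for both
    PGTVnd (60 Gy) and PCTV (45 Gy).  OARs: spinal cord and femoral-head
    near-maximum doses, bladder D_35%, rectum D_60%, kidney V_18Gy,
    femoral-head V_35Gy.
    """
    H, L = Direction.HIGHER_BETTER, Direction.LOWER_BETTER
    V, DRV, DAV, DMIN = (
        MetricKind.VOLUME_AT_DOSE,
        MetricKind.DOSE_AT_RELATIVE_VOLUME,
        MetricKind.DOSE_AT_ABSOLUTE_VOLUME,
        MetricKind.MINIMUM_DOSE,
    )

    def thr(cid, structure, metric, direction, acceptable, excellent, pts):
        return Criterion(cid, structure, metric, direction, pts, acceptable, excellent)

    def ci(cid, structure):
        return Criterion(cid, structure, "CI", H, 2.0, mode=ScoreMode.CI_LINEAR)

    def hi(cid, structure):
        return Criterion(cid, structure, "HI", L, 2.0, mode=ScoreMode.HI_LINEAR)

    rows = (
        thr("pgtvnd_v60", st.PGTVND, _m(V, 60.0), H, 97.0, 100.0, 8.0),
        thr("pgtvnd_v66", st.PGTVND, _m(V, 66.0), L, 10.0, 5.0, 8.0),
        thr("pgtvnd_dmin", st.PGTVND, _m(DMIN), H, 54.6, 55.8, 5.0),
        ci("pgtvnd_ci", st.PGTVND),
        hi("pgtvnd_hi", st.PGTVND),
        thr("pctv_v45", st.PCTV, _m(V, 45.0), H, 97.0, 100.0, 8.0),
        thr("pctv_v49.5", st.PCTV, _m(V, 49.5), L, 20.0, 10.0, 8.0),
        thr("pctv_dmin", st.PCTV, _m(DMIN), H, 40.95, 41.85, 5.0),
        ci("pctv_ci", st.PCTV),
        hi("pctv_hi", st.PCTV),
        thr("cord_d0.03cc", "spinal_cord", _m(DAV, 0.03), L, 45.0, 40.0, 10.0),
        thr("bladder_d35", "bladder", _m(DRV, 35.0), L, 50.0, 45.0, 10.0),
        thr("rectum_d60", "rectum", _m(DRV, 60.0), L, 45.0, 40.0, 10.0),
        thr("kidney_l_v18", "kidney_l", _m(V, 18.0), L, 32.0, 20.0, 5.0),
        thr("kidney_r_v18", "kidney_r", _m(V, 18.0), L, 32.0, 20.0, 5.0),
        thr("femur_l_v35", "femoral_head_l", _m(V, 35.0), L, 50.0, 15.0, 3.0),
        thr("femur_l_d0.03cc", "femoral_head_l", _m(DAV, 0.03), L, 65.0, 50.0, 2.0),
        thr("femur_r_v35", "femoral_head_r", _m(V, 35.0), L, 50.0, 15.0, 3.0),
        thr("femur_r_d0.03cc", "femoral_head_r", _m(DAV, 0.03), L, 65.0, 50.0, 2.0),
    )
    return CriteriaSet(name="pelvic-100", criteria=rows)


def score_criterion(value: float, c: Criterion) -> float:
    """Points awarded for a measured endpoint value under one criterion.

    Threshold mode: 0 below acceptable, ``0.6 * max_points`` at exactly
    acceptable, linear up to ``max_points`` at the excellent level, and
    clipped to the full points beyond it.  CI/HI modes scale linearly
    with the index itself.
    """
    if not (value == value and abs(value) != float("inf")):
        raise ValueError(f"{c.cid}: value must be finite, got {value}")
    if c.mode == ScoreMode.CI_LINEAR:
        points = c.max_points * value
    elif c.mode == ScoreMode.HI_LINEAR:
        points = c.max_points * (1.0 - value)
    else:
        acc, exc = float(c.acceptable), float(c.excellent)
        if c.direction == Direction.LOWER_BETTER:
            worse, progress = value > acc, acc - value
            span = acc - exc
        else:
            worse, progress = value < acc, value - acc
            span = exc - acc
        if worse:
            return 0.0
        if span <= 0:  # acceptable == excellent: a pure pass/fail row
            return c.max_points
        base = ACCEPTABLE_FRACTION * c.max_points
        points = base + (c.max_points - base) * progress / span
    return float(min(max(points, 0.0), c.max_points))


def score_plan(
    plan: PlanRecord,
    criteria: Optional[CriteriaSet] = None,
    ci_hi: Optional[Mapping[str, Mapping[str, float]]] = None,
    iso_fraction: float = 0.95,
) -> ScoreReport:
    """Score a plan against a criteria set (default: the 100-point set).

    CI and HI per target may be supplied via ``ci_hi`` as
    ``{target: {"CI": value, "HI": value}}``; otherwise they are derived
    from the plan's target and body curves at ``iso_fraction`` of each
    target's prescription.
    """
    cset = criteria if criteria is not None else default_criteria()
    needed = {c.structure for c in cset.criteria}
    missing = sorted(needed - set(plan.curves))
    if missing:
        raise LookupError(
            f"plan {plan.patient_id} is missing structures required by "
            f"criteria set '{cset.name}': {missing}"
        )
    scores = []
    for c in cset.criteria:
        if isinstance(c.metric, str):
            if ci_hi is not None and c.structure in ci_hi:
                value = float(ci_hi[c.structure][c.metric])
            elif c.metric == "HI":
                value = homogeneity_index(plan.curve(c.structure))
            else:
                rx = plan.prescriptions[c.structure]
                inputs = ci_inputs_from_plan(
                    plan.curve(c.structure), plan.curve(st.BODY), rx, iso_fraction
                )
                value = conformity_index(inputs)
        else:
            value = evaluate_metric(plan, c.structure, c.metric)
        scores.append(
            CriterionScore(
                cid=c.cid,
                structure=c.structure,
                metric_label=c.metric_label,
                value=value,
                points=score_criterion(value, c),
                max_points=c.max_points,
            )
        )
    return ScoreReport(
        per_criterion=tuple(scores), total=float(sum(s.points for s in scores))
    )
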