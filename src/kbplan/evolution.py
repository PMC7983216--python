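"""Closed-loop evolution of the DVH-prediction model (C_0 -> C_6).

The loop alternates three mechanisms:

1. *Flagging*: database plans whose achieved OAR endpoints exceed the
   model's prediction by more than a margin are relatively suboptimal.
2. *Re-optimization*: flagged (and candidate) plans are re-planned under
   the guidance of the estimated DVHs — in the synthetic world by
   repeatedly shrinking the excess-dose parameter until every endpoint
   meets its predicted value.
3. *Self-checking gate*: only plans whose endpoints are all at or below
   the prediction are admitted to the database.

After an initial model trained on 25 plans, the first round refines the
database in place (C_1); each subsequent round additionally admits 15
gate-passing new plans and retrains, growing the database 25 -> 100
over models C_2 ... C_6.  No plan is ever removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import structures as st
from .cohort import plan_with_skill
from .dvh import (
    DoseMetricSpec,
    MetricKind,
    PlanRecord,
    evaluate_metric,
    evaluate_metric_on_curve,
)
from .model import (
    DVHEstimate,
    GeometryFeatures,
    ModelConfig,
    PredictionModel,
    fit_model,
    predict_dvh,
)
from .pqm import CriteriaSet, score_plan

__all__ = [
    "RefinementConfig",
    "PlanDatabase",
    "EvolutionTrace",
    "default_margins",
    "flag_suboptimal",
    "reoptimize_plan",
    "self_check_gate",
    "run_refinement_round",
    "run_evolution",
]

log = logging.getLogger(__name__)

#: hard cap on candidates examined per round before declaring the stream
#: insufficient
_MAX_CANDIDATES_FACTOR = 200


@dataclass(frozen=True)
class RefinementConfig:
    """Knobs of the evolution procedure.

    Defaults reproduce the 25-plan initial database growing to 100 over
    one closed-loop round plus five adding rounds (models C_0 ... C_6).
    ``margin_fraction`` sets the suboptimality margin: that fraction of
    the 45 Gy pelvic prescription for dose endpoints, and the same
    fraction of 100 percentage points for volume endpoints.
    """

    initial_size: int = 25
    additions_per_round: int = 15
    n_rounds: int = 6
    margin_fraction: float = 0.02
    reopt_factor: float = 0.5
    max_reopt_iterations: int = 8
    seed: int = 0
    model_config: ModelConfig = field(default_factory=ModelConfig)
    endpoints: Mapping[str, DoseMetricSpec] = field(
        default_factory=lambda: dict(st.OAR_ENDPOINTS)
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.reopt_factor < 1.0:
            raise ValueError("reopt_factor must be in (0, 1)")
        if self.initial_size < 2 or self.additions_per_round < 0 or self.n_rounds < 1:
            raise ValueError("invalid evolution sizes")


@dataclass
class PlanDatabase:
    """The training database: plans with their geometry features."""

    entries: list[tuple[PlanRecord, GeometryFeatures]]
    version: int = 0

    def __post_init__(self) -> None:
        ids = [p.patient_id for p, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient ids in database")
        if len(self.entries) < 2:
            raise ValueError("database needs at least 2 plans")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class EvolutionTrace:
    """Per-round record: model label, database size, evaluation errors, PQM."""

    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def default_margins(
    endpoints: Mapping[str, DoseMetricSpec], margin_fraction: float = 0.02
) -> dict[str, float]:
    """Suboptimality margin per OAR, in the endpoint's own units."""
    margins = {}
    for oar, ep in endpoints.items():
        if ep.kind == MetricKind.VOLUME_AT_DOSE:
            margins[oar] = margin_fraction * 100.0  # percentage points
        else:
            margins[oar] = margin_fraction * st.PELVIC_RX  # Gy
    return margins


def _predicted_endpoints(
    model: PredictionModel,
    features: GeometryFeatures,
    endpoints: Mapping[str, DoseMetricSpec],
) -> dict[str, float]:
    out = {}
    for oar, ep in endpoints.items():
        est = predict_dvh(model, features, oar, z=0.0)
        out[oar] = evaluate_metric_on_curve(est.predicted, ep)
    return out


def _plan_endpoints(
    plan: PlanRecord, endpoints: Mapping[str, DoseMetricSpec]
) -> dict[str, float]:
    return {oar: evaluate_metric(plan, oar, ep) for oar, ep in endpoints.items()}


def flag_suboptimal(
    db: PlanDatabase,
    model: PredictionModel,
    margins: Optional[Mapping[str, float]] = None,
    endpoints: Optional[Mapping[str, DoseMetricSpec]] = None,
) -> list[str]:
    """Ids of plans whose achieved dose exceeds prediction + margin anywhere."""
    eps = dict(endpoints) if endpoints is not None else dict(st.OAR_ENDPOINTS)
    m = dict(margins) if margins is not None else default_margins(eps)
    flagged = []
    for plan, features in db.entries:
        predicted = _predicted_endpoints(model, features, eps)
        achieved = _plan_endpoints(plan, eps)
        if any(achieved[oar] > predicted[oar] + m[oar] for oar in eps):
            flagged.append(plan.patient_id)
    return flagged


def reoptimize_plan(
    plan: PlanRecord,
    estimates: Mapping[str, DVHEstimate],
    config: RefinementConfig,
    planner: Optional[Callable[[float], PlanRecord]] = None,
) -> PlanRecord:
    """Re-plan under the guidance of estimated DVHs.

    The planner surrogate is called with successively smaller excess-dose
    parameters (``eps <- reopt_factor * eps``) until every OAR endpoint
    is at or below its predicted value, or the iteration cap is reached.
    Synthetic plans carry their own surrogate; external plans require an
    explicit ``planner``.
    """
    if planner is None:
        if plan.patient is None or plan.skill_eps is None:
            raise NotImplementedError(
                f"plan {plan.patient_id} has no planner surrogate; "
                "supply one to re-optimize non-synthetic plans"
            )
        planner = lambda eps: plan_with_skill(plan.patient, eps)  # noqa: E731

    targets = {
        oar: evaluate_metric_on_curve(est.predicted, config.endpoints[oar])
        for oar, est in estimates.items()
        if oar in config.endpoints
    }
    eps_specs = {o: config.endpoints[o] for o in targets}
    current = plan
    eps = plan.skill_eps if plan.skill_eps is not None else 1.0
    previous: Optional[dict[str, float]] = None
    for _ in range(config.max_reopt_iterations):
        achieved = _plan_endpoints(current, eps_specs)
        if all(achieved[o] <= targets[o] for o in targets):
            break
        if eps == 0.0:
            break  # already at the achievable optimum
        if previous is not None and all(
            abs(achieved[o] - previous[o]) < 1e-3 for o in targets
        ):
            break  # endpoints have converged; further shrinking is futile
        previous = achieved
        eps *= config.reopt_factor
        current = planner(eps)
    return current


def _gate_against_targets(
    plan: PlanRecord,
    predicted: Mapping[str, float],
    endpoints: Mapping[str, DoseMetricSpec],
) -> bool:
    achieved = _plan_endpoints(plan, endpoints)
    return all(achieved[oar] <= predicted[oar] for oar in endpoints)


def self_check_gate(
    plan: PlanRecord,
    features: GeometryFeatures,
    model: PredictionModel,
    endpoints: Optional[Mapping[str, DoseMetricSpec]] = None,
) -> bool:
    """Accept a plan iff every OAR endpoint is at or below the prediction."""
    eps = dict(endpoints) if endpoints is not None else dict(st.OAR_ENDPOINTS)
    predicted = _predicted_endpoints(model, features, eps)
    return _gate_against_targets(plan, predicted, eps)


def run_refinement_round(
    db: PlanDatabase,
    model: PredictionModel,
    new_candidates: Iterable[tuple[PlanRecord, GeometryFeatures]],
    config: RefinementConfig,
    n_additions: Optional[int] = None,
) -> tuple[PlanDatabase, PredictionModel]:
    """One evolution round: refine flagged plans, admit candidates, retrain.

    ``new_candidates`` is consumed until ``n_additions`` plans (default:
    ``config.additions_per_round``; 0 for a pure closed-loop round) pass
    the self-checking gate after re-optimization.
    """
    quota = config.additions_per_round if n_additions is None else n_additions
    margins = default_margins(config.endpoints, config.margin_fraction)

    flagged = set(flag_suboptimal(db, model, margins, config.endpoints))
    entries: list[tuple[PlanRecord, GeometryFeatures]] = []
    for plan, features in db.entries:
        if plan.patient_id in flagged:
            estimates = {
                oar: predict_dvh(model, features, oar, z=0.0)
                for oar in config.endpoints
            }
            plan = reoptimize_plan(plan, estimates, config)
        entries.append((plan, features))
    log.info(
        "round %d: %d/%d database plans re-optimized",
        db.version + 1,
        len(flagged),
        len(db.entries),
    )

    accepted = 0
    examined = 0
    cap = max(1, quota) * _MAX_CANDIDATES_FACTOR
    candidates = iter(new_candidates)
    while accepted < quota:
        try:
            plan, features = next(candidates)
        except StopIteration:
            raise ValueError(
                f"round {db.version + 1}: candidate stream exhausted after "
                f"{examined} candidates ({accepted}/{quota} accepted)"
            ) from None
        examined += 1
        if examined > cap:
            raise ValueError(
                f"round {db.version + 1}: {examined - 1} candidates examined "
                f"without filling the quota of {quota}"
            )
        estimates = {
            oar: predict_dvh(model, features, oar, z=0.0) for oar in config.endpoints
        }
        predicted = {
            oar: evaluate_metric_on_curve(est.predicted, config.endpoints[oar])
            for oar, est in estimates.items()
        }
        plan = reoptimize_plan(plan, estimates, config)
        if _gate_against_targets(plan, predicted, config.endpoints):
            entries.append((plan, features))
            accepted += 1
            log.debug("gate accepted %s", plan.patient_id)
        else:
            log.debug("gate rejected %s", plan.patient_id)

    new_db = PlanDatabase(entries=entries, version=db.version + 1)
    new_model = fit_model(
        new_db.entries, config.model_config, version_label=f"C_{new_db.version}"
    )
    return new_db, new_model


def _evaluate_model(
    model: PredictionModel,
    eval_cohort: Sequence[tuple[PlanRecord, GeometryFeatures]],
    endpoints: Mapping[str, DoseMetricSpec],
) -> dict[str, float]:
    """Mean absolute endpoint prediction error per OAR over the cohort."""
    from .model import prediction_error

    errors = {oar: [] for oar in endpoints}
    for plan, features in eval_cohort:
        for oar, ep in endpoints.items():
            est = predict_dvh(model, features, oar, z=0.0)
            errors[oar].append(prediction_error(est, plan, oar, ep))
    return {oar: float(np.mean(v)) for oar, v in errors.items()}


def _mean_pqm(db: PlanDatabase, criteria: Optional[CriteriaSet]) -> float:
    totals = [score_plan(plan, criteria).total for plan, _ in db.entries]
    return float(np.mean(totals))


def run_evolution(
    initial_entries: Sequence[tuple[PlanRecord, GeometryFeatures]],
    candidate_stream: Iterator[tuple[PlanRecord, GeometryFeatures]],
    eval_cohort: Sequence[tuple[PlanRecord, GeometryFeatures]],
    config: Optional[RefinementConfig] = None,
    criteria: Optional[CriteriaSet] = None,
) -> tuple[list[PredictionModel], EvolutionTrace]:
    """Run the full evolution: C_0 on the initial database through C_n.

    Round 1 is pure closed-loop refinement (no additions); rounds 2
    onward each admit ``additions_per_round`` gate-passing candidates.
    Every model is evaluated on the fixed evaluation cohort; the trace
    records database size, per-OAR mean prediction error and the mean
    plan-quality total of the database.
    """
    cfg = config or RefinementConfig()
    if len(initial_entries) != cfg.initial_size:
        raise ValueError(
            f"initial database has {len(initial_entries)} plans, "
            f"config expects {cfg.initial_size}"
        )
    db = PlanDatabase(entries=list(initial_entries), version=0)
    model = fit_model(db.entries, cfg.model_config, version_label="C_0")
    models = [model]
    trace = EvolutionTrace()

    def record(db: PlanDatabase, model: PredictionModel) -> None:
        row = {
            "model": model.version_label,
            "database_size": len(db),
            "mean_pqm": _mean_pqm(db, criteria),
        }
        for oar, err in _evaluate_model(model, eval_cohort, cfg.endpoints).items():
            row[f"error_{oar}"] = err
        trace.rows.append(row)

    record(db, model)
    candidates = iter(candidate_stream)
    for r in range(1, cfg.n_rounds + 1):
        n_add = 0 if r == 1 else cfg.additions_per_round
        db, model = run_refinement_round(db, model, candidates, cfg, n_additions=n_add)
        models.append(model)
        record(db, model)
    return models, trace
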