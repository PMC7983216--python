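"""Rank-based comparison of prediction models across an evaluation cohort.

For each patient and OAR, the competing models' absolute prediction
errors are ranked from small to large; with ``M`` models the best
receives ``M`` points, the second ``M - 1``, and so on down to 1, ties
sharing the average of the points they span.  Averaging the points over
patients yields a per-OAR model score that is robust to individual
outlier cases; the per-(patient, OAR) points always sum to
``M * (M + 1) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import structures as st
from .dvh import DoseMetricSpec, PlanRecord, evaluate_metric
from .model import GeometryFeatures, PredictionModel, predict_dvh, prediction_error

__all__ = [
    "RankingResult",
    "rank_models_for_patient",
    "aggregate_ranking",
    "rank_models_on_cohort",
]


@dataclass(frozen=True)
class RankingResult:
    models: tuple[str, ...]
    oars: tuple[str, ...]
    mean_points: pd.DataFrame  # index: models, columns: oars
    n_patients: int


def rank_models_for_patient(errors: Sequence[float]) -> np.ndarray:
    """Points per model from one patient's absolute prediction errors.

    Ascending error rank; ``M`` points for the smallest error, 1 for the
    largest; tied errors share the average of the spanned points.
    """
    e = np.asarray(errors, dtype=float)
    if e.size < 1:
        raise ValueError("need at least one model")
    if np.any(~np.isfinite(e)) or np.any(e < 0):
        raise ValueError(f"errors must be finite and non-negative, got {errors!r}")
    ranks = rankdata(e, method="average")
    return e.size + 1.0 - ranks


def aggregate_ranking(
    per_patient_points: np.ndarray,
    models: Sequence[str],
    oars: Sequence[str],
) -> RankingResult:
    """Average a (patients x models x OARs) points table over patients."""
    pts = np.asarray(per_patient_points, dtype=float)
    if pts.ndim != 3:
        raise ValueError(f"expected a 3-D points table, got shape {pts.shape}")
    n_pat, n_mod, n_oar = pts.shape
    if n_mod != len(models) or n_oar != len(oars):
        raise ValueError("table shape does not match model/OAR labels")
    m = len(models)
    expected = m * (m + 1) / 2.0
    sums = pts.sum(axis=1)
    if not np.allclose(sums, expected):
        raise ValueError(
            f"points per (patient, OAR) must sum to M(M+1)/2 = {expected}"
        )
    mean = pd.DataFrame(pts.mean(axis=0), index=list(models), columns=list(oars))
    return RankingResult(
        models=tuple(models), oars=tuple(oars), mean_points=mean, n_patients=n_pat
    )


def rank_models_on_cohort(
    models: Sequence[PredictionModel],
    eval_cohort: Sequence[tuple[PlanRecord, GeometryFeatures]],
    endpoints: Optional[Mapping[str, DoseMetricSpec]] = None,
) -> RankingResult:
    """Full pipeline: per-patient endpoint errors -> ranks -> mean scores.

    ``endpoints`` maps OAR name to the dosimetric endpoint compared
    (default: the primary endpoint per OAR).  The reference value is
    taken from each evaluation plan.
    """
    eps = dict(endpoints) if endpoints is not None else dict(st.OAR_ENDPOINTS)
    oars = tuple(eps)
    labels = tuple(m.version_label for m in models)
    pts = np.empty((len(eval_cohort), len(models), len(oars)))
    for p, (plan, features) in enumerate(eval_cohort):
        for o, oar in enumerate(oars):
            errors = [
                prediction_error(
                    predict_dvh(m, features, oar, z=0.0), plan, oar, eps[oar]
                )
                for m in models
            ]
            pts[p, :, o] = rank_models_for_patient(errors)
    return aggregate_ranking(pts, labels, oars)
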