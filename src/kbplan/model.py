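"""Trainable DVH-prediction model: geometry features -> DVH shape.

The model is a transparent principal-component regression, per OAR:
training DVHs are resampled to a common dose grid, their mean-centered
shapes are decomposed into a small number of principal modes, and a
ridge regression maps standardized anatomical features — overlap
fraction with the high-dose envelope, log dose-falloff scale, log organ
volume, log target volume — to the mode scores.  Prediction rebuilds a
curve from the regressed scores; per-mode residual scales give an
estimate band around it, whose lower bound serves as the OAR
optimization objective.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.linear_model import Ridge

from . import structures as st
from .dvh import (
    DoseMetricSpec,
    DVHCurve,
    PlanRecord,
    evaluate_metric,
    evaluate_metric_on_curve,
)

__all__ = [
    "TrainingError",
    "OARFeatures",
    "GeometryFeatures",
    "ModelConfig",
    "DVHBasis",
    "OARSubmodel",
    "PredictionModel",
    "DVHEstimate",
    "default_grid",
    "resample_to_grid",
    "fit_model",
    "predict_dvh",
    "objectives_from_estimate",
    "prediction_error",
    "save_model",
    "load_model",
]

FEATURE_NAMES = (
    "overlap_fraction",
    "log_falloff_scale",
    "log_organ_volume",
    "log_target_volume",
)


log = logging.getLogger(__name__)


class TrainingError(ValueError):
    """The training database cannot support the requested model."""


def default_grid() -> np.ndarray:
    """Default internal dose grid: 0-75 Gy in 0.05 Gy steps."""
    return np.linspace(0.0, 75.0, 1501)


@dataclass(frozen=True)
class OARFeatures:
    """Anatomy summary for one OAR of one patient.

    ``overlap_fraction`` is the fraction of the organ inside the
    high-dose envelope; ``falloff_scale`` (Gy) encodes how fast dose
    decays with distance from the target for this organ.
    """

    overlap_fraction: float
    falloff_scale: float
    organ_volume_cc: float
    target_volume_cc: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError(f"overlap_fraction outside [0,1]: {self.overlap_fraction}")
        if self.falloff_scale <= 0:
            raise ValueError(f"falloff_scale must be > 0: {self.falloff_scale}")
        if self.organ_volume_cc <= 0 or self.target_volume_cc <= 0:
            raise ValueError("volumes must be > 0")

    def vector(self) -> np.ndarray:
        return np.array(
            [
                self.overlap_fraction,
                np.log(self.falloff_scale),
                np.log(self.organ_volume_cc),
                np.log(self.target_volume_cc),
            ]
        )


GeometryFeatures = Mapping[str, OARFeatures]


@dataclass(frozen=True)
class ModelConfig:
    n_modes: int = 3
    ridge_alpha: float = 1e-3
    grid: Optional[np.ndarray] = None
    oars: tuple[str, ...] = st.OARS
    z: float = 1.0  # default band half-width in residual standard deviations

    def resolved_grid(self) -> np.ndarray:
        return default_grid() if self.grid is None else np.asarray(self.grid, float)


@dataclass(frozen=True)
class DVHBasis:
    """Principal-mode basis of one OAR's DVH shapes on a common grid."""

    grid: np.ndarray
    mean_curve: np.ndarray
    components: np.ndarray  # (k, len(grid)), orthonormal rows
    explained_variance: np.ndarray  # (k,)


@dataclass(frozen=True)
class OARSubmodel:
    basis: DVHBasis
    coef: np.ndarray  # (k, n_kept_features)
    intercept: np.ndarray  # (k,)
    feature_mean: np.ndarray  # (4,)
    feature_std: np.ndarray  # (4,)
    kept: np.ndarray  # (4,) bool mask of non-degenerate features
    residual_scale: np.ndarray  # (k,) per-mode RMS residual
    organ_volume_cc: float  # training-mean organ volume (fallback for output)


@dataclass(frozen=True)
class PredictionModel:
    version_label: str
    n_train: int
    grid: np.ndarray
    submodels: dict[str, OARSubmodel]
    config: ModelConfig = field(default_factory=ModelConfig)

    @property
    def oars(self) -> tuple[str, ...]:
        return tuple(self.submodels)


@dataclass(frozen=True)
class DVHEstimate:
    """A predicted DVH with its estimate band (lower <= predicted <= upper)."""

    oar: str
    predicted: DVHCurve
    lower: DVHCurve
    upper: DVHCurve


def resample_to_grid(curve: DVHCurve, grid: np.ndarray) -> DVHCurve:
    """Linear re-interpolation of a cumulative DVH onto a new dose grid."""
    grid = np.asarray(grid, dtype=float)
    rel = np.interp(grid, curve.dose_grid, curve.rel_volume)
    rel[0] = 1.0
    return DVHCurve(curve.structure_name, curve.volume_cc, grid, rel)


def _as_valid_curve(name: str, volume_cc: float, grid: np.ndarray, values: np.ndarray) -> DVHCurve:
    """Project raw predicted values onto a valid cumulative DVH.

    Clipping to [0, 1], pinning the origin to full coverage, and a
    running minimum from dose 0 (the minimal-distortion monotone
    projection).
    """
    v = np.clip(np.asarray(values, float), 0.0, 1.0)
    v[0] = 1.0
    v = np.minimum.accumulate(v)
    return DVHCurve(name, volume_cc, grid, v)


def fit_model(
    database: Sequence[tuple[PlanRecord, GeometryFeatures]],
    config: Optional[ModelConfig] = None,
    version_label: str = "C_0",
) -> PredictionModel:
    """Fit per-OAR principal-component ridge regressions to a plan database.

    Requires at least ``n_modes + 1`` plans.  Zero-variance features
    (e.g. a constant overlap fraction across the database) are dropped
    with a warning; with no informative feature left the model falls
    back to the mean training curve.
    """
    cfg = config or ModelConfig()
    n = len(database)
    if n < cfg.n_modes + 1:
        raise TrainingError(
            f"need at least n_modes + 1 = {cfg.n_modes + 1} plans, got {n}"
        )
    grid = cfg.resolved_grid()
    submodels: dict[str, OARSubmodel] = {}
    for oar in cfg.oars:
        curves = []
        feats = []
        for plan, features in database:
            curves.append(resample_to_grid(plan.curve(oar), grid).rel_volume)
            feats.append(features[oar].vector())
        Y = np.asarray(curves)  # (n, G)
        X = np.asarray(feats)  # (n, 4)

        pca = PCA(n_components=cfg.n_modes, svd_solver="full")
        scores = pca.fit_transform(Y)  # (n, k)
        basis = DVHBasis(
            grid=grid,
            mean_curve=pca.mean_,
            components=pca.components_,
            explained_variance=pca.explained_variance_,
        )

        mean = X.mean(axis=0)
        std = X.std(axis=0)
        kept = std > 1e-12
        if not kept.all():
            dropped = [FEATURE_NAMES[i] for i in np.nonzero(~kept)[0]]
            log.warning("%s: dropping zero-variance feature(s) %s", oar, dropped)
        if kept.any():
            Xs = (X[:, kept] - mean[kept]) / std[kept]
            reg = Ridge(alpha=cfg.ridge_alpha, fit_intercept=True)
            reg.fit(Xs, scores)
            coef = np.atleast_2d(reg.coef_)
            intercept = np.atleast_1d(reg.intercept_)
            fitted = reg.predict(Xs)
        else:
            coef = np.zeros((cfg.n_modes, 0))
            intercept = scores.mean(axis=0)
            fitted = np.broadcast_to(intercept, scores.shape)
        residual = scores - fitted
        residual_scale = np.sqrt((residual**2).mean(axis=0))
        submodels[oar] = OARSubmodel(
            basis=basis,
            coef=coef,
            intercept=intercept,
            feature_mean=mean,
            feature_std=std,
            kept=kept,
            residual_scale=residual_scale,
            organ_volume_cc=float(np.exp(X[:, 2].mean())),
        )
    return PredictionModel(
        version_label=version_label,
        n_train=n,
        grid=grid,
        submodels=submodels,
        config=cfg,
    )


def predict_dvh(
    model: PredictionModel,
    features: GeometryFeatures,
    oar: str,
    z: Optional[float] = None,
) -> DVHEstimate:
    """Predict one OAR's DVH with an estimate band of half-width ``z`` sigma.

    The band is the pointwise propagation of the per-mode residual
    scales through the basis; all three curves are projected back onto
    valid cumulative DVHs.
    """
    if oar not in model.submodels:
        raise LookupError(f"OAR '{oar}' not in model (has {list(model.submodels)})")
    if z is None:
        z = model.config.z
    sm = model.submodels[oar]
    f = features[oar]
    x = f.vector()
    if sm.kept.any():
        xs = (x[sm.kept] - sm.feature_mean[sm.kept]) / sm.feature_std[sm.kept]
        scores = sm.intercept + sm.coef @ xs
    else:
        scores = sm.intercept
    raw = sm.basis.mean_curve + scores @ sm.basis.components
    vol = f.organ_volume_cc
    grid = sm.basis.grid
    predicted = _as_valid_curve(oar, vol, grid, raw)
    if z == 0.0:
        return DVHEstimate(oar=oar, predicted=predicted, lower=predicted, upper=predicted)
    # pointwise band: independent mode residuals propagated through the basis
    delta = z * np.sqrt(
        ((sm.residual_scale[:, None] * sm.basis.components) ** 2).sum(axis=0)
    )
    lower = _as_valid_curve(oar, vol, grid, raw - delta)
    upper = _as_valid_curve(oar, vol, grid, raw + delta)
    return DVHEstimate(oar=oar, predicted=predicted, lower=lower, upper=upper)


def objectives_from_estimate(
    estimate: DVHEstimate, endpoints: Sequence[DoseMetricSpec]
) -> list[tuple[DoseMetricSpec, float]]:
    """Optimization objectives: the endpoints evaluated on the LOWER band.

    Taking the lower bound of the estimate range pushes the optimizer
    toward the best OAR sparing the model deems achievable.
    """
    return [(ep, evaluate_metric_on_curve(estimate.lower, ep)) for ep in endpoints]


def prediction_error(
    estimate: DVHEstimate,
    reference_plan: PlanRecord,
    oar: str,
    endpoint: DoseMetricSpec,
) -> float:
    """|endpoint(predicted) - endpoint(reference plan)| for one OAR."""
    predicted = evaluate_metric_on_curve(estimate.predicted, endpoint)
    reference = evaluate_metric(reference_plan, oar, endpoint)
    return abs(predicted - reference)


# -- serialization -----------------------------------------------------------


def _model_to_dict(model: PredictionModel) -> dict:
    return {
        "format": "kbplan-model",
        "schema_version": 1,
        "version_label": model.version_label,
        "n_train": model.n_train,
        "grid": model.grid.tolist(),
        "config": {
            "n_modes": model.config.n_modes,
            "ridge_alpha": model.config.ridge_alpha,
            "z": model.config.z,
        },
        "submodels": {
            oar: {
                "mean_curve": sm.basis.mean_curve.tolist(),
                "components": sm.basis.components.tolist(),
                "explained_variance": sm.basis.explained_variance.tolist(),
                "coef": sm.coef.tolist(),
                "intercept": sm.intercept.tolist(),
                "feature_mean": sm.feature_mean.tolist(),
                "feature_std": sm.feature_std.tolist(),
                "kept": sm.kept.astype(int).tolist(),
                "residual_scale": sm.residual_scale.tolist(),
                "organ_volume_cc": sm.organ_volume_cc,
            }
            for oar, sm in model.submodels.items()
        },
    }


def save_model(model: PredictionModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(_model_to_dict(model), fh)


def load_model(path) -> PredictionModel:
    with open(path) as fh:
        d = json.load(fh)
    if d.get("format") != "kbplan-model":
        raise ValueError(f"{path}: not a kbplan model file")
    grid = np.asarray(d["grid"], float)
    submodels = {}
    for oar, s in d["submodels"].items():
        submodels[oar] = OARSubmodel(
            basis=DVHBasis(
                grid=grid,
                mean_curve=np.asarray(s["mean_curve"], float),
                components=np.asarray(s["components"], float),
                explained_variance=np.asarray(s["explained_variance"], float),
            ),
            coef=np.asarray(s["coef"], float),
            intercept=np.asarray(s["intercept"], float),
            feature_mean=np.asarray(s["feature_mean"], float),
            feature_std=np.asarray(s["feature_std"], float),
            kept=np.asarray(s["kept"], bool),
            residual_scale=np.asarray(s["residual_scale"], float),
            organ_volume_cc=float(s["organ_volume_cc"]),
        )
    cfg = ModelConfig(
        n_modes=int(d["config"]["n_modes"]),
        ridge_alpha=float(d["config"]["ridge_alpha"]),
        z=float(d["config"]["z"]),
        oars=tuple(submodels),
    )
    return PredictionModel(
        version_label=d["version_label"],
        n_train=int(d["n_train"]),
        grid=grid,
        submodels=submodels,
        config=cfg,
    )
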