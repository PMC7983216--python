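"""Synthetic pelvic-plan cohorts with controllable anatomy and planner skill.

Each synthetic patient carries per-OAR geometry features and a
closed-form *achievable* DVH per structure — the best-effort plan the
anatomy admits.  An OAR's achievable cumulative DVH mixes a target-region
component with an exponential dose falloff:

    V(D) = f * T(D) + (1 - f) * exp(-D / tau) * T(D)
         = T(D) * (f + (1 - f) * exp(-D / tau))

where ``f`` is the organ's overlap fraction with the high-dose envelope,
``tau`` the dose-decay scale (Gy), and ``T`` the near-rectangular
target-region curve (full coverage up to the prescription, linear ramp
to zero shortly above it).  The target-region factor caps the falloff
component at the maximum plan dose — no normal tissue exceeds the
hottest target dose — which keeps near-maximum endpoints (D_0.03cc)
finite and realistic; below the prescription plateau the falloff is the
plain exponential.  Planner skill is a single excess-dose
parameter ``eps >= 0`` that dilates the dose axis of the OAR curves by
``1 + eps``; ``eps = 0`` reproduces the achievable plan, larger values
yield strictly worse (but valid) plans.  Target coverage is unaffected
by skill, mirroring clinical practice where target goals are met first
and skill shows up in organ sparing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np

from . import structures as st
from .dvh import DVHCurve, PlanRecord
from .model import GeometryFeatures, OARFeatures, default_grid

__all__ = [
    "OARPrior",
    "CohortConfig",
    "SyntheticPatient",
    "DEFAULT_PRIORS",
    "sample_geometry",
    "target_region_curve",
    "achievable_dvh",
    "achievable_plan_curves",
    "plan_with_skill",
    "generate_cohort",
    "cohort_stream",
]


@dataclass(frozen=True)
class OARPrior:
    """Sampling distributions for one OAR's geometry features.

    Overlap fraction ~ scale * Beta(a, b); falloff scale ~ log-normal.
    """

    f_beta: tuple[float, float]
    f_scale: float
    tau_log_mu: float
    tau_log_sigma: float
    volume_range: tuple[float, float]

    def __post_init__(self) -> None:
        a, b = self.f_beta
        lo, hi = self.volume_range
        if a <= 0 or b <= 0 or not 0.0 <= self.f_scale <= 1.0:
            raise ValueError("invalid overlap-fraction prior")
        if self.tau_log_sigma <= 0 or not 0 < lo < hi:
            raise ValueError("invalid falloff/volume prior")


def _ln(median: float, sigma: float) -> tuple[float, float]:
    return float(np.log(median)), sigma


#: Default pelvic anatomy priors.  Bladder and rectum abut the clinical
#: target (large, variable overlap; slow falloff), femoral heads overlap
#: marginally, kidneys are essentially out of field with a fast falloff,
#: and the spinal cord never overlaps but sees a moderate dose tail.
DEFAULT_PRIORS: dict[str, OARPrior] = {
    "spinal_cord": OARPrior((1.0, 1.0), 0.0, *_ln(2.5, 0.15), (30.0, 60.0)),
    "bladder": OARPrior((4.0, 4.0), 0.6, *_ln(8.0, 0.15), (200.0, 500.0)),
    "rectum": OARPrior((4.0, 4.0), 0.6, *_ln(8.0, 0.15), (50.0, 120.0)),
    "kidney_l": OARPrior((1.0, 60.0), 0.1, *_ln(4.0, 0.15), (120.0, 200.0)),
    "kidney_r": OARPrior((1.0, 60.0), 0.1, *_ln(4.0, 0.15), (120.0, 200.0)),
    "femoral_head_l": OARPrior((2.0, 8.0), 0.2, *_ln(9.0, 0.15), (120.0, 180.0)),
    "femoral_head_r": OARPrior((2.0, 8.0), 0.2, *_ln(9.0, 0.15), (120.0, 180.0)),
}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort."""

    n_patients: int = 100
    seed: int = 0
    priors: dict[str, OARPrior] = field(default_factory=lambda: dict(DEFAULT_PRIORS))
    sigma_eps: float = 0.08  # planner-skill scale (half-normal)
    target_spread: float = 0.03  # relative width of the target dose ramp
    pgtvnd_volume_range: tuple[float, float] = (20.0, 80.0)
    pctv_volume_range: tuple[float, float] = (700.0, 1100.0)
    body_volume_range: tuple[float, float] = (7000.0, 9000.0)
    dose_spill: float = 1.3  # reference-isodose volume / target volume
    body_tau: float = 9.0  # Gy, body dose-bath falloff scale
    grid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.sigma_eps < 0 or self.target_spread <= 0:
            raise ValueError("scales must be positive")

    def resolved_grid(self) -> np.ndarray:
        return default_grid() if self.grid is None else np.asarray(self.grid, float)


@dataclass(frozen=True)
class SyntheticPatient:
    """Sampled anatomy: geometry features, volumes, and skill parameter."""

    patient_id: str
    features: dict[str, OARFeatures]
    target_volumes: dict[str, float]
    body_volume_cc: float
    skill_eps: float
    config: CohortConfig


def sample_geometry(
    rng: np.random.Generator, config: CohortConfig, patient_id: str = "SYN-0000"
) -> SyntheticPatient:
    """Draw one patient's geometry features (skill drawn separately)."""
    target_volumes = {
        st.PGTVND: float(rng.uniform(*config.pgtvnd_volume_range)),
        st.PCTV: float(rng.uniform(*config.pctv_volume_range)),
    }
    features: dict[str, OARFeatures] = {}
    for oar in st.OARS:
        prior = config.priors[oar]
        f = float(prior.f_scale * rng.beta(*prior.f_beta)) if prior.f_scale > 0 else 0.0
        tau = float(np.exp(rng.normal(prior.tau_log_mu, prior.tau_log_sigma)))
        vol = float(rng.uniform(*prior.volume_range))
        features[oar] = OARFeatures(
            overlap_fraction=f,
            falloff_scale=tau,
            organ_volume_cc=vol,
            target_volume_cc=target_volumes[st.PCTV],
        )
    return SyntheticPatient(
        patient_id=patient_id,
        features=features,
        target_volumes=target_volumes,
        body_volume_cc=float(rng.uniform(*config.body_volume_range)),
        skill_eps=0.0,
        config=config,
    )


def target_region_curve(grid: np.ndarray, rx: float, spread: float) -> np.ndarray:
    """Near-rectangular target cumulative curve.

    Full coverage up to the prescription ``rx``, then a linear ramp to
    zero at ``rx * (1 + 2 * spread)``; its homogeneity index is about
    ``2 * spread``.
    """
    if rx <= 0:
        raise ValueError("prescription must be > 0")
    hi_edge = rx * (1.0 + 2.0 * spread)
    t = np.clip((hi_edge - grid) / (hi_edge - rx), 0.0, 1.0)
    return t


def achievable_dvh(
    features: OARFeatures,
    rx: float,
    grid: Optional[np.ndarray] = None,
    spread: float = 0.03,
    name: str = "oar",
) -> DVHCurve:
    """Ground-truth best-effort OAR DVH for the given geometry."""
    if features.falloff_scale <= 0:
        raise ValueError("falloff_scale must be > 0")
    g = default_grid() if grid is None else np.asarray(grid, float)
    f = features.overlap_fraction
    v = target_region_curve(g, rx, spread) * (
        f + (1.0 - f) * np.exp(-g / features.falloff_scale)
    )
    return DVHCurve(name, features.organ_volume_cc, g, v)


def _oar_curve(
    features: OARFeatures, rx: float, grid: np.ndarray, spread: float, eps: float, name: str
) -> DVHCurve:
    """Planned OAR curve: the achievable curve dilated in dose by 1 + eps."""
    g = np.asarray(grid, float)
    d = g / (1.0 + eps)
    f = features.overlap_fraction
    v = target_region_curve(d, rx, spread) * (
        f + (1.0 - f) * np.exp(-d / features.falloff_scale)
    )
    return DVHCurve(name, features.organ_volume_cc, g, v)


def _body_curve(patient: SyntheticPatient, grid: np.ndarray, eps: float) -> DVHCurve:
    """Body (external contour) curve: target plateaus plus a dose bath.

    Weighted by the dose-spill factor so the reference-isodose volume
    exceeds the target volume and the conformity index lands in a
    plausible 0.5-0.85 range; the background falloff dilates with skill,
    so poorer plans spill more dose and conform less.
    """
    cfg = patient.config
    w_g = cfg.dose_spill * patient.target_volumes[st.PGTVND] / patient.body_volume_cc
    w_t = cfg.dose_spill * patient.target_volumes[st.PCTV] / patient.body_volume_cc
    # the bath is capped at the hottest target dose, dilated with skill
    d = grid / (1.0 + eps)
    bath = np.exp(-d / cfg.body_tau) * target_region_curve(
        d, st.PRESCRIPTIONS[st.PGTVND], cfg.target_spread
    )
    v = (
        w_g * target_region_curve(grid, st.PRESCRIPTIONS[st.PGTVND], cfg.target_spread)
        + w_t * target_region_curve(grid, st.PRESCRIPTIONS[st.PCTV], cfg.target_spread)
        + (1.0 - w_g - w_t) * bath
    )
    return DVHCurve(st.BODY, patient.body_volume_cc, grid, v)


def achievable_plan_curves(patient: SyntheticPatient) -> dict[str, DVHCurve]:
    """All structure curves of the best-effort (eps = 0) plan."""
    return plan_with_skill(patient, 0.0).curves


def plan_with_skill(patient: SyntheticPatient, eps: float) -> PlanRecord:
    """Emit the plan a planner of skill ``eps`` produces for this patient.

    OAR and body-bath doses inflate by ``1 + eps``; target coverage is
    preserved.  ``eps = 0`` is the achievable (best-effort) plan.
    """
    if eps < 0:
        raise ValueError(f"skill eps must be >= 0, got {eps}")
    cfg = patient.config
    grid = cfg.resolved_grid()
    curves: dict[str, DVHCurve] = {}
    for tgt in st.TARGETS:
        curves[tgt] = DVHCurve(
            tgt,
            patient.target_volumes[tgt],
            grid,
            target_region_curve(grid, st.PRESCRIPTIONS[tgt], cfg.target_spread),
        )
    for oar in st.OARS:
        curves[oar] = _oar_curve(
            patient.features[oar], st.PELVIC_RX, grid, cfg.target_spread, eps, oar
        )
    curves[st.BODY] = _body_curve(patient, grid, eps)
    return PlanRecord(
        patient_id=patient.patient_id,
        curves=curves,
        prescriptions=dict(st.PRESCRIPTIONS),
        provenance="synthetic",
        skill_eps=float(eps),
        patient=patient,
    )


def generate_cohort(
    config: Optional[CohortConfig] = None,
) -> list[tuple[PlanRecord, GeometryFeatures]]:
    """Sample a full cohort: plans at half-normal skill plus their features."""
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    out = []
    for i in range(cfg.n_patients):
        patient = sample_geometry(rng, cfg, patient_id=f"SYN-{i:04d}")
        eps = float(abs(rng.normal(0.0, cfg.sigma_eps))) if cfg.sigma_eps > 0 else 0.0
        patient = replace(patient, skill_eps=eps)
        plan = plan_with_skill(patient, eps)
        out.append((plan, patient.features))
    return out


def cohort_stream(
    config: CohortConfig, start_index: int = 0
) -> Iterator[tuple[PlanRecord, GeometryFeatures]]:
    """Endless patient stream drawn from the cohort configuration.

    Used as the candidate supply for the evolution loop; deterministic
    under the config seed.
    """
    rng = np.random.default_rng(config.seed)
    i = start_index
    while True:
        patient = sample_geometry(rng, config, patient_id=f"CAND-{i:05d}")
        eps = float(abs(rng.normal(0.0, config.sigma_eps))) if config.sigma_eps > 0 else 0.0
        patient = replace(patient, skill_eps=eps)
        yield plan_with_skill(patient, eps), patient.features
        i += 1
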