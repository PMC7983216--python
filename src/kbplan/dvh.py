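"""Cumulative dose-volume histograms and the dose metrics built on them.

The cumulative DVH is the canonical representation throughout the package:
``V(D)`` is the fraction of a structure receiving at least dose ``D``.
Every endpoint used for plan evaluation — D_x%, V_xGy, D_mean, D_min,
D_xcc near-maximum doses, and the conformity/homogeneity indices — is a
functional of this curve, computed by linear interpolation on both axes.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional

import numpy as np

__all__ = [
    "DVHValidationError",
    "MetricDomainError",
    "DVHCurve",
    "PlanRecord",
    "MetricKind",
    "DoseMetricSpec",
    "ConformityInputs",
    "volume_at_dose",
    "dose_at_volume",
    "mean_dose",
    "dose_at_absolute_volume",
    "minimum_dose",
    "conformity_index",
    "ci_inputs_from_plan",
    "homogeneity_index",
    "evaluate_metric_on_curve",
    "evaluate_metric",
]

#: relative-volume tolerance below full coverage that still counts as "100%"
FULL_COVERAGE_TOL = 1e-9
#: tolerance used by D_min's full-coverage plateau scan
DMIN_TOL = 1e-6
#: monotonicity glitches up to this size are repaired silently on input
GLITCH_TOL = 1e-9


class DVHValidationError(ValueError):
    """A curve violates the cumulative-DVH invariants."""


class MetricDomainError(ValueError):
    """A metric was requested outside its natural domain."""


@dataclass(frozen=True)
class DVHCurve:
    """One structure's cumulative DVH.

    Parameters
    ----------
    structure_name
        Name of the contoured structure ("bladder", "pgtvnd", ...).
    volume_cc
        Absolute structure volume in cm^3; must be positive.
    dose_grid
        Strictly increasing dose samples in Gy, starting at 0.
    rel_volume
        Relative volumes (fraction of the structure receiving at least
        the corresponding dose); non-increasing, starts at 1, in [0, 1].

    Monotonicity glitches no larger than ``GLITCH_TOL`` (floating-point
    noise from interchange files) are repaired by a running minimum;
    anything larger is rejected.
    """

    structure_name: str
    volume_cc: float
    dose_grid: np.ndarray
    rel_volume: np.ndarray

    def __post_init__(self) -> None:
        dose = np.asarray(self.dose_grid, dtype=float)
        rel = np.asarray(self.rel_volume, dtype=float)
        if not math.isfinite(self.volume_cc) or self.volume_cc <= 0:
            raise DVHValidationError(
                f"{self.structure_name}: volume_cc must be > 0, got {self.volume_cc}"
            )
        if dose.ndim != 1 or rel.ndim != 1 or dose.size != rel.size or dose.size < 2:
            raise DVHValidationError(
                f"{self.structure_name}: dose_grid and rel_volume must be 1-D, "
                f"equal length >= 2 (got {dose.shape} / {rel.shape})"
            )
        if not (np.isfinite(dose).all() and np.isfinite(rel).all()):
            raise DVHValidationError(f"{self.structure_name}: non-finite values")
        if dose[0] != 0.0 or np.any(np.diff(dose) <= 0):
            raise DVHValidationError(
                f"{self.structure_name}: dose_grid must start at 0 and increase strictly"
            )
        if abs(rel[0] - 1.0) > GLITCH_TOL:
            raise DVHValidationError(
                f"{self.structure_name}: rel_volume[0] must be 1.0, got {rel[0]!r}"
            )
        if rel.min() < -GLITCH_TOL or rel.max() > 1.0 + GLITCH_TOL:
            raise DVHValidationError(
                f"{self.structure_name}: rel_volume outside [0, 1]"
            )
        increases = np.diff(rel)
        worst = increases.max()
        if worst > GLITCH_TOL:
            raise DVHValidationError(
                f"{self.structure_name}: rel_volume increases by "
                f"{worst:.3g} (non-monotone cumulative DVH)"
            )
        if worst > 0 or rel[0] != 1.0 or rel.min() < 0.0 or rel.max() > 1.0:
            # repair sub-tolerance glitches only when present
            rel = np.minimum.accumulate(np.clip(rel, 0.0, 1.0))
            rel[0] = 1.0
        dose.setflags(write=False)
        rel.setflags(write=False)
        object.__setattr__(self, "dose_grid", dose)
        object.__setattr__(self, "rel_volume", rel)

    def __len__(self) -> int:
        return int(self.dose_grid.size)


@dataclass
class PlanRecord:
    """One patient's plan: per-structure cumulative DVHs plus prescriptions.

    ``provenance`` carries the plan class label (AP/MP/CP/synthetic).
    Synthetic plans additionally carry the planner-skill parameter
    ``skill_eps`` (excess-dose dilation) and a reference to the synthetic
    patient they were generated from, which lets the evolution loop
    re-plan them at a different skill level.
    """

    patient_id: str
    curves: dict[str, DVHCurve]
    prescriptions: dict[str, float]
    provenance: str = "synthetic"
    skill_eps: Optional[float] = None
    patient: Any = field(default=None, repr=False, compare=False)

    def curve(self, structure: str) -> DVHCurve:
        try:
            return self.curves[structure]
        except KeyError:
            raise LookupError(
                f"plan {self.patient_id}: structure '{structure}' not present "
                f"(has: {sorted(self.curves)})"
            ) from None


class MetricKind(str, enum.Enum):
    """The endpoint families used on Tables-style criteria."""

    DOSE_AT_RELATIVE_VOLUME = "dose_at_relative_volume"  # D_x%
    VOLUME_AT_DOSE = "volume_at_dose"  # V_xGy (reported in percent)
    MEAN_DOSE = "mean_dose"  # D_mean
    DOSE_AT_ABSOLUTE_VOLUME = "dose_at_absolute_volume"  # D_xcc
    MINIMUM_DOSE = "minimum_dose"  # D_min


@dataclass(frozen=True)
class DoseMetricSpec:
    """A dosimetric endpoint: the metric family plus its parameter.

    ``parameter`` is a percent for D_x%, a dose in Gy for V_xGy, a volume
    in cc for D_xcc, and unused for D_mean / D_min.
    """

    kind: MetricKind
    parameter: float = 0.0

    def __post_init__(self) -> None:
        k, p = self.kind, self.parameter
        if k == MetricKind.DOSE_AT_RELATIVE_VOLUME and not 0.0 <= p <= 100.0:
            raise MetricDomainError(f"D_x%: percent must be in [0, 100], got {p}")
        if k == MetricKind.VOLUME_AT_DOSE and p < 0:
            raise MetricDomainError(f"V_xGy: dose must be >= 0, got {p}")
        if k == MetricKind.DOSE_AT_ABSOLUTE_VOLUME and p < 0:
            raise MetricDomainError(f"D_xcc: volume must be >= 0, got {p}")

    @property
    def label(self) -> str:
        if self.kind == MetricKind.DOSE_AT_RELATIVE_VOLUME:
            return f"D_{self.parameter:g}%"
        if self.kind == MetricKind.VOLUME_AT_DOSE:
            return f"V_{self.parameter:g}Gy"
        if self.kind == MetricKind.DOSE_AT_ABSOLUTE_VOLUME:
            return f"D_{self.parameter:g}cc"
        if self.kind == MetricKind.MEAN_DOSE:
            return "D_mean"
        return "D_min"

    @property
    def units(self) -> str:
        return "%" if self.kind == MetricKind.VOLUME_AT_DOSE else "Gy"


def volume_at_dose(curve: DVHCurve, dose: float) -> float:
    """Fraction of the structure receiving at least ``dose`` Gy.

    Linear interpolation on the curve; doses beyond the grid return the
    final tabulated value.
    """
    if dose < 0:
        raise MetricDomainError(f"dose must be >= 0, got {dose}")
    return float(np.interp(dose, curve.dose_grid, curve.rel_volume))


def dose_at_volume(curve: DVHCurve, fraction: float) -> float:
    """Largest dose at which the relative volume is still >= ``fraction``.

    Inverse linear interpolation; ``fraction=1`` returns the end of the
    full-coverage plateau (relative volume >= 1 - 1e-9).
    """
    if not 0.0 <= fraction <= 1.0:
        raise MetricDomainError(f"fraction must be in [0, 1], got {fraction}")
    dose, rel = curve.dose_grid, curve.rel_volume
    if fraction >= 1.0 - FULL_COVERAGE_TOL:
        idx = np.nonzero(rel >= 1.0 - FULL_COVERAGE_TOL)[0]
        return float(dose[idx[-1]])
    # first index where the (non-increasing) curve drops below `fraction`
    below = np.nonzero(rel < fraction)[0]
    if below.size == 0:
        return float(dose[-1])
    j = int(below[0])
    i = j - 1  # rel[i] >= fraction > rel[j]; i >= 0 since rel[0] = 1
    return float(
        dose[i] + (rel[i] - fraction) / (rel[i] - rel[j]) * (dose[j] - dose[i])
    )


def mean_dose(curve: DVHCurve) -> float:
    """Mean structure dose: the integral of the cumulative DVH over dose.

    Trapezoid rule on the tabulated grid; equals the mean of the
    differential DVH for curves that reach zero within the grid.
    """
    return float(np.trapezoid(curve.rel_volume, curve.dose_grid))


def dose_at_absolute_volume(curve: DVHCurve, cc: float) -> float:
    """Near-maximum dose D_xcc: the minimum dose to the hottest ``cc`` cm^3."""
    if not 0.0 < cc <= curve.volume_cc:
        raise MetricDomainError(
            f"cc must be in (0, volume_cc={curve.volume_cc}], got {cc}"
        )
    return dose_at_volume(curve, cc / curve.volume_cc)


def minimum_dose(curve: DVHCurve) -> float:
    """D_min: the largest dose still covering the full structure.

    The end of the relative-volume >= 1 - 1e-6 plateau.
    """
    idx = np.nonzero(curve.rel_volume >= 1.0 - DMIN_TOL)[0]
    return float(curve.dose_grid[idx[-1]])


@dataclass(frozen=True)
class ConformityInputs:
    """Volumes entering the conformity index.

    ``v_t`` is the target volume, ``v_tref`` the part of the target
    covered by the reference isodose, ``v_ref`` the total volume of the
    reference isodose (all in cc).
    """

    v_t: float
    v_tref: float
    v_ref: float

    def __post_init__(self) -> None:
        if self.v_t <= 0 or self.v_ref <= 0:
            raise MetricDomainError(
                f"V_T and V_ref must be > 0 (got {self.v_t}, {self.v_ref})"
            )
        if not 0.0 <= self.v_tref <= min(self.v_t, self.v_ref) * (1 + 1e-12):
            raise MetricDomainError(
                f"V_Tref={self.v_tref} outside [0, min(V_T, V_ref)]"
            )


def conformity_index(inputs: ConformityInputs) -> float:
    """CI = (V_Tref / V_T) x (V_Tref / V_ref).

    The product of target coverage and dose selectivity at the reference
    isodose; 1 only for a reference isodose exactly matching the target.
    """
    ci = (inputs.v_tref / inputs.v_t) * (inputs.v_tref / inputs.v_ref)
    return float(min(ci, 1.0))


def ci_inputs_from_plan(
    target: DVHCurve, body: DVHCurve, rx: float, iso_fraction: float = 0.95
) -> ConformityInputs:
    """Derive CI volumes from target and body DVHs at ``iso_fraction * rx``.

    The reference isodose volume is read off the body (external contour)
    curve, so both coverage and selectivity use the same isodose level.
    """
    if rx <= 0:
        raise MetricDomainError(f"prescription must be > 0, got {rx}")
    if body is None:
        raise MetricDomainError("a body curve is required to derive V_ref")
    level = iso_fraction * rx
    v_t = target.volume_cc
    v_tref = v_t * volume_at_dose(target, level)
    v_ref = body.volume_cc * volume_at_dose(body, level)
    # the target sits inside the body, so numerically tiny excesses of
    # V_Tref over V_ref are grid artefacts
    v_tref = min(v_tref, v_ref)
    return ConformityInputs(v_t=v_t, v_tref=v_tref, v_ref=v_ref)


def homogeneity_index(curve: DVHCurve) -> float:
    """HI = (D_2% - D_98%) / D_50%; zero for a perfectly uniform target dose."""
    d2 = dose_at_volume(curve, 0.02)
    d98 = dose_at_volume(curve, 0.98)
    d50 = dose_at_volume(curve, 0.50)
    if d50 <= 0:
        raise MetricDomainError("D_50% is zero; HI undefined")
    return float((d2 - d98) / d50)


def evaluate_metric_on_curve(curve: DVHCurve, spec: DoseMetricSpec) -> float:
    """Evaluate one endpoint on one curve.

    V_xGy is returned in percent (0-100); dose endpoints in Gy.
    """
    k = spec.kind
    if k == MetricKind.DOSE_AT_RELATIVE_VOLUME:
        return dose_at_volume(curve, spec.parameter / 100.0)
    if k == MetricKind.VOLUME_AT_DOSE:
        return 100.0 * volume_at_dose(curve, spec.parameter)
    if k == MetricKind.MEAN_DOSE:
        return mean_dose(curve)
    if k == MetricKind.DOSE_AT_ABSOLUTE_VOLUME:
        return dose_at_absolute_volume(curve, spec.parameter)
    if k == MetricKind.MINIMUM_DOSE:
        return minimum_dose(curve)
    raise LookupError(f"unknown metric kind {spec.kind!r}")


def evaluate_metric(plan: PlanRecord, structure: str, spec: DoseMetricSpec) -> float:
    """Evaluate one endpoint on one structure of a plan record."""
    return evaluate_metric_on_curve(plan.curve(structure), spec)
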