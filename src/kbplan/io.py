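"""Interchange formats: plan bundles (JSON), structure curves (CSV),
criteria sets (YAML/JSON), feature tables (CSV) and run manifests.

Plan bundle schema (JSON, version 1)::

    {
      "format": "kbplan-plan", "schema_version": 1,
      "patient_id": "...", "provenance": "AP|MP|CP|synthetic",
      "prescriptions": {"pgtvnd": 60.0, "pctv": 45.0},
      "skill_eps": 0.05,                      # optional, synthetic plans
      "structures": [
        {"structure": "...", "volume_cc": ...,
         "dose_gy": [...], "volume_pct": [...]},   # cumulative, percent
        ...
      ]
    }

Per-structure CSV: comment header lines ``# structure=<name>`` and
``# volume_cc=<v>``, then ``dose_gy,volume_pct`` rows.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import yaml

from .dvh import DoseMetricSpec, DVHCurve, MetricKind, PlanRecord
from .model import GeometryFeatures, OARFeatures
from .pqm import CriteriaSet, Criterion, Direction, ScoreMode

__all__ = [
    "write_plan_bundle",
    "read_plan_bundle",
    "write_structure_csv",
    "read_structure_csv",
    "write_features_csv",
    "read_features_csv",
    "save_criteria",
    "load_criteria",
    "write_manifest",
]

PathLike = Union[str, Path]
_ROUND = 9  # decimals kept in interchange files


class PlanParseError(ValueError):
    """A plan bundle violates the interchange schema."""


def write_plan_bundle(plan: PlanRecord, path: PathLike) -> None:
    d = {
        "format": "kbplan-plan",
        "schema_version": 1,
        "patient_id": plan.patient_id,
        "provenance": plan.provenance,
        "prescriptions": {k: float(v) for k, v in plan.prescriptions.items()},
        "structures": [
            {
                "structure": name,
                "volume_cc": round(float(c.volume_cc), _ROUND),
                "dose_gy": np.round(c.dose_grid, _ROUND).tolist(),
                "volume_pct": np.round(100.0 * c.rel_volume, _ROUND).tolist(),
            }
            for name, c in plan.curves.items()
        ],
    }
    if plan.skill_eps is not None:
        d["skill_eps"] = float(plan.skill_eps)
    Path(path).write_text(json.dumps(d))


def read_plan_bundle(path: PathLike) -> PlanRecord:
    """Read and validate a plan bundle; percent volumes become fractions."""
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise PlanParseError(f"{path}: not valid JSON ({e})") from e
    if d.get("format") != "kbplan-plan":
        raise PlanParseError(f"{path}: missing format tag 'kbplan-plan'")
    if d.get("schema_version") != 1:
        raise PlanParseError(f"{path}: unsupported schema_version {d.get('schema_version')}")
    for key in ("patient_id", "prescriptions", "structures"):
        if key not in d:
            raise PlanParseError(f"{path}: missing field '{key}'")
    curves = {}
    for s in d["structures"]:
        for key in ("structure", "volume_cc", "dose_gy", "volume_pct"):
            if key not in s:
                raise PlanParseError(
                    f"{path}: structures[].{key} missing "
                    f"(structure={s.get('structure', '?')})"
                )
        curves[s["structure"]] = DVHCurve(
            structure_name=s["structure"],
            volume_cc=float(s["volume_cc"]),
            dose_grid=np.asarray(s["dose_gy"], float),
            rel_volume=np.asarray(s["volume_pct"], float) / 100.0,
        )
    return PlanRecord(
        patient_id=str(d["patient_id"]),
        curves=curves,
        prescriptions={k: float(v) for k, v in d["prescriptions"].items()},
        provenance=str(d.get("provenance", "unknown")),
        skill_eps=float(d["skill_eps"]) if "skill_eps" in d else None,
    )


def write_structure_csv(curve: DVHCurve, path: PathLike) -> None:
    lines = [f"# structure={curve.structure_name}", f"# volume_cc={curve.volume_cc:g}"]
    lines.append("dose_gy,volume_pct")
    for d, v in zip(curve.dose_grid, curve.rel_volume):
        lines.append(f"{d:.{_ROUND}g},{100.0 * v:.{_ROUND}g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_structure_csv(path: PathLike) -> DVHCurve:
    name, volume_cc = None, None
    dose, vol = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition("=")
            if key.strip() == "structure":
                name = value.strip()
            elif key.strip() == "volume_cc":
                volume_cc = float(value)
        elif not line.startswith("dose_gy"):
            d, v = line.split(",")
            dose.append(float(d))
            vol.append(float(v))
    if name is None or volume_cc is None:
        raise PlanParseError(f"{path}: missing '# structure=' or '# volume_cc=' header")
    return DVHCurve(name, volume_cc, np.asarray(dose), np.asarray(vol) / 100.0)


_FEATURE_COLUMNS = (
    "patient_id",
    "oar",
    "overlap_fraction",
    "falloff_scale",
    "organ_volume_cc",
    "target_volume_cc",
)


def write_features_csv(features: Mapping[str, GeometryFeatures], path: PathLike) -> None:
    """Write per-patient, per-OAR geometry features as a flat CSV."""
    lines = [",".join(_FEATURE_COLUMNS)]
    for pid, gf in features.items():
        for oar, f in gf.items():
            lines.append(
                f"{pid},{oar},{f.overlap_fraction:.{_ROUND}g},"
                f"{f.falloff_scale:.{_ROUND}g},{f.organ_volume_cc:.{_ROUND}g},"
                f"{f.target_volume_cc:.{_ROUND}g}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_features_csv(path: PathLike) -> dict[str, dict[str, OARFeatures]]:
    import csv

    out: dict[str, dict[str, OARFeatures]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.setdefault(row["patient_id"], {})[row["oar"]] = OARFeatures(
                overlap_fraction=float(row["overlap_fraction"]),
                falloff_scale=float(row["falloff_scale"]),
                organ_volume_cc=float(row["organ_volume_cc"]),
                target_volume_cc=float(row["target_volume_cc"]),
            )
    return out


def _criterion_to_dict(c: Criterion) -> dict:
    d = {
        "cid": c.cid,
        "structure": c.structure,
        "direction": c.direction.value,
        "max_points": c.max_points,
        "mode": c.mode.value,
    }
    if isinstance(c.metric, str):
        d["metric"] = c.metric
    else:
        d["metric"] = {"kind": c.metric.kind.value, "parameter": c.metric.parameter}
    if c.acceptable is not None:
        d["acceptable"] = c.acceptable
    if c.excellent is not None:
        d["excellent"] = c.excellent
    return d


def save_criteria(cset: CriteriaSet, path: PathLike) -> None:
    d = {"name": cset.name, "criteria": [_criterion_to_dict(c) for c in cset.criteria]}
    p = Path(path)
    if p.suffix in (".yml", ".yaml"):
        p.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        p.write_text(json.dumps(d, indent=1))


def load_criteria(path: PathLike) -> CriteriaSet:
    p = Path(path)
    text = p.read_text()
    d = yaml.safe_load(text) if p.suffix in (".yml", ".yaml") else json.loads(text)
    criteria = []
    for c in d["criteria"]:
        metric = c["metric"]
        if isinstance(metric, dict):
            metric = DoseMetricSpec(MetricKind(metric["kind"]), float(metric["parameter"]))
        criteria.append(
            Criterion(
                cid=c["cid"],
                structure=c["structure"],
                metric=metric,
                direction=Direction(c["direction"]),
                max_points=float(c["max_points"]),
                acceptable=c.get("acceptable"),
                excellent=c.get("excellent"),
                mode=ScoreMode(c.get("mode", "threshold")),
            )
        )
    return CriteriaSet(name=d.get("name", "custom"), criteria=tuple(criteria))


def write_manifest(path: PathLike, **fields) -> None:
    """Record how an output was produced (inputs, seed, config echo)."""
    from . import __version__

    payload = dict(fields)
    payload["kbplan_version"] = __version__
    blob = json.dumps(payload, sort_keys=True, default=str)
    payload["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True, default=str))
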