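"""Shared structure names, prescriptions and per-OAR evaluation endpoints.

The pelvic VMAT setting evaluated here uses two planning targets —
a nodal gross target (PGTVnd, 60 Gy in 25 fractions) and the clinical
target (PCTV, 45 Gy in 25 fractions) — and seven organs at risk.
Each OAR has one primary dosimetric endpoint (the serial organs a
near-maximum or high-percentile dose, the parallel organs a volume at
dose), used by the prediction-model comparison and the evolution loop.
"""

from __future__ import annotations

from .dvh import DoseMetricSpec, MetricKind

PGTVND = "pgtvnd"
PCTV = "pctv"
BODY = "body"

TARGETS: tuple[str, ...] = (PGTVND, PCTV)

#: prescription dose per target, Gy (25 fractions)
PRESCRIPTIONS: dict[str, float] = {PGTVND: 60.0, PCTV: 45.0}

#: the prescription governing the pelvic dose bath the OARs sit in
PELVIC_RX: float = PRESCRIPTIONS[PCTV]

OARS: tuple[str, ...] = (
    "spinal_cord",
    "bladder",
    "rectum",
    "kidney_l",
    "kidney_r",
    "femoral_head_l",
    "femoral_head_r",
)

#: primary (lower-better) endpoint per OAR used for prediction comparison
OAR_ENDPOINTS: dict[str, DoseMetricSpec] = {
    "spinal_cord": DoseMetricSpec(MetricKind.DOSE_AT_ABSOLUTE_VOLUME, 0.03),
    "bladder": DoseMetricSpec(MetricKind.DOSE_AT_RELATIVE_VOLUME, 35.0),
    "rectum": DoseMetricSpec(MetricKind.DOSE_AT_RELATIVE_VOLUME, 60.0),
    "kidney_l": DoseMetricSpec(MetricKind.VOLUME_AT_DOSE, 18.0),
    "kidney_r": DoseMetricSpec(MetricKind.VOLUME_AT_DOSE, 18.0),
    "femoral_head_l": DoseMetricSpec(MetricKind.VOLUME_AT_DOSE, 35.0),
    "femoral_head_r": DoseMetricSpec(MetricKind.VOLUME_AT_DOSE, 35.0),
}
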