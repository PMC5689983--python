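"""Delivery plans: sinogram rows plus the gantry/couch trajectory.

A plan is an ordered list of projections; each projection holds the
gantry angle, the couch (isocenter) z position, the projection duration
and 64 leaf-open-time (LOT) fractions.  On disk a plan is a versioned
JSON document — a deliberately transparent replacement for proprietary
machine-archive XML and DICOM RTPLAN private tags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["Projection", "Plan", "LatencyModel", "read_plan", "write_plan",
           "apply_latency", "total_open_time"]

PLAN_FORMAT = "tomovsm-plan"
PLAN_VERSION = 1


@dataclass(frozen=True)
class Projection:
    gantry_angle_deg: float
    couch_z_cm: float
    duration_s: float
    lot: np.ndarray  # 64 fractions in [0, 1]

    def __post_init__(self) -> None:
        lot = np.asarray(self.lot, dtype=float)
        object.__setattr__(self, "lot", lot)
        if lot.shape != (64,):
            raise ValueError("each projection needs exactly 64 LOT values")
        bad = np.flatnonzero((lot < 0) | (lot > 1))
        if bad.size:
            raise ValueError(f"LOT out of [0, 1] for leaf {bad[0] + 1}: "
                             f"{lot[bad[0]]:g}")
        if self.duration_s <= 0:
            raise ValueError("projection duration must be positive")


@dataclass(frozen=True)
class Plan:
    jaw_label: float
    iso_xy_cm: tuple[float, float]
    projections: tuple[Projection, ...]

    def __post_init__(self) -> None:
        if float(self.jaw_label) not in (1.0, 2.5, 5.0):
            raise ValueError("jaw_label must be 1.0, 2.5 or 5.0 cm")
        projs = tuple(self.projections)
        object.__setattr__(self, "projections", projs)
        if not projs:
            raise ValueError("plan has no projections")
        z = np.array([p.couch_z_cm for p in projs])
        if not (np.all(np.diff(z) >= 0) or np.all(np.diff(z) <= 0)):
            raise ValueError("couch_z must be monotone (helical) or constant")

    @property
    def n_projections(self) -> int:
        return len(self.projections)

    def lot_matrix(self) -> np.ndarray:
        """Sinogram as an (n_projections, 64) array."""
        return np.stack([p.lot for p in self.projections])


@dataclass(frozen=True)
class LatencyModel:
    """Affine programmed-LOT to effective-LOT correction per leaf.

    effective = clamp(gain * programmed + offset_s / duration, 0, 1).
    The compressed-air drive of a binary MLC opens/closes leaves with a
    machine-specific lag; an additive time offset plus a gain per leaf is
    the simplest correction that captures it.
    """

    offset_s: np.ndarray = field(default_factory=lambda: np.zeros(64))
    gain: np.ndarray = field(default_factory=lambda: np.ones(64))

    def __post_init__(self) -> None:
        for name in ("offset_s", "gain"):
            arr = np.broadcast_to(np.asarray(getattr(self, name), dtype=float),
                                  (64,)).copy()
            object.__setattr__(self, name, arr)


def apply_latency(plan: Plan, model: LatencyModel) -> Plan:
    """Return a plan with effective LOTs; the identity model is a no-op."""
    new_projs = []
    for p in plan.projections:
        eff = np.clip(model.gain * p.lot + model.offset_s / p.duration_s, 0.0, 1.0)
        new_projs.append(replace(p, lot=eff))
    return replace(plan, projections=tuple(new_projs))


def total_open_time(plan: Plan) -> float:
    """Total LOT in seconds, summed over every leaf and every projection."""
    return float(sum(p.lot.sum() * p.duration_s for p in plan.projections))


def write_plan(plan: Plan, path: str | Path) -> None:
    doc = {
        "format": PLAN_FORMAT,
        "version": PLAN_VERSION,
        "jaw_cm": plan.jaw_label,
        "iso_xy_cm": list(plan.iso_xy_cm),
        "projections": [
            {"gantry_deg": p.gantry_angle_deg, "couch_z_cm": p.couch_z_cm,
             "duration_s": p.duration_s, "lot": p.lot.tolist()}
            for p in plan.projections
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_plan(path: str | Path) -> Plan:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not valid JSON ({exc})") from exc
    if doc.get("format") != PLAN_FORMAT:
        raise ValueError(f"{path}: missing or wrong 'format' field "
                         f"(expected {PLAN_FORMAT!r})")
    if doc.get("version") != PLAN_VERSION:
        raise ValueError(f"{path}: unsupported plan version {doc.get('version')}")
    for key in ("jaw_cm", "iso_xy_cm", "projections"):
        if key not in doc:
            raise ValueError(f"{path}: missing field {key!r}")
    try:
        projections = tuple(
            Projection(gantry_angle_deg=float(rec["gantry_deg"]),
                       couch_z_cm=float(rec["couch_z_cm"]),
                       duration_s=float(rec["duration_s"]),
                       lot=np.asarray(rec["lot"], dtype=float))
            for rec in doc["projections"]
        )
        return Plan(jaw_label=float(doc["jaw_cm"]),
                    iso_xy_cm=tuple(doc["iso_xy_cm"]),
                    projections=projections)
    except (KeyError, ValueError) as exc:
        raise ValueError(f"{path}: {exc}") from exc
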