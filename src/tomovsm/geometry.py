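"""Beam-to-patient coordinate transforms for helical delivery.

Patient coordinates follow the DICOM convention (x right-to-left,
y anterior-to-posterior, z inferior-to-superior); the machine uses the
IEC 61217 gantry system (z_IEC up, y_IEC toward the gantry).  The two
are related by a +90 degree rotation about x.  For each projection the
transform chain is composed, in order, of the isocenter translation,
the IEC-to-DICOM rotation, couch and gantry rotations, the source-axis
distance translation and the collimator rotation:

    T(iso) * Rx(90) * Rz(-couch) * Ry(gantry) * T(0, 0, SAD) * Rz(col)

Couch and collimator angles are always zero for tomotherapy but are
kept in the chain for completeness.  The public interface works in the
*beam frame*: origin at the isocenter, +z from isocenter toward the
source, so the source sits at ``(0, 0, sad)``.  At gantry angle 0 the
source maps to ``(0, -sad, 0)`` in patient coordinates (anterior of the
isocenter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plan import Plan

__all__ = ["TransformChain", "build_transform", "apply_to_point",
           "apply_to_direction", "projection_frames"]

DEFAULT_SAD_CM = 85.0


def _rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _affine(rot: np.ndarray | None = None, trans=(0.0, 0.0, 0.0)) -> np.ndarray:
    m = np.eye(4)
    if rot is not None:
        m[:3, :3] = rot
    m[:3, 3] = trans
    return m


@dataclass(frozen=True)
class TransformChain:
    """Composed affine map from the beam frame to patient coordinates."""

    gantry_angle_deg: float
    couch_angle_deg: float
    collimator_angle_deg: float
    sad_cm: float
    iso_cm: tuple[float, float, float]
    matrix: np.ndarray  # 4x4, beam frame (isocenter origin) -> patient

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def source_position(self) -> np.ndarray:
        """Source location in patient coordinates."""
        return apply_to_point(self, np.array([0.0, 0.0, self.sad_cm]))


def build_transform(gantry_angle_deg: float,
                    iso_cm=(0.0, 0.0, 0.0),
                    sad_cm: float = DEFAULT_SAD_CM,
                    couch_angle_deg: float = 0.0,
                    collimator_angle_deg: float = 0.0) -> TransformChain:
    """Compose the projection transform for one gantry position.

    The chain is composed exactly in the stated order on device
    coordinates (origin at the source); the trailing shift by
    ``(0, 0, -sad)`` re-expresses it on the isocentric beam frame the
    sampler emits particles in, so the isocenter maps to the isocenter
    and the source to a point ``sad_cm`` away.
    """
    if sad_cm <= 0:
        raise ValueError("sad_cm must be positive")
    full = (_affine(trans=iso_cm)
            @ _affine(_rot_x(90.0))
            @ _affine(_rot_z(-couch_angle_deg))
            @ _affine(_rot_y(gantry_angle_deg))
            @ _affine(trans=(0.0, 0.0, sad_cm))
            @ _affine(_rot_z(collimator_angle_deg)))
    beam = full @ _affine(trans=(0.0, 0.0, -sad_cm))
    return TransformChain(gantry_angle_deg, couch_angle_deg,
                          collimator_angle_deg, sad_cm, tuple(iso_cm), beam)


def apply_to_point(chain: TransformChain, p) -> np.ndarray:
    """Map beam-frame point(s) (cm) to patient coordinates."""
    p = np.asarray(p, dtype=float)
    return p @ chain.rotation.T + chain.matrix[:3, 3]


def apply_to_direction(chain: TransformChain, v) -> np.ndarray:
    """Map beam-frame direction(s) to patient coordinates (rotation only)."""
    v = np.asarray(v, dtype=float)
    return v @ chain.rotation.T


def projection_frames(plan: Plan, sad_cm: float = DEFAULT_SAD_CM) -> list[TransformChain]:
    """One transform per projection of a plan.

    Each projection uses its own gantry angle; the isocenter sits at the
    plan's transverse position with the couch z of that projection.
    """
    x0, y0 = plan.iso_xy_cm
    return [build_transform(p.gantry_angle_deg, (x0, y0, p.couch_z_cm), sad_cm)
            for p in plan.projections]
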