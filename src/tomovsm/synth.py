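"""Synthetic beam models, phantoms and plans for testing and examples.

Real tomotherapy beam data (cone/jaw profiles, per-leaf filters) are
proprietary machine commissioning data; this module generates
structurally faithful stand-ins: a peaked cone profile without a
flattening filter, error-function jaw penumbras for the 1.0/2.5/5.0 cm
jaw settings, and 64 leaf filters with a tunable tongue-and-groove dip.
Phantoms and delivery plans reproduce the standard validation
geometries: a water tank, a low-density slab phantom, the cylindrical
"cheese" DQA phantom, a picket-fence leaf pattern and helical plans.

All fixtures are pure functions of their parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .beam_model import (BeamModel, ConeProfile, FocalSpot, JawProfile,
                         LeafFilterSet)
from .phantom import VoxelPhantom
from .plan import Plan, Projection
from .spectrum import EnergySpectrum

__all__ = ["SynthModelParams", "make_synthetic_model", "make_water_tank",
           "make_slab_phantom", "make_cheese_phantom",
           "make_picket_fence_plan", "make_static_open_field_plan",
           "make_helical_plan"]

SAD_CM = 85.0
FIELD_HALF_TANGENT = 20.0 / SAD_CM  # 40 cm lateral field at isocenter


@dataclass(frozen=True)
class SynthModelParams:
    """Shape parameters of the synthetic beam model (tangent units)."""

    cone_half_width: float = FIELD_HALF_TANGENT
    cone_edge_drop: float = 0.5     # relative fluence drop at the field edge
    cone_shape_exponent: float = 1.8
    jaw_sigma: dict = field(default_factory=lambda: {1.0: 0.0018, 2.5: 0.0018,
                                                     5.0: 0.0022})
    leaf_sigma: float = 0.002       # width of the tongue-and-groove dip
    tg_dip: float = 0.35            # dip depth in [0, 1]
    grid_step: float = 0.001

    def __post_init__(self) -> None:
        if self.leaf_sigma <= 0:
            raise ValueError("leaf_sigma must be positive")
        if not 0.0 <= self.tg_dip <= 1.0:
            raise ValueError("tg_dip must lie in [0, 1]")


def _smooth_window(x: np.ndarray, lo: float, hi: float, sigma: float) -> np.ndarray:
    s = sigma * np.sqrt(2.0)
    return 0.5 * (erf((x - lo) / s) - erf((x - hi) / s))


def make_synthetic_model(params: SynthModelParams | None = None,
                         spectrum: EnergySpectrum | None = None,
                         focal_spot: FocalSpot | None = None,
                         sad_cm: float = SAD_CM) -> BeamModel:
    """Build a complete synthetic beam model."""
    p = params or SynthModelParams()
    hw = p.cone_half_width
    x = np.arange(-1.1 * hw, 1.1 * hw + 0.5 * p.grid_step, p.grid_step)
    x = x - x[np.argmin(np.abs(x))]  # ensure a node exactly at x = 0

    # cone: peaked, unflattened; zero outside the collimated half-width
    cone_val = np.where(np.abs(x) <= hw,
                        1.0 - p.cone_edge_drop
                        * (np.abs(x) / hw) ** p.cone_shape_exponent, 0.0)
    cone = ConeProfile(x, cone_val)

    # jaws: separable error-function windows, normalized at the center
    jaws = {}
    for label, sig in p.jaw_sigma.items():
        h = label / sad_cm  # nominal longitudinal width in tangent units
        y = np.arange(-(h / 2 + 6 * sig), h / 2 + 6 * sig + 0.5 * p.grid_step,
                      p.grid_step)
        y = y - y[np.argmin(np.abs(y))]
        wy = _smooth_window(y, -h / 2, h / 2, sig)
        wx = _smooth_window(x, -hw, hw, sig)
        val = wx[:, None] * wy[None, :]
        val = val / val[np.argmin(np.abs(x)), np.argmin(np.abs(y))]
        jaws[float(label)] = JawProfile(float(label), x, y, np.clip(val, 0, None))

    # Leaf filters: indicator windows narrowed by a Gaussian T&G dip at
    # every edge that faces a closed MLC neighbour.  Edges facing an
    # open neighbour match the open-open indicator, so open apertures
    # tile without seams and the all-open map reduces exactly to the
    # open-field map; with dip = 0 all three stored profiles coincide.
    # The outer edges of leaves 1 and 64 face the collimator (whose
    # shape already lives in the cone profile): no tongue-and-groove
    # there.  Penumbral blur of the delivered dose comes from the focal
    # spot, its physical origin, not from the stored filters.
    edges = np.linspace(-hw, hw, 65)
    f_cc = np.empty((64, x.size))
    f_co = np.empty((64, x.size))
    f_oc = np.empty((64, x.size))
    for i in range(64):
        lo, hi = edges[i], edges[i + 1]
        ind = ((x >= lo) & (x < hi)).astype(float)
        bump_l = np.exp(-0.5 * ((x - lo) / p.leaf_sigma) ** 2) \
            if i > 0 else 0.0
        bump_r = np.exp(-0.5 * ((x - hi) / p.leaf_sigma) ** 2) \
            if i < 63 else 0.0
        f_co[i] = np.clip(ind - p.tg_dip * bump_l, 0.0, 1.0)
        f_oc[i] = np.clip(ind - p.tg_dip * bump_r, 0.0, 1.0)
        f_cc[i] = np.clip(ind - p.tg_dip * (bump_l + bump_r), 0.0, 1.0)
    filters = LeafFilterSet(x, f_cc, f_co, f_oc, edges)

    return BeamModel(cone=cone, jaws=jaws, filters=filters,
                     spectrum=spectrum or EnergySpectrum(),
                     focal_spot=focal_spot or FocalSpot(), sad_cm=sad_cm)


# ---------------------------------------------------------------------------
# Phantoms (beam at gantry 0 travels along +y; depth below the surface
# at y = ssd - SAD)
# ---------------------------------------------------------------------------

def make_water_tank(lateral_cm: float = 44.0, depth_cm: float = 32.0,
                    length_cm: float = 12.0,
                    voxel_cm=(0.5, 0.25, 0.5),
                    ssd_cm: float = 85.0) -> VoxelPhantom:
    """Uniform water tank with its surface at the given SSD."""
    dims = tuple(int(round(e / v)) for e, v in
                 zip((lateral_cm, depth_cm, length_cm), voxel_cm))
    origin = (-lateral_cm / 2.0, ssd_cm - SAD_CM, -length_cm / 2.0)
    return VoxelPhantom(origin, tuple(voxel_cm), np.ones(dims))


def make_slab_phantom(lateral_cm: float = 10.0, length_cm: float = 10.0,
                      voxel_cm=(0.25, 0.25, 0.25), ssd_cm: float = 75.0,
                      slab_density: float = 0.1,
                      thicknesses_cm=(5.0, 15.0, 5.0)) -> VoxelPhantom:
    """Water / low-density / water slab stack along the beam direction."""
    depth_cm = float(sum(thicknesses_cm))
    dims = tuple(int(round(e / v)) for e, v in
                 zip((lateral_cm, depth_cm, length_cm), voxel_cm))
    origin = (-lateral_cm / 2.0, ssd_cm - SAD_CM, -length_cm / 2.0)
    density = np.ones(dims)
    depth = (np.arange(dims[1]) + 0.5) * voxel_cm[1]
    t1, t2, _ = thicknesses_cm
    low = (depth >= t1) & (depth < t1 + t2)
    density[:, low, :] = slab_density
    return VoxelPhantom(origin, tuple(voxel_cm), density)


def make_cheese_phantom(coarsen: int = 1) -> VoxelPhantom:
    """Solid-water DQA cylinder, 30 cm diameter, axis along patient z.

    At ``coarsen=1`` the grid matches the standard pre-scanned CT of the
    phantom: 256 x 256 x 58 voxels of 0.1953 x 0.1953 x 0.3 cm.
    """
    if coarsen < 1:
        raise ValueError("coarsen must be >= 1")
    nx = ny = 256 // coarsen
    nz = 58
    sx = sy = 0.1953 * coarsen
    sz = 0.3
    origin = (-nx * sx / 2.0, -ny * sy / 2.0, -nz * sz / 2.0)
    cx = (np.arange(nx) + 0.5) * sx + origin[0]
    cy = (np.arange(ny) + 0.5) * sy + origin[1]
    r2 = cx[:, None] ** 2 + cy[None, :] ** 2
    disk = (r2 <= 15.0 ** 2).astype(float)
    return VoxelPhantom(origin, (sx, sy, sz),
                        np.repeat(disk[:, :, None], nz, axis=2))


# ---------------------------------------------------------------------------
# Plans
# ---------------------------------------------------------------------------

def make_static_open_field_plan(jaw_cm: float, duration_s: float = 1.0,
                                gantry_deg: float = 0.0) -> Plan:
    """Single static projection with all 64 leaves fully open."""
    proj = Projection(gantry_deg, 0.0, duration_s, np.ones(64))
    return Plan(jaw_label=jaw_cm, iso_xy_cm=(0.0, 0.0), projections=(proj,))


def make_picket_fence_plan(duration_s: float = 1.0) -> Plan:
    """Static tongue-and-groove test: even leaves open up to leaf 34,
    odd leaves open from leaf 35 (1-based numbering)."""
    lot = np.zeros(64)
    for leaf in range(1, 65):
        if (leaf <= 34 and leaf % 2 == 0) or (leaf >= 35 and leaf % 2 == 1):
            lot[leaf - 1] = 1.0
    proj = Projection(0.0, 0.0, duration_s, lot)
    return Plan(jaw_label=2.5, iso_xy_cm=(0.0, 0.0), projections=(proj,))


def make_helical_plan(pitch: float = 0.22, jaw_cm: float = 2.5,
                      n_rotations: int = 2, projections_per_rotation: int = 51,
                      open_leaves=range(31, 35), lot_fraction: float = 1.0,
                      duration_s: float = 0.2) -> Plan:
    """Helical delivery: uniform gantry advance, couch advancing
    ``pitch * jaw_cm`` per rotation, a block of open leaves (default the
    central four, a 2.5 cm wide aperture).  Leaves are 1-based."""
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    n_proj = n_rotations * projections_per_rotation
    lot = np.zeros(64)
    for leaf in open_leaves:
        lot[leaf - 1] = lot_fraction
    dz_per_proj = pitch * jaw_cm / projections_per_rotation
    z0 = -0.5 * dz_per_proj * (n_proj - 1)
    step = 360.0 / projections_per_rotation
    projs = tuple(Projection(j * step, z0 + j * dz_per_proj, duration_s, lot)
                  for j in range(n_proj))
    return Plan(jaw_label=jaw_cm, iso_xy_cm=(0.0, 0.0), projections=projs)
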