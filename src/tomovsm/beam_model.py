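"""Virtual source model of a tomotherapy fan beam.

The beam is described by a single virtual photon source at the target:

* a double-Gaussian focal spot in the target plane,
* a parametric energy spectrum (:mod:`tomovsm.spectrum`),
* a 1D transverse *cone* profile ``C(x)`` (no flattening filter),
* a 2D *jaw* profile ``J(x, y)`` per nominal jaw width (1.0/2.5/5.0 cm),
* 64 per-leaf *leaf filters* conditioning the transmitted fluence on the
  open/closed state of the two neighbouring binary-MLC leaves.

All transverse/longitudinal coordinates are tangents of the off-axis
angle (dimensionless), which makes profiles applicable at any distance
from the source.  The per-projection fluence map is

    f(s, x, y) = C(x) * J(x, y) * LF(s, x)

where ``LF`` folds the 64 leaf-open-time fractions ``s_i`` with the leaf
filters, weighting the four neighbour states (open-open, close-close,
close-open, open-close) by the time fractions spent in each state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .spectrum import EnergySpectrum, sample_energy

__all__ = [
    "FocalSpot",
    "ConeProfile",
    "JawProfile",
    "LeafFilterSet",
    "LotCoefficients",
    "FluenceMap",
    "ParticleState",
    "BeamModel",
    "lot_coefficients",
    "leaf_filtered_profile",
    "build_open_field_fluence",
    "build_projection_fluence",
    "sample_particle",
]

JAW_LABELS = (1.0, 2.5, 5.0)


@dataclass(frozen=True)
class FocalSpot:
    """Double-Gaussian focal spot in the target plane (widths in mm)."""

    sigma1_mm: float = 0.5
    sigma2_mm: float = 1.0
    weight1: float = 0.7

    def __post_init__(self) -> None:
        if self.sigma1_mm < 0 or self.sigma2_mm < 0:
            raise ValueError("focal spot sigmas must be >= 0")
        if not 0.0 <= self.weight1 <= 1.0:
            raise ValueError("weight1 must lie in [0, 1]")

    def sample_offsets_cm(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw ``n`` (x, y) origin offsets in cm from the Gaussian mixture."""
        pick1 = rng.random(n) < self.weight1
        sigma = np.where(pick1, self.sigma1_mm, self.sigma2_mm) * 0.1  # mm -> cm
        return rng.standard_normal((2, n)).T * sigma[:, None]


@dataclass(frozen=True)
class ConeProfile:
    """1D transverse fluence profile over tangent-of-off-axis-angle."""

    x_tangent: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x_tangent, dtype=float)
        v = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "x_tangent", x)
        object.__setattr__(self, "value", v)
        if x.ndim != 1 or x.shape != v.shape:
            raise ValueError("x_tangent and value must be matching 1D arrays")
        if np.any(np.diff(x) <= 0):
            raise ValueError("x grid must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("cone profile values must be >= 0")
        if abs(self(0.0) - 1.0) > 1e-6:
            raise ValueError("cone profile must be normalized to 1 at x = 0")

    def __call__(self, x):
        return np.interp(x, self.x_tangent, self.value, left=0.0, right=0.0)


@dataclass(frozen=True)
class JawProfile:
    """2D fluence envelope of one jaw setting over tangent coordinates."""

    jaw_label: float
    x_tangent: np.ndarray
    y_tangent: np.ndarray
    value: np.ndarray  # shape (nx, ny)

    def __post_init__(self) -> None:
        if float(self.jaw_label) not in JAW_LABELS:
            raise ValueError(f"jaw_label must be one of {JAW_LABELS}")
        x = np.asarray(self.x_tangent, dtype=float)
        y = np.asarray(self.y_tangent, dtype=float)
        v = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "x_tangent", x)
        object.__setattr__(self, "y_tangent", y)
        object.__setattr__(self, "value", v)
        if v.shape != (x.size, y.size):
            raise ValueError("value must have shape (len(x), len(y))")
        if np.any(v < 0):
            raise ValueError("jaw profile values must be >= 0")
        if abs(self(0.0, 0.0) - 1.0) > 1e-6:
            raise ValueError("jaw profile must be normalized to 1 at (0, 0)")

    def __call__(self, x, y):
        """Bilinear interpolation; zero outside the stored grid."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        fx = np.interp(x, self.x_tangent, np.arange(self.x_tangent.size),
                       left=-1.0, right=-1.0)
        fy = np.interp(y, self.y_tangent, np.arange(self.y_tangent.size),
                       left=-1.0, right=-1.0)
        out_of_grid = (fx < 0) | (fy < 0)
        fx = np.clip(fx, 0, self.x_tangent.size - 1)
        fy = np.clip(fy, 0, self.y_tangent.size - 1)
        ix = np.minimum(fx.astype(int), self.x_tangent.size - 2)
        iy = np.minimum(fy.astype(int), self.y_tangent.size - 2)
        tx, ty = fx - ix, fy - iy
        v = self.value
        out = (v[ix, iy] * (1 - tx) * (1 - ty) + v[ix + 1, iy] * tx * (1 - ty)
               + v[ix, iy + 1] * (1 - tx) * ty + v[ix + 1, iy + 1] * tx * ty)
        return np.where(out_of_grid, 0.0, out)


@dataclass(frozen=True)
class LeafFilterSet:
    """Per-leaf transmission profiles for the 64 binary MLC leaves.

    ``f_cc``/``f_co``/``f_oc`` are stored relative to the cone profile on
    a shared tangent grid.  The open-open profile is *not* stored: it is
    the indicator of the leaf's tangent interval, so that with every leaf
    open the filters tile the field with unit transmission and the
    projection map reduces to the open-field map exactly.
    """

    x_tangent: np.ndarray           # shared grid, shape (nx,)
    f_cc: np.ndarray                # shape (64, nx)
    f_co: np.ndarray                # left neighbour closed, right open
    f_oc: np.ndarray                # left neighbour open, right closed
    leaf_edges_tangent: np.ndarray  # shape (65,), leaf i covers [e[i], e[i+1])

    n_leaves: int = field(default=64, init=False)

    def __post_init__(self) -> None:
        x = np.asarray(self.x_tangent, dtype=float)
        edges = np.asarray(self.leaf_edges_tangent, dtype=float)
        object.__setattr__(self, "x_tangent", x)
        object.__setattr__(self, "leaf_edges_tangent", edges)
        for name in ("f_cc", "f_co", "f_oc"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (64, x.size):
                raise ValueError(f"{name} must have shape (64, len(x_tangent))")
            if np.any(arr < 0) or np.any(arr > 1 + 1e-9):
                raise ValueError(f"{name} values must lie in [0, 1]")
        if edges.shape != (65,) or np.any(np.diff(edges) <= 0):
            raise ValueError("leaf_edges_tangent must be 65 increasing values")
        # ordering holds within each leaf's aperture support (outside it
        # the profiles are penumbra tails with no ordering constraint)
        for i in range(64):
            inside = (x >= edges[i]) & (x < edges[i + 1])
            if np.any(self.f_cc[i, inside] > self.f_co[i, inside] + 1e-9) or \
               np.any(self.f_cc[i, inside] > self.f_oc[i, inside] + 1e-9):
                raise ValueError("f_cc must not exceed f_co or f_oc inside "
                                 "the leaf aperture (an open neighbour can "
                                 "only add fluence)")

    @property
    def leaf_centers_tangent(self) -> np.ndarray:
        e = self.leaf_edges_tangent
        return 0.5 * (e[:-1] + e[1:])

    @property
    def leaf_pitch_tangent(self) -> float:
        return float(np.mean(np.diff(self.leaf_edges_tangent)))

    def f_oo(self, i: int, x) -> np.ndarray:
        """Open-open profile: indicator of leaf ``i``'s tangent interval."""
        e = self.leaf_edges_tangent
        x = np.asarray(x, dtype=float)
        return ((x >= e[i]) & (x < e[i + 1])).astype(float)


@dataclass(frozen=True)
class LotCoefficients:
    """Per-projection time fractions of the four neighbour states."""

    a1: float  # open-open
    a2: float  # close-close
    a3: float  # close-open
    a4: float  # open-close

    def __iter__(self):
        return iter((self.a1, self.a2, self.a3, self.a4))


@dataclass(frozen=True)
class FluenceMap:
    """2D relative fluence on a tangent-coordinate grid at the MLC exit."""

    x_tangent: np.ndarray
    y_tangent: np.ndarray
    value: np.ndarray  # shape (nx, ny)

    def __post_init__(self) -> None:
        x = np.asarray(self.x_tangent, dtype=float)
        y = np.asarray(self.y_tangent, dtype=float)
        v = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "x_tangent", x)
        object.__setattr__(self, "y_tangent", y)
        object.__setattr__(self, "value", v)
        if v.shape != (x.size, y.size):
            raise ValueError("value must have shape (len(x), len(y))")
        if np.any(v < 0):
            raise ValueError("fluence must be non-negative")

    @property
    def total(self) -> float:
        return float(self.value.sum())


@dataclass
class ParticleState:
    """A primary particle in the beam frame (origin at isocenter)."""

    position: np.ndarray   # cm
    direction: np.ndarray  # unit vector
    energy: float          # MeV
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if self.energy <= 0 or self.weight <= 0:
            raise ValueError("energy and weight must be positive")


# ---------------------------------------------------------------------------
# Leaf-open-time state coefficients
# ---------------------------------------------------------------------------

def lot_coefficients(s_prev: float, s_i: float, s_next: float) -> LotCoefficients:
    """Time fractions the open leaf spends in the four neighbour states.

    Leaves of a binary MLC open as pulses centred in the projection; for
    centred pulses the overlap fractions have the closed form

        a1 = min(s_prev, s_i, s_next)                 (both open)
        a2 = max(0, s_i - max(s_prev, s_next))        (both closed)
        a3/a4 = remainder, assigned to the longer-open neighbour side.

    The ``max(0, ...)`` clamp keeps a2 non-negative when both neighbours
    are open longer than the leaf itself; all four coefficients are
    non-negative and sum exactly to ``s_i``.
    """
    for v in (s_prev, s_i, s_next):
        if not 0.0 <= v <= 1.0:
            raise ValueError("open-time fractions must lie in [0, 1]")
    a1 = min(s_prev, s_i, s_next)
    a2 = max(0.0, s_i - max(s_prev, s_next))
    rest = s_i - a1 - a2
    if s_next > s_prev:
        a3, a4 = rest, 0.0
    else:
        a3, a4 = 0.0, rest
    return LotCoefficients(a1, a2, a3, a4)


def leaf_filtered_profile(row: Sequence[float], filters: LeafFilterSet,
                          x_grid: np.ndarray) -> np.ndarray:
    """MLC transmission profile ``LF(s, x)`` for one projection.

    Sums, over the 64 leaves, the four leaf-filter profiles weighted by
    the neighbour-state time fractions.  The outer neighbours of leaves 1
    and 64 are treated as permanently closed.
    """
    row = np.asarray(row, dtype=float)
    if row.shape != (64,):
        raise ValueError("row must contain exactly 64 leaf open-time fractions")
    if np.any((row < 0) | (row > 1)):
        raise ValueError("leaf open-time fractions must lie in [0, 1]")
    x = np.asarray(x_grid, dtype=float)
    padded = np.concatenate([[0.0], row, [0.0]])
    lf = np.zeros_like(x)
    for i in range(64):
        s_prev, s_i, s_next = padded[i], padded[i + 1], padded[i + 2]
        if s_i == 0.0:
            continue
        a1, a2, a3, a4 = lot_coefficients(s_prev, s_i, s_next)
        if a1:
            lf += a1 * filters.f_oo(i, x)
        if a2:
            lf += a2 * np.interp(x, filters.x_tangent, filters.f_cc[i], left=0, right=0)
        if a3:
            lf += a3 * np.interp(x, filters.x_tangent, filters.f_co[i], left=0, right=0)
        if a4:
            lf += a4 * np.interp(x, filters.x_tangent, filters.f_oc[i], left=0, right=0)
    return lf


# ---------------------------------------------------------------------------
# Fluence maps
# ---------------------------------------------------------------------------

def build_open_field_fluence(cone: ConeProfile, jaw: JawProfile) -> FluenceMap:
    """Open-field fluence ``C(x) * J(x, y)`` on the union grid."""
    x = cone.x_tangent
    y = jaw.y_tangent
    if x[-1] < jaw.x_tangent[0] or jaw.x_tangent[-1] < x[0]:
        raise ValueError("cone and jaw tangent grids do not overlap")
    cx = cone(x)
    jxy = jaw(x[:, None], y[None, :])
    return FluenceMap(x, y, cx[:, None] * jxy)


def build_projection_fluence(row: Sequence[float], filters: LeafFilterSet,
                             cone: ConeProfile, jaw: JawProfile) -> FluenceMap:
    """Per-projection map ``C(x) * J(x, y) * LF(s, x)``.

    Reduces elementwise to the open-field map when every leaf is fully
    open, because the open-open filters are exact indicators tiling the
    64-leaf field.
    """
    open_field = build_open_field_fluence(cone, jaw)
    lf = leaf_filtered_profile(row, filters, open_field.x_tangent)
    return FluenceMap(open_field.x_tangent, open_field.y_tangent,
                      open_field.value * lf[:, None])


# ---------------------------------------------------------------------------
# Primary-particle sampling (reference implementation; the transport
# engine uses an equivalent compiled sampler)
# ---------------------------------------------------------------------------

def sample_particle(fluence: FluenceMap, spot: FocalSpot, spec: EnergySpectrum,
                    sad_cm: float, plane_dist_cm: float,
                    rng: np.random.Generator) -> ParticleState:
    """Sample one primary photon from the virtual source.

    The exit position is drawn from the fluence map at the MLC exit plane
    (``plane_dist_cm`` downstream of the source), with uniform jitter
    within a grid cell; the origin is drawn from the double-Gaussian
    focal spot in the target plane; the direction is the unit vector from
    origin to exit position.  Beam frame: origin at isocenter, +z toward
    the source, so the source sits at ``(0, 0, sad_cm)``.
    """
    states = sample_particles(fluence, spot, spec, sad_cm, plane_dist_cm, rng, 1)
    return states[0]


def sample_particle_arrays(fluence: FluenceMap, spot: FocalSpot,
                           spec: EnergySpectrum, sad_cm: float,
                           plane_dist_cm: float, rng: np.random.Generator,
                           n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized sampler: returns (positions (n,3), directions (n,3),
    energies (n,)) in the beam frame."""
    total = fluence.total
    if total <= 0:
        raise ValueError("fluence map is empty (total = 0)")
    flat = fluence.value.ravel()
    cdf = np.cumsum(flat) / total
    idx = np.searchsorted(cdf, rng.random(n), side="right")
    ix, iy = np.unravel_index(np.minimum(idx, flat.size - 1), fluence.value.shape)

    x_edges = _cell_edges(fluence.x_tangent)
    y_edges = _cell_edges(fluence.y_tangent)
    xt = x_edges[ix] + rng.random(n) * (x_edges[ix + 1] - x_edges[ix])
    yt = y_edges[iy] + rng.random(n) * (y_edges[iy + 1] - y_edges[iy])

    exit_pos = np.column_stack([xt * plane_dist_cm, yt * plane_dist_cm,
                                np.full(n, sad_cm - plane_dist_cm)])
    origin_xy = spot.sample_offsets_cm(rng, n)
    origin = np.column_stack([origin_xy, np.full(n, sad_cm)])
    direction = exit_pos - origin
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    energies = sample_energy(spec, rng, n)
    return exit_pos, direction, energies


def sample_particles(fluence: FluenceMap, spot: FocalSpot, spec: EnergySpectrum,
                     sad_cm: float, plane_dist_cm: float,
                     rng: np.random.Generator, n: int) -> list[ParticleState]:
    """Batch version of :func:`sample_particle` returning states."""
    pos, direction, energies = sample_particle_arrays(
        fluence, spot, spec, sad_cm, plane_dist_cm, rng, n)
    return [ParticleState(pos[i], direction[i], float(energies[i]))
            for i in range(n)]


def _cell_edges(centers: np.ndarray) -> np.ndarray:
    if centers.size == 1:  # degenerate single-cell grid: zero-width cell
        return np.array([centers[0], centers[0]])
    mids = 0.5 * (centers[:-1] + centers[1:])
    first = centers[0] - (mids[0] - centers[0])
    last = centers[-1] + (centers[-1] - mids[-1])
    return np.concatenate([[first], mids, [last]])


# ---------------------------------------------------------------------------
# Beam-model container
# ---------------------------------------------------------------------------

@dataclass
class BeamModel:
    """Bundle of everything the virtual source needs, with disk round trip.

    On disk the model is a directory of delimited-text tables plus a JSON
    header (``model.json``): ``cone.tsv`` (columns x_tangent, value), one
    ``jaw_<label>.tsv`` per jaw width (first column x_tangent, remaining
    column headers the y_tangent grid) and ``leaf_filters.tsv`` (column
    x_tangent then ``leaf<i>_cc/co/oc``), with the leaf edges in the
    header.
    """

    cone: ConeProfile
    jaws: dict[float, JawProfile]
    filters: LeafFilterSet
    spectrum: EnergySpectrum
    focal_spot: FocalSpot
    sad_cm: float = 85.0
    plane_dist_cm: float = 30.0

    def jaw(self, label: float) -> JawProfile:
        key = float(label)
        if key not in self.jaws:
            raise KeyError(f"no jaw profile for width {label} cm "
                           f"(available: {sorted(self.jaws)})")
        return self.jaws[key]

    # -- I/O -------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        header = {
            "format": "tomovsm-beam-model",
            "version": 1,
            "sad_cm": self.sad_cm,
            "plane_dist_cm": self.plane_dist_cm,
            "spectrum": {"a": self.spectrum.a, "b": self.spectrum.b,
                         "c": self.spectrum.c, "d": self.spectrum.d,
                         "e_min": self.spectrum.e_min, "e_max": self.spectrum.e_max},
            "focal_spot": {"sigma1_mm": self.focal_spot.sigma1_mm,
                           "sigma2_mm": self.focal_spot.sigma2_mm,
                           "weight1": self.focal_spot.weight1},
            "jaw_labels": sorted(self.jaws),
            "leaf_edges_tangent": self.filters.leaf_edges_tangent.tolist(),
        }
        (path / "model.json").write_text(json.dumps(header, indent=1))
        pd.DataFrame({"x_tangent": self.cone.x_tangent,
                      "value": self.cone.value}).to_csv(path / "cone.tsv",
                                                        sep="\t", index=False)
        for label, jaw in self.jaws.items():
            df = pd.DataFrame(jaw.value, index=jaw.x_tangent, columns=jaw.y_tangent)
            df.index.name = "x_tangent"
            df.to_csv(path / f"jaw_{label:.1f}.tsv", sep="\t")
        cols = {"x_tangent": self.filters.x_tangent}
        for i in range(64):
            cols[f"leaf{i + 1}_cc"] = self.filters.f_cc[i]
            cols[f"leaf{i + 1}_co"] = self.filters.f_co[i]
            cols[f"leaf{i + 1}_oc"] = self.filters.f_oc[i]
        pd.DataFrame(cols).to_csv(path / "leaf_filters.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "BeamModel":
        path = Path(path)
        header = json.loads((path / "model.json").read_text())
        if header.get("format") != "tomovsm-beam-model":
            raise ValueError(f"{path} is not a beam-model directory")
        spec = EnergySpectrum(**header["spectrum"])
        spot = FocalSpot(**header["focal_spot"])
        cone_df = pd.read_csv(path / "cone.tsv", sep="\t")
        cone = ConeProfile(cone_df["x_tangent"].to_numpy(),
                           cone_df["value"].to_numpy())
        jaws = {}
        for label in header["jaw_labels"]:
            df = pd.read_csv(path / f"jaw_{label:.1f}.tsv", sep="\t",
                             index_col="x_tangent")
            jaws[float(label)] = JawProfile(float(label),
                                            df.index.to_numpy(dtype=float),
                                            df.columns.to_numpy(dtype=float),
                                            df.to_numpy())
        lf_df = pd.read_csv(path / "leaf_filters.tsv", sep="\t")
        x = lf_df["x_tangent"].to_numpy()
        f_cc = np.stack([lf_df[f"leaf{i + 1}_cc"].to_numpy() for i in range(64)])
        f_co = np.stack([lf_df[f"leaf{i + 1}_co"].to_numpy() for i in range(64)])
        f_oc = np.stack([lf_df[f"leaf{i + 1}_oc"].to_numpy() for i in range(64)])
        filters = LeafFilterSet(x, f_cc, f_co, f_oc,
                                np.asarray(header["leaf_edges_tangent"]))
        return cls(cone=cone, jaws=jaws, filters=filters, spectrum=spec,
                   focal_spot=spot, sad_cm=header["sad_cm"],
                   plane_dist_cm=header["plane_dist_cm"])
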