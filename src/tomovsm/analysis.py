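"""Absolute-dose calibration and dose-comparison analytics.

Covers the standard validation toolbox for a tomotherapy Monte Carlo
engine: the machine calibration factor that converts dose-per-particle
to Gy, percent-depth-dose and transverse/longitudinal profile
extraction, the gamma index (dose difference + distance to agreement),
and cumulative dose-volume histograms with D_p statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .transport import DoseGrid

__all__ = ["CalibrationModel", "GammaResult", "DvhCurve",
           "calibration_factor", "extract_pdd", "extract_profile",
           "gamma_map", "compute_dvh", "dvh_stats"]


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationModel:
    """Machine calibration: measured dose = M * T_open * D_mc.

    ``m_factor`` (particles/s) converts a Monte Carlo result in
    Gy/particle to absolute dose given the plan's total leaf open time.
    """

    m_factor: float
    d_measured_gy: float
    t_open_s: float
    d_mc_gy_per_particle: float

    def absolute_dose(self, t_open_s: float, d_mc) -> np.ndarray | float:
        """Convert a Gy/particle result to Gy for a plan of given open time."""
        return self.m_factor * t_open_s * np.asarray(d_mc)


def calibration_factor(d_measured_gy: float, t_open_s: float,
                       d_mc_gy_per_particle: float) -> CalibrationModel:
    """Determine M = D_measured / (T_open * D_MC)."""
    for name, v in (("d_measured_gy", d_measured_gy), ("t_open_s", t_open_s),
                    ("d_mc_gy_per_particle", d_mc_gy_per_particle)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    m = d_measured_gy / (t_open_s * d_mc_gy_per_particle)
    return CalibrationModel(m, d_measured_gy, t_open_s, d_mc_gy_per_particle)


# ---------------------------------------------------------------------------
# PDD and profiles
# ---------------------------------------------------------------------------

def _interpolator(grid: DoseGrid) -> RegularGridInterpolator:
    axes = [grid.voxel_centers(a) for a in range(3)]
    return RegularGridInterpolator(axes, grid.dose, bounds_error=False,
                                   fill_value=np.nan)


def extract_pdd(dose_grid: DoseGrid, entry_point, direction,
                step_cm: float = 0.2, max_depth_cm: float | None = None
                ) -> pd.DataFrame:
    """Percent depth dose along a ray, normalized so the maximum is 100.

    ``entry_point`` is the surface intersection of the beam axis (cm,
    patient frame) and ``direction`` the beam direction.  Dose is
    sampled trilinearly every ``step_cm``.
    """
    entry = np.asarray(entry_point, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    interp = _interpolator(dose_grid)
    if max_depth_cm is None:
        ext = np.asarray(dose_grid.spacing_cm) * np.asarray(dose_grid.dims)
        max_depth_cm = float(np.linalg.norm(ext))
    depth = np.arange(0.0, max_depth_cm + 0.5 * step_cm, step_cm)
    vals = interp(entry[None, :] + depth[:, None] * d[None, :])
    ok = np.isfinite(vals)
    if not ok.any():
        raise ValueError("axis does not intersect the dose grid")
    depth, vals = depth[ok], vals[ok]
    peak = vals.max()
    if peak <= 0:
        raise ValueError("dose along the axis is zero")
    return pd.DataFrame({"depth_cm": depth, "pdd_pct": 100.0 * vals / peak})


def extract_profile(dose_grid: DoseGrid, depth_cm: float, direction: str = "x",
                    entry_point=(0.0, None, 0.0), beam_axis=(0.0, 1.0, 0.0),
                    step_cm: float = 0.2, half_width_cm: float | None = None
                    ) -> pd.DataFrame:
    """Dose profile at a given depth, normalized to the central-axis value.

    The beam is assumed to enter at ``entry_point`` travelling along
    ``beam_axis`` (default: anterior static beam along +y, entering at
    the grid's y minimum).  ``direction`` is 'x' (transverse) or 'z'
    (longitudinal).
    """
    if direction not in ("x", "z"):
        raise ValueError("direction must be 'x' or 'z'")
    entry = list(entry_point)
    if entry[1] is None:
        entry[1] = dose_grid.origin_cm[1]
    entry = np.asarray(entry, dtype=float)
    axis = np.asarray(beam_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    center = entry + depth_cm * axis
    lat = np.zeros(3)
    lat["xyz".index(direction)] = 1.0
    if half_width_cm is None:
        a = "xyz".index(direction)
        half_width_cm = 0.5 * dose_grid.dims[a] * dose_grid.spacing_cm[a]
    pos = np.arange(-half_width_cm, half_width_cm + 0.5 * step_cm, step_cm)
    interp = _interpolator(dose_grid)
    vals = interp(center[None, :] + pos[:, None] * lat[None, :])
    cax = float(interp(center[None, :])[0])
    if not np.isfinite(cax) or cax <= 0:
        raise ValueError("central-axis dose at the requested depth is not positive")
    ok = np.isfinite(vals)
    return pd.DataFrame({"position_cm": pos[ok],
                         "dose_rel": vals[ok] / cax})


# ---------------------------------------------------------------------------
# Gamma index
# ---------------------------------------------------------------------------

@dataclass
class GammaResult:
    gamma: np.ndarray       # per evaluated reference point; NaN below threshold
    pass_fraction: float
    dose_pct: float
    dta_mm: float
    threshold_pct: float
    mode: str


def gamma_map(reference: DoseGrid, evaluated: DoseGrid, dose_pct: float = 2.0,
              dta_mm: float = 2.0, threshold_pct: float = 10.0,
              mode: str = "global") -> GammaResult:
    """Gamma index of ``evaluated`` against ``reference``.

    For every reference point above the low-dose threshold the gamma is
    the minimum over a neighbourhood (radius 3x DTA, sampled at 0.1x DTA
    via linear interpolation of the evaluated grid) of

        sqrt((dD / tol)^2 + (dr / dta)^2)

    with ``tol`` either ``dose_pct`` of the reference maximum (global)
    or of the local reference dose (local).  A point passes when
    gamma <= 1.
    """
    if dose_pct <= 0 or dta_mm <= 0:
        raise ValueError("dose_pct and dta_mm must be positive")
    if mode not in ("global", "local"):
        raise ValueError("mode must be 'global' or 'local'")
    dta_cm = dta_mm / 10.0
    ref = reference.dose
    ref_max = ref.max()
    if ref_max <= 0:
        raise ValueError("reference grid has no dose")
    ref_axes = [reference.voxel_centers(a) for a in range(3)]
    ev_axes = [evaluated.voxel_centers(a) for a in range(3)]
    for a in range(3):
        if ev_axes[a][-1] < ref_axes[a][0] - 1e-9 or \
           ref_axes[a][-1] < ev_axes[a][0] - 1e-9:
            raise ValueError("reference and evaluated grids do not overlap")
    interp = RegularGridInterpolator(ev_axes, evaluated.dose,
                                     bounds_error=False, fill_value=np.nan)

    mask = ref >= threshold_pct / 100.0 * ref_max
    pts = np.stack(np.meshgrid(*ref_axes, indexing="ij"), axis=-1)[mask]
    ref_vals = ref[mask]
    tol = dose_pct / 100.0 * (ref_max if mode == "global" else ref_vals)

    # search stencil: only along axes with more than one sample
    step = 0.1 * dta_cm
    radius = 3.0 * dta_cm
    nstep = int(radius / step)
    offsets_1d = [np.arange(-nstep, nstep + 1) * step
                  if reference.dims[a] > 1 and evaluated.dims[a] > 1
                  else np.array([0.0]) for a in range(3)]
    grid = np.stack(np.meshgrid(*offsets_1d, indexing="ij"), axis=-1).reshape(-1, 3)
    r2 = (grid ** 2).sum(axis=1)
    grid = grid[r2 <= radius ** 2 + 1e-12]
    r_term = (grid ** 2).sum(axis=1) / dta_cm ** 2
    order = np.argsort(r_term)
    grid, r_term = grid[order], r_term[order]

    gam2 = np.full(ref_vals.shape, np.inf)
    chunk = max(1, int(2e6 / max(1, ref_vals.size)))
    for s in range(0, grid.shape[0], chunk):
        off = grid[s:s + chunk]
        rt = r_term[s:s + chunk]
        if np.all(gam2 <= rt[0]):
            break  # farther offsets cannot improve the minimum
        ev = interp(pts[None, :, :] + off[:, None, :])
        dd2 = ((ev - ref_vals[None, :]) / tol) ** 2
        cand = dd2 + rt[:, None]
        cand = np.where(np.isnan(cand), np.inf, cand)
        gam2 = np.minimum(gam2, cand.min(axis=0))
    gamma_flat = np.sqrt(gam2)

    gamma = np.full(ref.shape, np.nan)
    gamma[mask] = gamma_flat
    evaluated_pts = np.isfinite(gamma_flat)
    pass_fraction = float(np.mean(gamma_flat[evaluated_pts] <= 1.0 + 1e-12)) \
        if evaluated_pts.any() else 0.0
    return GammaResult(gamma, pass_fraction, dose_pct, dta_mm,
                       threshold_pct, mode)


# ---------------------------------------------------------------------------
# DVH
# ---------------------------------------------------------------------------

@dataclass
class DvhCurve:
    """Cumulative DVH: fraction of the structure receiving >= each edge."""

    dose_edges_gy: np.ndarray
    volume_fraction: np.ndarray
    dmean_gy: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.volume_fraction) > 1e-12):
            raise ValueError("cumulative DVH must be non-increasing")


def compute_dvh(dose, mask=None, bin_width_gy: float = 0.01) -> DvhCurve:
    """Cumulative DVH of the masked voxels of a dose grid or array."""
    values = dose.dose if isinstance(dose, DoseGrid) else np.asarray(dose)
    if mask is not None:
        values = values[np.asarray(mask, dtype=bool)]
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("DVH mask selects no voxels")
    dmax = float(values.max())
    edges = np.arange(0.0, dmax, bin_width_gy)
    edges = np.append(edges, dmax)  # last edge exactly at the maximum
    frac = (values[None, :] >= edges[:, None] - 1e-12).mean(axis=1)
    return DvhCurve(edges, frac, dmean_gy=float(values.mean()))


def dose_at_volume(curve: DvhCurve, volume_pct: float) -> float:
    """D_p: the dose received by at least ``volume_pct`` of the volume.

    Reads the inverse of the cumulative curve.  A plateau of the curve
    exactly at the requested level is resolved to its midpoint;
    otherwise the crossing bin is interpolated linearly.
    """
    p = volume_pct / 100.0
    e, v = curve.dose_edges_gy, curve.volume_fraction
    ge = v >= p - 1e-12
    if not ge.any():
        return float(e[0])
    i_ge = int(np.flatnonzero(ge)[-1])
    gt = v > p + 1e-12
    if not gt.any():
        return float(e[i_ge])
    i_gt = int(np.flatnonzero(gt)[-1])
    if i_gt < i_ge:
        # the curve sits exactly at p over (e[i_gt], e[i_ge]]: a tie
        # between discrete dose levels, resolved to the midpoint
        return 0.5 * (float(e[i_gt]) + float(e[i_ge]))
    k = i_gt + 1
    if k >= e.size:
        return float(e[-1])
    frac = (v[k - 1] - p) / (v[k - 1] - v[k])
    return float(e[k - 1] + frac * (e[k] - e[k - 1]))


def dvh_stats(curve: DvhCurve) -> tuple[float, float, float]:
    """(Dmean, D50, D95) in Gy."""
    return curve.dmean_gy, dose_at_volume(curve, 50.0), dose_at_volume(curve, 95.0)


# ---------------------------------------------------------------------------
# CSV writers
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def dvh_table(curve: DvhCurve) -> pd.DataFrame:
    return pd.DataFrame({"dose_gy": curve.dose_edges_gy,
                         "volume_fraction": curve.volume_fraction})
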