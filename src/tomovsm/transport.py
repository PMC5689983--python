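"""Coupled photon-electron Monte Carlo transport in voxel phantoms.

A fast, deliberately simplified engine in the fast-planning-MC lineage:

* photons: Woodcock (majorant) tracking through the density grid;
  Compton scattering with Klein-Nishina free-electron kinematics,
  photoelectric absorption (photoelectron continues along the photon
  direction) and pair production (kinetic energy split uniformly at
  random; the positron annihilates at the end of its range into two
  back-to-back 511 keV photons).  Photons at or below the cutoff
  (default 50 keV) deposit locally.
* electrons: class II condensed history — restricted stopping power
  deposited continuously along short steps, Gaussian (Highland) multiple
  scattering per step, discrete Moller knock-on and bremsstrahlung
  events above 200 keV thresholds, and a straight-line CSDA residual
  below the electron cutoff.

All kernels are numba-compiled and driven by a counter-seeded PCG32
stream per batch, so results are bit-identical for a fixed seed
regardless of the number of worker threads.
"""

from __future__ import annotations

import math
import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit, uint32, uint64

from .beam_model import BeamModel
from .geometry import projection_frames
from .materials import MaterialTable, water_table
from .phantom import VoxelPhantom
from .plan import Plan

__all__ = ["TransportConfig", "DoseGrid", "EnergyTally", "run_simulation",
           "simulate_primaries", "transport_photon", "transport_electron",
           "first_interaction_depths", "relative_uncertainty",
           "mean_relative_uncertainty", "write_dose", "read_dose"]

MEV_TO_J = 1.602176634e-13
_VACUUM_RHO = 1e-6
_STACK_CAP = 256


@dataclass(frozen=True)
class TransportConfig:
    """Cutoffs, stepping and execution parameters."""

    photon_cutoff_mev: float = 0.05
    electron_cutoff_mev: float = 0.2   # hard-collision threshold and cutoff
    brems_cutoff_mev: float = 0.2
    max_step_cm: float = 0.25
    seed: int = 0
    n_workers: int = 1
    n_batches: int = 10

    def __post_init__(self) -> None:
        if self.photon_cutoff_mev <= 0 or self.electron_cutoff_mev <= 0:
            raise ValueError("cutoff energies must be positive")
        if self.n_batches < 1 or self.n_workers < 1:
            raise ValueError("n_batches and n_workers must be >= 1")

    def materials(self) -> MaterialTable:
        return water_table(self.electron_cutoff_mev, self.brems_cutoff_mev)


@dataclass
class EnergyTally:
    """Per-voxel deposited energy (MeV) plus the energy ledger."""

    edep_mev: np.ndarray
    launched_mev: float = 0.0
    escaped_mev: float = 0.0

    @property
    def deposited_mev(self) -> float:
        return float(self.edep_mev.sum())


@dataclass
class DoseGrid:
    """Dose per source particle on the phantom grid, with batch variance."""

    origin_cm: tuple[float, float, float]
    spacing_cm: tuple[float, float, float]
    dose: np.ndarray              # Gy per primary, (nx, ny, nz)
    variance: np.ndarray          # variance of the mean, same shape
    n_histories: int
    n_batches: int
    energy_launched_mev: float = 0.0
    energy_deposited_mev: float = 0.0
    energy_escaped_mev: float = 0.0

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.dose.shape

    def voxel_centers(self, axis: int) -> np.ndarray:
        n = self.dims[axis]
        return (self.origin_cm[axis]
                + (np.arange(n) + 0.5) * self.spacing_cm[axis])


# ---------------------------------------------------------------------------
# PCG32 random stream
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _pcg_next(st):
    old = st[0]
    st[0] = old * uint64(6364136223846793005) + st[1]
    xorshifted = uint32(((old >> uint64(18)) ^ old) >> uint64(27))
    rot = uint32(old >> uint64(59))
    return uint32((xorshifted >> rot) | (xorshifted << ((uint32(0) - rot) & uint32(31))))


@njit(cache=True, inline="always")
def _rand(st):
    return (float(_pcg_next(st)) + 0.5) * (1.0 / 4294967296.0)


@njit(cache=True)
def _pcg_init(seed, stream):
    st = np.empty(2, dtype=np.uint64)
    st[0] = uint64(0)
    st[1] = (uint64(stream) << uint64(1)) | uint64(1)
    _pcg_next(st)
    st[0] = st[0] + uint64(seed)
    _pcg_next(st)
    _pcg_next(st)
    return st


@njit(cache=True, inline="always")
def _randn(st):
    u1 = _rand(st)
    u2 = _rand(st)
    return math.sqrt(-2.0 * math.log(u1)) * math.cos(2.0 * math.pi * u2)


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _voxel_flat(x, y, z, ox, oy, oz, sx, sy, sz, nx, ny, nz):
    ix = int(math.floor((x - ox) / sx))
    iy = int(math.floor((y - oy) / sy))
    iz = int(math.floor((z - oz) / sz))
    if ix < 0 or iy < 0 or iz < 0 or ix >= nx or iy >= ny or iz >= nz:
        return -1
    return (ix * ny + iy) * nz + iz


@njit(cache=True)
def _ray_box_entry(px, py, pz, dx, dy, dz, lo0, lo1, lo2, hi0, hi1, hi2):
    """Parameter t >= 0 at which the ray enters the box, or -1 if it misses."""
    t0 = 0.0
    t1 = 1e30
    for axis in range(3):
        if axis == 0:
            p, d, lo, hi = px, dx, lo0, hi0
        elif axis == 1:
            p, d, lo, hi = py, dy, lo1, hi1
        else:
            p, d, lo, hi = pz, dz, lo2, hi2
        if abs(d) < 1e-12:
            if p < lo or p > hi:
                return -1.0
        else:
            ta = (lo - p) / d
            tb = (hi - p) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    if t1 < t0:
        return -1.0
    return t0


@njit(cache=True, inline="always")
def _rotate(u, v, w, ct, phi):
    """Rotate unit vector (u,v,w) by polar angle acos(ct), azimuth phi."""
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(w) > 0.999999:
        sign = 1.0 if w > 0 else -1.0
        return st * cp, sign * st * sp, sign * ct
    rho = math.sqrt(u * u + v * v)
    un = u * ct + st * (u * w * cp - v * sp) / rho
    vn = v * ct + st * (v * w * cp + u * sp) / rho
    wn = w * ct - rho * st * cp
    norm = math.sqrt(un * un + vn * vn + wn * wn)
    return un / norm, vn / norm, wn / norm


# ---------------------------------------------------------------------------
# Compton sampling (EGS-style mixture/rejection on eps = E'/E)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sample_compton_eps(k, st):
    eps_min = 1.0 / (1.0 + 2.0 * k)
    a1 = math.log(1.0 / eps_min)
    a2 = 0.5 * (1.0 - eps_min * eps_min)
    while True:
        if _rand(st) * (a1 + a2) < a1:
            eps = eps_min * math.exp(a1 * _rand(st))
        else:
            eps = math.sqrt(eps_min * eps_min
                            + (1.0 - eps_min * eps_min) * _rand(st))
        t = (1.0 - eps) / (k * eps)
        sin2 = t * (2.0 - t)
        g = 1.0 - eps * sin2 / (1.0 + eps * eps)
        if _rand(st) <= g:
            return eps


# ---------------------------------------------------------------------------
# The history processor: transports everything on the particle stack
# ---------------------------------------------------------------------------

@njit(cache=True, nogil=True)
def _process_stack(sp, p_type, p_e, p_x, p_y, p_z, p_u, p_v, p_w,
                   dens, nx, ny, nz, ox, oy, oz, sx, sy, sz, rho_max,
                   e_ph, mu_c_tab, mu_pe_tab, mu_tot_tab,
                   e_el, l_res_tab, sig_mol_tab, sig_br_tab, csda_tab, x0_rad,
                   pcut, ecut, kcut, max_step,
                   edep, acc, st):
    """Pop and transport particles until the stack is empty.

    acc[0] accumulates escaped energy.  Stack slots above _STACK_CAP-2
    deposit locally instead of pushing (energy is always conserved).
    """
    hi0 = ox + nx * sx
    hi1 = oy + ny * sy
    hi2 = oz + nz * sz
    min_sp = min(sx, min(sy, sz))

    while sp > 0:
        sp -= 1
        ptype = p_type[sp]
        e = p_e[sp]
        x = p_x[sp]
        y = p_y[sp]
        z = p_z[sp]
        u = p_u[sp]
        v = p_v[sp]
        w = p_w[sp]

        if ptype == 0:
            # ---------------- photon ----------------
            idx = _voxel_flat(x, y, z, ox, oy, oz, sx, sy, sz, nx, ny, nz)
            if idx < 0:
                t_in = _ray_box_entry(x, y, z, u, v, w, ox, oy, oz, hi0, hi1, hi2)
                if t_in < 0.0:
                    acc[0] += e
                    continue
                x += (t_in + 1e-9) * u
                y += (t_in + 1e-9) * v
                z += (t_in + 1e-9) * w
            alive = True
            while alive:
                if e <= pcut:
                    idx = _voxel_flat(x, y, z, ox, oy, oz, sx, sy, sz, nx, ny, nz)
                    if idx >= 0:
                        edep[idx] += e
                    else:
                        acc[0] += e
                    break
                mu_t = np.interp(e, e_ph, mu_tot_tab)
                mu_maj = rho_max * mu_t
                if mu_maj <= 1e-12:
                    acc[0] += e
                    break
                step = -math.log(_rand(st)) / mu_maj
                x += step * u
                y += step * v
                z += step * w
                idx = _voxel_flat(x, y, z, ox, oy, oz, sx, sy, sz, nx, ny, nz)
                if idx < 0:
                    acc[0] += e
                    break
                rho = dens[idx]
                if _rand(st) * mu_maj > rho * mu_t:
                    continue  # virtual (Woodcock) collision
                mu_c = np.interp(e, e_ph, mu_c_tab)
                mu_pe = np.interp(e, e_ph, mu_pe_tab)
                r = _rand(st) * mu_t
                if r < mu_c:
                    # Compton on a free electron
                    k = e / 0.511
                    eps = _sample_compton_eps(k, st)
                    e_sc = eps * e
                    t_el = e - e_sc
                    ct = 1.0 - (1.0 - eps) / (k * eps)
                    if ct > 1.0:
                        ct = 1.0
                    elif ct < -1.0:
                        ct = -1.0
                    phi = 2.0 * math.pi * _rand(st)
                    nu, nv, nw = _rotate(u, v, w, ct, phi)
                    # electron direction from momentum conservation
                    ex = e * u - e_sc * nu
                    ey = e * v - e_sc * nv
                    ez = e * w - e_sc * nw
                    en = math.sqrt(ex * ex + ey * ey + ez * ez)
                    if en < 1e-12:
                        ex, ey, ez = u, v, w
                    else:
                        ex /= en
                        ey /= en
                        ez /= en
                    if t_el > 0.0:
                        if sp < _STACK_CAP - 2:
                            p_type[sp] = 1
                            p_e[sp] = t_el
                            p_x[sp] = x
                            p_y[sp] = y
                            p_z[sp] = z
                            p_u[sp] = ex
                            p_v[sp] = ey
                            p_w[sp] = ez
                            sp += 1
                        else:
                            edep[idx] += t_el
                    u, v, w = nu, nv, nw
                    e = e_sc
                elif r < mu_c + mu_pe:
                    # photoelectric: photoelectron continues forward
                    p_type[sp] = 1
                    p_e[sp] = e
                    p_x[sp] = x
                    p_y[sp] = y
                    p_z[sp] = z
                    p_u[sp] = u
                    p_v[sp] = v
                    p_w[sp] = w
                    sp += 1
                    break
                else:
                    # pair production: uniform kinetic-energy split
                    t_tot = e - 1.022
                    if t_tot < 0.0:
                        t_tot = 0.0
                    f = _rand(st)
                    if sp < _STACK_CAP - 3:
                        p_type[sp] = 1
                        p_e[sp] = f * t_tot
                        p_x[sp] = x
                        p_y[sp] = y
                        p_z[sp] = z
                        p_u[sp] = u
                        p_v[sp] = v
                        p_w[sp] = w
                        sp += 1
                        p_type[sp] = 2
                        p_e[sp] = (1.0 - f) * t_tot
                        p_x[sp] = x
                        p_y[sp] = y
                        p_z[sp] = z
                        p_u[sp] = u
                        p_v[sp] = v
                        p_w[sp] = w
                        sp += 1
                    else:
                        edep[idx] += e
                    break
            continue

        # ---------------- electron / positron ----------------
        is_pos = ptype == 2
        t_e = e
        n_vac = 0
        while True:
            idx = _voxel_flat(x, y, z, ox, oy, oz, sx, sy, sz, nx, ny, nz)
            if idx < 0:
                acc[0] += t_e + (1.022 if is_pos else 0.0)
                is_pos = False
                break
            rho = dens[idx]
            if rho < _VACUUM_RHO:
                x += min_sp * u
                y += min_sp * v
                z += min_sp * w
                n_vac += 1
                if n_vac > 100000:
                    acc[0] += t_e + (1.022 if is_pos else 0.0)
                    is_pos = False
                    break
                continue
            if t_e <= ecut:
                # straight-line CSDA residual
                r_cm = np.interp(t_e, e_el, csda_tab) / rho
                if r_cm < min_sp:
                    edep[idx] += t_e
                else:
                    nseg = int(r_cm / (0.5 * min_sp)) + 1
                    if nseg > 16:
                        nseg = 16
                    seg = r_cm / nseg
                    for i in range(nseg):
                        mx = x + (i + 0.5) * seg * u
                        my = y + (i + 0.5) * seg * v
                        mz = z + (i + 0.5) * seg * w
                        im = _voxel_flat(mx, my, mz, ox, oy, oz, sx, sy, sz,
                                         nx, ny, nz)
                        if im >= 0:
                            edep[im] += t_e / nseg
                        else:
                            acc[0] += t_e / nseg
                    x += r_cm * u
                    y += r_cm * v
                    z += r_cm * w
                break
            # condensed-history step
            sig_m = np.interp(t_e, e_el, sig_mol_tab)
            sig_b = np.interp(t_e, e_el, sig_br_tab)
            sig_cm = (sig_m + sig_b) * rho
            if sig_cm > 1e-12:
                d_hard = -math.log(_rand(st)) / sig_cm
            else:
                d_hard = 1e30
            l_cm = np.interp(t_e, e_el, l_res_tab) * rho
            h = 0.15 * t_e / l_cm
            if h > max_step:
                h = max_step
            if h > min_sp:
                h = min_sp
            hard = False
            if d_hard <= h:
                h = d_hard
                hard = True
            de = l_cm * h
            if de >= t_e - ecut:
                de = t_e - ecut
                h = de / l_cm
                hard = False
            # continuous loss goes to the voxel the step started in (the
            # stopping power used belongs to that voxel's density)
            edep[idx] += de
            t_e -= de
            x += h * u
            y += h * v
            z += h * w
            # Highland small-angle multiple scattering
            t_rad = h * rho / x0_rad
            if t_rad > 1e-12:
                pc2 = t_e * (t_e + 1.022)
                beta_pc = pc2 / (t_e + 0.511)
                if beta_pc > 1e-6:
                    lt = math.log(t_rad)
                    th0 = 13.6 / beta_pc * math.sqrt(t_rad) \
                        * (1.0 + 0.038 * lt)
                    if th0 > 0.0:
                        theta = th0 * _randn(st)
                        u, v, w = _rotate(u, v, w, math.cos(theta),
                                          2.0 * math.pi * _rand(st))
            if hard and t_e > ecut:
                if _rand(st) * (sig_m + sig_b) < sig_m and t_e > 2.0 * ecut:
                    # Moller knock-on, 1/T^2 spectrum on [ecut, T/2]
                    uu = _rand(st)
                    t_d = 1.0 / (1.0 / ecut - uu * (1.0 / ecut - 2.0 / t_e))
                    if t_d > 0.5 * t_e:
                        t_d = 0.5 * t_e
                    ct2 = t_d * (t_e + 1.022) / (t_e * (t_d + 1.022))
                    ct_d = math.sqrt(min(1.0, ct2))
                    t_e -= t_d
                    if sp < _STACK_CAP - 2:
                        du, dv, dw = _rotate(u, v, w, ct_d,
                                             2.0 * math.pi * _rand(st))
                        p_type[sp] = 1
                        p_e[sp] = t_d
                        p_x[sp] = x
                        p_y[sp] = y
                        p_z[sp] = z
                        p_u[sp] = du
                        p_v[sp] = dv
                        p_w[sp] = dw
                        sp += 1
                    else:
                        im2 = _voxel_flat(x, y, z, ox, oy, oz, sx, sy, sz,
                                          nx, ny, nz)
                        if im2 >= 0:
                            edep[im2] += t_d
                        else:
                            acc[0] += t_d
                else:
                    # bremsstrahlung, 1/k spectrum on [kcut, T]
                    k_ph = kcut * math.pow(t_e / kcut, _rand(st)) \
                        if t_e > kcut else 0.0
                    if k_ph > 0.0:
                        if k_ph > t_e:
                            k_ph = t_e
                        t_e -= k_ph
                        if sp < _STACK_CAP - 2:
                            p_type[sp] = 0
                            p_e[sp] = k_ph
                            p_x[sp] = x
                            p_y[sp] = y
                            p_z[sp] = z
                            p_u[sp] = u
                            p_v[sp] = v
                            p_w[sp] = w
                            sp += 1
                        else:
                            im2 = _voxel_flat(x, y, z, ox, oy, oz, sx, sy, sz,
                                              nx, ny, nz)
                            if im2 >= 0:
                                edep[im2] += k_ph
                            else:
                                acc[0] += k_ph
        if is_pos:
            # annihilation at rest: two back-to-back 511 keV photons
            ct = 2.0 * _rand(st) - 1.0
            phi = 2.0 * math.pi * _rand(st)
            stn = math.sqrt(max(0.0, 1.0 - ct * ct))
            au = stn * math.cos(phi)
            av = stn * math.sin(phi)
            aw = ct
            if sp < _STACK_CAP - 3:
                for sgn in (1.0, -1.0):
                    p_type[sp] = 0
                    p_e[sp] = 0.511
                    p_x[sp] = x
                    p_y[sp] = y
                    p_z[sp] = z
                    p_u[sp] = sgn * au
                    p_v[sp] = sgn * av
                    p_w[sp] = sgn * aw
                    sp += 1
            else:
                im = _voxel_flat(x, y, z, ox, oy, oz, sx, sy, sz, nx, ny, nz)
                if im >= 0:
                    edep[im] += 1.022
                else:
                    acc[0] += 1.022
    return sp


@njit(cache=True, nogil=True)
def _run_batch_plan(seed, stream, n_hist,
                    proj_cdf, proj_map_id, r_flat, t_flat,
                    cdf_flat, cdf_off, map_nx, map_ny,
                    map_x0, map_dx, map_y0, map_dy,
                    sad, plane_dist, sig1, sig2, w1,
                    u_grid, eg_grid,
                    dens, nx, ny, nz, ox, oy, oz, sx, sy, sz, rho_max,
                    e_ph, mu_c_tab, mu_pe_tab, mu_tot_tab,
                    e_el, l_res_tab, sig_mol_tab, sig_br_tab, csda_tab, x0_rad,
                    pcut, ecut, kcut, max_step,
                    edep, acc):
    st = _pcg_init(seed, stream)
    p_type = np.empty(_STACK_CAP, dtype=np.int8)
    p_e = np.empty(_STACK_CAP)
    p_x = np.empty(_STACK_CAP)
    p_y = np.empty(_STACK_CAP)
    p_z = np.empty(_STACK_CAP)
    p_u = np.empty(_STACK_CAP)
    p_v = np.empty(_STACK_CAP)
    p_w = np.empty(_STACK_CAP)
    launched = 0.0
    for _ in range(n_hist):
        # projection, weighted by its share of the total open time
        j = np.searchsorted(proj_cdf, _rand(st))
        if j >= proj_cdf.shape[0]:
            j = proj_cdf.shape[0] - 1
        m = proj_map_id[j]
        ncell = map_nx[m] * map_ny[m]
        seg = cdf_flat[cdf_off[m]:cdf_off[m] + ncell]
        c = np.searchsorted(seg, _rand(st))
        if c >= ncell:
            c = ncell - 1
        ix = c // map_ny[m]
        iy = c - ix * map_ny[m]
        xt = map_x0[m] + (ix + _rand(st)) * map_dx[m]
        yt = map_y0[m] + (iy + _rand(st)) * map_dy[m]
        # beam-frame exit point and focal-spot origin
        bx = xt * plane_dist
        by = yt * plane_dist
        bz = sad - plane_dist
        sig = sig1 if _rand(st) < w1 else sig2
        gx = sig * _randn(st)
        gy = sig * _randn(st)
        du = bx - gx
        dv = by - gy
        dw = bz - sad
        nrm = math.sqrt(du * du + dv * dv + dw * dw)
        du /= nrm
        dv /= nrm
        dw /= nrm
        e0 = np.interp(_rand(st), u_grid, eg_grid)
        launched += e0
        # beam frame -> patient frame
        r0 = j * 9
        px = r_flat[r0] * bx + r_flat[r0 + 1] * by + r_flat[r0 + 2] * bz + t_flat[j * 3]
        py = r_flat[r0 + 3] * bx + r_flat[r0 + 4] * by + r_flat[r0 + 5] * bz + t_flat[j * 3 + 1]
        pz = r_flat[r0 + 6] * bx + r_flat[r0 + 7] * by + r_flat[r0 + 8] * bz + t_flat[j * 3 + 2]
        pu = r_flat[r0] * du + r_flat[r0 + 1] * dv + r_flat[r0 + 2] * dw
        pv = r_flat[r0 + 3] * du + r_flat[r0 + 4] * dv + r_flat[r0 + 5] * dw
        pw = r_flat[r0 + 6] * du + r_flat[r0 + 7] * dv + r_flat[r0 + 8] * dw
        p_type[0] = 0
        p_e[0] = e0
        p_x[0] = px
        p_y[0] = py
        p_z[0] = pz
        p_u[0] = pu
        p_v[0] = pv
        p_w[0] = pw
        _process_stack(1, p_type, p_e, p_x, p_y, p_z, p_u, p_v, p_w,
                       dens, nx, ny, nz, ox, oy, oz, sx, sy, sz, rho_max,
                       e_ph, mu_c_tab, mu_pe_tab, mu_tot_tab,
                       e_el, l_res_tab, sig_mol_tab, sig_br_tab, csda_tab,
                       x0_rad, pcut, ecut, kcut, max_step, edep, acc, st)
    return launched


@njit(cache=True, nogil=True)
def _run_batch_given(seed, stream, ptypes, energies, pos, dirs,
                     dens, nx, ny, nz, ox, oy, oz, sx, sy, sz, rho_max,
                     e_ph, mu_c_tab, mu_pe_tab, mu_tot_tab,
                     e_el, l_res_tab, sig_mol_tab, sig_br_tab, csda_tab,
                     x0_rad, pcut, ecut, kcut, max_step, edep, acc):
    st = _pcg_init(seed, stream)
    p_type = np.empty(_STACK_CAP, dtype=np.int8)
    p_e = np.empty(_STACK_CAP)
    p_x = np.empty(_STACK_CAP)
    p_y = np.empty(_STACK_CAP)
    p_z = np.empty(_STACK_CAP)
    p_u = np.empty(_STACK_CAP)
    p_v = np.empty(_STACK_CAP)
    p_w = np.empty(_STACK_CAP)
    launched = 0.0
    for i in range(energies.shape[0]):
        launched += energies[i]
        p_type[0] = ptypes[i]
        p_e[0] = energies[i]
        p_x[0] = pos[i, 0]
        p_y[0] = pos[i, 1]
        p_z[0] = pos[i, 2]
        p_u[0] = dirs[i, 0]
        p_v[0] = dirs[i, 1]
        p_w[0] = dirs[i, 2]
        _process_stack(1, p_type, p_e, p_x, p_y, p_z, p_u, p_v, p_w,
                       dens, nx, ny, nz, ox, oy, oz, sx, sy, sz, rho_max,
                       e_ph, mu_c_tab, mu_pe_tab, mu_tot_tab,
                       e_el, l_res_tab, sig_mol_tab, sig_br_tab, csda_tab,
                       x0_rad, pcut, ecut, kcut, max_step, edep, acc, st)
    return launched


@njit(cache=True, nogil=True)
def _first_interaction(seed, energies, pos, dirs,
                       dens, nx, ny, nz, ox, oy, oz, sx, sy, sz, rho_max,
                       e_ph, mu_tot_tab, out_dist):
    """Woodcock distance (cm, from the starting point) to the first real
    interaction per primary photon; inf if the photon escapes first."""
    st = _pcg_init(seed, 0)
    hi0 = ox + nx * sx
    hi1 = oy + ny * sy
    hi2 = oz + nz * sz
    for i in range(energies.shape[0]):
        e = energies[i]
        x = pos[i, 0]
        y = pos[i, 1]
        z = pos[i, 2]
        u = dirs[i, 0]
        v = dirs[i, 1]
        w = dirs[i, 2]
        travelled = 0.0
        idx = _voxel_flat(x, y, z, ox, oy, oz, sx, sy, sz, nx, ny, nz)
        if idx < 0:
            t_in = _ray_box_entry(x, y, z, u, v, w, ox, oy, oz, hi0, hi1, hi2)
            if t_in < 0:
                out_dist[i] = np.inf
                continue
            x += (t_in + 1e-9) * u
            y += (t_in + 1e-9) * v
            z += (t_in + 1e-9) * w
            travelled += t_in + 1e-9
        mu_t = np.interp(e, e_ph, mu_tot_tab)
        mu_maj = rho_max * mu_t
        out_dist[i] = np.inf
        if mu_maj <= 1e-12:
            continue
        while True:
            step = -math.log(_rand(st)) / mu_maj
            x += step * u
            y += step * v
            z += step * w
            travelled += step
            idx = _voxel_flat(x, y, z, ox, oy, oz, sx, sy, sz, nx, ny, nz)
            if idx < 0:
                break
            if _rand(st) * mu_maj <= dens[idx] * mu_t:
                out_dist[i] = travelled
                break


# ---------------------------------------------------------------------------
# Python drivers
# ---------------------------------------------------------------------------

def _table_args(mat: MaterialTable):
    return (mat.e_photon, mat.mu_compton, mat.mu_photo, mat.mu_total,
            mat.e_electron, mat.stopping_restricted, mat.sigma_moller,
            mat.sigma_brems, mat.csda_range, mat.radiation_length)


def _phantom_args(phantom: VoxelPhantom):
    nx, ny, nz = phantom.dims
    ox, oy, oz = phantom.origin_cm
    sx, sy, sz = phantom.spacing_cm
    dens = np.ascontiguousarray(phantom.density.reshape(-1))
    return dens, nx, ny, nz, ox, oy, oz, sx, sy, sz, float(phantom.density.max())


def _uniform_grid(centers: np.ndarray):
    d = np.diff(centers)
    if d.size and not np.allclose(d, d[0], rtol=1e-6, atol=1e-12):
        raise ValueError("fluence map grid must be uniform for sampling")
    step = float(d[0]) if d.size else 1.0
    return float(centers[0] - 0.5 * step), step


def _batch_sizes(n_histories: int, n_batches: int) -> list[int]:
    base = n_histories // n_batches
    sizes = [base] * n_batches
    for i in range(n_histories - base * n_batches):
        sizes[i] += 1
    return [s for s in sizes if s > 0]


def run_simulation(plan: Plan, beam_model: BeamModel, phantom: VoxelPhantom,
                   cfg: TransportConfig, n_histories: int) -> DoseGrid:
    """Simulate a delivery plan and return dose per primary particle.

    Histories are sampled across projections in proportion to each
    projection's summed leaf open time.  The run is split into
    ``cfg.n_batches`` independently seeded batches (the batch spread
    gives the per-voxel variance); batches are distributed over
    ``cfg.n_workers`` threads without affecting the result.
    """
    if n_histories < 1:
        raise ValueError("n_histories must be >= 1")
    from .beam_model import build_projection_fluence

    # per-projection fluence maps, cached over repeated sinogram rows
    jaw = beam_model.jaw(plan.jaw_label)
    cache: dict[bytes, int] = {}
    maps = []
    proj_map_id = np.empty(plan.n_projections, dtype=np.int64)
    for j, proj in enumerate(plan.projections):
        key = proj.lot.tobytes()
        if key not in cache:
            cache[key] = len(maps)
            maps.append(build_projection_fluence(proj.lot, beam_model.filters,
                                                 beam_model.cone, jaw))
        proj_map_id[j] = cache[key]

    weights = np.array([p.lot.sum() * p.duration_s for p in plan.projections])
    if weights.sum() <= 0:
        raise ValueError("plan has zero total open time")
    proj_cdf = np.cumsum(weights) / weights.sum()

    cdf_parts, off = [], [0]
    map_nx = np.empty(len(maps), dtype=np.int64)
    map_ny = np.empty(len(maps), dtype=np.int64)
    map_x0 = np.empty(len(maps))
    map_dx = np.empty(len(maps))
    map_y0 = np.empty(len(maps))
    map_dy = np.empty(len(maps))
    for m, fmap in enumerate(maps):
        flat = fmap.value.ravel()
        total = flat.sum()
        if total <= 0:
            raise ValueError("a projection fluence map is empty")
        cdf_parts.append(np.cumsum(flat) / total)
        off.append(off[-1] + flat.size)
        map_nx[m], map_ny[m] = fmap.value.shape
        map_x0[m], map_dx[m] = _uniform_grid(fmap.x_tangent)
        map_y0[m], map_dy[m] = _uniform_grid(fmap.y_tangent)
    cdf_flat = np.concatenate(cdf_parts)
    cdf_off = np.asarray(off[:-1], dtype=np.int64)

    frames = projection_frames(plan, beam_model.sad_cm)
    r_flat = np.concatenate([f.rotation.ravel() for f in frames])
    t_flat = np.concatenate([f.matrix[:3, 3] for f in frames])

    u_grid, eg_grid = beam_model.spectrum.inverse_cdf_table()
    spot = beam_model.focal_spot
    mat = cfg.materials()
    ph_args = _phantom_args(phantom)
    (e_ph, mu_c, mu_pe, mu_tot, e_el, l_res, sig_m, sig_b, csda,
     x0_rad) = _table_args(mat)

    sizes = _batch_sizes(n_histories, cfg.n_batches)
    nvox = int(np.prod(phantom.dims))
    edep_batches = np.zeros((len(sizes), nvox))
    escaped = np.zeros(len(sizes))
    launched = np.zeros(len(sizes))

    def _one(b: int) -> None:
        acc = np.zeros(1)
        launched[b] = _run_batch_plan(
            np.uint64(cfg.seed), np.uint64(b + 1), sizes[b],
            proj_cdf, proj_map_id, r_flat, t_flat,
            cdf_flat, cdf_off, map_nx, map_ny, map_x0, map_dx, map_y0, map_dy,
            beam_model.sad_cm, beam_model.plane_dist_cm,
            spot.sigma1_mm * 0.1, spot.sigma2_mm * 0.1, spot.weight1,
            u_grid, eg_grid, *ph_args,
            e_ph, mu_c, mu_pe, mu_tot, e_el, l_res, sig_m, sig_b, csda, x0_rad,
            cfg.photon_cutoff_mev, cfg.electron_cutoff_mev,
            cfg.brems_cutoff_mev, cfg.max_step_cm,
            edep_batches[b], acc)
        escaped[b] = acc[0]

    if cfg.n_workers == 1:
        for b in range(len(sizes)):
            _one(b)
    else:
        with ThreadPoolExecutor(max_workers=cfg.n_workers) as pool:
            list(pool.map(_one, range(len(sizes))))

    return _finalize(phantom, edep_batches, np.asarray(sizes), launched,
                     escaped, warn_on_empty=True)


def _finalize(phantom: VoxelPhantom, edep_batches: np.ndarray,
              sizes: np.ndarray, launched: np.ndarray, escaped: np.ndarray,
              warn_on_empty: bool = False) -> DoseGrid:
    mass_kg = phantom.density.reshape(-1) * phantom.voxel_volume_cm3() * 1e-3
    inv_mass = np.where(mass_kg > 0, 1.0 / np.maximum(mass_kg, 1e-300), 0.0)
    dose_batches = (edep_batches * MEV_TO_J * inv_mass[None, :]
                    / sizes[:, None])
    dose = dose_batches.mean(axis=0)
    nb = len(sizes)
    if nb > 1:
        var = dose_batches.var(axis=0, ddof=1) / nb
    else:
        var = np.zeros_like(dose)
    shape = phantom.dims
    if warn_on_empty and edep_batches.sum() == 0.0:
        warnings.warn("beam did not intersect the phantom: dose grid is zero")
    return DoseGrid(origin_cm=phantom.origin_cm, spacing_cm=phantom.spacing_cm,
                    dose=dose.reshape(shape), variance=var.reshape(shape),
                    n_histories=int(sizes.sum()), n_batches=nb,
                    energy_launched_mev=float(launched.sum()),
                    energy_deposited_mev=float(edep_batches.sum()),
                    energy_escaped_mev=float(escaped.sum()))


def simulate_primaries(positions: np.ndarray, directions: np.ndarray,
                       energies: np.ndarray, phantom: VoxelPhantom,
                       cfg: TransportConfig, ptypes=None) -> EnergyTally:
    """Transport explicit primaries (default photons) and tally energy."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    energies = np.atleast_1d(np.asarray(energies, dtype=float))
    if ptypes is None:
        ptypes = np.zeros(energies.size, dtype=np.int8)
    else:
        ptypes = np.asarray(ptypes, dtype=np.int8)
    mat = cfg.materials()
    (e_ph, mu_c, mu_pe, mu_tot, e_el, l_res, sig_m, sig_b, csda,
     x0_rad) = _table_args(mat)
    edep = np.zeros(int(np.prod(phantom.dims)))
    acc = np.zeros(1)
    launched = _run_batch_given(
        np.uint64(cfg.seed), np.uint64(1), ptypes, energies, positions,
        directions, *_phantom_args(phantom),
        e_ph, mu_c, mu_pe, mu_tot, e_el, l_res, sig_m, sig_b, csda, x0_rad,
        cfg.photon_cutoff_mev, cfg.electron_cutoff_mev, cfg.brems_cutoff_mev,
        cfg.max_step_cm, edep, acc)
    return EnergyTally(edep_mev=edep.reshape(phantom.dims),
                       launched_mev=float(launched), escaped_mev=float(acc[0]))


def transport_photon(state, phantom: VoxelPhantom, cfg: TransportConfig,
                     tally: EnergyTally | None = None) -> EnergyTally:
    """Transport one primary photon (convenience wrapper for tests)."""
    out = simulate_primaries(state.position, state.direction,
                             np.array([state.energy]), phantom, cfg)
    return _merge(tally, out)


def transport_electron(state, phantom: VoxelPhantom, cfg: TransportConfig,
                       tally: EnergyTally | None = None) -> EnergyTally:
    """Transport one primary electron."""
    out = simulate_primaries(state.position, state.direction,
                             np.array([state.energy]), phantom, cfg,
                             ptypes=np.array([1], dtype=np.int8))
    return _merge(tally, out)


def _merge(tally: EnergyTally | None, out: EnergyTally) -> EnergyTally:
    if tally is None:
        return out
    tally.edep_mev += out.edep_mev
    tally.launched_mev += out.launched_mev
    tally.escaped_mev += out.escaped_mev
    return tally


def first_interaction_depths(positions, directions, energies,
                             phantom: VoxelPhantom,
                             cfg: TransportConfig) -> np.ndarray:
    """Distance travelled to the first real interaction per photon."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    energies = np.atleast_1d(np.asarray(energies, dtype=float))
    mat = cfg.materials()
    out = np.empty(energies.size)
    dens, nx, ny, nz, ox, oy, oz, sx, sy, sz, rho_max = _phantom_args(phantom)
    _first_interaction(np.uint64(cfg.seed), energies, positions, directions,
                       dens, nx, ny, nz, ox, oy, oz, sx, sy, sz, rho_max,
                       mat.e_photon, mat.mu_total, out)
    return out


# ---------------------------------------------------------------------------
# Uncertainty and I/O
# ---------------------------------------------------------------------------

def relative_uncertainty(dose_grid: DoseGrid,
                         threshold: float = 0.5) -> np.ndarray:
    """Per-voxel standard error / mean for voxels above ``threshold`` of
    the maximum dose; NaN elsewhere."""
    if dose_grid.n_batches < 2:
        raise ValueError("at least 2 batches are required for uncertainty")
    dmax = dose_grid.dose.max()
    if dmax <= 0:
        raise ValueError("dose grid is empty")
    mask = dose_grid.dose > threshold * dmax
    rel = np.full(dose_grid.dose.shape, np.nan)
    rel[mask] = np.sqrt(dose_grid.variance[mask]) / dose_grid.dose[mask]
    return rel


def mean_relative_uncertainty(dose_grid: DoseGrid,
                              threshold: float = 0.5) -> float:
    rel = relative_uncertainty(dose_grid, threshold)
    return float(np.nanmean(rel))


_DOSE_FORMAT = "tomovsm-dose-v1"


def write_dose(dose_grid: DoseGrid, path: str | Path) -> None:
    np.savez_compressed(
        path, format=_DOSE_FORMAT, dose=dose_grid.dose,
        variance=dose_grid.variance,
        origin_cm=np.asarray(dose_grid.origin_cm),
        spacing_cm=np.asarray(dose_grid.spacing_cm),
        n_histories=dose_grid.n_histories, n_batches=dose_grid.n_batches,
        energy_mev=np.array([dose_grid.energy_launched_mev,
                             dose_grid.energy_deposited_mev,
                             dose_grid.energy_escaped_mev]))


def read_dose(path: str | Path) -> DoseGrid:
    with np.load(path) as data:
        if str(data.get("format", "")) != _DOSE_FORMAT:
            raise ValueError(f"{path} is not a {_DOSE_FORMAT} container")
        e = data["energy_mev"]
        return DoseGrid(tuple(data["origin_cm"]), tuple(data["spacing_cm"]),
                        data["dose"], data["variance"],
                        int(data["n_histories"]), int(data["n_batches"]),
                        float(e[0]), float(e[1]), float(e[2]))
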