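"""Parametric photon energy spectrum of an unflattened 6 MV fan beam.

The spectral density is modelled with the four-parameter family

    phi(E) = a*sqrt(E) + b/sqrt(E) + c*exp(-E) + d        [E in MeV]

clamped to zero where the fit goes negative.  The default coefficients
describe a tomotherapy-type beam whose density vanishes near 6 MeV and
whose mean energy is about 1.5 MeV.  The fit is unphysical below about
0.25 MeV (the 1/sqrt(E) term diverges negative), so the support starts
at ``e_min`` and ends at the zero crossing ``e_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "EnergySpectrum",
    "evaluate_spectrum",
    "spectrum_max_energy",
    "sample_energy",
]

#: Default fit coefficients for a 6 MV unflattened tomotherapy beam.
DEFAULT_COEFFICIENTS = (-0.352, -1.42, 2.22, 1.437)
DEFAULT_E_MIN = 0.25


def _raw_density(a: float, b: float, c: float, d: float, e):
    e = np.asarray(e, dtype=float)
    return a * np.sqrt(e) + b / np.sqrt(e) + c * np.exp(-e) + d


@dataclass(frozen=True)
class EnergySpectrum:
    """Clamped parametric photon spectrum on ``[e_min, e_max]`` (MeV).

    ``e_max`` defaults to the zero crossing of the raw density above
    1 MeV, so the clamped density is non-negative on its whole support.
    """

    a: float = DEFAULT_COEFFICIENTS[0]
    b: float = DEFAULT_COEFFICIENTS[1]
    c: float = DEFAULT_COEFFICIENTS[2]
    d: float = DEFAULT_COEFFICIENTS[3]
    e_min: float = DEFAULT_E_MIN
    e_max: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.e_max is None:
            object.__setattr__(self, "e_max", spectrum_max_energy(self))
        if not self.e_min < self.e_max:
            raise ValueError(f"e_min ({self.e_min}) must be < e_max ({self.e_max})")

    # -- evaluation ------------------------------------------------------

    def density(self, e):
        """Unnormalized clamped density; zero outside ``[e_min, e_max]``."""
        e = np.asarray(e, dtype=float)
        if np.any(e <= 0.0):
            raise ValueError("photon energy must be positive")
        val = np.maximum(0.0, _raw_density(self.a, self.b, self.c, self.d, e))
        val = np.where((e < self.e_min) | (e > self.e_max), 0.0, val)
        return val if val.ndim else float(val)

    def inverse_cdf_table(self, n_grid: int = 32768):
        """(u_grid, e_grid) table of the inverse CDF for table lookup sampling."""
        e = np.linspace(self.e_min, self.e_max, n_grid)
        pdf = np.asarray(self.density(e))
        cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) * 0.5 * np.diff(e))])
        total = cdf[-1]
        if total <= 0:
            raise ValueError("spectrum density integrates to zero")
        return cdf / total, e

    def mean_energy(self, n_grid: int = 32768) -> float:
        e = np.linspace(self.e_min, self.e_max, n_grid)
        pdf = np.asarray(self.density(e))
        return float(np.trapezoid(e * pdf, e) / np.trapezoid(pdf, e))


def evaluate_spectrum(spec: EnergySpectrum, e):
    """Clamped spectral density at energy ``e`` (MeV); unnormalized."""
    return spec.density(e)


def spectrum_max_energy(spec: EnergySpectrum, bracket=(1.0, 10.0), tol: float = 1e-6) -> float:
    """Zero crossing of the raw (unclamped) density above 1 MeV.

    Found by bracketed root finding to ``tol`` MeV.  Raises if the raw
    density has no sign change in ``bracket`` (e.g. a constant density);
    in that case an explicitly supplied ``e_max`` is the only bound.
    """
    lo, hi = bracket
    f = lambda e: float(_raw_density(spec.a, spec.b, spec.c, spec.d, e))
    f_lo = f(lo)
    if f_lo <= 0:
        raise ValueError("density not positive at lower bracket")
    # walk the bracket up until the density turns negative
    e_hi = None
    for e_try in np.linspace(lo, hi, 256)[1:]:
        if f(e_try) < 0:
            e_hi = float(e_try)
            break
    if e_hi is None:
        # degenerate density with no zero crossing (e.g. a constant):
        # an explicitly imposed upper bound is the only endpoint
        if spec.e_max is not None:
            return float(spec.e_max)
        raise ValueError("spectrum density has no zero crossing in bracket")
    return float(brentq(f, lo, e_hi, xtol=tol))


def sample_energy(spec: EnergySpectrum, rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw ``n`` i.i.d. photon energies (MeV) from the spectrum.

    Sampling inverts the CDF on a dense energy grid (linear interpolation
    between grid nodes); reproducible for a fixed ``rng`` state.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    u_grid, e_grid = spec.inverse_cdf_table()
    u = rng.random(n)
    return np.interp(u, u_grid, e_grid)
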