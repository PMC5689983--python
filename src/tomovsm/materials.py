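"""Water interaction data for the coupled photon-electron engine.

Everything is expressed per unit mass thickness (cm^2/g, MeV cm^2/g) so
a single water-composition table serves any density-scaled voxel grid.

* Compton attenuation is the analytic Klein-Nishina total cross section
  per free electron times the electron density of water, which keeps the
  attenuation coefficient exactly consistent with the sampled kinematics.
* Photoelectric absorption uses an E^-3 power law anchored at 100 keV
  (adequate above the 50 keV photon cutoff, where it is a few percent of
  the total and falling fast).
* Pair production and electron collision/radiative stopping powers are
  compact tables transcribed once from a standard public compilation for
  liquid water, interpolated log-linearly.
* Rayleigh scattering is omitted (it redistributes but barely attenuates
  at therapy energies).

The class II condensed-history split is built here too: the restricted
stopping power excludes energy going into knock-on electrons above the
hard-collision threshold and into bremsstrahlung photons above the
photon threshold; those channels appear instead as discrete-event cross
sections (Moller in the small-scattering-angle 1/T^2 form, brems with a
1/k photon spectrum normalised to the radiative stopping power).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MaterialTable", "water_table", "ELECTRON_REST_MEV"]

ELECTRON_REST_MEV = 0.511
R_E_CM = 2.8179403262e-13           # classical electron radius
ELECTRON_DENSITY_WATER = 3.3428e23  # electrons per gram
#: 2*pi*r_e^2*m_e*c^2*N_e for water, MeV cm^2/g (Moller prefactor)
_MOLLER_C = 2.0 * np.pi * R_E_CM**2 * ELECTRON_REST_MEV * ELECTRON_DENSITY_WATER
RADIATION_LENGTH_WATER = 36.08      # g/cm^2, for multiple scattering

PAIR_THRESHOLD_MEV = 2.0 * ELECTRON_REST_MEV

# mass pair-production coefficient of water, cm^2/g
_PAIR_E = np.array([PAIR_THRESHOLD_MEV, 1.25, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0])
_PAIR_MU = np.array([0.0, 3.2e-5, 1.4e-4, 3.9e-4, 1.13e-3, 1.87e-3,
                     2.57e-3, 3.19e-3, 4.34e-3, 5.32e-3])

# electron collision stopping power of water, MeV cm^2/g
_SCOL_E = np.array([0.01, 0.02, 0.03, 0.05, 0.07, 0.1, 0.15, 0.2, 0.3, 0.4,
                    0.5, 0.7, 1.0, 1.25, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0])
_SCOL = np.array([22.56, 13.17, 9.753, 6.603, 5.295, 4.115, 3.238, 2.793,
                  2.355, 2.148, 2.034, 1.911, 1.849, 1.829, 1.822, 1.824,
                  1.846, 1.870, 1.892, 1.911, 1.943, 1.968])

# electron radiative stopping power of water, MeV cm^2/g
_SRAD_E = np.array([0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 3.0, 4.0,
                    5.0, 6.0, 8.0, 10.0])
_SRAD = np.array([3.9e-4, 5.1e-4, 9.0e-4, 1.6e-3, 2.9e-3, 6.5e-3, 1.28e-2,
                  2.84e-2, 4.57e-2, 6.36e-2, 8.19e-2, 1.005e-1, 1.388e-1,
                  1.825e-1])

_CSDA_R_AT_10KEV = 2.52e-4  # g/cm^2, range below the table floor


def klein_nishina_total(e_mev) -> np.ndarray:
    """Total Klein-Nishina cross section per electron (cm^2)."""
    k = np.asarray(e_mev, dtype=float) / ELECTRON_REST_MEV
    t = 1.0 + 2.0 * k
    log_t = np.log(t)
    sigma = 2.0 * np.pi * R_E_CM**2 * (
        (1.0 + k) / k**2 * (2.0 * (1.0 + k) / t - log_t / k)
        + log_t / (2.0 * k)
        - (1.0 + 3.0 * k) / t**2
    )
    return sigma


def _beta2(t_mev):
    gamma = 1.0 + np.asarray(t_mev, dtype=float) / ELECTRON_REST_MEV
    return 1.0 - 1.0 / gamma**2


def _loglog_interp(e, e_tab, v_tab):
    return np.exp(np.interp(np.log(e), np.log(e_tab), np.log(v_tab)))


@dataclass(frozen=True)
class MaterialTable:
    """Dense per-energy tables (cm^2/g, MeV cm^2/g) for one material."""

    # photons
    e_photon: np.ndarray
    mu_compton: np.ndarray
    mu_photo: np.ndarray
    mu_pair: np.ndarray
    mu_total: np.ndarray
    # electrons
    e_electron: np.ndarray
    stopping_restricted: np.ndarray
    stopping_collision: np.ndarray
    stopping_radiative: np.ndarray
    sigma_moller: np.ndarray
    sigma_brems: np.ndarray
    csda_range: np.ndarray          # g/cm^2
    # cutoffs baked into the restricted quantities
    electron_cutoff_mev: float
    brems_cutoff_mev: float
    radiation_length: float = RADIATION_LENGTH_WATER

    def mu_total_at(self, e_mev):
        return np.interp(e_mev, self.e_photon, self.mu_total)

    def csda_range_at(self, t_mev):
        return np.interp(t_mev, self.e_electron, self.csda_range)


def water_table(electron_cutoff_mev: float = 0.2,
                brems_cutoff_mev: float = 0.2,
                n_grid: int = 512) -> MaterialTable:
    """Build the dense water table for the given hard-event thresholds."""
    if electron_cutoff_mev <= 0 or brems_cutoff_mev <= 0:
        raise ValueError("cutoffs must be positive")
    e_ph = np.geomspace(0.01, 10.0, n_grid)
    mu_c = klein_nishina_total(e_ph) * ELECTRON_DENSITY_WATER
    mu_pe = 2.76e-3 * (e_ph / 0.1) ** -3
    mu_pp = np.where(e_ph <= PAIR_THRESHOLD_MEV, 0.0,
                     np.interp(e_ph, _PAIR_E, _PAIR_MU))
    mu_tot = mu_c + mu_pe + mu_pp

    e_el = np.geomspace(0.01, 10.0, n_grid)
    s_col = _loglog_interp(e_el, _SCOL_E, _SCOL)
    s_rad = _loglog_interp(e_el, _SRAD_E, _SRAD)
    beta2 = _beta2(e_el)

    tc, kc = electron_cutoff_mev, brems_cutoff_mev
    # hard Moller channel exists only above 2*Tc (delta-ray max is T/2)
    hard_mol = e_el > 2.0 * tc
    de_hard = np.where(hard_mol, _MOLLER_C / beta2 * np.log(e_el / (2.0 * tc)), 0.0)
    sig_mol = np.where(hard_mol, _MOLLER_C / beta2 * (1.0 / tc - 2.0 / e_el), 0.0)
    # hard brems: 1/k photon spectrum on [kc, E] carrying the above-kc
    # share of the radiative loss; the below-kc share stays continuous
    hard_br = e_el > kc
    sig_br = np.where(hard_br, s_rad / e_el * np.log(e_el / kc), 0.0)
    s_rad_soft = np.where(hard_br, s_rad * kc / e_el, s_rad)

    restricted = np.maximum(s_col - de_hard + s_rad_soft, 0.05 * s_col)

    # CSDA range from the unrestricted total stopping power
    s_tot = s_col + s_rad
    inv = 1.0 / s_tot
    csda = np.concatenate([[0.0], np.cumsum(
        0.5 * (inv[1:] + inv[:-1]) * np.diff(e_el))]) + _CSDA_R_AT_10KEV

    return MaterialTable(
        e_photon=e_ph, mu_compton=mu_c, mu_photo=mu_pe, mu_pair=mu_pp,
        mu_total=mu_tot, e_electron=e_el, stopping_restricted=restricted,
        stopping_collision=s_col, stopping_radiative=s_rad,
        sigma_moller=sig_mol, sigma_brems=sig_br, csda_range=csda,
        electron_cutoff_mev=electron_cutoff_mev,
        brems_cutoff_mev=brems_cutoff_mev,
    )
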