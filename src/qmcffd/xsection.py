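"""Analytic photon cross sections for the bundled material tables.

The transport code reads linear attenuation coefficients from small
per-material tables shipped with the package (see :mod:`qmcffd.physics`).
Those tables are generated once, by ``scripts/make_material_tables.py``,
from the closed-form models in this module:

* Compton (incoherent): free-electron Klein-Nishina, total and
  differential.  An optional incoherent-scattering-function correction
  is available but off by default.
* Rayleigh (coherent): Thomson differential cross section times the
  square of a screened one-parameter atomic form factor; the single
  screening constant is calibrated against a tabulated aluminium
  coherent cross section at 60 keV.
* Photoelectric: the classic ``Z^4.5 / E^3.1`` power-law fit per atom,
  calibrated against a tabulated aluminium value at 30 keV.

These models reproduce total attenuation of light elements to a few
percent over 16-120 keV, which is the diagnostic-energy window this
package targets.  They are *approximations*: no absorption edges, no
Doppler broadening, no relativistic form-factor corrections.
"""

from __future__ import annotations

import functools

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

MEC2_KEV = 510.99895  #: electron rest energy, keV
R_E2_BARN = 0.0794080  #: classical electron radius squared, barn/sr
SIGMA_T_BARN = 8.0 * np.pi / 3.0 * R_E2_BARN  #: Thomson cross section, barn
N_A = 0.602214076  #: Avogadro's number in units of 1/(mol * barn * cm)
HC_KEV_A = 12.39842  #: h*c in keV * Angstrom

#: atomic number and standard atomic weight of the elements we need
ELEMENTS = {
    "H": (1, 1.008), "C": (6, 12.011), "N": (7, 14.007), "O": (8, 15.999),
    "Na": (11, 22.990), "Mg": (12, 24.305), "Al": (13, 26.982),
    "P": (15, 30.974), "S": (16, 32.06), "Cl": (17, 35.45),
    "Ar": (18, 39.948), "K": (19, 39.098), "Ca": (20, 40.078),
}

#: mass fractions and densities (g/cm^3) of the bundled materials
COMPOSITIONS = {
    "aluminium": ({"Al": 1.0}, 2.699),
    "water": ({"H": 0.1119, "O": 0.8881}, 0.998),
    "air": ({"N": 0.755, "O": 0.232, "Ar": 0.013}, 1.205e-3),
    "soft_tissue": (
        {"H": 0.102, "C": 0.143, "N": 0.034, "O": 0.708, "Na": 0.002,
         "P": 0.003, "S": 0.003, "Cl": 0.002, "K": 0.003}, 1.06),
    "cortical_bone": (
        {"H": 0.034, "C": 0.155, "N": 0.042, "O": 0.435, "Na": 0.001,
         "Mg": 0.002, "P": 0.103, "S": 0.003, "Ca": 0.225}, 1.92),
}

# Calibration anchors (mass attenuation components of aluminium, cm^2/g,
# from standard photon cross-section tabulations).
_AL_PHOTO_30KEV = 0.888
_AL_COH_60KEV = 0.0211
_PE_Z_EXP = 4.5
_PE_E_EXP = 3.1


def klein_nishina_dcs(energy_kev, cos_theta):
    """Klein-Nishina differential cross section, barn/sr per electron."""
    k = np.asarray(energy_kev, dtype=float) / MEC2_KEV
    c = np.asarray(cos_theta, dtype=float)
    ratio = 1.0 / (1.0 + k * (1.0 - c))  # E'/E
    sin2 = 1.0 - c * c
    return 0.5 * R_E2_BARN * ratio * ratio * (ratio + 1.0 / ratio - sin2)


def klein_nishina_total(energy_kev):
    """Total Klein-Nishina cross section, barn per electron (closed form)."""
    k = np.asarray(energy_kev, dtype=float) / MEC2_KEV
    t = 1.0 + 2.0 * k
    lg = np.log(t)
    term = ((1.0 + k) / k**2) * (2.0 * (1.0 + k) / t - lg / k)
    return 2.0 * np.pi * R_E2_BARN * (
        term + lg / (2.0 * k) - (1.0 + 3.0 * k) / t**2)


def compton_energy(energy_kev, cos_theta):
    """Photon energy after Compton scattering through angle acos(cos_theta)."""
    return energy_kev / (1.0 + (energy_kev / MEC2_KEV) * (1.0 - cos_theta))


def momentum_transfer(energy_kev, cos_theta):
    """Momentum-transfer variable x = sin(theta/2)/lambda in 1/Angstrom."""
    s = np.sqrt(np.maximum(0.5 * (1.0 - np.asarray(cos_theta, float)), 0.0))
    return s * np.asarray(energy_kev, float) / HC_KEV_A


def form_factor(x, z):
    """Screened atomic form factor F(x, Z); x in 1/Angstrom.

    One-parameter Thomas-Fermi-like screening: F = Z / (1 + (x/(g Z^(1/3)))^2)^2
    with g calibrated once (see :func:`_screening_constant`).
    """
    g = _screening_constant()
    u = np.asarray(x, float) / (g * z ** (1.0 / 3.0))
    return z / (1.0 + u * u) ** 2


def incoherent_scattering_function(x, z):
    """Crude analytic S(x, Z): 0 at x=0, -> Z at large x.

    Uses the same screening scale as :func:`form_factor`.  Optional
    low-energy binding correction for the Compton channel; off by
    default throughout the package.
    """
    g = _screening_constant()
    u = np.asarray(x, float) / (g * z ** (1.0 / 3.0))
    return z * u * u / (1.0 + u * u)


def rayleigh_dcs(energy_kev, cos_theta, z):
    """Coherent (Rayleigh) differential cross section, barn/sr per atom."""
    c = np.asarray(cos_theta, float)
    f = form_factor(momentum_transfer(energy_kev, c), z)
    return 0.5 * R_E2_BARN * (1.0 + c * c) * f * f


def rayleigh_total(energy_kev, z):
    """Total coherent cross section per atom, barn, by quadrature."""
    def integrand(c):
        return 2.0 * np.pi * rayleigh_dcs(energy_kev, c, z)
    val, _ = quad(integrand, -1.0, 1.0, limit=200)
    return val


def photoelectric_total(energy_kev, z):
    """Photoelectric cross section per atom, barn (power-law fit)."""
    return _pe_constant() * z ** _PE_Z_EXP * np.asarray(
        energy_kev, float) ** (-_PE_E_EXP)


@functools.lru_cache(maxsize=1)
def _pe_constant():
    # anchor: aluminium photoelectric mass attenuation at 30 keV
    z, a = ELEMENTS["Al"]
    sigma_barn = _AL_PHOTO_30KEV * a / N_A  # cm^2/g -> barn/atom
    return sigma_barn * 30.0 ** _PE_E_EXP / z ** _PE_Z_EXP


@functools.lru_cache(maxsize=1)
def _screening_constant():
    # anchor: aluminium coherent mass attenuation at 60 keV
    z, a = ELEMENTS["Al"]
    target_barn = _AL_COH_60KEV * a / N_A

    def sigma_with_g(g):
        def integrand(c):
            s = np.sqrt(max(0.5 * (1.0 - c), 0.0))
            x = s * 60.0 / HC_KEV_A
            u = x / (g * z ** (1.0 / 3.0))
            f = z / (1.0 + u * u) ** 2
            return np.pi * R_E2_BARN * (1.0 + c * c) * f * f
        val, _ = quad(integrand, -1.0, 1.0, limit=200)
        return val

    return brentq(lambda g: sigma_with_g(g) - target_barn, 1e-3, 10.0,
                  xtol=1e-10)


def mass_attenuation(material: str, energy_kev, use_sfunc: bool = False):
    """Mass attenuation components (photoelectric, Compton, Rayleigh).

    Parameters
    ----------
    material
        A key of :data:`COMPOSITIONS`.
    energy_kev
        Scalar or array of photon energies.
    use_sfunc
        Apply the incoherent-scattering-function correction to the
        Compton component (crude; default off).

    Returns
    -------
    (mu_pe, mu_compton, mu_rayleigh)
        Mass attenuation coefficients in cm^2/g.
    """
    fractions, _rho = COMPOSITIONS[material]
    e = np.asarray(energy_kev, dtype=float)
    mu_pe = np.zeros_like(e)
    mu_c = np.zeros_like(e)
    mu_r = np.zeros_like(e)
    for sym, w in fractions.items():
        z, a = ELEMENTS[sym]
        atoms_per_g = N_A / a  # in 1/(barn cm) units per gram: N_A/A * 1e-24 cm^2/barn
        mu_pe = mu_pe + w * atoms_per_g * photoelectric_total(e, z)
        if use_sfunc:
            sig_c = np.array([
                quad(lambda c, ee=ee: 2 * np.pi * klein_nishina_dcs(ee, c)
                     * incoherent_scattering_function(
                         momentum_transfer(ee, c), z) / z,
                     -1, 1, limit=200)[0] * z
                for ee in np.atleast_1d(e)]).reshape(e.shape)
        else:
            sig_c = z * klein_nishina_total(e)
        mu_c = mu_c + w * atoms_per_g * sig_c
        sig_r = np.array([rayleigh_total(ee, z)
                          for ee in np.atleast_1d(e)]).reshape(e.shape)
        mu_r = mu_r + w * atoms_per_g * sig_r
    return mu_pe, mu_c, mu_r


def linear_attenuation(material: str, energy_kev, use_sfunc: bool = False):
    """Linear attenuation components in 1/mm."""
    _fractions, rho = COMPOSITIONS[material]
    mu_pe, mu_c, mu_r = mass_attenuation(material, energy_kev, use_sfunc)
    scale = rho / 10.0  # cm^2/g * g/cm^3 = 1/cm -> 1/mm
    return mu_pe * scale, mu_c * scale, mu_r * scale
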