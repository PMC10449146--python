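"""Materials, attenuation tables, Compton kinematics and the source spectrum.

Attenuation coefficients are stored as per-material tables on a keV grid
(photoelectric, Compton and Rayleigh components in 1/mm) and evaluated by
log-log interpolation between the knots.  Energies outside the table range
raise rather than extrapolate.  The tables bundled under ``qmcffd/data``
cover 16-120 keV, the diagnostic window of the simulated CT system.
"""

from __future__ import annotations

import functools
import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from . import xsection as xs

ENERGY_MIN_KEV = 16.0
ENERGY_MAX_KEV = 120.0

COMPTON = 0  #: delta = 0, incoherent scatter
RAYLEIGH = 1  #: delta = 1, coherent scatter

BUNDLED_MATERIALS = ("air", "aluminium", "cortical_bone", "soft_tissue", "water")


class EnergyOutOfRangeError(ValueError):
    """Requested energy falls outside a material's tabulated grid."""


@dataclass(frozen=True)
class EnergySpectrum:
    """Discrete X-ray source spectrum phi(E): energies in keV, relative weights."""

    energies: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if e.ndim != 1 or e.shape != w.shape:
            raise ValueError("energies and weights must be 1-D and equal length")
        if not np.all(np.diff(e) > 0):
            raise ValueError("energies must be strictly increasing")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be >= 0 with at least one > 0")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w)

    def normalized(self) -> "EnergySpectrum":
        return EnergySpectrum(self.energies, self.weights / self.weights.sum())

    @property
    def mean_energy(self) -> float:
        w = self.weights / self.weights.sum()
        return float(np.sum(self.energies * w))

    @classmethod
    def monoenergetic(cls, energy_kev: float) -> "EnergySpectrum":
        return cls(np.array([energy_kev]), np.array([1.0]))

    @classmethod
    def from_csv(cls, path_or_buf) -> "EnergySpectrum":
        data = np.genfromtxt(path_or_buf, delimiter=",", names=True)
        return cls(np.atleast_1d(data["energy_keV"]),
                   np.atleast_1d(data["weight"]))

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.energies, self.weights])
        np.savetxt(path, arr, delimiter=",", header="energy_keV,weight",
                   comments="", fmt="%.8g")


@dataclass(frozen=True)
class Material:
    """Attenuation-table entry for one material.

    ``mu_pe``, ``mu_compton`` and ``mu_rayleigh`` are linear attenuation
    components in 1/mm on ``energy_grid`` (keV).  ``atomic_number_eff``
    drives the Rayleigh form factor; for mixtures it is a cross-section
    weighted effective Z.
    """

    name: str
    energy_grid: np.ndarray
    mu_pe: np.ndarray
    mu_compton: np.ndarray
    mu_rayleigh: np.ndarray
    atomic_number_eff: float

    def __post_init__(self):
        for attr in ("energy_grid", "mu_pe", "mu_compton", "mu_rayleigh"):
            object.__setattr__(self, attr,
                               np.asarray(getattr(self, attr), dtype=float))
        if np.any(self.mu_pe < 0) or np.any(self.mu_compton < 0) \
                or np.any(self.mu_rayleigh < 0):
            raise ValueError("attenuation coefficients must be >= 0")

    @property
    def mu_tot(self) -> np.ndarray:
        return self.mu_pe + self.mu_compton + self.mu_rayleigh

    @property
    def is_vacuum(self) -> bool:
        return not np.any(self.mu_tot > 0)


def vacuum(name: str = "vacuum") -> Material:
    grid = np.array([ENERGY_MIN_KEV, ENERGY_MAX_KEV])
    zero = np.zeros(2)
    return Material(name, grid, zero, zero, zero, 0.0)


def _loglog_interp(e, grid, values):
    """Log-log interpolation; identity at the knots, zeros tolerated."""
    e = np.asarray(e, dtype=float)
    values = np.asarray(values, dtype=float)
    if not np.any(values > 0):
        return np.zeros_like(e)
    tiny = 1e-300
    logv = np.log(np.maximum(values, tiny))
    out = np.exp(np.interp(np.log(e), np.log(grid), logv))
    out[out < 1e-250] = 0.0
    # exact table values at exact knot energies (bit-for-bit)
    idx = np.searchsorted(grid, e)
    idx = np.clip(idx, 0, len(grid) - 1)
    on_knot = grid[idx] == e
    out[on_knot] = values[idx[on_knot]]
    return out


def mu_components(material: Material, energy_kev):
    """(mu_pe, mu_compton, mu_rayleigh) in 1/mm at ``energy_kev``.

    Log-log interpolation of the stored tables; identity at the knots.
    Raises :class:`EnergyOutOfRangeError` outside the grid.
    """
    e = np.atleast_1d(np.asarray(energy_kev, dtype=float))
    grid = material.energy_grid
    if np.any(e < grid[0]) or np.any(e > grid[-1]):
        raise EnergyOutOfRangeError(
            f"energy outside [{grid[0]}, {grid[-1]}] keV for {material.name}")
    comps = tuple(_loglog_interp(e, grid, v)
                  for v in (material.mu_pe, material.mu_compton,
                            material.mu_rayleigh))
    if np.isscalar(energy_kev) or np.ndim(energy_kev) == 0:
        return tuple(float(c[0]) for c in comps)
    return comps


def mu_total(material: Material, energy_kev):
    pe, c, r = mu_components(material, energy_kev)
    return pe + c + r


def compton_energy(energy_kev, cos_theta):
    """Post-collision photon energy, standard free-electron Compton formula."""
    return xs.compton_energy(energy_kev, cos_theta)


def scatter_type_probs(material: Material, energy_kev):
    """(p_compton, p_rayleigh) = (mu_T0, mu_T1) / mu_tot at this energy."""
    pe, c, r = mu_components(material, energy_kev)
    tot = pe + c + r
    if np.any(np.asarray(tot) == 0):
        raise ZeroDivisionError(
            f"mu_tot = 0 for {material.name}: interaction undefined in vacuum")
    return c / tot, r / tot


def angular_pdf(kind: int, material: Material, energy_kev, cos_theta,
                use_sfunc: bool = False):
    """Polar-angle PDF of the scatter deflection, per steradian.

    ``kind=COMPTON``: Klein-Nishina (optionally times the incoherent
    scattering function), normalized over the unit sphere.
    ``kind=RAYLEIGH``: Thomson times squared screened form factor for the
    material's effective Z, normalized likewise.
    """
    c = np.asarray(cos_theta, dtype=float)
    if kind == COMPTON:
        num = xs.klein_nishina_dcs(energy_kev, c)
        if use_sfunc:
            z = max(material.atomic_number_eff, 1.0)
            num = num * xs.incoherent_scattering_function(
                xs.momentum_transfer(energy_kev, c), z) / z
        norm = _sphere_integral(
            lambda cc: xs.klein_nishina_dcs(energy_kev, cc)
            * (xs.incoherent_scattering_function(
                xs.momentum_transfer(energy_kev, cc),
                max(material.atomic_number_eff, 1.0))
               / max(material.atomic_number_eff, 1.0) if use_sfunc else 1.0))
    elif kind == RAYLEIGH:
        z = max(material.atomic_number_eff, 1.0)
        num = xs.rayleigh_dcs(energy_kev, c, z)
        norm = _sphere_integral(lambda cc: xs.rayleigh_dcs(energy_kev, cc, z))
    else:
        raise ValueError(f"unknown interaction kind {kind!r}")
    return num / norm


@functools.lru_cache(maxsize=1)
def _gauss_nodes(n: int = 4096):
    return np.polynomial.legendre.leggauss(n)


def _sphere_integral(dcs_of_cos, n: int = 4096):
    """Integral of an azimuthally symmetric DCS over 4 pi steradians
    (Gauss-Legendre in cos(theta); spectrally accurate for the peaked
    coherent-scatter kernels)."""
    c, w = _gauss_nodes(n)
    return 2.0 * np.pi * float(np.sum(w * dcs_of_cos(c)))


@dataclass(frozen=True)
class DeflectionKernel:
    """Polar-angle deflection density of one interaction kind at a fixed
    energy, usable directly as a sampling target (see
    :func:`qmcffd.sampling.build_rita`)."""

    kind: int
    material: Material
    energy_kev: float
    use_sfunc: bool = False

    def pdf(self, cos_theta):
        return angular_pdf(self.kind, self.material, self.energy_kev,
                           cos_theta, self.use_sfunc)


@dataclass
class MaterialTable:
    """Ordered material list; id 0 is reserved for air (or vacuum)."""

    materials: list = field(default_factory=list)

    def __post_init__(self):
        names = [m.name for m in self.materials]
        if len(set(names)) != len(names):
            raise ValueError("material names must be unique")

    def __len__(self):
        return len(self.materials)

    def __getitem__(self, i) -> Material:
        return self.materials[i]

    @property
    def names(self):
        return [m.name for m in self.materials]

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown material {name!r}") from None


def _material_csv(name: str) -> str:
    return resources.files("qmcffd.data").joinpath(f"material_{name}.csv") \
        .read_text()


def _effective_z(name: str) -> float:
    """Coherent-scattering effective Z: weighted by atomic fraction * Z^2."""
    if name not in xs.COMPOSITIONS:
        return 0.0
    fractions, _rho = xs.COMPOSITIONS[name]
    num = den = 0.0
    for sym, w in fractions.items():
        z, a = xs.ELEMENTS[sym]
        n = w / a
        num += n * z ** 3
        den += n * z
    return (num / den) ** 0.5 if den > 0 else 0.0


def load_material(name: str) -> Material:
    """Load one bundled material table by name ('vacuum' is synthesized)."""
    if name == "vacuum":
        return vacuum()
    if name not in BUNDLED_MATERIALS:
        raise KeyError(f"unknown material {name!r}; bundled: "
                       f"{BUNDLED_MATERIALS}")
    data = np.genfromtxt(io.StringIO(_material_csv(name)), delimiter=",",
                         names=True)
    return Material(name, data["energy_keV"], data["mu_pe_per_mm"],
                    data["mu_compton_per_mm"], data["mu_rayleigh_per_mm"],
                    _effective_z(name))


def load_material_table(names) -> MaterialTable:
    return MaterialTable([load_material(n) for n in names])


def default_spectrum() -> EnergySpectrum:
    """The bundled 120 kVp-like spectrum (16-120 keV, 1 keV bins)."""
    text = resources.files("qmcffd.data").joinpath("spectrum_120kvp.csv") \
        .read_text()
    return EnergySpectrum.from_csv(io.StringIO(text))
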