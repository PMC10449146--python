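"""Low-discrepancy / pseudorandom drivers and the samplers they feed.

One photon history of maximum scatter order ``n`` consumes exactly one
point of a 4n-dimensional stream: variate 1 picks the source energy
(Walker alias sampling of the spectrum), variates 2-3 the source
direction, variate 4 the first forced interaction depth; every further
order consumes one variate for the scatter type, two for the scatter
direction (polar angle via RITA, uniform azimuth) and one for the forced
depth.

Sobol' streams are Owen-scrambled by default so that independent
scramble ids give independent unbiased replicates (needed for replicate
standard deviations).  With scrambling off the stream starts at index 1,
skipping the all-zeros point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from .phantom import VoxelPhantom
from .physics import EnergySpectrum

SOBOL = "sobol"
PSEUDORANDOM = "pseudorandom"

#: variates consumed per scatter order (type/dir/dir/depth)
VARIATES_PER_ORDER = 4


@dataclass
class SampleStream:
    """Reproducible point source over [0, 1)^dimension.

    ``kind`` is ``"sobol"`` or ``"pseudorandom"``.  ``scramble`` selects
    the randomization: an integer id (distinct ids are independent) or
    ``None`` for the plain, unscrambled Sobol' sequence.  The i-th point
    of a given (kind, dimension, seed, scramble) is reproducible
    bit-for-bit; advancing the counter is the only state change.
    """

    kind: str
    dimension: int
    seed: int = 0
    scramble: int | None = 0
    counter: int = field(default=0, init=False)

    def __post_init__(self):
        if self.kind not in (SOBOL, PSEUDORANDOM):
            raise ValueError(f"unknown stream kind {self.kind!r}")
        if self.kind == SOBOL and self.dimension > 21201:
            raise ValueError("Sobol' dimension exceeds generator maximum")
        self._init_engine()

    def _init_engine(self):
        if self.kind == SOBOL:
            if self.scramble is None:
                self._engine = qmc.Sobol(self.dimension, scramble=False)
                self._engine.fast_forward(1)  # skip the all-zeros point
            else:
                ss = np.random.SeedSequence([self.seed, self.scramble])
                self._engine = qmc.Sobol(self.dimension, scramble=True,
                                         seed=np.random.default_rng(ss))
        else:
            sc = 0 if self.scramble is None else self.scramble
            ss = np.random.SeedSequence([self.seed, sc])
            self._engine = np.random.default_rng(ss)

    def next_point(self) -> np.ndarray:
        return self.take(1)[0]

    def take(self, n: int) -> np.ndarray:
        """The next ``n`` points, shape (n, dimension)."""
        if self.kind == SOBOL:
            pts = self._engine.random(n)
        else:
            pts = self._engine.random((n, self.dimension))
        self.counter += n
        return pts

    def replicate(self, scramble: int) -> "SampleStream":
        """A fresh stream with a different scramble id (independent)."""
        return SampleStream(self.kind, self.dimension, self.seed, scramble)


@dataclass(frozen=True)
class AliasTable:
    """Walker alias table: O(1) discrete sampling from one uniform variate."""

    probs: np.ndarray  #: normalized source distribution
    cut: np.ndarray  #: per-bin acceptance threshold
    alias: np.ndarray  #: donor bin when the threshold test fails


def build_alias(weights) -> AliasTable:
    """Vose's stable construction of a Walker alias table."""
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise ValueError("weights must be a non-empty 1-D array")
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must not be all zero")
    k = w.size
    probs = w / total
    scaled = probs * k
    cut = np.ones(k)
    alias = np.arange(k, dtype=np.int64)
    small = [i for i in range(k) if scaled[i] < 1.0]
    large = [i for i in range(k) if scaled[i] >= 1.0]
    scaled = scaled.copy()
    while small and large:
        s = small.pop()
        l = large.pop()
        cut[s] = scaled[s]
        alias[s] = l
        scaled[l] = scaled[l] - (1.0 - scaled[s])
        (small if scaled[l] < 1.0 else large).append(l)
    for i in small + large:
        cut[i] = 1.0
        alias[i] = i
    return AliasTable(probs, cut, alias)


def alias_sample(table: AliasTable, u: float) -> int:
    """Single-variate draw: the integer part picks the bin, the fractional
    part resolves the cut-vs-alias test."""
    k = table.cut.size
    x = u * k
    j = min(int(x), k - 1)
    frac = x - j
    return j if frac < table.cut[j] else int(table.alias[j])


def sample_energy(spectrum: EnergySpectrum, u: float,
                  table: AliasTable | None = None) -> float:
    """Alias-sample a spectrum bin and return its energy in keV."""
    if table is None:
        table = build_alias(spectrum.weights)
    return float(spectrum.energies[alias_sample(table, u)])


def source_cone_rectangle(source, phantom: VoxelPhantom):
    """The phantom-facing rectangle every source ray is aimed through.

    The rectangle is the face of the phantom bounding box nearest the
    source along the beam axis (+y), spanned in x and z.  Returns
    (y_plane, (x_lo, x_hi), (z_lo, z_hi)).
    """
    lo, hi = phantom.bbox_min, phantom.bbox_max
    src = np.asarray(source, dtype=float)
    y_plane = lo[1] if src[1] < lo[1] else hi[1]
    return float(y_plane), (float(lo[0]), float(hi[0])), \
        (float(lo[2]), float(hi[2]))


def sample_direction_source(u2: float, u3: float, source,
                            phantom: VoxelPhantom) -> np.ndarray:
    """Unit emission direction through the phantom-facing rectangle.

    (u2, u3) parametrize the entry rectangle bilinearly, so (0.5, 0.5)
    is the central axis and the unit-square corners map to the rectangle
    corners; every emitted ray intersects the phantom bounding box.
    """
    src = np.asarray(source, dtype=float)
    y_plane, (x0, x1), (z0, z1) = source_cone_rectangle(src, phantom)
    target = np.array([x0 + (x1 - x0) * u2, y_plane, z0 + (z1 - z0) * u3])
    d = target - src
    return d / np.linalg.norm(d)


def sample_scatter_type(p_compton: float, p_rayleigh: float, u: float):
    """Importance-sampled interaction kind and its survival weight factor.

    Picks Compton with probability p_T0/(p_T0 + p_T1), else Rayleigh; the
    returned weight factor (p_T0 + p_T1) is the probability that the
    forced interaction is a scatter rather than photoelectric absorption.
    """
    total = p_compton + p_rayleigh
    if total <= 0:
        raise ValueError("no scatter channel open: p_T0 + p_T1 = 0")
    kind = 0 if u * total < p_compton else 1
    return kind, total


@dataclass(frozen=True)
class RitaTable:
    """Rational inverse transform with aliasing-style tabulated sampler.

    Knots ``x`` with exact CDF values ``xi`` and per-interval rational
    interpolation parameters ``a``, ``b`` (PENELOPE parametrization).
    ``max_error`` is the measured sup-norm CDF deviation of the sampler.
    """

    x: np.ndarray
    xi: np.ndarray
    a: np.ndarray
    b: np.ndarray
    max_error: float


class NonNormalizableError(ValueError):
    pass


def _rita_params(x, xi, pdf_at):
    dx = np.diff(x)
    dxi = np.diff(xi)
    p0 = np.maximum(pdf_at(x[:-1]), 1e-300)
    p1 = np.maximum(pdf_at(x[1:]), 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dx > 0, dxi / np.maximum(dx, 1e-300), 0.0)
        b = 1.0 - ratio * ratio / (p0 * p1)
        a = np.where(p0 > 0, ratio / p0, 1.0) - b - 1.0
    return a, b


def _rita_invert(x, xi, a, b, u):
    """Evaluate the rational inverse at uniform variates u (vectorized)."""
    u = np.asarray(u, dtype=float)
    idx = np.clip(np.searchsorted(xi, u, side="right") - 1, 0, len(x) - 2)
    dxi = xi[idx + 1] - xi[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(dxi > 0, (u - xi[idx]) / np.maximum(dxi, 1e-300), 0.0)
    num = (1.0 + a[idx] + b[idx]) * tau
    den = 1.0 + a[idx] * tau + b[idx] * tau * tau
    step = np.where(den != 0, num / den, tau)
    out = x[idx] + np.clip(step, 0.0, 1.0) * (x[idx + 1] - x[idx])
    return out


def build_rita(pdf, support=(-1.0, 1.0), tolerance: float = 1e-4,
               max_knots: int = 128, dense: int = 4096) -> RitaTable:
    """Adaptive RITA construction for a 1-D density on ``support``.

    ``pdf`` is any vectorized density (not necessarily normalized; it is
    normalized internally), or an object with a ``pdf`` method such as
    :class:`qmcffd.physics.DeflectionKernel`.  Knots are inserted at the
    midpoint of the interval with the largest sampler CDF error until
    the sup-norm error drops below ``tolerance`` or ``max_knots`` is
    reached.
    """
    if hasattr(pdf, "pdf"):
        pdf = pdf.pdf
    lo, hi = support
    grid = np.linspace(lo, hi, dense)
    vals = np.asarray(pdf(grid), dtype=float)
    if np.any(~np.isfinite(vals)) or np.any(vals < 0):
        raise NonNormalizableError("density must be finite and >= 0")
    cdf_dense = np.concatenate([[0.0], np.cumsum(
        0.5 * (vals[1:] + vals[:-1]) * np.diff(grid))])
    norm = cdf_dense[-1]
    if not norm > 0:
        raise NonNormalizableError("density integrates to zero")
    cdf_dense /= norm

    def exact_cdf(x):
        return np.interp(x, grid, cdf_dense)

    def norm_pdf(x):
        return np.asarray(pdf(x), dtype=float) / norm

    x = np.linspace(lo, hi, 9)
    u_test = np.linspace(0.0, 1.0, 1024, endpoint=False) + 0.5 / 1024
    while True:
        xi = exact_cdf(x)
        a, b = _rita_params(x, xi, norm_pdf)
        samples = _rita_invert(x, xi, a, b, u_test)
        err = np.abs(exact_cdf(samples) - u_test)
        max_err = float(err.max())
        if max_err < tolerance or len(x) >= max_knots:
            return RitaTable(x, xi, a, b, max_err)
        # split the interval containing the worst sample
        worst = samples[np.argmax(err)]
        k = np.clip(np.searchsorted(x, worst) - 1, 0, len(x) - 2)
        mid = 0.5 * (x[k] + x[k + 1])
        x = np.sort(np.append(x, mid))


def sample_cos_theta(table: RitaTable, u):
    """Inverse-CDF draw(s) from a RITA table; monotone in u."""
    out = _rita_invert(table.x, table.xi, table.a, table.b, u)
    if np.ndim(u) == 0:
        return float(out)
    return out
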