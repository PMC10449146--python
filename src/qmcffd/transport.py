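"""Forced-fixed-detection transport: scenes, the estimator, and oracles.

The estimator follows the weighted-history scheme: each history is
driven by one 4n-dimensional point; at every forced interaction the
probability of scattering toward each detector pixel and escaping the
phantom unattenuated is accumulated (``ffd_splat``), with the photon
weight tracking the interaction probabilities
``W_1 = 1 - p_0`` and ``W_i = W_{i-1} (p_T0 + p_T1) (1 - p_{i-1})``.
Averaging ``f_{n,j}`` over N stream points gives the per-order scatter
image; with a Sobol' stream this is the QMC estimator, with a
pseudorandom stream the MC estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels as k
from . import xsection as xs
from .phantom import (PHANTOM_DETECTOR_MM, SOURCE_PHANTOM_MM, VoxelPhantom)
from .physics import (COMPTON, RAYLEIGH, EnergySpectrum, MaterialTable,
                      angular_pdf, compton_energy, default_spectrum,
                      mu_components, scatter_type_probs)
from .raytrace import intersect_phantom, material_path_lengths
from .sampling import (SampleStream, build_alias, build_rita,
                       source_cone_rectangle)

DETECTOR_DISTANCE_MM = SOURCE_PHANTOM_MM + PHANTOM_DETECTOR_MM
FULL_DETECTOR_PIXELS = 512
FULL_DETECTOR_PITCH_MM = 0.8
ENERGY_FLOOR_KEV = 16.0


@dataclass(frozen=True)
class Detector:
    """Flat pixel detector in the package's fixed frame.

    The plane is at ``center`` with normal -y (facing the source);
    in-plane axes are +x (index ``ju``) and +z (index ``jv``).  Pixel
    (ju, jv) has its center at
    ``center + (ju - (nu-1)/2) pitch x_hat + (jv - (nv-1)/2) pitch z_hat``.
    """

    nu: int = 64
    nv: int = 64
    pitch: float = FULL_DETECTOR_PITCH_MM * FULL_DETECTOR_PIXELS / 64
    center: tuple = (0.0, DETECTOR_DISTANCE_MM, 0.0)

    @classmethod
    def full(cls) -> "Detector":
        """The 512 x 512, 0.8 mm detector of the simulated CT system."""
        return cls(FULL_DETECTOR_PIXELS, FULL_DETECTOR_PIXELS,
                   FULL_DETECTOR_PITCH_MM)

    @classmethod
    def coarse(cls, n: int = 64) -> "Detector":
        """n x n pixels covering the same 409.6 mm square aperture."""
        return cls(n, n, FULL_DETECTOR_PITCH_MM * FULL_DETECTOR_PIXELS / n)

    @classmethod
    def central_pixel(cls) -> "Detector":
        """A single full-resolution (0.8 mm) pixel on the beam axis."""
        return cls(1, 1, FULL_DETECTOR_PITCH_MM)

    @property
    def area_mm2(self) -> float:
        return self.pitch ** 2

    def pixel_center(self, ju: int, jv: int) -> np.ndarray:
        c = np.asarray(self.center, dtype=float)
        return c + np.array([(ju - 0.5 * (self.nu - 1)) * self.pitch, 0.0,
                             (jv - 0.5 * (self.nv - 1)) * self.pitch])


@dataclass
class PhotonState:
    """Markov-chain walker state at an interaction point."""

    position: np.ndarray
    direction: np.ndarray
    energy: float
    weight: float
    order: int
    last_kind: Optional[int] = None


@dataclass
class Scene:
    """Everything one simulation needs: phantom, source, detector, order."""

    phantom: VoxelPhantom
    spectrum: EnergySpectrum = field(default_factory=default_spectrum)
    detector: Detector = field(default_factory=Detector)
    source: tuple = (0.0, 0.0, 0.0)
    n_orders: int = 10
    energy_floor_kev: float = ENERGY_FLOOR_KEV
    kill_below_floor: bool = False

    @property
    def dimension(self) -> int:
        return 4 * self.n_orders

    @property
    def materials(self) -> MaterialTable:
        return self.phantom.materials

    def stream(self, kind: str = "sobol", seed: int = 0,
               scramble: int | None = 0) -> SampleStream:
        return SampleStream(kind, self.dimension, seed, scramble)


def al_scene(**kw) -> Scene:
    from .phantom import build_al_phantom
    return Scene(build_al_phantom(), **kw)


def bt_scene(**kw) -> Scene:
    from .phantom import build_bt_cylinder
    return Scene(build_bt_cylinder(), **kw)


# --------------------------------------------------------------------------
# dense tables for the compiled kernels

_DENSE_E0 = 16.0
_DENSE_DE = 0.25
_DENSE_N = 417  # 16..120 keV inclusive
_RITA_EGRID = 64
_RITA_KMAX = 128


class TransportTables:
    """Dense, kernel-ready resampling of a scene's physics.

    Attenuation components are resampled from the materials' log-log
    tables onto a uniform 0.25 keV grid; Rayleigh angular normalizations
    are precomputed per material and energy; RITA sampling tables are
    built on a 64-point log-energy grid (nearest-table lookup at sample
    time).
    """

    def __init__(self, scene: Scene):
        self.scene = scene
        mats = scene.materials
        n_mat = len(mats)
        e = _DENSE_E0 + _DENSE_DE * np.arange(_DENSE_N)
        self.e0, self.de = _DENSE_E0, _DENSE_DE
        self.mu_pe = np.zeros((n_mat, _DENSE_N))
        self.mu_c = np.zeros((n_mat, _DENSE_N))
        self.mu_r = np.zeros((n_mat, _DENSE_N))
        for m, mat in enumerate(mats):
            pe, c, r = mu_components(mat, e)
            self.mu_pe[m], self.mu_c[m], self.mu_r[m] = pe, c, r
        self.mu_tot = self.mu_pe + self.mu_c + self.mu_r
        self.zeff = np.array([max(m.atomic_number_eff, 1e-6) for m in mats])
        self.gscreen = xs._screening_constant()
        # Rayleigh angular normalization integral per (material, energy);
        # Gauss-Legendre nodes for the forward-peaked kernel
        cgrid, cw = np.polynomial.legendre.leggauss(2048)
        self.ray_norm = np.zeros((n_mat, _DENSE_N))
        for m, mat in enumerate(mats):
            if mat.atomic_number_eff <= 0:
                continue
            dcs = xs.rayleigh_dcs(e[:, None], cgrid[None, :],
                                  self.zeff[m])
            self.ray_norm[m] = 2.0 * np.pi * (dcs @ cw)
        # spectrum alias table
        spec = scene.spectrum.normalized()
        alias = build_alias(spec.weights)
        self.spec_e = spec.energies.copy()
        self.spec_w = spec.weights.copy()
        self.spec_cut = alias.cut
        self.spec_alias = alias.alias.astype(np.int64)
        # RITA packs on a log energy grid
        eg = np.geomspace(_DENSE_E0, 120.0, _RITA_EGRID)
        self.eg_ln0 = math.log(eg[0])
        self.eg_dln = math.log(eg[1]) - math.log(eg[0])
        self.rc = self._pack_rita(
            [build_rita(lambda c, ee=ee: xs.klein_nishina_dcs(ee, c))
             for ee in eg])
        rr_tables = []
        for m, mat in enumerate(mats):
            z = self.zeff[m]
            if mat.atomic_number_eff <= 0:
                rr_tables.append(
                    [build_rita(lambda c: np.ones_like(np.asarray(c, float)))
                     for _ in eg])
            else:
                rr_tables.append(
                    [build_rita(lambda c, ee=ee, zz=z: xs.rayleigh_dcs(
                        ee, c, zz)) for ee in eg])
        self.rr = self._pack_rita_2d(rr_tables)
        # geometry
        self.bbox_min = scene.phantom.bbox_min
        self.bbox_max = scene.phantom.bbox_max
        self.voxel = scene.phantom.voxel_size
        self.rect = source_cone_rectangle(scene.source, scene.phantom)

    @staticmethod
    def _pack_rita(tables):
        n = len(tables)
        x = np.zeros((n, _RITA_KMAX))
        xi = np.zeros((n, _RITA_KMAX))
        a = np.zeros((n, _RITA_KMAX))
        b = np.zeros((n, _RITA_KMAX))
        nk = np.zeros(n, dtype=np.int64)
        for i, t in enumerate(tables):
            m = len(t.x)
            x[i, :m] = t.x
            xi[i, :m] = t.xi
            xi[i, m - 1] = 1.0
            a[i, :m - 1] = t.a
            b[i, :m - 1] = t.b
            nk[i] = m
        return x, xi, a, b, nk

    @classmethod
    def _pack_rita_2d(cls, tables2d):
        packs = [cls._pack_rita(row) for row in tables2d]
        return tuple(np.stack([p[i] for p in packs]) for i in range(5))

    def kernel_args(self, detector: Detector | None = None):
        """The long positional tail shared by the transport kernels."""
        det = detector or self.scene.detector
        lo, hi = self.bbox_min, self.bbox_max
        h = self.voxel
        y_plane, (x0, x1), (z0, z1) = self.rect
        src = np.asarray(self.scene.source, dtype=float)
        c = np.asarray(det.center, dtype=float)
        return (self.scene.phantom.material_ids,
                lo[0], lo[1], lo[2], h[0], h[1], h[2], hi[0], hi[1], hi[2],
                self.mu_tot, self.mu_pe, self.mu_c, self.mu_r,
                self.e0, self.de,
                self.ray_norm, self.zeff, self.gscreen,
                self.spec_e, self.spec_cut, self.spec_alias,
                src[0], src[1], src[2], y_plane, x0, x1, z0, z1,
                c[0], c[1], c[2], det.pitch, det.nu, det.nv,
                *self.rc, *self.rr,
                self.eg_ln0, self.eg_dln,
                self.scene.n_orders, self.scene.energy_floor_kev,
                self.scene.kill_below_floor)


# --------------------------------------------------------------------------
# results container

@dataclass
class ScatterImage:
    """Per-order scatter estimate on the detector grid.

    ``per_order[i-1]`` estimates E[P(l_{i,j})]: the probability, per
    source photon, of reaching pixel j after exactly i interactions.
    ``sumsq`` holds the raw per-history sums of squares for standard
    errors.
    """

    per_order: np.ndarray  # (n_orders, nu, nv) means
    sumsq: np.ndarray  # raw sum of squared per-history contributions
    n_histories: int
    meta: dict = field(default_factory=dict)

    @property
    def n_orders(self) -> int:
        return self.per_order.shape[0]

    @property
    def total(self) -> np.ndarray:
        return self.per_order.sum(axis=0)

    @property
    def total_probability(self) -> float:
        """Total detected scatter probability, all orders and pixels."""
        return float(self.per_order.sum())

    def sem(self) -> np.ndarray:
        """Standard error of the mean per (order, pixel); for a
        pseudorandom stream only (QMC errors are estimated across
        scrambled replicates instead)."""
        n = self.n_histories
        var = self.sumsq / n - self.per_order ** 2
        return np.sqrt(np.maximum(var, 0.0) / n)

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("per_order", data=self.per_order)
            f.create_dataset("sumsq", data=self.sumsq)
            if "primary" in self.meta:
                f.create_dataset("primary", data=self.meta["primary"])
            f.attrs["n_histories"] = self.n_histories
            for key, val in self.meta.items():
                if key != "primary":
                    f.attrs[key] = val

    @classmethod
    def load(cls, path) -> "ScatterImage":
        import h5py

        with h5py.File(path, "r") as f:
            per_order = f["per_order"][...]
            sumsq = f["sumsq"][...]
            meta = dict(f.attrs)
            n = int(meta.pop("n_histories"))
            if "primary" in f:
                meta["primary"] = f["primary"][...]
        return cls(per_order, sumsq, n, meta)


# --------------------------------------------------------------------------
# estimator and oracles

def estimate_scatter(scene: Scene, n_histories: int, stream: SampleStream,
                     tables: TransportTables | None = None,
                     batch: int = 16384) -> ScatterImage:
    """QMC/MC mean of per-history detector contributions (per order).

    Deterministic for a fixed stream configuration: identical scene,
    kind, seed and scramble id give a bit-identical image.
    """
    if n_histories < 1:
        raise ValueError("n_histories must be >= 1")
    if stream.dimension != scene.dimension:
        raise ValueError(
            f"stream dimension {stream.dimension} != 4n = {scene.dimension}")
    tables = tables or TransportTables(scene)
    det = scene.detector
    out_sum = np.zeros((scene.n_orders, det.nu, det.nv))
    out_sq = np.zeros_like(out_sum)
    args = tables.kernel_args()
    remaining = n_histories
    while remaining > 0:
        take = min(batch, remaining)
        pts = stream.take(take)
        k._run_batch(pts, *args, out_sum, out_sq)
        remaining -= take
    meta = {"sampler": stream.kind, "seed": stream.seed,
            "scramble": -1 if stream.scramble is None else stream.scramble,
            "n_orders": scene.n_orders}
    return ScatterImage(out_sum / n_histories, out_sq, n_histories, meta)


def simulate_history(point: np.ndarray, scene: Scene,
                     tables: TransportTables | None = None):
    """Run Algorithm-style steps 1-6 for a single 4n-dimensional point.

    Returns ``(per_order, trace)`` where ``per_order`` is the
    (n_orders, nu, nv) contribution array of this history and ``trace``
    records interaction positions, weights W_i and pre-collision
    energies (entries beyond the realized chain length are zero).
    """
    point = np.asarray(point, dtype=float)
    if point.shape != (scene.dimension,):
        raise ValueError(f"point must have shape ({scene.dimension},)")
    tables = tables or TransportTables(scene)
    det = scene.detector
    out_sum = np.zeros((scene.n_orders, det.nu, det.nv))
    out_sq = np.zeros_like(out_sum)
    n_mat = len(scene.materials)
    mu_vec = np.zeros(n_mat)
    lengths = np.zeros(n_mat)
    trace_pos = np.zeros((scene.n_orders, 3))
    trace_w = np.zeros(scene.n_orders)
    trace_e = np.zeros(scene.n_orders)
    done = k._history(point, *tables.kernel_args(), out_sum, out_sq,
                      mu_vec, lengths, trace_pos, trace_w, trace_e)
    trace = {"orders_done": int(done), "positions": trace_pos,
             "weights": trace_w, "energies": trace_e}
    return out_sum, trace


def ffd_splat(state: PhotonState, detector: Detector,
              phantom: VoxelPhantom, materials: MaterialTable,
              isotropic: bool = False) -> np.ndarray:
    """Reference (pure NumPy) forced-fixed-detection splat.

    Computes P_i(A_i -> D_j) for every pixel: the probability that the
    photon at ``state.position`` scatters toward pixel j and escapes the
    phantom unattenuated, approximating the pixel solid angle by
    ``cos(alpha) h^2 / r^2``.  ``isotropic=True`` replaces the physical
    angular kernels by an isotropic stub (for geometry tests).  The
    returned array is *not* multiplied by ``state.weight``.
    """
    pos = np.asarray(state.position, dtype=float)
    w_in = np.asarray(state.direction, dtype=float)
    e_pre = state.energy
    out = np.zeros((detector.nu, detector.nv))
    normal_cos_axis = 1  # +y component is cos(alpha)
    if isotropic:
        p_t = (1.0, 0.0)
    else:
        mat = materials[phantom.material_at(pos)]
        p_t = scatter_type_probs(mat, e_pre)
    for ju in range(detector.nu):
        for jv in range(detector.nv):
            q = detector.pixel_center(ju, jv)
            v = q - pos
            r = np.linalg.norm(v)
            omega = v / r
            cosa = omega[normal_cos_axis]
            if cosa <= 0:
                continue
            omega_solid = cosa * detector.area_mm2 / r ** 2
            if isotropic:
                out[ju, jv] = omega_solid / (4.0 * math.pi)
                continue
            cost = float(w_in @ omega)
            hit = intersect_phantom(phantom, pos, omega)
            term = 0.0
            if p_t[COMPTON] > 0:
                e_c = max(compton_energy(e_pre, cost), ENERGY_FLOOR_KEV)
                pdf_c = angular_pdf(COMPTON, mat, e_pre, cost)
                tau = _tau_reference(phantom, materials, pos, omega, hit, e_c)
                term += p_t[COMPTON] * float(pdf_c) * math.exp(-tau)
            if p_t[RAYLEIGH] > 0:
                pdf_r = angular_pdf(RAYLEIGH, mat, e_pre, cost)
                tau = _tau_reference(phantom, materials, pos, omega, hit,
                                     e_pre)
                term += p_t[RAYLEIGH] * float(pdf_r) * math.exp(-tau)
            out[ju, jv] = term * omega_solid
    return out


def _tau_reference(phantom, materials, pos, omega, hit, energy):
    if hit is None:
        return 0.0
    t0, t1 = hit
    lengths = material_path_lengths(phantom, pos, omega, t0, t1)
    from .physics import mu_total

    return float(sum(L * mu_total(m, energy)
                     for L, m in zip(lengths, materials)))


def primary_projection(scene: Scene,
                       tables: TransportTables | None = None) -> np.ndarray:
    """Deterministic Lambert-Beer primary image.

    For each pixel center: sum over spectrum bins of
    ``phi(E) exp(-tau(source -> pixel, E))``; no geometric falloff term,
    so an empty phantom gives a flat image of 1.
    """
    tables = tables or TransportTables(scene)
    det = scene.detector
    lo, hi = tables.bbox_min, tables.bbox_max
    h = tables.voxel
    src = np.asarray(scene.source, dtype=float)
    c = np.asarray(det.center, dtype=float)
    out = np.zeros((det.nu, det.nv))
    k._primary(scene.phantom.material_ids,
               lo[0], lo[1], lo[2], h[0], h[1], h[2], hi[0], hi[1], hi[2],
               tables.mu_tot, tables.e0, tables.de,
               tables.spec_e, tables.spec_w,
               src[0], src[1], src[2],
               c[0], c[1], c[2], det.pitch, det.nu, det.nv, out)
    return out


def analog_scatter(scene: Scene, n_histories: int, seed: int,
                   tables: TransportTables | None = None):
    """Unbiased analog Monte Carlo oracle.

    Transports photons with free paths from the untruncated exponential
    law, explicit photoelectric absorption and rejection-sampled scatter
    angles; scores binary detector crossings per order.  Returns
    ``(probabilities, hits)`` where ``probabilities[order]`` (order 0 =
    primary) is hits/n_histories on the scene's detector grid.
    """
    tables = tables or TransportTables(scene)
    det = scene.detector
    lo, hi = tables.bbox_min, tables.bbox_max
    h = tables.voxel
    y_plane, (x0, x1), (z0, z1) = tables.rect
    src = np.asarray(scene.source, dtype=float)
    c = np.asarray(det.center, dtype=float)
    hits = np.zeros((scene.n_orders + 1, det.nu, det.nv), dtype=np.int64)
    k._analog_batch(n_histories, seed, scene.phantom.material_ids,
                    lo[0], lo[1], lo[2], h[0], h[1], h[2],
                    hi[0], hi[1], hi[2],
                    tables.mu_tot, tables.mu_pe, tables.mu_c, tables.mu_r,
                    tables.e0, tables.de,
                    tables.zeff, tables.gscreen,
                    tables.spec_e, tables.spec_cut, tables.spec_alias,
                    src[0], src[1], src[2], y_plane, x0, x1, z0, z1,
                    c[0], c[1], c[2], det.pitch, det.nu, det.nv,
                    scene.n_orders, scene.energy_floor_kev, hits)
    return hits / n_histories, hits


def upsample_detector(coarse: np.ndarray, fine_shape=(512, 512)) -> np.ndarray:
    """Bilinear upsampling of a coarse detector image onto a fine grid.

    Interpolates pixel-center values (with linear extrapolation in the
    half-pixel border), so a constant image stays constant and an affine
    ramp is reproduced exactly at the fine pixel centers.  Fine
    dimensions must be integer multiples of the coarse ones.  Values are
    interpreted as intensities per pixel area: to conserve integrated
    probability, divide per-pixel probabilities by the area ratio
    afterwards (see :func:`upsample_probability`).
    """
    coarse = np.asarray(coarse, dtype=float)
    nu_c, nv_c = coarse.shape
    nu_f, nv_f = fine_shape
    if nu_f % nu_c or nv_f % nv_c:
        raise ValueError("fine shape must be divisible by coarse shape")

    def axis_weights(nc, nf):
        ratio = nc / nf
        pos = (np.arange(nf) + 0.5) * ratio - 0.5
        cell = np.clip(np.floor(pos).astype(int), 0, nc - 2)
        frac = pos - cell  # may leave [0,1]: linear extrapolation at edges
        w = np.zeros((nf, nc))
        w[np.arange(nf), cell] = 1.0 - frac
        w[np.arange(nf), cell + 1] = frac
        return w

    wu = axis_weights(nu_c, nu_f)
    wv = axis_weights(nv_c, nv_f)
    return wu @ coarse @ wv.T


def upsample_probability(coarse: np.ndarray, fine_shape=(512, 512)):
    """Upsample a per-pixel probability image, conserving the total."""
    coarse = np.asarray(coarse, dtype=float)
    scale = (coarse.shape[0] * coarse.shape[1]) / (fine_shape[0]
                                                   * fine_shape[1])
    return upsample_detector(coarse, fine_shape) * scale
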