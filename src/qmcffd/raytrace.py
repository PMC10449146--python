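"""Exact voxel traversal and radiological path integrals.

The traversal is incremental (Amanatides-Woo) with the phantom module's
half-open voxel convention: a point exactly on a voxel face belongs to
the voxel in the positive stepping direction.  Segments partition the
clipped ray exactly, so chord lengths always sum to ``t_exit - t_entry``
(watertight).  Direction components smaller than 1e-12 in magnitude are
treated as exactly zero.

Attenuation outside the phantom bounding box is zero: all path integrals
run over the in-phantom segment only.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .phantom import VoxelPhantom
from .physics import MaterialTable, mu_total

_EPS_DIR = 1e-12


class CannotForceError(ValueError):
    """Forced interaction requested on a segment with zero optical depth."""


@njit(cache=True, fastmath=True)
def _aabb(ox, oy, oz, dx, dy, dz, bx0, by0, bz0, bx1, by1, bz1):
    """Slab-method ray/AABB intersection clamped to t >= 0.

    Returns (t0, t1); a miss is signaled by t0 > t1.
    """
    t0 = 0.0
    t1 = math.inf
    for axis in range(3):
        if axis == 0:
            o, d, lo, hi = ox, dx, bx0, bx1
        elif axis == 1:
            o, d, lo, hi = oy, dy, by0, by1
        else:
            o, d, lo, hi = oz, dz, bz0, bz1
        if -_EPS_DIR < d < _EPS_DIR:
            if o < lo or o >= hi:
                return 1.0, -1.0
        else:
            ta = (lo - o) / d
            tb = (hi - o) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    if t0 > t1:
        return 1.0, -1.0
    return t0, t1


@njit(cache=True, fastmath=True)
def _march_lengths(ids, bx0, by0, bz0, hx, hy, hz,
                   ox, oy, oz, dx, dy, dz, t0, t1, lengths):
    """Accumulate per-material chord lengths over the ray segment [t0, t1]."""
    nx, ny, nz = ids.shape
    px = ox + t0 * dx
    py = oy + t0 * dy
    pz = oz + t0 * dz
    ix = int(math.floor((px - bx0) / hx))
    iy = int(math.floor((py - by0) / hy))
    iz = int(math.floor((pz - bz0) / hz))
    if ix < 0:
        ix = 0
    elif ix > nx - 1:
        ix = nx - 1
    if iy < 0:
        iy = 0
    elif iy > ny - 1:
        iy = ny - 1
    if iz < 0:
        iz = 0
    elif iz > nz - 1:
        iz = nz - 1
    # per-axis parametric step setup
    if dx > _EPS_DIR:
        sx = 1
        tmx = t0 + (bx0 + (ix + 1) * hx - px) / dx
        tdx = hx / dx
    elif dx < -_EPS_DIR:
        sx = -1
        tmx = t0 + (bx0 + ix * hx - px) / dx
        tdx = -hx / dx
    else:
        sx = 0
        tmx = math.inf
        tdx = math.inf
    if dy > _EPS_DIR:
        sy = 1
        tmy = t0 + (by0 + (iy + 1) * hy - py) / dy
        tdy = hy / dy
    elif dy < -_EPS_DIR:
        sy = -1
        tmy = t0 + (by0 + iy * hy - py) / dy
        tdy = -hy / dy
    else:
        sy = 0
        tmy = math.inf
        tdy = math.inf
    if dz > _EPS_DIR:
        sz = 1
        tmz = t0 + (bz0 + (iz + 1) * hz - pz) / dz
        tdz = hz / dz
    elif dz < -_EPS_DIR:
        sz = -1
        tmz = t0 + (bz0 + iz * hz - pz) / dz
        tdz = -hz / dz
    else:
        sz = 0
        tmz = math.inf
        tdz = math.inf
    t = t0
    while t < t1:
        tn = tmx
        axis = 0
        if tmy < tn:
            tn = tmy
            axis = 1
        if tmz < tn:
            tn = tmz
            axis = 2
        if tn > t1:
            tn = t1
        seg = tn - t
        if seg > 0.0:
            lengths[ids[ix, iy, iz]] += seg
        t = tn
        if t >= t1:
            break
        if axis == 0:
            ix += sx
            tmx += tdx
            if ix < 0 or ix >= nx:
                break
        elif axis == 1:
            iy += sy
            tmy += tdy
            if iy < 0 or iy >= ny:
                break
        else:
            iz += sz
            tmz += tdz
            if iz < 0 or iz >= nz:
                break


@njit(cache=True, fastmath=True)
def _march_forced(ids, bx0, by0, bz0, hx, hy, hz, mu_vec,
                  ox, oy, oz, dx, dy, dz, t1, target_tau):
    """First t in [0, t1] with cumulative optical depth == target_tau.

    Marches voxel by voxel from t = 0 (origin assumed inside the box) and
    inverts analytically inside the voxel where the target depth falls.
    Returns -1.0 if the total depth along the segment is below the target.
    """
    nx, ny, nz = ids.shape
    ix = int(math.floor((ox - bx0) / hx))
    iy = int(math.floor((oy - by0) / hy))
    iz = int(math.floor((oz - bz0) / hz))
    if ix < 0:
        ix = 0
    elif ix > nx - 1:
        ix = nx - 1
    if iy < 0:
        iy = 0
    elif iy > ny - 1:
        iy = ny - 1
    if iz < 0:
        iz = 0
    elif iz > nz - 1:
        iz = nz - 1
    if dx > _EPS_DIR:
        sx = 1
        tmx = (bx0 + (ix + 1) * hx - ox) / dx
        tdx = hx / dx
    elif dx < -_EPS_DIR:
        sx = -1
        tmx = (bx0 + ix * hx - ox) / dx
        tdx = -hx / dx
    else:
        sx = 0
        tmx = math.inf
        tdx = math.inf
    if dy > _EPS_DIR:
        sy = 1
        tmy = (by0 + (iy + 1) * hy - oy) / dy
        tdy = hy / dy
    elif dy < -_EPS_DIR:
        sy = -1
        tmy = (by0 + iy * hy - oy) / dy
        tdy = -hy / dy
    else:
        sy = 0
        tmy = math.inf
        tdy = math.inf
    if dz > _EPS_DIR:
        sz = 1
        tmz = (bz0 + (iz + 1) * hz - oz) / dz
        tdz = hz / dz
    elif dz < -_EPS_DIR:
        sz = -1
        tmz = (bz0 + iz * hz - oz) / dz
        tdz = -hz / dz
    else:
        sz = 0
        tmz = math.inf
        tdz = math.inf
    t = 0.0
    tau = 0.0
    while t < t1:
        tn = tmx
        axis = 0
        if tmy < tn:
            tn = tmy
            axis = 1
        if tmz < tn:
            tn = tmz
            axis = 2
        if tn > t1:
            tn = t1
        seg = tn - t
        mu = mu_vec[ids[ix, iy, iz]]
        if mu > 0.0 and tau + mu * seg >= target_tau:
            return t + (target_tau - tau) / mu
        tau += mu * seg
        t = tn
        if t >= t1:
            break
        if axis == 0:
            ix += sx
            tmx += tdx
            if ix < 0 or ix >= nx:
                break
        elif axis == 1:
            iy += sy
            tmy += tdy
            if iy < 0 or iy >= ny:
                break
        else:
            iz += sz
            tmz += tdz
            if iz < 0 or iz >= nz:
                break
    return -1.0


def _unit(direction):
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if not math.isclose(n, 1.0, rel_tol=0, abs_tol=1e-9):
        d = d / n
    return d


def intersect_phantom(phantom: VoxelPhantom, origin, direction):
    """(t_entry, t_exit) of the ray with the phantom AABB, or None on miss.

    Both parameters are clamped to t >= 0 (rays starting inside the box
    get t_entry = 0).
    """
    o = np.asarray(origin, dtype=float)
    d = _unit(direction)
    lo, hi = phantom.bbox_min, phantom.bbox_max
    t0, t1 = _aabb(o[0], o[1], o[2], d[0], d[1], d[2],
                   lo[0], lo[1], lo[2], hi[0], hi[1], hi[2])
    if t0 > t1:
        return None
    return float(t0), float(t1)


def material_path_lengths(phantom: VoxelPhantom, origin, direction,
                          t_start: float, t_stop: float) -> np.ndarray:
    """Per-material chord lengths (mm) along the ray between two parameters."""
    o = np.asarray(origin, dtype=float)
    d = _unit(direction)
    lengths = np.zeros(len(phantom.materials))
    if t_stop > t_start:
        lo = phantom.bbox_min
        h = phantom.voxel_size
        _march_lengths(phantom.material_ids, lo[0], lo[1], lo[2],
                       h[0], h[1], h[2], o[0], o[1], o[2],
                       d[0], d[1], d[2], t_start, t_stop, lengths)
    return lengths


def _mu_vector(materials: MaterialTable, energy_kev: float) -> np.ndarray:
    return np.array([mu_total(m, energy_kev) for m in materials])


def radiological_path(phantom: VoxelPhantom, materials: MaterialTable,
                      origin, direction, t_max: float,
                      energy_kev: float) -> float:
    """Optical depth tau (unitless) along the ray up to ``t_max``."""
    if t_max < 0:
        raise ValueError("t_max must be >= 0")
    hit = intersect_phantom(phantom, origin, direction)
    if hit is None:
        return 0.0
    t0, t1 = hit
    t1 = min(t1, t_max)
    if t1 <= t0:
        return 0.0
    lengths = material_path_lengths(phantom, origin, direction, t0, t1)
    return float(lengths @ _mu_vector(materials, energy_kev))


def escape_probability(phantom: VoxelPhantom, materials: MaterialTable,
                       position, direction, energy_kev: float) -> float:
    """exp(-tau) from an in-phantom position to the boundary; 1 in vacuum."""
    tau = radiological_path(phantom, materials, position, direction,
                            math.inf, energy_kev)
    return math.exp(-tau)


def sample_forced_interaction(phantom: VoxelPhantom, materials: MaterialTable,
                              position, direction, energy_kev: float,
                              u: float):
    """Invert the truncated free-path CDF on the in-phantom segment.

    Returns ``(t, new_position)`` with cumulative optical depth along the
    segment equal to ``-ln(1 - (1 - exp(-tau_total)) * u)``.  Raises
    :class:`CannotForceError` when the segment has zero optical depth.
    """
    if not 0.0 <= u < 1.0:
        raise ValueError("u must be in [0, 1)")
    o = np.asarray(position, dtype=float)
    d = _unit(direction)
    hit = intersect_phantom(phantom, o, d)
    if hit is None:
        raise CannotForceError("ray does not intersect the phantom")
    t0, t1 = hit
    lengths = material_path_lengths(phantom, o, d, t0, t1)
    mu_vec = _mu_vector(materials, energy_kev)
    tau_total = float(lengths @ mu_vec)
    if tau_total <= 0.0:
        raise CannotForceError("zero optical depth: cannot force interaction")
    target = -math.log1p(-(1.0 - math.exp(-tau_total)) * u)
    lo = phantom.bbox_min
    h = phantom.voxel_size
    entry = o + t0 * d  # march from the entry point (t0 = 0 when inside)
    t_in = _march_forced(phantom.material_ids, lo[0], lo[1], lo[2],
                         h[0], h[1], h[2], mu_vec,
                         entry[0], entry[1], entry[2],
                         d[0], d[1], d[2], t1 - t0, target)
    if t_in < 0.0:  # numerical guard: target == tau_total within rounding
        t_in = (t1 - t0) * (1.0 - 1e-12)
    t = t0 + t_in
    return float(t), o + t * d
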