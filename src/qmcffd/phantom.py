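"""Voxel phantoms: data model, the three built-in phantoms, and file I/O.

World coordinate convention (fixed throughout the package): right-handed
frame with the X-ray point source at the origin and the beam axis along
+y.  Phantoms are centered on the beam axis with their center at
``SOURCE_PHANTOM_MM`` from the source; the detector plane sits a further
``PHANTOM_DETECTOR_MM`` downstream.  Voxel ``(i, j, k)`` spans the
half-open box ``[origin + i*h, origin + (i+1)*h)`` per axis, indexed
0-based with C-order storage (z fastest).
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass

import numpy as np

from .physics import MaterialTable, load_material_table

SOURCE_PHANTOM_MM = 500.0
PHANTOM_DETECTOR_MM = 500.0


class PhantomFormatError(ValueError):
    """Header/payload mismatch or malformed phantom file."""


@dataclass
class VoxelPhantom:
    """A 3-D material-index grid with world placement.

    ``material_ids[i, j, k]`` indexes into ``materials``; id 0 is air (or
    vacuum).  ``voxel_size`` is the per-axis edge length in mm and
    ``origin`` the world position of the corner of voxel (0, 0, 0).
    """

    material_ids: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray
    materials: MaterialTable

    def __post_init__(self):
        self.material_ids = np.ascontiguousarray(self.material_ids,
                                                 dtype=np.uint8)
        if self.material_ids.ndim != 3:
            raise ValueError("material_ids must be 3-D")
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.voxel_size.ndim == 0:
            self.voxel_size = np.repeat(self.voxel_size, 3)
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be > 0")
        self.origin = np.asarray(self.origin, dtype=float)
        if self.material_ids.max(initial=0) >= len(self.materials):
            raise PhantomFormatError("material id out of range")

    @property
    def shape(self):
        return self.material_ids.shape

    @property
    def bbox_min(self) -> np.ndarray:
        return self.origin.copy()

    @property
    def bbox_max(self) -> np.ndarray:
        return self.origin + np.asarray(self.shape) * self.voxel_size

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.bbox_min + self.bbox_max)

    def material_at(self, point) -> int:
        """Material id of the voxel containing a world point (half-open)."""
        idx = np.floor((np.asarray(point, float) - self.origin)
                       / self.voxel_size).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.shape)):
            raise IndexError(f"point {point} outside phantom")
        return int(self.material_ids[tuple(idx)])

    def voxel_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size[axis]

    def volume_mm3(self, material_id: int) -> float:
        count = int(np.count_nonzero(self.material_ids == material_id))
        return count * float(np.prod(self.voxel_size))

    def __eq__(self, other):
        return (isinstance(other, VoxelPhantom)
                and np.array_equal(self.material_ids, other.material_ids)
                and np.array_equal(self.voxel_size, other.voxel_size)
                and np.array_equal(self.origin, other.origin)
                and self.materials.names == other.materials.names)


def _centered_origin(shape, voxel_size) -> np.ndarray:
    half = 0.5 * np.asarray(shape) * np.asarray(voxel_size, float)
    return np.array([0.0, SOURCE_PHANTOM_MM, 0.0]) - half


def build_al_phantom() -> VoxelPhantom:
    """Homogeneous aluminium box, 160 x 28 x 160 voxels of 1 mm.

    28 mm thick along the beam axis (+y), centered between source and
    detector (500 mm to each).
    """
    shape = (160, 28, 160)
    materials = load_material_table(["air", "aluminium"])
    ids = np.ones(shape, dtype=np.uint8)
    return VoxelPhantom(ids, np.ones(3), _centered_origin(shape, 1.0),
                        materials)


def build_bt_cylinder(voxel_mm: float = 0.5) -> VoxelPhantom:
    """Bone-Tissue cylinder: bone annulus (radii 25-30 mm) around a soft-
    tissue core, 54 mm tall, air outside, on a 0.5 mm grid by default.

    The cylinder axis is vertical (z); the beam crosses the 60 mm
    diameter.  Bounding grid at 0.5 mm: 120 x 120 x 108 voxels.
    Voxels take the material of their center point.
    """
    r_outer, r_inner, height = 30.0, 25.0, 54.0
    nx = ny = int(round(2 * r_outer / voxel_mm))
    nz = int(round(height / voxel_mm))
    shape = (nx, ny, nz)
    origin = _centered_origin(shape, voxel_mm)
    x = origin[0] + (np.arange(nx) + 0.5) * voxel_mm
    y = origin[1] + (np.arange(ny) + 0.5) * voxel_mm - SOURCE_PHANTOM_MM
    r2 = x[:, None] ** 2 + y[None, :] ** 2
    ids2d = np.zeros((nx, ny), dtype=np.uint8)
    ids2d[r2 < r_outer ** 2] = 1  # bone annulus
    ids2d[r2 < r_inner ** 2] = 2  # tissue core
    ids = np.repeat(ids2d[:, :, None], nz, axis=2)
    materials = load_material_table(["air", "cortical_bone", "soft_tissue"])
    return VoxelPhantom(ids, np.full(3, voxel_mm), origin, materials)


# 3-D Shepp-Logan ellipsoids in a normalized [-1, 1]^3 box:
# (a, b, c, x0, y0, z0, rotation about z in degrees, label)
# label 1 = bone (outer shell), 2 = water (interior structures).
_SHEPP_LOGAN = [
    (0.69, 0.92, 0.81, 0.0, 0.0, 0.0, 0.0, 1),
    (0.6624, 0.874, 0.780, 0.0, -0.0184, 0.0, 0.0, 2),
    (0.11, 0.31, 0.22, 0.22, 0.0, 0.0, -18.0, 2),
    (0.16, 0.41, 0.28, -0.22, 0.0, 0.0, 18.0, 2),
    (0.21, 0.25, 0.41, 0.0, 0.35, -0.15, 0.0, 2),
    (0.046, 0.046, 0.05, 0.0, 0.1, 0.25, 0.0, 2),
    (0.046, 0.046, 0.05, 0.0, -0.1, 0.25, 0.0, 2),
    (0.046, 0.023, 0.05, -0.08, -0.605, 0.0, 0.0, 2),
    (0.023, 0.023, 0.02, 0.0, -0.606, 0.0, 0.0, 2),
    (0.023, 0.046, 0.02, 0.06, -0.605, 0.0, 0.0, 2),
]


def build_shepp_logan(scale: float = 1.0) -> VoxelPhantom:
    """3-D Shepp-Logan head phantom rasterized to bone/water/air.

    Full scale: 320 x 400 x 360 voxels of 0.5 mm.  The outer ellipsoid
    shell maps to cortical bone ("skull") and every interior ellipsoid to
    water; background is air.  ``scale`` < 1 shrinks the grid (and the
    phantom with it) for tests.  The ellipsoid-to-material mapping is this
    package's own choice, documented in docs/methods.md.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    full = np.array([320, 400, 360])
    shape = tuple(np.maximum((full * scale).astype(int), 8))
    voxel_mm = 0.5 * (full[0] / shape[0])  # keep aspect, shrink grid
    half_extent = 0.5 * np.asarray(shape) * voxel_mm
    origin = _centered_origin(shape, voxel_mm)
    xs_ = (np.arange(shape[0]) + 0.5) * voxel_mm - half_extent[0]
    ys_ = (np.arange(shape[1]) + 0.5) * voxel_mm - half_extent[1]
    zs_ = (np.arange(shape[2]) + 0.5) * voxel_mm - half_extent[2]
    # normalized coordinates in [-1, 1] per axis
    xn = xs_ / half_extent[0]
    yn = ys_ / half_extent[1]
    zn = zs_ / half_extent[2]
    ids = np.zeros(shape, dtype=np.uint8)
    for (a, b, c, x0, y0, z0, phi_deg, label) in _SHEPP_LOGAN:
        phi = np.deg2rad(phi_deg)
        cx = xn[:, None, None] - x0
        cy = yn[None, :, None] - y0
        cz = zn[None, None, :] - z0
        xr = cx * np.cos(phi) + cy * np.sin(phi)
        yr = -cx * np.sin(phi) + cy * np.cos(phi)
        inside = (xr / a) ** 2 + (yr / b) ** 2 + (cz / c) ** 2 <= 1.0
        ids[inside] = label
    materials = load_material_table(["air", "cortical_bone", "water"])
    return VoxelPhantom(ids, np.full(3, voxel_mm), origin, materials)


BUILDERS = {
    "al": build_al_phantom,
    "bt": build_bt_cylinder,
    "shepp-logan": build_shepp_logan,
}


def write_phantom(phantom: VoxelPhantom, path) -> None:
    """Write header (JSON) + raw uint8 volume (little-endian, z fastest).

    ``path`` is the header path; the payload goes to ``path`` + '.raw'.
    """
    path = pathlib.Path(path)
    header = {
        "shape": list(phantom.shape),
        "voxel_size_mm": list(phantom.voxel_size),
        "origin_mm": list(phantom.origin),
        "materials": phantom.materials.names,
        "dtype": "uint8",
        "byte_order": "little",
        "storage": "C-order, z fastest",
    }
    path.write_text(json.dumps(header, indent=1))
    raw = pathlib.Path(str(path) + ".raw")
    raw.write_bytes(phantom.material_ids.astype("<u1").tobytes(order="C"))


def read_phantom(path) -> VoxelPhantom:
    """Inverse of :func:`write_phantom`; round-trips bit-exactly."""
    path = pathlib.Path(path)
    try:
        header = json.loads(path.read_text())
        shape = tuple(int(n) for n in header["shape"])
        names = header["materials"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise PhantomFormatError(f"malformed phantom header {path}") from exc
    payload = pathlib.Path(str(path) + ".raw").read_bytes()
    expected = int(np.prod(shape))
    if len(payload) != expected:
        raise PhantomFormatError(
            f"raw payload has {len(payload)} bytes, header implies {expected}")
    ids = np.frombuffer(payload, dtype="<u1").reshape(shape).copy()
    materials = load_material_table(names)  # KeyError on unknown name
    return VoxelPhantom(ids, np.asarray(header["voxel_size_mm"], float),
                        np.asarray(header["origin_mm"], float), materials)
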