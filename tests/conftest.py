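import numpy as np
import pytest

from qmcffd.phantom import VoxelPhantom, SOURCE_PHANTOM_MM
from qmcffd.physics import (EnergySpectrum, MaterialTable, load_material,
                            vacuum)
from qmcffd.transport import Detector, Scene, TransportTables


def make_cube_phantom(material="aluminium", n=8, voxel_mm=2.0):
    """Homogeneous cube (n x n x n voxels) centered on the beam axis."""
    ids = np.ones((n, n, n), dtype=np.uint8)
    half = 0.5 * n * voxel_mm
    origin = np.array([-half, SOURCE_PHANTOM_MM - half, -half])
    materials = MaterialTable([vacuum("vacuum"), load_material(material)])
    return VoxelPhantom(ids, np.full(3, voxel_mm), origin, materials)


def make_vacuum_phantom(n=4, voxel_mm=4.0):
    ids = np.zeros((n, n, n), dtype=np.uint8)
    half = 0.5 * n * voxel_mm
    origin = np.array([-half, SOURCE_PHANTOM_MM - half, -half])
    return VoxelPhantom(ids, np.full(3, voxel_mm), origin,
                        MaterialTable([vacuum("vacuum")]))


@pytest.fixture(scope="session")
def tiny_scene():
    """Desk-scale scene: 16 mm Al cube, monoenergetic 60 keV source,
    4 x 4 detector of 40 mm pixels, two scatter orders."""
    return Scene(make_cube_phantom(),
                 spectrum=EnergySpectrum.monoenergetic(60.0),
                 detector=Detector(4, 4, 40.0),
                 n_orders=2)


@pytest.fixture(scope="session")
def tiny_tables(tiny_scene):
    return TransportTables(tiny_scene)


@pytest.fixture(scope="session")
def aluminium():
    return load_material("aluminium")


@pytest.fixture(scope="session")
def water():
    return load_material("water")
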