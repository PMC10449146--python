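"""Regenerate the bundled material attenuation tables.

Writes src/qmcffd/data/material_<name>.csv for each bundled material:
columns energy_keV, mu_pe_per_mm, mu_compton_per_mm, mu_rayleigh_per_mm
on a 60-point log grid over 16-120 keV, from the analytic cross-section
models in qmcffd.xsection.  Run from the repository root.
"""

import pathlib

import numpy as np

import sys
sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from qmcffd import xsection as xs  # noqa: E402

OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "qmcffd" / "data"
GRID = np.geomspace(16.0, 120.0, 60)
GRID[0], GRID[-1] = 16.0, 120.0


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    for name in sorted(xs.COMPOSITIONS):
        pe, c, r = xs.linear_attenuation(name, GRID)
        arr = np.column_stack([GRID, pe, c, r])
        path = OUT / f"material_{name}.csv"
        np.savetxt(path, arr, delimiter=",", fmt="%.8e",
                   header="energy_keV,mu_pe_per_mm,mu_compton_per_mm,"
                          "mu_rayleigh_per_mm", comments="")
        print("wrote", path)


if __name__ == "__main__":
    main()
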