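"""Regenerate the bundled 120 kVp-like X-ray spectrum.

Kramers bremsstrahlung shape phi(E) ~ (E_max/E - 1) filtered by 2.5 mm of
aluminium, tabulated on 1 keV bins over 16-120 keV and normalized to unit
sum.  Written to src/qmcffd/data/spectrum_120kvp.csv.
"""

import pathlib
import sys

import numpy as np

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from qmcffd import xsection as xs  # noqa: E402

OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "qmcffd" / "data"
KVP = 120.0
FILTER_MM_AL = 2.5


def main():
    e = np.arange(16.0, 121.0, 1.0)
    kramers = np.maximum(KVP / e - 1.0, 0.0)
    pe, c, r = xs.linear_attenuation("aluminium", e)
    mu = pe + c + r  # 1/mm
    phi = kramers * np.exp(-mu * FILTER_MM_AL)
    phi /= phi.sum()
    path = OUT / "spectrum_120kvp.csv"
    np.savetxt(path, np.column_stack([e, phi]), delimiter=",", fmt="%.8e",
               header="energy_keV,weight", comments="")
    print("wrote", path)


if __name__ == "__main__":
    main()
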