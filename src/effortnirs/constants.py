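"""Optical constants for continuous-wave NIRS at 760 and 850 nm.

Molar extinction coefficients are the values compiled in the widely used
Cope/Homer tables, expressed in cm^-1 per mM. The differential pathlength
factor (DPF) converts the geometric emitter-detector separation into the
effective photon path length; 6.0 is a conventional adult-forehead default.
"""

from __future__ import annotations

import numpy as np

WAVELENGTHS_NM: tuple[int, int] = (760, 850)

#: extinction[wavelength][chromophore] in cm^-1 mM^-1
EXTINCTION_MM_CM: dict[int, dict[str, float]] = {
    760: {"hbo": 0.5863, "hbr": 1.5485},
    850: {"hbo": 1.0580, "hbr": 0.6913},
}

DEFAULT_DPF: float = 6.0


def extinction_matrix(wavelengths=WAVELENGTHS_NM) -> np.ndarray:
    """2x2 matrix E with rows per wavelength, columns (HbO, HbR), cm^-1 mM^-1."""
    return np.array(
        [[EXTINCTION_MM_CM[w]["hbo"], EXTINCTION_MM_CM[w]["hbr"]] for w in wavelengths]
    )
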