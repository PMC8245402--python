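"""Haemoglobin extinction coefficients and the absorption-concentration map.

The two-wavelength modified Beer-Lambert inversion needs the decadic molar
extinction coefficients of oxy- and deoxy-haemoglobin at the laser
wavelengths.  Values below are linear interpolations of the standard
compiled in-vitro tabulation of human haemoglobin spectra (Prahl/OMLC
compilation), in 1/(M cm).
"""

from __future__ import annotations

import numpy as np

__all__ = ["EXTINCTION_M_CM", "absorption_matrix", "DEFAULT_WAVELENGTHS"]

DEFAULT_WAVELENGTHS = (687.0, 826.0)

#: Decadic molar extinction, 1/(M cm): {wavelength nm: (HbO2, HHb)}
EXTINCTION_M_CM: dict[float, tuple[float, float]] = {
    687.0: (271.8, 2158.8),
    826.0: (950.8, 720.6),
}

LN10 = float(np.log(10.0))


def absorption_matrix(
    wavelengths: tuple[float, float] = DEFAULT_WAVELENGTHS,
    max_condition: float = 20.0,
) -> np.ndarray:
    """2x2 matrix K mapping (dO2Hb, dHHb) in uM to d(mu_a) in 1/cm.

    ``dmua[i] = K[i, 0] * dO2Hb_uM + K[i, 1] * dHHb_uM`` with row i the i-th
    wavelength.  Natural-log absorption: K = ln(10) * eps * 1e-6.

    Raises if the pair of wavelengths yields a matrix with 2-norm condition
    number above ``max_condition`` (poorly separable chromophores).
    """
    try:
        eps = np.array([EXTINCTION_M_CM[float(w)] for w in wavelengths])
    except KeyError as e:
        known = sorted(EXTINCTION_M_CM)
        raise KeyError(f"no tabulated extinction at {e} nm; known: {known}")
    k = LN10 * eps * 1e-6
    cond = np.linalg.cond(k)
    if cond > max_condition:
        raise ValueError(
            f"extinction matrix condition number {cond:.1f} exceeds "
            f"{max_condition}; choose better-separated wavelengths"
        )
    return k
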