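"""Coarse AM1.5-like solar irradiance weighting table.

SYNTHETIC / APPROXIMATE: a smooth, hand-authored 5-nm table of relative
spectral irradiance (arbitrary units, shape only) spanning 380–700 nm,
emulating the broad visible envelope of the AM1.5 global reference spectrum
— rising through the blue, a broad maximum around 500–650 nm, and shallow
telluric/Fraunhofer dips near 430, 490 and 590 nm. It is adequate as a
weighting function for enhancement integrals; it is NOT the tabulated
reference spectrum.
"""

from __future__ import annotations

import numpy as np

__all__ = ["solar_weighting", "SOLAR_WAVELENGTHS_NM", "SOLAR_IRRADIANCE_REL"]

SOLAR_WAVELENGTHS_NM = np.arange(380.0, 705.0, 5.0)

# smooth envelope with mild dips; relative units (max ≈ 1)
_lam = SOLAR_WAVELENGTHS_NM


def _envelope(lam: np.ndarray) -> np.ndarray:
    rise = 1.0 / (1.0 + np.exp(-(lam - 430.0) / 28.0))  # blue shoulder
    fall = 1.0 / (1.0 + np.exp((lam - 900.0) / 120.0))  # gentle red decline
    dips = (
        1.0
        - 0.10 * np.exp(-0.5 * ((lam - 430.0) / 8.0) ** 2)
        - 0.05 * np.exp(-0.5 * ((lam - 490.0) / 7.0) ** 2)
        - 0.04 * np.exp(-0.5 * ((lam - 590.0) / 6.0) ** 2)
    )
    return (0.35 + 0.65 * rise) * fall * dips


SOLAR_IRRADIANCE_REL = _envelope(_lam) / _envelope(_lam).max()


def solar_weighting(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Interpolate the relative irradiance table onto ``wavelengths_nm``."""
    lam = np.asarray(wavelengths_nm, dtype=float)
    if lam.min() < SOLAR_WAVELENGTHS_NM[0] - 1e-9 or lam.max() > SOLAR_WAVELENGTHS_NM[-1] + 1e-9:
        raise ValueError(
            f"solar weighting table covers {SOLAR_WAVELENGTHS_NM[0]:.0f}-"
            f"{SOLAR_WAVELENGTHS_NM[-1]:.0f} nm; requested "
            f"{lam.min():.0f}-{lam.max():.0f} nm"
        )
    return np.interp(lam, SOLAR_WAVELENGTHS_NM, SOLAR_IRRADIANCE_REL)
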