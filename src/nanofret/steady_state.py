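"""Steady-state analysis: spectral decomposition, concentration and FRET
efficiency arithmetic, and emission-enhancement integrals.

The donor-quenching efficiency E = 1 − F_DA/F_D, the unloaded-particle
correction E_true = E_obs/(1−f) (donor-only discs emit unquenched and
dilute the observed quenching), and the Förster distance law
E = 1/(1+(r/R0)⁶) are the pen-and-paper core; spectral unmixing is a
non-negative least-squares over basis spectra, and the enhancement is a
ratio of (optionally solar-weighted) trapezoidal integrals of per-mole
acceptor emission responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear

from .io import Spectrum
from .solar import solar_weighting

__all__ = [
    "DecompositionResult",
    "EfficiencyResult",
    "decompose_spectrum",
    "concentration_from_absorbance",
    "fret_efficiency_donor_quenching",
    "correct_unloaded_fraction",
    "emission_enhancement",
    "efficiency_from_distance",
]


@dataclass
class DecompositionResult:
    """Non-negative coefficients of basis spectra plus an optional baseline."""

    coefficients: np.ndarray
    residual_norm: float
    baseline: float = 0.0
    warnings: "list[str]" = field(default_factory=list)


@dataclass
class EfficiencyResult:
    """Observed and unloaded-corrected FRET efficiencies (fractions)."""

    E_observed: float
    f_unloaded: float
    E_corrected: float

    def __post_init__(self) -> None:
        for name in ("E_observed", "E_corrected"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if not 0.0 <= self.f_unloaded < 1.0:
            raise ValueError("f_unloaded must be in [0, 1)")


def _common_grid(mixed: Spectrum, basis: "list[Spectrum]") -> np.ndarray:
    lo = max([mixed.wavelengths[0]] + [b.wavelengths[0] for b in basis])
    hi = min([mixed.wavelengths[-1]] + [b.wavelengths[-1] for b in basis])
    grid = mixed.wavelengths[(mixed.wavelengths >= lo - 1e-9) & (mixed.wavelengths <= hi + 1e-9)]
    if grid.size < 2:
        raise ValueError("spectra share no usable wavelength window")
    return grid


def decompose_spectrum(
    mixed: Spectrum,
    basis: "list[Spectrum]",
    fit_baseline: bool = False,
) -> DecompositionResult:
    """Unmix ``mixed`` as a non-negative combination of ``basis`` spectra.

    All spectra are linearly resampled onto the intersection of their grids
    (no extrapolation). The optional baseline is a single signed constant.
    Linearly dependent basis spectra produce a warning in the result, not an
    error.
    """
    if not basis:
        raise ValueError("need at least one basis spectrum")
    grid = _common_grid(mixed, basis)
    y = mixed.interp(grid).values
    A = np.column_stack([b.interp(grid).values for b in basis])
    notes: list[str] = []
    if np.linalg.matrix_rank(A, tol=1e-10 * np.abs(A).max()) < A.shape[1]:
        notes.append("basis spectra are linearly dependent to machine precision")
    n = A.shape[1]
    if fit_baseline:
        A = np.column_stack([A, np.ones(grid.size)])
        lb = np.concatenate([np.zeros(n), [-np.inf]])
        ub = np.full(n + 1, np.inf)
    else:
        lb = np.zeros(n)
        ub = np.full(n, np.inf)
    res = lsq_linear(A, y, bounds=(lb, ub))
    coeffs = res.x[:n]
    baseline = float(res.x[n]) if fit_baseline else 0.0
    residual = float(np.linalg.norm(A @ res.x - y))
    return DecompositionResult(coeffs, residual, baseline, notes)


def concentration_from_absorbance(A: float, epsilon: float, path: float = 1.0) -> float:
    """Beer–Lambert: c = A/(ε·l), with ε in M⁻¹cm⁻¹ and l in cm."""
    if epsilon <= 0:
        raise ValueError("molar absorption coefficient must be positive")
    if path <= 0:
        raise ValueError("path length must be positive")
    if A < 0:
        raise ValueError("absorbance must be non-negative")
    return A / (epsilon * path)


def fret_efficiency_donor_quenching(F_DA: float, F_D: float) -> float:
    """E = 1 − F_DA/F_D from donor emission with/without the acceptor."""
    if F_D <= 0:
        raise ValueError("donor-only intensity must be positive")
    if F_DA < 0:
        raise ValueError("donor intensity must be non-negative")
    if F_DA > F_D:
        raise ValueError(
            f"F_DA = {F_DA} exceeds F_D = {F_D}; check the normalisation of the inputs"
        )
    return 1.0 - F_DA / F_D


def correct_unloaded_fraction(E_obs: float, f: float) -> float:
    """True per-particle efficiency when a fraction ``f`` of particles carry
    only the donor: E_true = E_obs/(1−f).

    Donor-only particles contribute fully unquenched emission, so the
    ensemble efficiency underestimates the loaded-particle one. Out-of-range
    results are an inconsistency error, never a clip.
    """
    if not 0.0 <= f < 1.0:
        raise ValueError("unloaded fraction must be in [0, 1)")
    if not 0.0 <= E_obs <= 1.0:
        raise ValueError("observed efficiency must be in [0, 1]")
    if E_obs > 1.0 - f + 1e-12:
        raise ValueError(
            f"E_obs = {E_obs} with f = {f} implies a true efficiency above 1; inconsistent inputs"
        )
    return E_obs / (1.0 - f)


def emission_enhancement(
    em_with: Spectrum,
    em_without: Spectrum,
    excitation_range: tuple[float, float],
    weighting: str = "none",
) -> float:
    """Percent enhancement of the acceptor's effective absorption.

    Both inputs are per-mole acceptor emission responses versus excitation
    wavelength on a shared grid. Returns
    100·(∫ w·em_with dλ / ∫ w·em_without dλ − 1) over ``excitation_range``
    by trapezoid, with w = 1 or the approximate AM1.5-like table
    (``weighting='solar'``).
    """
    if em_with.wavelengths.shape != em_without.wavelengths.shape or not np.allclose(
        em_with.wavelengths, em_without.wavelengths
    ):
        raise ValueError("the two responses must share a wavelength grid")
    lo, hi = excitation_range
    if lo >= hi:
        raise ValueError("excitation range must be (low, high)")
    lam = em_with.wavelengths
    m = (lam >= lo - 1e-9) & (lam <= hi + 1e-9)
    if m.sum() < 2:
        raise ValueError("excitation range contains fewer than 2 grid points")
    if weighting == "none":
        w = np.ones(int(m.sum()))
    elif weighting == "solar":
        w = solar_weighting(lam[m])
    else:
        raise ValueError("weighting must be 'none' or 'solar'")
    num = np.trapezoid(w * em_with.values[m], lam[m])
    den = np.trapezoid(w * em_without.values[m], lam[m])
    if den <= 0:
        raise ValueError("denominator integral is non-positive")
    return 100.0 * (num / den - 1.0)


def efficiency_from_distance(r: float, R0: float) -> float:
    """Förster distance law E = 1/(1 + (r/R0)⁶)."""
    if r < 0:
        raise ValueError("distance must be non-negative")
    if R0 <= 0:
        raise ValueError("Förster radius must be positive")
    return 1.0 / (1.0 + (r / R0) ** 6)
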