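"""Mean-square-displacement analysis of particle trajectories and
transition-dipole orientation statistics.

For Brownian motion in d dimensions MSD(Δt) = 2·d·D·Δt; the diffusion
constant is the fitted slope over a central lag window divided by 2d. The
MSD is both time-averaged (all window pairs at each lag, computed with the
FFT autocorrelation algorithm) and ensemble-averaged over particles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["Trajectory", "DiffusionEstimate", "msd", "estimate_D", "dipole_angles"]

UM2_PER_S_FROM_NM2_PER_NS = 1.0e3  # 1 nm²/ns = 1000 μm²/s


@dataclass
class Trajectory:
    """Particle positions over time: (n_times, n_particles, dims) in nm."""

    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3:
            raise ValueError("positions must have shape (n_times, n_particles, dims)")
        if self.positions.shape[0] != self.times.size:
            raise ValueError("positions first axis must match the time grid")
        if self.positions.shape[2] not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def dims(self) -> int:
        return self.positions.shape[2]


def _msd_fft_1d(x: np.ndarray) -> np.ndarray:
    """Time-averaged MSD of one coordinate series for lags 0..n-1, O(n log n)."""
    n = x.size
    f = np.fft.rfft(x, 2 * n)
    acf = np.fft.irfft(f * np.conjugate(f))[:n]
    sq = x * x
    ss = np.concatenate(([0.0], np.cumsum(sq)))
    total = ss[-1]
    k = np.arange(n)
    # S1[k] = Σ_{t<n-k} x[t]² + Σ_{t≥k} x[t]² over the n-k valid pairs
    s1 = ss[n - k] + (total - ss[k])
    return (s1 - 2.0 * acf) / (n - k)


def msd(traj: Trajectory, max_lag_fraction: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Time- and ensemble-averaged MSD.

    Returns (lags ns, msd nm²) for lags 1..⌊max_lag_fraction·(n−1)⌋. Assumes
    a uniform time grid (checked).
    """
    if traj.times.size < 2:
        raise ValueError("need at least 2 frames")
    dt = np.diff(traj.times)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("MSD analysis requires a uniform time grid")
    if not 0 < max_lag_fraction <= 1:
        raise ValueError("max_lag_fraction must be in (0, 1]")
    n = traj.times.size
    max_lag = max(int(np.floor(max_lag_fraction * (n - 1))), 1)
    acc = np.zeros(n)
    n_t, n_p, dims = traj.positions.shape
    for p in range(n_p):
        for d in range(dims):
            acc += _msd_fft_1d(np.ascontiguousarray(traj.positions[:, p, d]))
    acc /= n_p
    lags = np.arange(1, max_lag + 1) * dt[0]
    return lags, acc[1 : max_lag + 1]


@dataclass
class DiffusionEstimate:
    """A diffusion constant in μm² s⁻¹ with its 95% CI half-width."""

    D: float
    ci95: float
    slope_nm2_per_ns: float


def estimate_D(
    msd_table: tuple[np.ndarray, np.ndarray],
    dims: int = 2,
    fit_range: tuple[float, float] | None = None,
) -> DiffusionEstimate:
    """OLS slope of MSD versus lag → D = slope/(2·dims), in μm² s⁻¹.

    ``fit_range`` is a (lo, hi) lag window in ns; the default uses lags
    between 10% and 50% of the maximum lag, avoiding both short-lag noise
    and the statistics collapse at long lags. Units: 1 nm²/ns = 1000 μm²/s.
    """
    lags, values = np.asarray(msd_table[0], float), np.asarray(msd_table[1], float)
    if dims not in (2, 3):
        raise ValueError("dims must be 2 or 3")
    if fit_range is None:
        fit_range = (0.1 * lags[-1], 0.5 * lags[-1])
    m = (lags >= fit_range[0]) & (lags <= fit_range[1])
    if m.sum() < 3:
        raise ValueError("need at least 3 lag points inside the fit window")
    x, y = lags[m], values[m]
    A = np.column_stack([x, np.ones_like(x)])
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope = float(coef[0])
    n_pts = x.size
    dof = n_pts - 2
    resid = y - A @ coef
    s2 = float(resid @ resid) / dof
    sxx = float(np.sum((x - x.mean()) ** 2))
    slope_se = np.sqrt(s2 / sxx)
    if slope < 0:
        warnings.warn("negative MSD slope; clipping D at 0", RuntimeWarning, stacklevel=2)
        slope = 0.0
    D = slope / (2.0 * dims) * UM2_PER_S_FROM_NM2_PER_NS
    ci = 1.96 * slope_se / (2.0 * dims) * UM2_PER_S_FROM_NM2_PER_NS
    return DiffusionEstimate(D, ci, slope)


def dipole_angles(vectors, normal) -> np.ndarray:
    """Angles (degrees, folded to [0°, 90°]) between dipole axes and the
    membrane normal. Transition dipoles are axes, not directions, hence the
    absolute value of the projection."""
    normal = np.asarray(normal, dtype=float).reshape(3)
    n_norm = np.linalg.norm(normal)
    if n_norm < 1e-12:
        raise ValueError("membrane normal is a zero vector")
    n_hat = normal / n_norm
    vecs = np.atleast_2d(np.asarray(vectors, dtype=float))
    norms = np.linalg.norm(vecs, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-length dipole vector")
    cosines = np.abs(vecs @ n_hat) / norms
    return np.degrees(np.arccos(np.clip(cosines, 0.0, 1.0)))
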