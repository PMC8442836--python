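"""Global (target) analysis of transient-absorption maps.

A first-order compartmental scheme (sequential chain or acyclic branched
network) is fitted to the full ΔA(time, wavelength) matrix by variable
projection: for a trial set of time constants (and Gaussian IRF) the
populations C(t) are computed analytically from the rate matrix, the
species spectra solve the linear problem S = argmin‖ΔA − C·S‖², and the
outer nonlinear search runs over the time constants only, with multi-start
initialisation. The fitted spectra are the evolution-associated difference
spectra (EADS) of the scheme; the decay-associated difference spectra
(DADS) — the amplitude spectra of the pure exponential eigenmodes — follow
by the linear eigenmode expansion in :func:`nanofret.kinetics.eads_to_dads`.

Usage::

    res = GlobalTAModel(ta_map, scheme="sequential", n_components=3).fit()
    print(res.summary())
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .io import TAMap
from .kinetics import (
    KineticModel,
    build_branched_model,
    build_sequential_model,
    eads_to_dads,
    solve_populations,
)
from .trfs import FitError

__all__ = [
    "GlobalTAResults",
    "GlobalTAModel",
    "fit_global",
    "TraceFitResult",
    "fit_trace",
]


@dataclass
class GlobalTAResults:
    """Fitted kinetic scheme with its EADS/DADS.

    ``taus`` are ps, ascending, with ``inf`` for a non-decaying terminal
    compartment. ``eads``/``dads`` rows follow the same order.
    """

    taus: np.ndarray
    ci95_taus: np.ndarray
    eads: np.ndarray
    dads: np.ndarray
    chi2_reduced: float
    irf: tuple[float, float]
    model: KineticModel
    wavelengths: np.ndarray
    times: np.ndarray
    warnings: "list[str]" = field(default_factory=list)

    def reconstruct(self) -> np.ndarray:
        """ΔA predicted by the fitted scheme on the data grids."""
        C = solve_populations(self.model, self.times)
        return C @ self.eads

    def summary(self) -> str:
        lines = [
            "Global transient-absorption fit",
            f"  scheme: {self.model.scheme}   compartments: {self.model.n_compartments}"
            f"   chi2_red: {self.chi2_reduced:.4g}",
            f"  IRF: t0 = {self.irf[0]:.3f} ps, fwhm = {self.irf[1]:.3f} ps",
        ]
        for i, (tau, ci) in enumerate(zip(self.taus, self.ci95_taus), start=1):
            tau_str = "inf" if np.isinf(tau) else f"{tau:.4g} ± {ci:.2g}"
            lines.append(f"  EADS{i}: tau = {tau_str} ps")
        for note in self.warnings:
            lines.append(f"  warning: {note}")
        return "\n".join(lines)


def _tau_starts(n: int, tmin: float, tmax: float, n_restarts: int) -> list[np.ndarray]:
    grid = np.geomspace(tmin, tmax, max(n + 4, 6))
    combos = [np.array(c) for c in itertools.combinations(grid, n)]
    if len(combos) <= n_restarts:
        return combos
    idx = np.linspace(0, len(combos) - 1, n_restarts).astype(int)
    return [combos[i] for i in idx]


class GlobalTAModel:
    """Compartmental model of a TA map, fitted by variable projection.

    Parameters
    ----------
    ta_map : TAMap
    scheme : 'sequential' or 'branched'.
    n_components : compartments of a sequential scheme (≤ 6). A terminal
        non-decaying compartment is included when ``terminal_infinite``.
    connectivity, losses : branched-scheme edges ``(from, to, tau)`` and
        ground-state losses ``(compartment, tau)``; the taus are starting
        values and are all fitted.
    irf : fixed (t0 ps, fwhm ps) Gaussian IRF, fitted instead when
        ``fit_irf`` is true.
    init_taus : starting time constants for the sequential scheme.
    """

    def __init__(
        self,
        ta_map: TAMap,
        scheme: str = "sequential",
        n_components: int = 3,
        terminal_infinite: bool = True,
        init_taus=None,
        fit_irf: bool = False,
        irf: tuple[float, float] = (0.0, 0.0),
        connectivity=None,
        losses=None,
        initial_populations=None,
    ) -> None:
        if scheme not in ("sequential", "branched"):
            raise ValueError("scheme must be 'sequential' or 'branched'")
        if not np.all(np.isfinite(ta_map.delta_A)):
            raise ValueError("TA map contains non-finite values")
        if n_components > 6:
            raise ValueError("at most 6 compartments are supported")
        self.map = ta_map
        self.scheme = scheme
        self.terminal_infinite = terminal_infinite
        self.fit_irf = fit_irf
        self.irf0 = irf
        self.init_taus = None if init_taus is None else np.asarray(init_taus, dtype=float)
        self.initial_populations = initial_populations
        if scheme == "branched":
            if not connectivity:
                raise ValueError("branched scheme requires a connectivity list")
            self.connectivity = list(connectivity)
            self.losses = list(losses or [])
            self.n_finite = len(self.connectivity) + len(self.losses)
            self.n_components = max(
                [max(a, b) for a, b, _ in self.connectivity]
                + [c for c, _ in self.losses]
            ) + 1
        else:
            self.connectivity = None
            self.losses = None
            self.n_components = n_components
            self.n_finite = n_components - (1 if terminal_infinite else 0)
            if self.n_finite < 1:
                raise ValueError("need at least one finite time constant")

    # -- model assembly -----------------------------------------------------

    def _build(self, taus: np.ndarray, irf: tuple[float, float]) -> KineticModel:
        if self.scheme == "sequential":
            return build_sequential_model(taus, self.terminal_infinite, irf=irf)
        conn = [(a, b, tau) for (a, b, _), tau in zip(self.connectivity, taus)]
        loss = [
            (c, tau)
            for (c, _), tau in zip(self.losses, taus[len(self.connectivity):])
        ]
        return build_branched_model(
            conn, loss, initial_populations=self.initial_populations, irf=irf
        )

    def _split(self, theta: np.ndarray):
        taus = np.exp(theta[: self.n_finite])
        if self.fit_irf:
            irf = (float(theta[self.n_finite]), float(np.exp(theta[self.n_finite + 1])))
        else:
            irf = self.irf0
        return taus, irf

    def _residual(self, theta: np.ndarray):
        taus, irf = self._split(theta)
        model = self._build(taus, irf)
        C = solve_populations(model, self.map.times)
        S, *_ = np.linalg.lstsq(C, self.map.delta_A, rcond=None)
        return ((C @ S) - self.map.delta_A).ravel(), model, C, S

    def fit(self, n_restarts: int = 8) -> GlobalTAResults:
        t = self.map.times
        tmax = t[-1] - t[0]
        if self.scheme == "branched":
            base = np.array([tau for *_, tau in self.connectivity] + [tau for _, tau in self.losses])
            starts = [base] + [base * f for f in (0.3, 3.0, 0.1, 10.0)][: max(n_restarts - 1, 0)]
        elif self.init_taus is not None:
            starts = [self.init_taus] + [
                self.init_taus * f for f in (0.3, 3.0, 0.1, 10.0)
            ][: max(n_restarts - 1, 0)]
        else:
            starts = _tau_starts(self.n_finite, 0.1, tmax, n_restarts)

        irf_extra = (
            [np.array([self.irf0[0], np.log(max(self.irf0[1], 1e-3))])] if self.fit_irf else []
        )
        best = None
        for taus0 in starts:
            theta0 = np.concatenate([np.log(taus0)] + irf_extra)
            try:
                sol = least_squares(
                    lambda th: self._residual(th)[0],
                    theta0,
                    method="trf",
                    max_nfev=200 * theta0.size,
                )
            except Exception:
                continue
            if (
                best is None
                or sol.cost < best.cost * (1 - 1e-9)
                or (
                    abs(sol.cost - best.cost) <= 1e-9 * best.cost
                    and np.exp(sol.x[0]) < np.exp(best.x[0])
                )
            ):
                best = sol
        if best is None:
            raise FitError("no restart of the global fit converged")

        taus, irf = self._split(best.x)
        notes: list[str] = []
        order = np.argsort(taus) if self.scheme == "sequential" else np.arange(taus.size)
        taus = taus[order]
        # rebuild at (sorted) optimum
        theta = np.concatenate(
            [np.log(taus)] + ([np.array([irf[0], np.log(max(irf[1], 1e-12))])] if self.fit_irf else [])
        )
        resid, model, C, S = self._residual(theta)
        if np.linalg.cond(C) > 1e8:
            notes.append("population matrix nearly rank-deficient: time constants are degenerate")

        dof = max(resid.size - (theta.size + S.size), 1)
        chi2 = float(resid @ resid / dof)
        # CIs on the finite taus from the outer jacobian (log-parameterised)
        try:
            J = best.jac
            cov = np.linalg.inv(J.T @ J) * (2.0 * best.cost / dof)
            sig_log = np.sqrt(np.clip(np.diag(cov)[: self.n_finite], 0.0, None))[order]
        except np.linalg.LinAlgError:
            sig_log = np.full(self.n_finite, np.nan)
        ci = 1.96 * taus * sig_log

        taus_out = taus.copy()
        ci_out = ci.copy()
        if self.scheme == "sequential" and self.terminal_infinite:
            taus_out = np.append(taus_out, np.inf)
            ci_out = np.append(ci_out, np.nan)
        dads = eads_to_dads(S, model)
        return GlobalTAResults(
            taus=taus_out,
            ci95_taus=ci_out,
            eads=S,
            dads=dads,
            chi2_reduced=chi2,
            irf=irf,
            model=model,
            wavelengths=self.map.wavelengths,
            times=self.map.times,
            warnings=notes,
        )


def fit_global(
    ta_map: TAMap,
    scheme: str = "sequential",
    n_components: int = 3,
    init_taus=None,
    fit_irf: bool = False,
    **kwargs,
) -> GlobalTAResults:
    """Functional wrapper around :class:`GlobalTAModel`."""
    return GlobalTAModel(
        ta_map,
        scheme=scheme,
        n_components=n_components,
        init_taus=init_taus,
        fit_irf=fit_irf,
        **kwargs,
    ).fit()


# ---------------------------------------------------------------------------
# single-wavelength traces
# ---------------------------------------------------------------------------


@dataclass
class TraceFitResult:
    """Signed multi-exponential fit of one kinetic trace.

    ``unresolved[i]`` marks components whose time constant exceeds the
    measurement window by the guard factor — their value is reported but
    only a lower bound is meaningful.
    """

    taus: np.ndarray
    amplitudes: np.ndarray
    chi2_reduced: float
    irf: tuple[float, float]
    unresolved: np.ndarray
    fitted_curve: np.ndarray

    def summary(self) -> str:
        rows = [
            f"  A = {a:+.4g}, tau = {t:.4g} ps" + ("  [inf/unresolved]" if u else "")
            for a, t, u in zip(self.amplitudes, self.taus, self.unresolved)
        ]
        return "Kinetic trace fit\n" + "\n".join(rows) + f"\n  chi2_red: {self.chi2_reduced:.4g}"


def fit_trace(
    times: np.ndarray,
    values: np.ndarray,
    n_components: int = 1,
    fit_irf: bool = False,
    irf: tuple[float, float] = (0.0, 0.0),
    init_taus=None,
    window_guard: float = 5.0,
    n_restarts: int = 8,
) -> TraceFitResult:
    """Fit Σ aᵢ·exp(−t/τᵢ) (⊗ Gaussian IRF) to a single-wavelength trace.

    Amplitudes are signed, so rise components (negative amplitude at a
    bleach, say) are allowed. A component with τ > ``window_guard`` × the
    time window is flagged unresolved — with a 0–700 ps window a nanosecond
    decay is only bounded, not measured.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    from ._expgauss import FWHM_TO_SIGMA, exp_conv_gauss

    span = times[-1] - times[0]

    def design(taus, irf_par):
        t0, fwhm = irf_par
        sigma = fwhm * FWHM_TO_SIGMA
        return np.column_stack([exp_conv_gauss(times - t0, 1.0 / tau, sigma) for tau in taus])

    def split(theta):
        taus = np.exp(theta[:n_components])
        irf_par = (
            (float(theta[n_components]), float(np.exp(theta[n_components + 1])))
            if fit_irf
            else irf
        )
        return taus, irf_par

    def residual(theta):
        taus, irf_par = split(theta)
        C = design(taus, irf_par)
        a, *_ = np.linalg.lstsq(C, values, rcond=None)
        return C @ a - values, a, C

    if init_taus is not None:
        base = np.asarray(init_taus, dtype=float)
        starts = [base] + [base * f for f in (0.3, 3.0)]
    else:
        starts = _tau_starts(n_components, max(span * 1e-4, 1e-3), 2 * span, n_restarts)
    irf_extra = [np.array([irf[0], np.log(max(irf[1], 1e-3))])] if fit_irf else []
    best = None
    for taus0 in starts:
        theta0 = np.concatenate([np.log(taus0)] + irf_extra)
        try:
            sol = least_squares(lambda th: residual(th)[0], theta0, max_nfev=300 * theta0.size)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("trace fit did not converge")
    taus, irf_par = split(best.x)
    _, amps, C = residual(best.x)
    fitted = C @ np.asarray(amps)
    order = np.argsort(taus)
    taus, amps = taus[order], np.asarray(amps)[order]
    unresolved = taus > window_guard * span
    dof = max(times.size - (best.x.size + n_components), 1)
    chi2 = float(np.sum((fitted - values) ** 2) / dof)
    return TraceFitResult(taus, amps, chi2, irf_par, unresolved, fitted)
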