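"""First-order compartmental kinetic schemes and their analytic solutions.

A kinetic model is an n×n rate matrix K (ps⁻¹) acting on compartment
populations, dc/dt = K·c. Off-diagonal K[j, i] ≥ 0 is transfer from
compartment i into compartment j; the diagonal carries the total loss out
of each compartment, so every column sums to ≤ 0 (strictly negative where
population is lost to the ground state). For the acyclic schemes used here
K is triangular under a topological ordering, the eigenvalues are real, and
the populations are sums of exponentials (the Bateman solution), which are
convolved in closed form with a Gaussian instrument response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._expgauss import FWHM_TO_SIGMA, exp_conv_gauss

__all__ = [
    "KineticModel",
    "build_sequential_model",
    "build_branched_model",
    "solve_populations",
    "eads_to_dads",
]


@dataclass
class KineticModel:
    """A first-order compartmental scheme with an optional Gaussian IRF.

    ``irf`` is (t0 ps, fwhm ps); fwhm = 0 means a delta-function response.
    """

    K: np.ndarray
    initial_populations: np.ndarray
    irf: tuple[float, float] = (0.0, 0.0)
    scheme: str = "custom"

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        if self.K.ndim != 2 or self.K.shape[0] != self.K.shape[1]:
            raise ValueError("K must be a square matrix")
        off = self.K - np.diag(np.diag(self.K))
        if np.any(off < -1e-12):
            raise ValueError("off-diagonal rate entries must be non-negative")
        colsums = self.K.sum(axis=0)
        if np.any(colsums > 1e-9):
            raise ValueError("column sums of K must be <= 0 (no population creation)")
        self.initial_populations = np.asarray(self.initial_populations, dtype=float)
        if self.initial_populations.shape != (self.K.shape[0],):
            raise ValueError("initial_populations length must match K")
        if abs(self.initial_populations.sum() - 1.0) > 1e-9:
            raise ValueError("initial populations must sum to 1")

    @property
    def n_compartments(self) -> int:
        return self.K.shape[0]


def build_sequential_model(
    taus: "list[float] | np.ndarray",
    terminal_infinite: bool = True,
    irf: tuple[float, float] = (0.0, 0.0),
) -> KineticModel:
    """Unidirectional chain 1→2→…→n with rate 1/τᵢ out of compartment i.

    With ``terminal_infinite`` a non-decaying terminal compartment is
    appended (rate 0), matching the long-lived final species of a
    transient-absorption fit; otherwise the last compartment decays to the
    ground state with the last τ.
    """
    taus = np.asarray(taus, dtype=float)
    if taus.size == 0:
        raise ValueError("need at least one time constant")
    if np.any(taus <= 0):
        raise ValueError("time constants must be positive")
    n = taus.size + (1 if terminal_infinite else 0)
    K = np.zeros((n, n))
    for i, tau in enumerate(taus):
        K[i, i] -= 1.0 / tau
        if i + 1 < n:
            K[i + 1, i] += 1.0 / tau
    c0 = np.zeros(n)
    c0[0] = 1.0
    return KineticModel(K, c0, irf=irf, scheme="sequential")


def build_branched_model(
    connectivity: "list[tuple[int, int, float]]",
    losses: "list[tuple[int, float]] | None" = None,
    initial_populations: np.ndarray | None = None,
    irf: tuple[float, float] = (0.0, 0.0),
) -> KineticModel:
    """Assemble K from transfer edges ``(from, to, tau)`` plus ground-state
    losses ``(compartment, tau)``. The transfer graph must be acyclic."""
    losses = losses or []
    nodes = set()
    for a, b, _ in connectivity:
        nodes.update((a, b))
    for c, _ in losses:
        nodes.add(c)
    if not nodes:
        raise ValueError("empty scheme")
    n = max(nodes) + 1
    # cycle check by DFS over the transfer edges
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for a, b, tau in connectivity:
        if tau <= 0:
            raise ValueError("edge time constants must be positive")
        adj[a].append(b)
    state = [0] * n  # 0 unvisited, 1 on stack, 2 done

    def visit(u: int) -> None:
        state[u] = 1
        for v in adj[u]:
            if state[v] == 1:
                raise ValueError(f"cycle detected through compartments {u} and {v}")
            if state[v] == 0:
                visit(v)
        state[u] = 2

    for u in range(n):
        if state[u] == 0:
            visit(u)

    K = np.zeros((n, n))
    for a, b, tau in connectivity:
        K[b, a] += 1.0 / tau
        K[a, a] -= 1.0 / tau
    for c, tau in losses:
        if tau <= 0:
            raise ValueError("loss time constants must be positive")
        K[c, c] -= 1.0 / tau
    if initial_populations is None:
        c0 = np.zeros(n)
        c0[0] = 1.0
    else:
        c0 = np.asarray(initial_populations, dtype=float)
    return KineticModel(K, c0, irf=irf, scheme="branched")


def _eigendecompose(model: KineticModel):
    """Eigendecomposition of K with a tiny perturbation for degenerate rates."""
    K = model.K.copy()
    lam, V = np.linalg.eig(K)
    n = K.shape[0]
    scale = max(np.max(np.abs(lam)), 1e-30)
    for _ in range(3):
        dist = np.abs(lam[:, None] - lam[None, :]) + np.eye(n) * 10 * scale
        if dist.min() > 1e-9 * scale:
            break
        warnings.warn(
            "degenerate rate constants; perturbing by 1e-9 relative to resolve eigenmodes",
            RuntimeWarning,
            stacklevel=3,
        )
        K = K + np.diag(np.diag(K)) * (1e-9 * np.arange(1, n + 1))
        lam, V = np.linalg.eig(K)
    if np.max(np.abs(lam.imag)) > 1e-9 * scale:
        raise ValueError("rate matrix has complex eigenvalues; acyclic first-order schemes only")
    lam = lam.real
    V = V.real
    try:
        w = np.linalg.solve(V, model.initial_populations)
    except np.linalg.LinAlgError as exc:
        raise ValueError("rate matrix not diagonalizable after perturbation") from exc
    return lam, V, w


def solve_populations(model: KineticModel, times: np.ndarray) -> np.ndarray:
    """Analytic populations c(t) on ``times``, Gaussian-IRF convolved.

    Returns an (n_times, n_compartments) matrix. For a delta IRF the
    populations are exactly the Bateman solution starting at t0.
    """
    times = np.asarray(times, dtype=float)
    lam, V, w = _eigendecompose(model)
    t0, fwhm = model.irf
    sigma = fwhm * FWHM_TO_SIGMA
    x = times - t0
    modes = np.empty((times.size, lam.size))
    for l, lam_l in enumerate(lam):
        k = max(-lam_l, 0.0)  # guard tiny positive round-off eigenvalues
        modes[:, l] = exp_conv_gauss(x, k, sigma)
    return modes @ (V * w[None, :]).T


def eads_to_dads(eads: np.ndarray, model: KineticModel) -> np.ndarray:
    """Convert evolution-associated to decay-associated difference spectra.

    Writing ΔA(t, λ) = Σᵢ cᵢ(t)·EADSᵢ(λ) and expanding each population in
    the eigenmodes of K gives ΔA = Σₗ e^{λₗ t}·DADSₗ(λ) with
    DADSₗ = wₗ·Σᵢ V[i,l]·EADSᵢ, where V are the eigenvectors and
    w = V⁻¹·c(t0). Rows come back ordered fastest-decaying first
    (ascending τ, any non-decaying mode last), matching the EADS order of a
    sequential scheme.
    """
    eads = np.asarray(eads, dtype=float)
    if eads.shape[0] != model.n_compartments:
        raise ValueError("eads rows must equal the number of compartments")
    lam, V, w = _eigendecompose(model)
    dads = (V.T @ eads) * w[:, None]
    order = np.argsort(lam)  # most negative eigenvalue = fastest decay first
    return dads[order]
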