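"""Synthetic-data generators for every input the pipeline consumes.

The generators emulate the study conditions of a dye/LHCII nanodisc
experiment: Gaussian band-model absorption/emission spectra with the Texas
Red (TR) and chlorophyll peak positions (TR abs 590 nm, em 614/673 nm;
Chl a abs ~675 nm, em 682/735 nm), TCSPC decays as multi-exponentials
convolved with a Gaussian IRF plus Poisson noise, transient-absorption maps
driven by a sequential compartmental scheme with Gaussian detector noise,
nanodisc chromophore geometries (~21 nm discs, TR dyes at the headgroup
planes around a central protein cylinder), and 2-D Brownian lipid
trajectories. All generators are pure functions of their parameters and an
explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._expgauss import FWHM_TO_SIGMA, exp_conv_gauss
from .io import ChromophoreSite, DecayTrace, Spectrum, TAMap
from .kinetics import KineticModel, build_sequential_model, solve_populations

__all__ = [
    "BandModel",
    "DiscGeometry",
    "gen_spectrum",
    "preset_band_model",
    "gen_decay",
    "gen_ta_map",
    "default_species_spectra",
    "gen_disc_geometry",
    "default_acceptor_sites",
    "gen_random_walk",
    "matched_enhancement_pair",
    "PRESETS",
]


@dataclass
class BandModel:
    """A sum of Gaussian bands: list of (center nm, fwhm nm, amplitude)."""

    bands: "list[tuple[float, float, float]]"
    kind: str = "absorption"

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("band list must not be empty")
        for c, fwhm, amp in self.bands:
            if fwhm <= 0:
                raise ValueError("band fwhm must be positive")
            if amp < 0:
                raise ValueError("band amplitude must be non-negative")


# Band positions follow the measured peaks of the TR/LHCII system; widths and
# relative amplitudes are plausible hand-picked values (the TR vibronic band
# is set to 0.2 of the 0-0 band, an arbitrary but documented choice).
PRESETS: dict[str, BandModel] = {
    "TR_absorption": BandModel([(590.0, 32.0, 1.0), (553.0, 38.0, 0.35)], "absorption"),
    "TR_emission": BandModel([(614.0, 30.0, 1.0), (673.0, 40.0, 0.2)], "emission"),
    "LHCII_absorption": BandModel(
        [(675.0, 22.0, 1.0), (650.0, 24.0, 0.45), (435.0, 32.0, 1.15), (470.0, 34.0, 0.75)],
        "absorption",
    ),
    "LHCII_emission": BandModel([(682.0, 20.0, 1.0), (735.0, 38.0, 0.18)], "emission"),
    "Chl_a_absorption": BandModel([(675.0, 20.0, 1.0), (435.0, 30.0, 1.1)], "absorption"),
}


def preset_band_model(name: str) -> BandModel:
    try:
        return PRESETS[name]
    except KeyError as exc:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from exc


def gen_spectrum(model: BandModel, grid: np.ndarray, label: str = "") -> Spectrum:
    """Evaluate a band model on a strictly increasing wavelength grid."""
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    values = np.zeros_like(grid)
    for center, fwhm, amp in model.bands:
        values += amp * np.exp(-4.0 * np.log(2.0) * ((grid - center) / fwhm) ** 2)
    return Spectrum(grid, values, kind=model.kind, label=label)


# ---------------------------------------------------------------------------
# TCSPC decays
# ---------------------------------------------------------------------------


def decay_model(
    times: np.ndarray,
    amplitudes: np.ndarray,
    taus: np.ndarray,
    t0: float,
    irf_fwhm: float,
) -> np.ndarray:
    """Noiseless Σ Aᵢ·(exp(−t/τᵢ) ⊗ Gaussian IRF) with amplitudes in percent."""
    sigma = irf_fwhm * FWHM_TO_SIGMA
    x = np.asarray(times, dtype=float) - t0
    out = np.zeros_like(x)
    for a, tau in zip(amplitudes, taus):
        out += (a / 100.0) * exp_conv_gauss(x, 1.0 / tau, sigma)
    return out


def gen_decay(
    amplitudes,
    taus,
    irf_fwhm: float,
    t0: float,
    grid: np.ndarray,
    peak_counts: float,
    seed: int,
    noise: bool = True,
) -> DecayTrace:
    """Poisson-sampled multi-exponential TCSPC decay with a Gaussian IRF.

    Amplitudes are percentages summing to 100; times in ns. The noiseless
    model is scaled so its maximum equals ``peak_counts`` before sampling.
    The trace carries the (noiseless) IRF vector scaled to the same peak.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    taus = np.asarray(taus, dtype=float)
    if np.any(taus <= 0):
        raise ValueError("time constants must be positive")
    if abs(amplitudes.sum() - 100.0) > 1e-9:
        raise ValueError(f"amplitudes must sum to 100, got {amplitudes.sum()}")
    grid = np.asarray(grid, dtype=float)
    model = decay_model(grid, amplitudes, taus, t0, irf_fwhm)
    peak = model.max()
    if peak <= 0:
        raise ValueError("model has no support on the requested grid")
    model = model * (peak_counts / peak)
    sigma = irf_fwhm * FWHM_TO_SIGMA
    if sigma > 0:
        irf = np.exp(-0.5 * ((grid - t0) / sigma) ** 2) * peak_counts
    else:
        irf = np.where(np.isclose(grid, t0), peak_counts, 0.0)
    if noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(model).astype(float)
    else:
        counts = model
    return DecayTrace(grid, counts, irf=irf)


# ---------------------------------------------------------------------------
# transient-absorption maps
# ---------------------------------------------------------------------------


def default_species_spectra(wavelengths: np.ndarray, n_components: int = 3) -> list[Spectrum]:
    """Plausible EADS-like species spectra for a TR→LHCII transfer scheme.

    Component 1: dominant TR ground-state bleach / stimulated emission
    (negative band at 593 nm) with little acceptor signal; successive
    components lose TR amplitude and gain the Chl a bleach at 675 nm,
    mimicking donor decay with a concomitant acceptor rise.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)

    def band(center, fwhm, amp):
        return amp * np.exp(-4 * np.log(2) * ((wavelengths - center) / fwhm) ** 2)

    tr = -band(593.0, 34.0, 1.0) - band(658.0, 30.0, 0.15)
    chl = -band(675.0, 18.0, 1.0)
    mixes = np.linspace(0.0, 1.0, n_components)
    spectra = []
    for i, m in enumerate(mixes):
        vals = (1.0 - m) * tr + 0.6 * m * chl
        spectra.append(Spectrum(wavelengths, vals, kind="delta_A", label=f"species{i + 1}"))
    return spectra


def gen_ta_map(
    model_type: str,
    taus,
    species_spectra: "list[Spectrum]",
    irf_fwhm: float,
    times: np.ndarray,
    noise_sigma: float,
    seed: int,
    t0: float = 0.0,
    model: KineticModel | None = None,
    terminal_infinite: bool = True,
) -> TAMap:
    """ΔA map from a compartmental scheme: ΔA = C(taus)·S + N(0, noise_sigma).

    ``model_type`` is ``sequential`` (chain built from ``taus``) or
    ``custom`` with an explicit :class:`KineticModel` passed via ``model``.
    Times in ps. Species spectra must share one wavelength grid, one per
    compartment.
    """
    times = np.asarray(times, dtype=float)
    if not species_spectra:
        raise ValueError("need at least one species spectrum")
    wl = species_spectra[0].wavelengths
    for s in species_spectra[1:]:
        if s.wavelengths.shape != wl.shape or not np.allclose(s.wavelengths, wl):
            raise ValueError("species spectra must share the wavelength grid")
    if model_type == "sequential":
        model = build_sequential_model(taus, terminal_infinite=terminal_infinite, irf=(t0, irf_fwhm))
    elif model_type in ("branched", "custom"):
        if model is None:
            raise ValueError(f"model_type {model_type!r} requires an explicit KineticModel")
        model = KineticModel(model.K, model.initial_populations, irf=(t0, irf_fwhm), scheme=model.scheme)
    else:
        raise ValueError(f"unknown model_type {model_type!r}")
    if model.n_compartments != len(species_spectra):
        raise ValueError(
            f"{model.n_compartments} compartments but {len(species_spectra)} species spectra"
        )
    C = solve_populations(model, times)
    S = np.vstack([s.values for s in species_spectra])
    dA = C @ S
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        dA = dA + rng.normal(0.0, noise_sigma, size=dA.shape)
    return TAMap(times, wl, dA)


# ---------------------------------------------------------------------------
# nanodisc geometry
# ---------------------------------------------------------------------------


@dataclass
class DiscGeometry:
    """Idealised nanodisc: protein cylinder centred in a lipid annulus.

    Defaults model a 21 nm disc (radius 10.5 nm) around a light-harvesting
    trimer footprint (radius 2.5 nm) with dye headgroup planes at z = ±2.3
    nm — the dye chromophores sit outside the bilayer core.
    """

    disc_radius: float = 10.5  # nm
    protein_radius: float = 2.5  # nm
    headgroup_z: float = 2.3  # nm
    n_tr: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.protein_radius < self.disc_radius:
            raise ValueError("need 0 < protein_radius < disc_radius")
        if self.n_tr < 0:
            raise ValueError("n_tr must be non-negative")


#: acceptor-site layout: (label, band, magnitude D, center eV, fwhm eV,
#: rim azimuth deg). Centres follow the usual Chl a/b Qy positions
#: (1.85 eV ≈ 670 nm, 1.91 eV ≈ 650 nm) with a 0.06 eV fwhm; magnitudes are
#: conventional literature-scale values (Chl a Qy 4.0 D, Chl b Qy 3.4 D,
#: Qx 1.0 D). All overridable.
_DEFAULT_ACCEPTORS = [
    ("Chl_a610", "Qy", 4.0, 1.85, 0.06, 0.0),
    ("Chl_a611", "Qy", 4.0, 1.85, 0.06, 50.0),
    ("Chl_a612", "Qy", 4.0, 1.85, 0.06, 100.0),
    ("Chl_b601", "Qy", 3.4, 1.91, 0.06, 180.0),
    ("Chl_b608", "Qy", 3.4, 1.91, 0.06, 260.0),
]


def default_acceptor_sites(
    protein_radius: float = 2.5,
    z: float = -0.9,
    include_qx: bool = True,
) -> list[ChromophoreSite]:
    """Chlorophyll acceptor sites on the protein rim (coordinates in nm).

    Qy dipoles are tangential to the rim; the optional Qx dipole of each Chl
    is the in-plane radial axis (the two Gouterman axes are orthogonal).
    ``z`` defaults to −0.9 nm: the membrane-exposed Chls sit toward the
    luminal leaflet.
    """
    sites = []
    for label, band, mag, center, fwhm, az in _DEFAULT_ACCEPTORS:
        phi = np.deg2rad(az)
        pos = np.array([protein_radius * np.cos(phi), protein_radius * np.sin(phi), z]) * 10.0
        tangent = np.array([-np.sin(phi), np.cos(phi), 0.0])
        radial = np.array([np.cos(phi), np.sin(phi), 0.0])
        sites.append(
            ChromophoreSite(pos, tangent, mag, band, f"{label}:{band}", center, fwhm)
        )
        if include_qx:
            sites.append(
                ChromophoreSite(pos, radial, 1.0, "Qx", f"{label}:Qx", 1.98, 0.06)
            )
    return sites


def gen_disc_geometry(
    geom: DiscGeometry,
    leaflets: "list[int] | None" = None,
    tilt_range_deg: tuple[float, float] = (20.0, 40.0),
    acceptors: "list[ChromophoreSite] | None" = None,
    tr_dipole_magnitude: float = 6.0,
    tr_center_ev: float = 2.05,
    tr_fwhm_ev: float = 0.10,
) -> list[ChromophoreSite]:
    """Place TR dye sites in the lipid annulus around fixed Chl acceptors.

    TR positions are uniform by area in the annulus protein_radius < r <
    disc_radius; each site sits at z = ±headgroup_z according to its leaflet
    flag (+1 stromal, −1 luminal; default all stromal, and flipping the
    flags mirrors the whole dye set to the other membrane face). Dipole
    polar angles are drawn uniformly within ``tilt_range_deg`` off the
    membrane normal, azimuths uniform. Returns acceptor sites followed by
    TR sites; coordinates in Å.
    """
    if geom.disc_radius - geom.protein_radius <= 0:
        raise ValueError("annulus has zero area")
    if leaflets is None:
        leaflets = [1] * geom.n_tr
    if len(leaflets) != geom.n_tr:
        raise ValueError("leaflets must have one flag per TR site")
    rng = np.random.default_rng(geom.seed)
    sites = list(acceptors) if acceptors is not None else default_acceptor_sites(geom.protein_radius)
    lo, hi = np.deg2rad(tilt_range_deg[0]), np.deg2rad(tilt_range_deg[1])
    for i in range(geom.n_tr):
        u = rng.random()
        r = np.sqrt(geom.protein_radius**2 + u * (geom.disc_radius**2 - geom.protein_radius**2))
        phi = rng.random() * 2 * np.pi
        z = geom.headgroup_z * (1 if leaflets[i] >= 0 else -1)
        pos = np.array([r * np.cos(phi), r * np.sin(phi), z]) * 10.0
        theta = lo + rng.random() * (hi - lo)  # polar angle off the membrane normal
        psi = rng.random() * 2 * np.pi
        normal_sign = 1.0 if leaflets[i] >= 0 else -1.0
        dip = np.array(
            [np.sin(theta) * np.cos(psi), np.sin(theta) * np.sin(psi), normal_sign * np.cos(theta)]
        )
        sites.append(
            ChromophoreSite(
                pos, dip, tr_dipole_magnitude, "dye", f"TR{i + 1}", tr_center_ev, tr_fwhm_ev
            )
        )
    return sites


# ---------------------------------------------------------------------------
# Brownian trajectories
# ---------------------------------------------------------------------------

NM2_PER_NS = 1.0e-3  # 1 μm²/s in nm²/ns


def gen_random_walk(
    D: float,
    dt: float,
    n_steps: int,
    n_particles: int,
    seed: int,
):
    """2-D Brownian trajectories with diffusion constant ``D`` (μm² s⁻¹).

    ``dt`` in ns. Per-axis step variance is 2·D·dt (in nm², via
    1 μm²/s = 10⁻³ nm²/ns). Returns a :class:`nanofret.diffusion.Trajectory`
    with positions of shape (n_steps+1, n_particles, 2) in nm.
    """
    from .diffusion import Trajectory  # local import to avoid a cycle

    if D < 0:
        raise ValueError("diffusion constant must be non-negative")
    rng = np.random.default_rng(seed)
    std = np.sqrt(2.0 * D * NM2_PER_NS * dt)
    steps = rng.normal(0.0, std, size=(n_steps, n_particles, 2)) if std > 0 else np.zeros(
        (n_steps, n_particles, 2)
    )
    positions = np.concatenate(
        [np.zeros((1, n_particles, 2)), np.cumsum(steps, axis=0)], axis=0
    )
    times = np.arange(n_steps + 1) * dt
    return Trajectory(times, positions)


# ---------------------------------------------------------------------------
# enhancement self-consistency pair
# ---------------------------------------------------------------------------


def matched_enhancement_pair(
    target_inrange_ratio: float = 3.62,
    target_full_ratio: float = 1.297,
    inrange: tuple[float, float] = (525.0, 625.0),
    full_range: tuple[float, float] = (380.0, 680.0),
    step: float = 1.0,
) -> tuple[Spectrum, Spectrum]:
    """Per-mole acceptor-emission responses whose enhancement integrals hit
    the requested in-range and full-range ratios exactly.

    Models the effective absorption of the acceptor with and without the
    dye: the donor-free response is the acceptor band model, the combined
    response adds a dye-shaped band. Two linear degrees of freedom — the
    dye-band amplitude and the acceptor's blue-band weight — are solved so
    that ∫(with)/∫(without) equals ``target_inrange_ratio`` on ``inrange``
    and ``target_full_ratio`` on ``full_range``. Used as the documented
    self-consistency construction for the enhancement integral; it does not
    reproduce measured spectra.
    """
    lo, hi = full_range
    grid = np.arange(lo, hi + step / 2, step)

    def band(center, fwhm, amp=1.0):
        return amp * np.exp(-4 * np.log(2) * ((grid - center) / fwhm) ** 2)

    # acceptor response: fixed red+blue bands plus a scalable broad green
    # tail (weak vibronic/carotenoid absorption in the green gap)
    red = (
        band(675.0, 22.0, 1.0)
        + band(650.0, 24.0, 0.45)
        + band(435.0, 32.0, 1.15)
        + band(470.0, 34.0, 0.75)
    )
    green = band(560.0, 120.0, 1.0)
    dye = band(590.0, 32.0, 1.0) + band(553.0, 38.0, 0.35)

    def integ(vals, window):
        m = (grid >= window[0]) & (grid <= window[1])
        return np.trapezoid(vals[m], grid[m])

    # unknowns: beta (green-tail weight), alpha (dye amplitude)
    # in-range:  integ(red+beta*green+alpha*dye) = R1 * integ(red+beta*green)
    # full:      integ(red+beta*green+alpha*dye) = R2 * integ(red+beta*green)
    r1, b1, d1 = integ(red, inrange), integ(green, inrange), integ(dye, inrange)
    r2, b2, d2 = integ(red, full_range), integ(green, full_range), integ(dye, full_range)
    k1 = target_inrange_ratio - 1.0
    k2 = target_full_ratio - 1.0
    # alpha*d1 = k1*(r1 + beta*b1);  alpha*d2 = k2*(r2 + beta*b2)
    # → beta = (k2*r2*d1 - k1*r1*d2) / (k1*b1*d2 - k2*b2*d1)
    denom = k1 * b1 * d2 - k2 * b2 * d1
    if abs(denom) < 1e-12:
        raise ValueError("band shapes cannot satisfy both ratio constraints")
    beta = (k2 * r2 * d1 - k1 * r1 * d2) / denom
    alpha = k1 * (r1 + beta * b1) / d1
    if beta < 0 or alpha < 0:
        raise ValueError("requested ratios require a negative band amplitude")
    without = red + beta * green
    with_ = without + alpha * dye
    return (
        Spectrum(grid, with_, kind="emission", label="per-mole response with donor"),
        Spectrum(grid, without, kind="emission", label="per-mole response without donor"),
    )
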