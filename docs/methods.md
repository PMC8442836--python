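# Methods

This note records the models, numerical choices and known limitations of
the package, in the order the pipeline runs.

## Steady-state analysis

Spectral unmixing solves min‖A·c − y‖² with c ≥ 0 (plus an optional signed
constant baseline) via bounded linear least squares; non-negativity is
imposed because component absorbances cannot be negative. All spectra are
linearly resampled onto the intersection of their wavelength grids before
fitting — extrapolation is always an error, never silent. A linearly
dependent basis produces a warning in the result rather than an exception,
since the minimiser is still well defined.

The efficiency arithmetic is deliberately plain: donor quenching
E = 1 − F_DA/F_D assumes the donor-only and donor+acceptor samples are
normalised per mole of donor; the unloaded-particle correction
E_true = E_obs/(1 − f) models a fraction f of particles whose donors have
no acceptor and therefore emit fully unquenched, so the ensemble efficiency
underestimates the per-loaded-particle one. E_obs > 1 − f is reported as an
inconsistency error, never clipped, because it can only arise from a
normalisation mistake upstream. f is an input (typically from
biochemical characterisation); the package does not estimate it.

Emission enhancement is the ratio of trapezoidal integrals of two per-mole
acceptor emission responses versus excitation wavelength, minus one, in
percent. The optional solar weighting uses a coarse 5-nm AM1.5-like
relative irradiance table (`nanofret.solar`). That table is synthetic — a
smooth hand-authored envelope with shallow dips, adequate as a weighting
shape but not the tabulated reference spectrum — so solar-weighted numbers
should be read as indicative (the flat-weighted integrals are exact for
the given inputs).

## TCSPC reconvolution fitting

The decay model is Σᵢ aᵢ·(exp(−t/τᵢ) ⊗ IRF) with aᵢ ≥ 0 (emission decays
have no rise terms; rises belong to the transient-absorption module).
Weighted least squares uses Poisson weights 1/max(count, 1). The
amplitudes enter linearly and are eliminated by non-negative least squares
inside the nonlinear search over log τ (variable projection); the outer
search is multi-start (log-spaced τ sets spanning twice the bin width to
half the record) because multi-exponential fitting is multimodal. Fits are
reported with τ ascending, amplitudes as percentages of the total.

IRF handling: when the trace carries a measured IRF vector, the model is a
discrete convolution on an 8× oversampled grid — the integrand has a kink
at the decay onset, and convolving at the raw bin width biases
sub-nanosecond components by a few percent. When no IRF vector is present,
a Gaussian IRF (t0, fwhm) is fitted jointly using the closed-form
exponential-Gaussian convolution
½·exp(σ²k²/2 − kx)·erfc((σk − x/σ)/√2), evaluated through the scaled
complementary error function for numerical stability. At fwhm → 0 this
reduces to the bare exponential, which is also the tail-fitting mode
(fitting from the peak bin onward).

95% confidence half-widths come from the scaled parameter covariance
(JᵀJ)⁻¹·s² of a joint refinement at the optimum, with the log-τ intervals
mapped by the delta method; amplitude intervals treat the percentage
normalisation as fixed. A fitted τ below the bin width raises a
degenerate-fit error; overfitting a monoexponential trace with two
components instead yields degenerate or negligible-amplitude components
and no significant χ² improvement, which is the caller's cue to prefer the
smaller model.

## Transient-absorption global analysis

The kinetic model is dc/dt = K·c for an n-compartment first-order scheme;
off-diagonal K[j,i] ≥ 0 moves population from i to j and column sums ≤ 0
allow ground-state loss. Sequential chains and acyclic branched networks
are supported; cycles are rejected. Because K is triangular under a
topological order its eigenvalues are real, and the populations are the
Bateman sums of exponentials, convolved analytically with the Gaussian
IRF. Degenerate rate constants are perturbed by 1 part in 10⁹ (with a
warning) to keep the eigenbasis well conditioned; the equal-rate limit is
reproduced to ~10⁻⁴, adequate for fitting, where exactly equal rates are a
measure-zero configuration.

Fitting uses variable projection: for trial time constants (and IRF) the
populations C(t) are analytic and the species spectra solve
S = argmin‖ΔA − C·S‖² by linear least squares; the outer optimiser runs
over log τ (plus t0 and log fwhm when the IRF is fitted) with 8 log-spaced
multi-starts, tie-broken toward the smallest leading τ. The terminal
compartment of a sequential scheme is a true infinity (rate zero) by
default; a finite terminal lifetime must be requested explicitly. The
fitted S rows are the EADS. DADS follow by the eigenmode expansion:
writing c(t) = V·e^{Λt}·V⁻¹c₀, each DADS_l = w_l·Σᵢ V[i,l]·EADSᵢ with
w = V⁻¹c₀, ordered fastest first; their sum equals EADS₁ whenever the
initial population sits in compartment 1. A nearly rank-deficient C
(indistinguishable time constants) adds a degeneracy warning to the
result.

Single-wavelength traces use the same machinery with signed amplitudes
(rise components allowed). A component whose τ exceeds five times the
measurement window is flagged unresolved — with a 0–700 ps window a
nanosecond decay is bounded, not measured.

No wavelength-dependent chirp correction or coherent-artifact model is
included; the IRF is one global Gaussian. That is a real limitation for
broadband visible probes and the first thing to add for instrument data.

## Förster engine

Couplings use the point-dipole approximation in the Debye–nm–cm⁻¹ system,
J(cm⁻¹) = 5.04·κ·μ_D·μ_A/(n²·r³), converted to meV (8.06554 cm⁻¹/meV);
the 5.04 prefactor is the conventional rounding of the SI evaluation
μ²/(4πε₀r³) = 5.034 cm⁻¹ for 1 D², 1 nm, and the tests pin it against
that SI oracle. Screening enters as 1/n² with default n² = 2.0, a generic
membrane/protein optical dielectric — configurable, and worth revisiting
for any quantitative comparison. Sites closer than 0.1 nm are rejected:
the point-dipole form is meaningless there, and it is already quantitative
only beyond roughly molecular dimensions (~1 nm). No transition-density or
excitonic corrections are attempted.

Transition lineshapes are unit-area Gaussians on the energy axis
(σ = fwhm/2.3548). Defaults: Chl a Qy 1.85 eV, Chl b Qy 1.91 eV, Qx
1.98 eV, all 0.06 eV fwhm; dye 2.05 eV, 0.10 eV fwhm; dipole magnitudes
Chl a Qy 4.0 D, Chl b Qy 3.4 D, Qx 1.0 D, dye 6.0 D. These are
conventional literature-scale stand-ins for system–bath lineshape
calculations, and every one is overridable per site or via config.
Spectral overlaps Θ = ∫f_D(E)a_A(E)dE are computed by trapezoid on a
common energy grid; wavelength spectra are converted with the Jacobian
|dE/dλ| = E²/hc and renormalised, so an experimentally derived donor
emission spectrum can replace the Gaussian. Rates are golden-rule,
k = (2π/ħ)|J|²Θ, and a donor's total rate is the plain sum over acceptor
transitions, with transfer time 1/k_total.

Distance scans translate the donor in the membrane plane (z preserved)
along the line to a target point, computing the total rate at each lateral
separation; a 0.5 nm guard skips unphysical requests. The
`isotropic_avg` mode replaces κ² by 2/3 — the dynamic-averaging value,
which the Monte-Carlo test recovers to ±0.005 — for time-averaged dipoles.
The R₀ route, R₀⁶(Å⁶) = 8.79×10⁻⁵·κ²·n⁻⁴·φ_D·J_λ with
J_λ = ∫F_D ε_A λ⁴dλ/∫F_D dλ, is kept deliberately independent of the
golden-rule route; a test verifies the two agree within 5% on a toy
Gaussian pair when bridged by the standard dipole-strength relations.

## Diffusion analysis

MSD is time-averaged over all window pairs per lag (FFT autocorrelation
algorithm, O(n log n)) and ensemble-averaged over particles. The diffusion
constant is the ordinary-least-squares slope over lags in 10–50% of the
maximum lag, divided by 2·dims; the window default avoids short-lag noise
and the statistics collapse at long lags, and the unit conversion is
1 nm²/ns = 1000 μm²/s. A negative fitted slope (possible for short,
noisy records) warns and clips D at zero. Dipole tilt angles are folded to
[0°, 90°] because transition dipoles are axes, not directions.

## Synthetic data: what it does and does not emulate

The generators define the conditions under which the pipeline is tested.
Spectra are sums of Gaussian bands with the system's peak positions (dye
absorption 590 nm, emission 614/673 nm; Chl a absorption ~675 nm, emission
682/735 nm); the dye vibronic amplitude is fixed at 0.2 of the 0–0 band,
an arbitrary but documented choice, and Voigt profiles are not used
because the rate engine itself assumes Gaussian lineshapes. Decays are
exact multi-exponentials with Poisson counting noise; TA maps are exact
compartmental kinetics with white Gaussian noise. The default nanodisc is
a 10.5 nm disc with a 2.5 nm protein cylinder and dye headgroup planes at
±2.3 nm; dyes are uniform by area in the lipid annulus with tilt angles
drawn from 20–40° off the membrane normal, and leaflet assignment is an
explicit flag (so a stromal set can be mirrored to the luminal face
deterministically rather than at random). Acceptor chlorophylls sit on the
protein rim at five azimuths, z = −0.9 nm, with tangential Qy and radial
Qx axes. Brownian walks are ideal 2-D Gaussian steps of per-axis variance
2·D·dt.

None of this reproduces real-data pathologies: detector afterpulsing and
pile-up, scattering backgrounds, probe chirp, anisotropic or anomalous
diffusion, conformational heterogeneity of the protein, or correlated
spectral noise. Passing tests therefore demonstrate the correctness of the
estimators on their stated models and their noise robustness at realistic
counting statistics — not instrument-grade calibration.

The per-mole enhancement pair used for the integral checks is a
self-consistency construction: two of its band amplitudes (the dye band
and the acceptor's broad green tail) are solved analytically so that the
525–625 nm integral ratio is exactly 3.62 and the 380–680 nm ratio exactly
1.297, and the enhancement integrals are then evaluated on it. It anchors
the integral definitions, not the underlying spectra.

## Problem sizes

Default test and reproduction sizes are chosen as typical desk-scale
analyses: 2000-bin decays at 10⁴ peak counts, 136×47 TA maps at
signal-to-noise ≈ 50, 10⁶ orientation samples, and walks of 10 particles ×
2×10⁴ steps, with Monte-Carlo statements averaged over 5–40 seeds.
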