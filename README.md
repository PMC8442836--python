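# nanofret

Analysis toolkit for excitation-energy transfer between lipid-linked dyes
and membrane light-harvesting proteins in lipid nanodiscs — the kind of
biohybrid system in which Texas Red (TR) labelled lipids act as extra
antenna pigments feeding plant light-harvesting complex II (LHCII).

It is written for spectroscopists and modellers who need to take such a
system from raw optical data to transfer rates:

- **Steady-state analysis** — non-negative spectral unmixing, Beer–Lambert
  concentration arithmetic, donor-quenching FRET efficiencies
  *E = 1 − F_DA/F_D*, the donor-only-particle correction
  *E_true = E_obs/(1 − f)*, and emission-enhancement integrals (flat or
  solar-weighted).
- **Time-resolved fluorescence (TCSPC)** — multi-exponential reconvolution
  fitting with Poisson weights and a measured or fitted Gaussian IRF;
  amplitude-weighted lifetimes ⟨τ⟩ = Σ Aᵢτᵢ/100 and lifetime-based
  efficiencies *E = 1 − τ_DA/τ_D*.
- **Transient-absorption global analysis** — sequential or branched
  first-order compartmental schemes fitted to ΔA(t, λ) maps by variable
  projection, with analytic (Bateman) populations, Gaussian-IRF
  convolution in closed form, and EADS/DADS extraction.
- **Structure-based Förster rates** — point-dipole couplings
  J = 5.04·κ·μ_D·μ_A/(n²r³) cm⁻¹ with the orientation factor
  κ = d̂_D·d̂_A − 3(d̂_D·r̂)(d̂_A·r̂), Gaussian lineshapes, energy-axis
  spectral overlaps Θ, golden-rule rates k = (2π/ħ)|J|²Θ, per-donor
  totals, distance scans, and the spectroscopist's R₀ route
  (R₀⁶ = 8.79×10⁻⁵ κ² n⁻⁴ φ_D J_λ Å⁶).
- **Diffusion analysis** — FFT-based time/ensemble-averaged mean-square
  displacements, diffusion constants from MSD slopes (MSD = 2·d·D·Δt), and
  transition-dipole tilt statistics.
- **Synthetic data** — seeded generators for band-model spectra, noisy
  decays, TA maps from kinetic schemes, nanodisc chromophore geometries
  and 2-D Brownian trajectories, so the whole pipeline runs and is tested
  without any instrument data.

## Worked example

Fit a biexponential donor decay (truth: 58.8% of 0.32 ns + 41.2% of
2.64 ns, 10⁴ peak counts, 0.15 ns IRF) and globally analyse a noisy TA map
generated from a sequential 3.7 ps → 128 ps → ∞ transfer scheme:

```python
import numpy as np
from nanofret import synth, trfs, ta

grid = np.arange(0.0, 25.0, 0.0125)                      # ns
trace = synth.gen_decay([58.8, 41.2], [0.32, 2.64], irf_fwhm=0.15, t0=1.0,
                        grid=grid, peak_counts=1e4, seed=1)
res = trfs.MultiExponentialDecayModel(trace, n_components=2).fit()
print(res.summary())

wl = np.arange(560.0, 700.0, 3.0)                        # nm
times = np.concatenate([np.linspace(-2, 5, 36), np.geomspace(5.5, 700, 100)])
m = synth.gen_ta_map("sequential", [3.7, 128.0],
                     synth.default_species_spectra(wl), 0.3, times, 0.02, seed=1)
g = ta.GlobalTAModel(m, scheme="sequential", n_components=3, fit_irf=True).fit()
print(g.summary())
```

Output:

```
Multi-exponential decay fit
  mode: reconvolution   components: 2   chi2_red: 0.984
       A (%)     tau (ns)   ±95% tau
        58.3       0.3129     0.0049
        41.7       2.6178     0.0063
  <tau> = 1.2752 ns (amplitude-weighted)

Global transient-absorption fit
  scheme: sequential   compartments: 3   chi2_red: 0.0003995
  IRF: t0 = 0.002 ps, fwhm = 0.291 ps
  EADS1: tau = 3.766 ± 0.11 ps
  EADS2: tau = 128.6 ± 3.3 ps
  EADS3: tau = inf ps
```

The decay fit recovers the generating amplitudes and time constants with a
reduced χ² near 1 and ⟨τ⟩ = 1.275 ns against a truth of 1.276 ns; the
global fit recovers both transfer time constants within a few percent at a
signal-to-noise ratio of about 50, together with the IRF width it was
generated with. `g.eads` and `g.dads` hold the associated
evolution/decay-associated difference spectra.

A donor quenched from ⟨τ⟩ = 3.94 ns to 1.28 ns corresponds to a transfer
efficiency of 68% (`trfs.fret_efficiency_from_lifetimes(1.28, 3.94)`), and
residual steady-state donor emission of 38% to 62%
(`steady_state.fret_efficiency_donor_quenching(0.38, 1.0)`); with 35% of
particles carrying no acceptor the per-loaded-particle efficiency rises to
95.4% (`steady_state.correct_unloaded_fraction(0.62, 0.35)`).

There is also a CLI (`nanofret simulate | steady-state | fit-decay |
fit-ta | forster | diffusion`) operating on plain CSV/PDB-subset files; see
`nanofret --help`.

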