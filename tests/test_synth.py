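"""Synthetic generators: determinism, limiting cases, statistical structure."""

import numpy as np
import pytest
from scipy.integrate import trapezoid

from nanofret import diffusion, synth, trfs
from nanofret.synth import BandModel, DiscGeometry


class TestGenSpectrum:
    def test_single_band_peak(self):
        grid = np.arange(400.0, 701.0, 1.0)
        s = synth.gen_spectrum(BandModel([(590.0, 30.0, 1.0)]), grid)
        assert grid[np.argmax(s.values)] == 590.0
        assert s.values.max() == pytest.approx(1.0)

    def test_linearity(self):
        grid = np.arange(400.0, 701.0, 1.0)
        one = synth.gen_spectrum(BandModel([(590.0, 30.0, 1.0)]), grid)
        two = synth.gen_spectrum(BandModel([(590.0, 30.0, 1.0)] * 2), grid)
        np.testing.assert_allclose(two.values, 2 * one.values, rtol=1e-12)

    def test_tr_emission_preset_peaks(self):
        grid = np.arange(560.0, 760.0, 0.5)
        s = synth.gen_spectrum(synth.preset_band_model("TR_emission"), grid)
        assert grid[np.argmax(s.values)] == pytest.approx(614.0, abs=1.0)
        # secondary local maximum at the vibronic band
        interior = (
            (s.values[1:-1] > s.values[:-2]) & (s.values[1:-1] > s.values[2:])
        )
        peaks = grid[1:-1][interior]
        assert np.any(np.abs(peaks - 673.0) < 2.0)

    def test_empty_band_list_rejected(self):
        with pytest.raises(ValueError):
            BandModel([])


class TestGenDecay:
    grid = np.arange(0.0, 30.0, 0.01)

    def test_delta_irf_limit_is_pure_exponential(self):
        tr = synth.gen_decay([100.0], [4.0], 0.0, 0.0, self.grid, 1e4, seed=0, noise=False)
        t = self.grid
        expected = 1e4 * np.exp(-t / 4.0)
        np.testing.assert_allclose(tr.counts, expected, rtol=1e-10)

    def test_seed_determinism(self):
        a = synth.gen_decay([100.0], [4.0], 0.1, 1.0, self.grid, 1e4, seed=7)
        b = synth.gen_decay([100.0], [4.0], 0.1, 1.0, self.grid, 1e4, seed=7)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_noiseless_integral_matches_amplitude_weighted_sum(self):
        # ∫ model dt = scale · Σ Aᵢτᵢ/100 for a delta IRF starting at t0=0
        amps, taus = [58.8, 41.2], [0.32, 2.64]
        tr = synth.gen_decay(amps, taus, 0.0, 0.0, self.grid, 1e4, seed=0, noise=False)
        scale = 1e4  # peak of Σ Aᵢ/100 exp(0) = 1 → scale = peak_counts
        expected = scale * np.dot(amps, taus) / 100.0
        assert trapezoid(tr.counts, tr.times) == pytest.approx(expected, rel=1e-3)

    def test_amplitude_sum_validated(self):
        with pytest.raises(ValueError, match="sum to 100"):
            synth.gen_decay([50.0, 40.0], [1.0, 2.0], 0.1, 1.0, self.grid, 1e4, seed=0)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            synth.gen_decay([100.0], [-1.0], 0.1, 1.0, self.grid, 1e4, seed=0)

    def test_round_trip_recovery_of_average_lifetime(self):
        # Monte-Carlo: generated from the biexponential truth used throughout,
        # <tau> = 0.588*0.32 + 0.412*2.64 = 1.276 ns
        grid = np.arange(0.0, 25.0, 0.0125)
        truth = 1.276
        vals = []
        for seed in range(3):
            tr = synth.gen_decay([58.8, 41.2], [0.32, 2.64], 0.15, 1.0, grid, 1e4, seed=seed)
            vals.append(trfs.fit_multiexponential(tr, 2).tau_avg)
        assert abs(np.mean(vals) - truth) / truth < 0.03


class TestGenTAMap:
    wl = np.arange(560.0, 700.0, 4.0)
    times = np.linspace(0.0, 50.0, 200)

    def test_single_compartment_columns_exponential(self):
        spec = synth.default_species_spectra(self.wl, 1)
        m = synth.gen_ta_map("sequential", [5.0], spec, 0.0, self.times, 0.0, 0,
                             terminal_infinite=False)
        ref = np.exp(-self.times / 5.0)
        for j in range(self.wl.size):
            col = m.delta_A[:, j]
            if np.abs(col[0]) > 1e-12:
                np.testing.assert_allclose(col / col[0], ref, atol=1e-10)

    def test_noiseless_fit_recovers_taus(self):
        from nanofret import ta

        spec = synth.default_species_spectra(self.wl, 3)
        times = np.concatenate([np.linspace(0, 5, 30), np.geomspace(5.5, 700, 80)])
        m = synth.gen_ta_map("sequential", [3.7, 128.0], spec, 0.0, times, 0.0, 0)
        res = ta.fit_global(m, "sequential", 3)
        np.testing.assert_allclose(res.taus[:2], [3.7, 128.0], rtol=1e-6)

    def test_grid_mismatch_rejected(self):
        s1 = synth.default_species_spectra(self.wl, 1)[0]
        s2 = synth.default_species_spectra(self.wl + 1.0, 1)[0]
        with pytest.raises(ValueError, match="share"):
            synth.gen_ta_map("sequential", [5.0], [s1, s2], 0.0, self.times, 0.0, 0)


class TestDiscGeometry:
    def test_empty_case_only_acceptors(self):
        sites = synth.gen_disc_geometry(DiscGeometry(n_tr=0, seed=1))
        assert all("TR" not in s.label for s in sites)
        assert len(sites) == 10  # 5 Chls × (Qy + Qx)

    def test_radial_support(self):
        geom = DiscGeometry(n_tr=200, seed=3)
        sites = synth.gen_disc_geometry(geom, leaflets=[1] * 200)
        tr = [s for s in sites if s.label.startswith("TR")]
        r = np.array([np.hypot(s.position[0], s.position[1]) / 10.0 for s in tr])
        assert np.all(r > geom.protein_radius) and np.all(r < geom.disc_radius)
        z = np.array([s.position[2] / 10.0 for s in tr])
        np.testing.assert_allclose(z, geom.headgroup_z)

    def test_dipole_tilt_range(self):
        sites = synth.gen_disc_geometry(DiscGeometry(n_tr=100, seed=4), leaflets=[1] * 100)
        tr = [s for s in sites if s.label.startswith("TR")]
        ang = diffusion.dipole_angles([s.dipole_unit for s in tr], [0, 0, 1])
        assert ang.min() >= 20.0 - 1e-9 and ang.max() <= 40.0 + 1e-9

    def test_leaflet_flip_mirrors_z(self):
        up = synth.gen_disc_geometry(DiscGeometry(n_tr=5, seed=5), leaflets=[1] * 5)
        down = synth.gen_disc_geometry(DiscGeometry(n_tr=5, seed=5), leaflets=[-1] * 5)
        for a, b in zip(up[-5:], down[-5:]):
            assert a.position[2] == -b.position[2]

    def test_mean_nearest_neighbour_distance_near_4nm(self):
        # 1 TR per 75 lipids at 0.65 nm²/lipid in a 10.5 nm disc with a
        # 2.5 nm protein → ~7 dyes; Poisson-process nearest-neighbour
        # spacing lands near the 4 nm scale
        geom_area = np.pi * (10.5**2 - 2.5**2)
        n_tr = round(geom_area / (75 * 0.65))
        dists = []
        for seed in range(40):
            sites = synth.gen_disc_geometry(
                DiscGeometry(n_tr=n_tr, seed=seed), leaflets=[1] * n_tr
            )
            pos = np.array([s.position[:2] for s in sites if s.label.startswith("TR")]) / 10.0
            d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            dists.append(d.min(axis=1).mean())
        assert abs(np.mean(dists) - 4.0) / 4.0 < 0.2


class TestRandomWalk:
    def test_zero_D_stationary(self):
        traj = synth.gen_random_walk(0.0, 1.0, 100, 5, seed=0)
        assert np.all(traj.positions == 0)

    def test_step_variance_construction(self):
        D, dt = 8.4, 1.0
        traj = synth.gen_random_walk(D, dt, 100000, 1, seed=1)
        steps = np.diff(traj.positions[:, 0, 0])
        assert np.var(steps) == pytest.approx(2 * D * 1e-3 * dt, rel=0.05)

    def test_negative_D_rejected(self):
        with pytest.raises(ValueError):
            synth.gen_random_walk(-1.0, 1.0, 10, 1, seed=0)

    def test_determinism(self):
        a = synth.gen_random_walk(5.0, 1.0, 50, 2, seed=9)
        b = synth.gen_random_walk(5.0, 1.0, 50, 2, seed=9)
        np.testing.assert_array_equal(a.positions, b.positions)
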