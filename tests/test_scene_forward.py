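"""Scene representation and the forward imaging model."""

import numpy as np
import pytest

import psim
from psim.scene import absorption_efficiency, illumination_pattern
from psim._utils import orientation_difference_deg


class TestAbsorptionEfficiency:
    @pytest.mark.parametrize("alpha,theta,eta,expected", [
        (0.0, 0.0, 1.0, 1.0),      # parallel dipole: maximum absorption
        (90.0, 0.0, 1.0, 0.0),     # perpendicular dipole: not excited
        (45.0, 0.0, 2.0, 1.0),     # cos^2 45 = 1/2, times eta = 2
    ])
    def test_malus_values(self, alpha, theta, eta, expected):
        assert absorption_efficiency(alpha, theta, eta) == pytest.approx(expected, abs=1e-12)

    def test_period_180_in_both_arguments(self):
        a = np.linspace(0, 360, 37)
        assert np.allclose(absorption_efficiency(a, 20.0),
                           absorption_efficiency(a + 180.0, 20.0))
        assert np.allclose(absorption_efficiency(33.0, a),
                           absorption_efficiency(33.0, a + 180.0))

    def test_rejects_nonpositive_eta(self):
        with pytest.raises(ValueError):
            absorption_efficiency(0.0, 0.0, 0.0)


class TestIlluminationPattern:
    def make_state(self, k, phase, intensity=2.0, m=1.0):
        return psim.IlluminationState(0, k, phase, 0.0, modulation=m,
                                      intensity=intensity)

    def test_peak_and_null_of_stripe(self):
        # k . r = 0 at the origin pixel
        st = self.make_state((0.0, 1e-3), 0.0)
        assert illumination_pattern((4, 4), 20.0, st)[0, 0] == pytest.approx(2.0)
        st = self.make_state((0.0, 1e-3), np.pi)
        assert illumination_pattern((4, 4), 20.0, st)[0, 0] == pytest.approx(0.0)

    def test_mean_over_full_periods_is_half_intensity(self):
        # 4 full cycles across 64 px
        st = self.make_state((0.0, 4 / (64 * 20.0)), 1.234, intensity=1.0)
        pat = illumination_pattern((1, 64), 20.0, st)
        assert pat.mean() == pytest.approx(0.5, abs=1e-12)

    def test_rejects_super_nyquist_stripes(self):
        st = self.make_state((0.0, 0.6 / 20.0), 0.0)
        with pytest.raises(ValueError, match="Nyquist"):
            illumination_pattern((8, 8), 20.0, st)


class TestRenderScene:
    def test_filament_along_x_has_mass_at_zero_degrees(self):
        sc = psim.render_scene("filament", points_nm=[[2560, 500], [2560, 4500]],
                               shape=(256, 256), pixel_nm=20.0, width_nm=40.0)
        m = sc.total_density() > 0.5 * sc.total_density().max()
        assert np.abs(orientation_difference_deg(sc.mean_orientation_deg()[m], 0.0)).max() < 0.1

    def test_circle_tangent_geometry(self):
        sc = psim.render_scene("circles", radii_nm=[1500.0], shape=(256, 256),
                               pixel_nm=20.0, width_nm=60.0)
        orient = sc.mean_orientation_deg()
        dens = sc.total_density()
        c = (256 - 1) / 2
        top = (int(round(c - 1500 / 20.0)), int(round(c)))     # 12 o'clock
        right = (int(round(c)), int(round(c + 1500 / 20.0)))   # 3 o'clock
        assert dens[top] > 0 and dens[right] > 0
        assert abs(orientation_difference_deg(orient[top], 0.0)) < 2.0
        assert abs(orientation_difference_deg(orient[right], 90.0)) < 2.0

    def test_bead_field_is_isotropic_per_pixel(self):
        sc = psim.render_scene("bead_field", n_beads=20, shape=(64, 64),
                               pixel_nm=20.0, rng=0)
        d = sc.density
        occupied = sc.total_density() > 0
        spread = d[occupied].max(axis=-1) - d[occupied].min(axis=-1)
        assert spread.max() < 1e-12 * d.max()

    def test_oblique_filament_orientation_encoding(self):
        # the two-bin angular interpolation keeps arbitrary orientations to
        # well under a tenth of a degree
        for phi in (17.0, 63.0, 121.5):
            c, L = 2560.0, 1500.0
            dy, dx = np.sin(np.deg2rad(phi)), np.cos(np.deg2rad(phi))
            sc = psim.render_scene(
                "filament", points_nm=[[c - L * dy, c - L * dx], [c + L * dy, c + L * dx]],
                shape=(256, 256), pixel_nm=20.0, width_nm=40.0)
            m = sc.total_density() > 0.5 * sc.total_density().max()
            err = orientation_difference_deg(sc.mean_orientation_deg()[m], phi)
            assert np.abs(err).max() < 0.1

    def test_subpixel_structures_rejected(self):
        with pytest.raises(ValueError, match="thinner than one pixel"):
            psim.render_scene("filament", points_nm=[[100, 100], [100, 2000]],
                              shape=(128, 128), pixel_nm=20.0, width_nm=10.0)

    def test_scene_invariants_enforced(self):
        with pytest.raises(ValueError, match="non-negative"):
            psim.DipoleScene(-np.ones((8, 8, 5)), 20.0, np.arange(5) * 36.0)
        with pytest.raises(ValueError, match="tile"):
            psim.DipoleScene(np.ones((8, 8, 5)), 20.0, np.arange(5) * 30.0)
        with pytest.raises(ValueError, match="at least 3"):
            psim.DipoleScene(np.ones((8, 8, 2)), 20.0, np.arange(2) * 90.0)


class TestSimulateAcquisition:
    def test_zero_scene_gives_zero_frames(self, protocol):
        sc = psim.DipoleScene(np.zeros((64, 64, 5)), 80.0, np.arange(5) * 36.0)
        stack = psim.simulate_acquisition(sc, protocol)
        assert np.all(stack.images == 0)

    def test_matches_dense_brute_force_evaluation(self, protocol):
        """Forward-model oracle: FFT pipeline vs direct summation over (r', alpha)."""
        rng = np.random.default_rng(0)
        n, na = 32, 5
        dens = rng.uniform(0, 1, (n, n, na))
        scene = psim.DipoleScene(dens, 80.0, np.arange(na) * 36.0)
        stack = psim.simulate_acquisition(scene, protocol)

        otf = protocol.optics.otf_grid((n, n), pixel_nm=80.0)
        psf = np.real(np.fft.ifft2(np.fft.ifftshift(otf)))
        states = protocol.states()
        idx = np.arange(n)
        for i in range(3):
            fa = absorption_efficiency(scene.angles_deg, protocol.thetas_deg[i],
                                       protocol.eta)
            for j in range(3):
                pat = illumination_pattern((n, n), 80.0, states[i][j])
                w = (dens * fa).sum(axis=2) * scene.delta_alpha_rad * pat
                D = np.empty((n, n))
                for y in range(n):
                    for x in range(n):
                        D[y, x] = (psf[(y - idx[:, None]) % n,
                                       (x - idx[None, :]) % n] * w).sum()
                rel = np.abs(D - stack.images[i, j]).max() / np.abs(D).max()
                assert rel < 1e-10

    def test_isotropic_scene_phase_averages_equal_across_directions(self, protocol):
        sc = psim.render_scene("bead_field", n_beads=30, shape=(256, 256),
                               pixel_nm=20.0, rng=1)
        stack = psim.simulate_acquisition(sc, protocol)
        means = stack.images.mean(axis=1)  # phase average per direction
        assert np.allclose(means[0], means[1], rtol=1e-9, atol=1e-12)
        assert np.allclose(means[0], means[2], rtol=1e-9, atol=1e-12)

    def test_unmodulated_isotropic_gives_nine_equal_frames(self):
        proto = psim.AcquisitionProtocol(modulation=0.0)
        sc = psim.render_scene("bead_field", n_beads=30, shape=(128, 128),
                               pixel_nm=20.0, rng=2)
        stack = psim.simulate_acquisition(sc, proto)
        ref = stack.images[0, 0]
        assert np.allclose(stack.images, ref[None, None], rtol=1e-9, atol=1e-12)

    def test_noise_is_seed_reproducible(self, star_scene, protocol):
        a = psim.simulate_acquisition(star_scene, protocol, photon_scale=200,
                                      read_sigma=1.0, seed=11)
        b = psim.simulate_acquisition(star_scene, protocol, photon_scale=200,
                                      read_sigma=1.0, seed=11)
        c = psim.simulate_acquisition(star_scene, protocol, photon_scale=200,
                                      read_sigma=1.0, seed=12)
        assert np.array_equal(a.images, b.images)
        assert not np.array_equal(a.images, c.images)

    def test_input_validation(self, star_scene, protocol):
        with pytest.raises(ValueError, match="read_sigma"):
            psim.simulate_acquisition(star_scene, protocol, read_sigma=-1.0)
        bad = psim.DipoleScene(np.zeros((100, 100, 5)), 30.0, np.arange(5) * 36.0)
        with pytest.raises(ValueError, match="integer multiple"):
            psim.simulate_acquisition(bad, protocol)


class TestPolarizedDetection:
    def make_state(self, n=64, cycles=4, theta=0.0):
        return psim.IlluminationState(0, (0.0, cycles / (n * 20.0)), 0.0, theta)

    def test_malus_law_on_fixed_dipole_layer(self):
        na = 36
        dens = np.zeros((32, 32, na))
        dens[:, :, 6] = 1.0  # all dipoles at 30 degrees
        sc = psim.DipoleScene(dens, 20.0, np.arange(na) * 5.0)
        st = self.make_state(n=32, theta=30.0)
        img = psim.simulate_polarized_detection(sc, st, [30.0, 120.0])
        assert img[0].max() > 0
        assert np.abs(img[1]).max() < 1e-12 * img[0].max()

    def test_empty_analyzer_list_rejected(self):
        sc = psim.render_scene("uniform", shape=(16, 16), pixel_nm=20.0)
        with pytest.raises(ValueError, match="empty"):
            psim.simulate_polarized_detection(sc, self.make_state(16), [])

    def test_x_alpha_image_has_nine_harmonics(self):
        """Product of two three-term cosine expansions: 1 DC + 2 spatial
        + 2 angular + 4 cross peaks."""
        sc = psim.render_scene("uniform", shape=(64, 64), pixel_nm=20.0,
                               n_angles=36)
        img = psim.simulate_polarized_detection(sc, self.make_state(64),
                                                np.arange(9) * 20.0)
        cat = psim.count_harmonics(img.T)  # axes (x, analyzer); analyzer is angular
        assert cat.n_peaks == 9
        assert cat.counts == {"dc": 1, "spatial": 2, "angular": 2, "cross": 4}
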