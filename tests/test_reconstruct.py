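"""Spectral assembly, the full pSIM pipeline, and the ablation experiment."""

import numpy as np
import pytest
import scipy.signal

import psim
from psim.harmonics import separate_components
from psim.reconstruct import assemble_direction, assemble_sim
from psim._utils import circular_rms_deg, orientation_difference_deg

from conftest import make_two_line_scene


def separated(stack, protocol):
    return [separate_components(stack.images[i], protocol.phases_rad[i])
            for i in range(3)]


def k_px(protocol, pixel_nm=80.0):
    return [protocol.k_vecs_nm[i] * pixel_nm for i in range(3)]


class TestAssembleSim:
    def test_zero_components_give_zero_image(self, protocol):
        zero = separate_components(np.zeros((3, 32, 32)), protocol.phases_rad[0])
        img = assemble_sim([zero] * 3, k_px(protocol), protocol.optics, 80.0)
        assert np.allclose(img, 0.0)

    def test_two_lines_below_abbe_resolved_by_sim_not_widefield(self, protocol):
        """130 nm line pair: below the ~218 nm widefield Abbe limit, above the
        SIM limit for the default stripe frequency."""
        scene = make_two_line_scene(130.0)
        stack = psim.simulate_acquisition(scene, protocol)
        sim = assemble_sim(separated(stack, protocol), k_px(protocol),
                           protocol.optics, 80.0)
        wf = psim.reconstruct_widefield(stack)
        # central row profiles across the line pair
        sim_prof = sim[sim.shape[0] // 2, sim.shape[1] // 2 - 8:sim.shape[1] // 2 + 9]
        wf_prof = wf[wf.shape[0] // 2, wf.shape[1] // 2 - 8:wf.shape[1] // 2 + 9]
        sim_peaks, _ = scipy.signal.find_peaks(sim_prof)
        wf_peaks, _ = scipy.signal.find_peaks(wf_prof)
        assert len(sim_peaks) >= 2
        assert len(wf_peaks) == 1

    def test_bead_fwhm_ratio_below_065(self, protocol):
        dens = np.zeros((256, 256, 15))
        dens[:, :, :] = 0.0
        dens[127:129, 127:129, :] = 1.0 / 15  # sub-diffraction emitter
        bead = psim.DipoleScene(dens, 20.0, np.arange(15) * 12.0)
        stack = psim.simulate_acquisition(bead, protocol)
        sim = assemble_sim(separated(stack, protocol), k_px(protocol),
                           protocol.optics, 80.0)
        wf = psim.reconstruct_widefield(stack)

        def fwhm(img, px):
            y, _ = np.unravel_index(np.argmax(img), img.shape)
            line = img[y].astype(float)
            xs = np.linspace(0, line.size - 1, line.size * 20)
            li = np.interp(xs, np.arange(line.size), line)
            above = xs[li >= line.max() / 2]
            return (above.max() - above.min()) * px

        assert fwhm(sim, 40.0) / fwhm(wf, 80.0) < 0.65


class TestReconstructPsim:
    def test_radial_star_orientation_both_assembly_modes(self, star_stack,
                                                         star_truth):
        alpha_gt, habs = star_truth
        m0 = habs > 0.2 * habs.max()
        for mode in ("hyperspace", "perdir"):
            res = psim.reconstruct_psim(
                star_stack, cfg=psim.PsimConfig(phases="nominal", assembly=mode))
            m = res.mask & m0
            assert m.sum() > 1000
            assert circular_rms_deg(res.orientation_deg, alpha_gt, m) < 2.0

    def test_assembly_modes_agree_on_orientation(self, star_stack, star_truth):
        _, habs = star_truth
        r1 = psim.reconstruct_psim(star_stack, cfg=psim.PsimConfig(phases="nominal"))
        r2 = psim.reconstruct_psim(
            star_stack, cfg=psim.PsimConfig(phases="nominal", assembly="perdir"))
        m = r1.mask & r2.mask & (habs > 0.2 * habs.max())
        assert circular_rms_deg(r1.orientation_deg, r2.orientation_deg, m) < 2.0

    def test_estimated_phases_match_nominal_reconstruction(self, star_stack,
                                                           star_truth):
        alpha_gt, habs = star_truth
        res = psim.reconstruct_psim(star_stack, cfg=psim.PsimConfig(phases="estimate"))
        m = res.mask & (habs > 0.2 * habs.max())
        assert circular_rms_deg(res.orientation_deg, alpha_gt, m) < 2.0

    def test_tangled_filaments_keep_their_own_orientation(self, protocol):
        """Two crossing filaments with tangential dipoles: away from the
        crossing each filament's reconstructed orientation matches its own
        tangent within 5 degrees."""
        a = psim.render_scene("filament", points_nm=[[1200, 800], [3900, 4300]],
                              shape=(256, 256), pixel_nm=20.0, width_nm=60.0,
                              normalize=False)
        b = psim.render_scene("filament", points_nm=[[3900, 800], [1200, 4300]],
                              shape=(256, 256), pixel_nm=20.0, width_nm=60.0,
                              normalize=False)
        scene = psim.DipoleScene(a.density + b.density, 20.0, a.angles_deg)
        scene.density /= scene.total_density().max()
        stack = psim.simulate_acquisition(scene, protocol)
        res = psim.reconstruct_psim(stack, cfg=psim.PsimConfig(phases="nominal"))
        h = scene.angular_harmonic().reshape(128, 2, 128, 2).sum(axis=(1, 3))
        s0 = scene.total_density().reshape(128, 2, 128, 2).sum(axis=(1, 3))
        # non-crossing pixels: angular mass concentrated, |h| close to s0
        single = (np.abs(h) > 0.9 * s0) & (s0 > 0.3 * s0.max())
        gt = np.mod(np.rad2deg(np.angle(h) / 2.0), 180.0)
        m = res.mask & single
        assert m.sum() > 300
        d = np.abs(orientation_difference_deg(res.orientation_deg[m], gt[m]))
        assert np.percentile(d, 95) < 5.0

    def test_isotropic_scene_orientation_fully_masked(self, protocol):
        scene = psim.render_scene("bead_field", n_beads=40, shape=(256, 256),
                                  pixel_nm=20.0, rng=7)
        stack = psim.simulate_acquisition(scene, protocol)
        res = psim.reconstruct_psim(stack, cfg=psim.PsimConfig(phases="nominal"))
        assert not res.mask.any()
        assert np.abs(res.polarization_factor).max() < 1e-6

    def test_intensity_consistent_with_sim_assembly_on_smooth_scene(self, protocol):
        yy, xx = np.mgrid[0:256, 0:256]
        blob = np.exp(-((yy - 128) ** 2 + (xx - 128) ** 2) / (2 * 40.0 ** 2))
        dens = np.zeros((256, 256, 15))
        dens[:, :, 3] = blob
        scene = psim.DipoleScene(dens, 20.0, np.arange(15) * 12.0)
        stack = psim.simulate_acquisition(scene, protocol)
        res = psim.reconstruct_psim(stack, cfg=psim.PsimConfig(phases="nominal"))
        sim = assemble_sim(separated(stack, protocol), k_px(protocol),
                           protocol.optics, 80.0, clip_negative=False)
        m = res.mask
        a = res.intensity[m] / res.intensity[m].mean()
        b = sim[m] / sim[m].mean()
        assert np.linalg.norm(a - b) / np.linalg.norm(b) < 0.02

    def test_bit_identical_for_identical_inputs(self, star_stack):
        cfg = psim.PsimConfig(phases="nominal")
        r1 = psim.reconstruct_psim(star_stack, cfg=cfg)
        r2 = psim.reconstruct_psim(star_stack, cfg=cfg)
        assert np.array_equal(r1.intensity, r2.intensity)
        assert np.array_equal(r1.orientation_deg, r2.orientation_deg)
        assert np.array_equal(r1.polarization_factor, r2.polarization_factor)


class TestReconstructPm:
    def test_ideal_fixed_dipole_bead_has_unit_polarization_factor(self, protocol):
        dens = np.zeros((256, 256, 15))
        dens[128, 128, 3] = 1.0  # rigid dipole at 36 degrees (a bin center)
        bead = psim.DipoleScene(dens, 20.0, np.arange(15) * 12.0)
        stack = psim.simulate_acquisition(bead, protocol)
        pm = psim.reconstruct_pm(stack)
        y, x = np.unravel_index(np.argmax(pm.intensity), pm.intensity.shape)
        assert pm.polarization_factor[y, x] == pytest.approx(1.0, abs=1e-9)
        assert abs(orientation_difference_deg(pm.orientation_deg[y, x], 36.0)) < 1e-6

    def test_matches_psim_orientation_on_smooth_patch(self, protocol):
        yy, xx = np.mgrid[0:256, 0:256]
        blob = np.exp(-((yy - 128) ** 2 + (xx - 128) ** 2) / (2 * 50.0 ** 2))
        dens = np.zeros((256, 256, 15))
        dens[:, :, 5] = blob  # uniform orientation 60 deg
        scene = psim.DipoleScene(dens, 20.0, np.arange(15) * 12.0)
        stack = psim.simulate_acquisition(scene, protocol)
        pm = psim.reconstruct_pm(stack)
        res = psim.reconstruct_psim(stack, cfg=psim.PsimConfig(phases="nominal"))
        assert circular_rms_deg(pm.orientation_deg, 60.0, pm.mask) < 1.0
        assert circular_rms_deg(res.orientation_deg, 60.0, res.mask) < 1.0

    def test_blank_stack_fully_masked(self, protocol):
        stack = psim.RawStack(np.zeros((3, 3, 64, 64)), protocol, 80.0)
        pm = psim.reconstruct_pm(stack)
        assert not pm.mask.any()


class TestResolutionDoubling:
    def test_spectral_energy_beyond_widefield_cutoff(self, protocol):
        """A full-field 190 nm lattice (fundamental beyond the widefield
        cutoff) keeps > 5% of its reconstructed spectral energy beyond that
        cutoff, while the widefield image has none."""
        scene = psim.render_scene("ring_lattice", period_nm=190.0,
                                  ring_length_nm=9500.0, margin_nm=200.0,
                                  shape=(512, 512), pixel_nm=20.0, width_nm=60.0)
        stack = psim.simulate_acquisition(scene, protocol)
        res = psim.reconstruct_psim(stack, cfg=psim.PsimConfig(phases="nominal"))

        def beyond_frac(img, pixel_nm):
            spec = np.abs(np.fft.fftshift(np.fft.fft2(img))) ** 2
            f = np.fft.fftshift(np.fft.fftfreq(img.shape[0], d=pixel_nm))
            kyg, kxg = np.meshgrid(f, f, indexing="ij")
            kr = np.hypot(kyg, kxg)
            kc = protocol.optics.cutoff_cycles_nm
            return spec[kr > kc].sum() / spec[kr > 1e-9].sum()

        assert beyond_frac(res.intensity, res.pixel_nm) > 0.05
        wf = psim.reconstruct_widefield(stack)
        assert beyond_frac(wf, 80.0) < 1e-12


@pytest.fixture(scope="module")
def ablation_pair(protocol):
    scene = psim.render_scene("radial_star", n_lines=4, shape=(256, 256),
                              pixel_nm=20.0, width_nm=60.0)
    obs = psim.ablate_cross_harmonics(scene, protocol, "psim_observable")
    full = psim.ablate_cross_harmonics(scene, protocol, "full_doubled")
    mask = scene.total_density() > 0.3 * scene.total_density().max()
    return obs, full, mask


class TestAblateCrossHarmonics:
    def test_intensity_unaffected(self, ablation_pair):
        (I1, _, _), (I2, _, _), m = ablation_pair
        assert np.linalg.norm((I1 - I2)[m]) / np.linalg.norm(I2[m]) < 0.01

    def test_orientation_unaffected(self, ablation_pair):
        (_, a1, _), (_, a2, _), m = ablation_pair
        assert circular_rms_deg(a1, a2, m) < 1.0

    def test_polarization_factor_shows_larger_deviation(self, ablation_pair):
        (I1, a1, p1), (I2, a2, p2), m = ablation_pair
        p_dev = np.linalg.norm((p1 - p2)[m]) / np.linalg.norm(p2[m])
        i_dev = np.linalg.norm((I1 - I2)[m]) / np.linalg.norm(I2[m])
        assert p_dev > 10 * i_dev
        assert np.abs(p1 - p2)[m].max() > 0.05

    def test_isolated_filament_orientation_strictly_preserved(self, protocol):
        scene = psim.render_scene("filament", points_nm=[[500, 500], [4500, 4600]],
                                  shape=(256, 256), pixel_nm=20.0, width_nm=60.0)
        _, a1, _ = psim.ablate_cross_harmonics(scene, protocol, "psim_observable")
        _, a2, _ = psim.ablate_cross_harmonics(scene, protocol, "full_doubled")
        m = scene.total_density() > 0.3 * scene.total_density().max()
        assert circular_rms_deg(a1, a2, m) < 1e-6

    def test_oversized_scene_rejected(self, protocol):
        big = psim.DipoleScene(np.zeros((512, 512, 15)), 20.0,
                               np.arange(15) * 12.0)
        with pytest.raises(ValueError, match="too large"):
            psim.ablate_cross_harmonics(big, protocol)
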