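"""Shared fixtures: default protocol and cached synthetic scenes/stacks."""

import numpy as np
import pytest

import psim


@pytest.fixture(scope="session")
def protocol():
    return psim.AcquisitionProtocol()


@pytest.fixture(scope="session")
def star_scene():
    """Siemens-star phantom with tangential dipoles, 20 nm grid."""
    return psim.render_scene("radial_star", n_lines=8, shape=(512, 512),
                             pixel_nm=20.0, width_nm=60.0)


@pytest.fixture(scope="session")
def star_stack(star_scene, protocol):
    """Noise-free 9-frame acquisition of the star (128 x 128 camera grid)."""
    return psim.simulate_acquisition(star_scene, protocol)


@pytest.fixture(scope="session")
def star_truth(star_scene):
    """Ground-truth first angular harmonic binned to the 2x reconstruction grid."""
    h = star_scene.angular_harmonic()
    n = h.shape[0] // 2
    h2 = h.reshape(n, 2, n, 2).sum(axis=(1, 3))
    alpha = np.mod(np.rad2deg(np.angle(h2) / 2.0), 180.0)
    return alpha, np.abs(h2)


def make_two_line_scene(separation_nm, shape=(256, 256), pixel_nm=20.0,
                        width_nm=40.0):
    """Two parallel vertical filaments separated by ``separation_nm``."""
    c = (shape[0] - 1) / 2.0 * pixel_nm
    parts = []
    for off in (-separation_nm / 2.0, separation_nm / 2.0):
        parts.append(psim.render_scene(
            "filament", points_nm=[[c - 1500, c + off], [c + 1500, c + off]],
            shape=shape, pixel_nm=pixel_nm, width_nm=width_nm, normalize=False))
    dens = sum(p.density for p in parts)
    scene = psim.DipoleScene(dens, pixel_nm, parts[0].angles_deg)
    scene.density *= 1.0 / scene.total_density().max()
    return scene


def canonical_k(k):
    """Map a stripe vector to the estimator's canonical half-plane."""
    k = np.asarray(k, dtype=float)
    if k[1] < -1e-3 or (abs(k[1]) <= 1e-3 and k[0] < 0):
        return -k
    return k
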