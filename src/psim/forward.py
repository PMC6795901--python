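"""Forward simulation of polarized structured-illumination acquisition.

Each raw frame is

    D = [ sum_alpha S(r, alpha) * I_{theta,phi}(r) * F_theta(alpha) d_alpha ]
        (x) PSF,

evaluated by midpoint quadrature over the angular bins, blurred with the
incoherent OTF on the fine scene grid, box-binned to the camera grid, and
optionally degraded with Poisson shot noise plus Gaussian read noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .optics import OpticalModel
from .scene import (
    AcquisitionProtocol,
    DipoleScene,
    IlluminationState,
    absorption_efficiency,
    illumination_pattern,
)

__all__ = ["RawStack", "simulate_acquisition", "simulate_polarized_detection"]


@dataclass
class RawStack:
    """A 3 x 3 (direction, phase) stack of raw SIM frames plus its protocol."""

    images: np.ndarray  # (3, 3, ny, nx), direction-major
    protocol: AcquisitionProtocol
    pixel_nm: float
    seed: Optional[int] = None
    states: Optional[list] = None  # ground-truth IlluminationStates when simulated
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        if self.images.shape[:2] != (3, 3) or self.images.ndim != 4:
            raise ValueError("images must have shape (3, 3, ny, nx)")
        for i in range(3):
            ph = np.mod(self.protocol.phases_rad[i], 2 * np.pi)
            if np.min(np.abs(np.subtract.outer(ph, ph))[~np.eye(3, dtype=bool)]) < 1e-9:
                raise ValueError(f"phases within direction {i} must be pairwise distinct")

    @property
    def shape(self):
        return self.images.shape[2:]

    def frames(self, direction: int):
        return self.images[direction]


def _bin_mean(img, factor):
    if factor == 1:
        return img
    ny, nx = img.shape
    return img.reshape(ny // factor, factor, nx // factor, factor).mean(axis=(1, 3))


def _gain_on_fine_grid(gain, fine_shape, factor):
    gain = np.asarray(gain, dtype=float)
    if gain.shape == fine_shape:
        return gain
    if (gain.shape[0] * factor, gain.shape[1] * factor) == fine_shape:
        return np.repeat(np.repeat(gain, factor, axis=0), factor, axis=1)
    raise ValueError("nonuniformity field shape matches neither scene nor camera grid")


def simulate_acquisition(
    scene: DipoleScene,
    protocol: AcquisitionProtocol,
    photon_scale=np.inf,
    read_sigma: float = 0.0,
    seed: Optional[int] = None,
    nonuniformity: Optional[np.ndarray] = None,
) -> RawStack:
    """Simulate the 9-frame pSIM acquisition of a dipole scene.

    Parameters
    ----------
    photon_scale:
        Expected photons per unit of noise-free signal; ``np.inf`` disables
        shot noise and returns the noise-free expectation.
    read_sigma:
        Gaussian read-noise SD in the same counts as the Poisson output.
    nonuniformity:
        Optional per-direction excitation gain fields, shape (3, ny, nx) on
        either the scene or the camera grid.  Applied to the excitation before
        the PSF blur, mirroring a spatially varying illumination intensity.
    """
    if read_sigma < 0:
        raise ValueError("read_sigma must be non-negative")
    factor = protocol.optics.pixel_nm / scene.pixel_nm
    if abs(factor - round(factor)) > 1e-9 or factor < 1 - 1e-9:
        raise ValueError(
            "camera pixel must be an integer multiple of the scene pixel "
            f"(got camera {protocol.optics.pixel_nm} nm, scene {scene.pixel_nm} nm)"
        )
    factor = int(round(factor))
    fine_shape = scene.shape
    if fine_shape[0] % factor or fine_shape[1] % factor:
        raise ValueError("scene grid must tile the camera grid exactly")

    rng = np.random.default_rng(seed)
    d_alpha = scene.delta_alpha_rad
    ny, nx = fine_shape[0] // factor, fine_shape[1] // factor
    out = np.zeros((3, 3, ny, nx))
    states = protocol.states()

    for i in range(3):
        # angular weighting is shared by the 3 phases of a direction
        f_alpha = absorption_efficiency(scene.angles_deg, protocol.thetas_deg[i],
                                        protocol.eta)
        weighted = (scene.density * f_alpha[None, None, :]).sum(axis=2) * d_alpha
        for j in range(3):
            st = states[i][j]
            pattern = illumination_pattern(fine_shape, scene.pixel_nm, st,
                                           origin_px=(factor - 1) / 2.0)
            signal = weighted * pattern
            if nonuniformity is not None:
                signal = signal * _gain_on_fine_grid(nonuniformity[i], fine_shape, factor)
            blurred = protocol.optics.blur(signal, pixel_nm=scene.pixel_nm)
            frame = _bin_mean(blurred, factor)
            if np.isfinite(photon_scale):
                frame = rng.poisson(np.clip(photon_scale * frame, 0, None)).astype(float)
            if read_sigma > 0:
                frame = frame + rng.normal(0.0, read_sigma, frame.shape)
            out[i, j] = frame

    return RawStack(out, protocol, protocol.optics.pixel_nm, seed=seed, states=states)


def simulate_polarized_detection(
    scene: DipoleScene,
    state: IlluminationState,
    analyzer_angles_deg,
    optics: Optional[OpticalModel] = None,
) -> np.ndarray:
    """In-silico analog of imaging the structured illumination itself.

    A uniform isotropic bead layer is excited by one pattern; a polarizer in
    the detection path at angle beta weights each dipole's emission by
    cos^2(beta - alpha).  Images are averaged along the stripes (assumed
    vertical: k along x) and the per-analyzer rows are stacked, producing the
    pattern in the x-alpha coordinate plane whose 2-D Fourier transform shows
    the spatial, angular and cross harmonics.

    Returns an (n_analyzer, nx) array.
    """
    betas = np.atleast_1d(np.asarray(analyzer_angles_deg, dtype=float))
    if betas.size == 0:
        raise ValueError("analyzer angle list is empty")
    ky, kx = state.k_vec_nm
    if abs(ky) > 1e-12 * max(abs(kx), 1e-30):
        raise ValueError("stripes must be vertical (k along x) for the x-alpha image")

    pattern = illumination_pattern(scene.shape, scene.pixel_nm, state)
    d_alpha = scene.delta_alpha_rad
    rows = np.zeros((betas.size, scene.shape[1]))
    f_exc = absorption_efficiency(scene.angles_deg, state.polarization_deg,
                                  state.absorption_scale)
    for b, beta in enumerate(betas):
        f_det = absorption_efficiency(scene.angles_deg, beta, 1.0)
        weighted = (scene.density * (f_exc * f_det)[None, None, :]).sum(axis=2) * d_alpha
        img = weighted * pattern
        if optics is not None:
            img = optics.blur(img, pixel_nm=scene.pixel_nm)
        rows[b] = img.mean(axis=0)
    return rows
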