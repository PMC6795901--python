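"""Scalar incoherent imaging model: circular-pupil OTF and its PSF.

The transfer function is the classical autocorrelation ("chinese-hat") OTF of
an aberration-free circular pupil,

    OTF(k) = (2/pi) * (arccos(rho) - rho * sqrt(1 - rho^2)),   rho = |k| / k_c,

with incoherent cutoff k_c = 2 NA / lambda (cycles/nm).  This is the standard
model for 2-D SIM simulation and reconstruction; it is real, non-negative,
radially symmetric, equals 1 at DC and vanishes at the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OpticalModel", "circular_pupil_otf"]


def circular_pupil_otf(k_cycles_nm, cutoff_cycles_nm):
    """Radial incoherent OTF values for spatial frequencies |k| (cycles/nm)."""
    rho = np.clip(np.abs(np.asarray(k_cycles_nm, dtype=float)) / cutoff_cycles_nm, 0.0, 1.0)
    return (2.0 / np.pi) * (np.arccos(rho) - rho * np.sqrt(1.0 - rho**2))


@dataclass(frozen=True)
class OpticalModel:
    """Diffraction-limited detection path of the microscope.

    Parameters
    ----------
    wavelength_nm:
        Emission wavelength used for the detection OTF.
    numerical_aperture:
        Objective NA.
    pixel_nm:
        Camera-plane sampling (nm per pixel).
    """

    wavelength_nm: float = 610.0
    numerical_aperture: float = 1.4
    pixel_nm: float = 80.0

    def __post_init__(self):
        if self.wavelength_nm <= 0 or self.numerical_aperture <= 0 or self.pixel_nm <= 0:
            raise ValueError("wavelength, NA and pixel size must be positive")

    @property
    def cutoff_cycles_nm(self) -> float:
        """Incoherent lateral cutoff 2 NA / lambda in cycles/nm."""
        return 2.0 * self.numerical_aperture / self.wavelength_nm

    def otf_radial(self, k_cycles_nm):
        return circular_pupil_otf(k_cycles_nm, self.cutoff_cycles_nm)

    def otf_grid(self, shape, pixel_nm=None, shift_cycles_nm=(0.0, 0.0)):
        """DC-centered OTF sampled on an FFT grid.

        ``shift_cycles_nm`` (ky, kx) recenters the pupil, as needed when
        weighting spectrally shifted SIM components.
        """
        if pixel_nm is None:
            pixel_nm = self.pixel_nm
        ky = np.fft.fftshift(np.fft.fftfreq(shape[0], d=pixel_nm))
        kx = np.fft.fftshift(np.fft.fftfreq(shape[1], d=pixel_nm))
        kyg, kxg = np.meshgrid(ky, kx, indexing="ij")
        kr = np.hypot(kyg - shift_cycles_nm[0], kxg - shift_cycles_nm[1])
        return self.otf_radial(kr)

    def psf_grid(self, shape, pixel_nm=None):
        """Real-space PSF matching :meth:`otf_grid` (periodic, sum approx. 1)."""
        otf = self.otf_grid(shape, pixel_nm=pixel_nm)
        psf = np.real(np.fft.ifft2(np.fft.ifftshift(otf)))
        return np.fft.fftshift(psf)

    def blur(self, image, pixel_nm=None):
        """Convolve with the PSF via the OTF (periodic boundary)."""
        otf = np.fft.ifftshift(self.otf_grid(image.shape, pixel_nm=pixel_nm))
        return np.real(np.fft.ifft2(np.fft.fft2(image) * otf))
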