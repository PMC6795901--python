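"""Shared numerics: axial (180-degree periodic) statistics and FFT helpers.

Dipole orientations are axes, not directions: alpha and alpha + 180 deg are the
same physical state.  All circular statistics therefore work on the doubled
angle 2*alpha, where the period collapses to 360 deg.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_orientation_deg",
    "orientation_difference_deg",
    "circular_mean_orientation_deg",
    "circular_rms_deg",
    "wrapped_std_deg",
    "centered_spectrum",
    "inverse_centered_spectrum",
    "freq_grids_cycles_px",
]


def wrap_orientation_deg(alpha):
    """Reduce an orientation (degrees) to the canonical interval [0, 180)."""
    return np.mod(alpha, 180.0)


def orientation_difference_deg(a, b):
    """Signed smallest difference a - b between two orientations, in (-90, 90]."""
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float) + 90.0, 180.0) - 90.0
    # fold the open endpoint so the interval is (-90, 90]
    d = np.where(d == -90.0, 90.0, d)
    return d


def circular_mean_orientation_deg(alpha, weights=None):
    """Mean orientation via the doubled-angle resultant vector."""
    a2 = np.deg2rad(2.0 * np.asarray(alpha, dtype=float))
    z = np.exp(1j * a2)
    if weights is not None:
        z = z * np.asarray(weights, dtype=float)
    m = np.angle(np.mean(z)) / 2.0
    return float(np.mod(np.rad2deg(m), 180.0))


def circular_rms_deg(alpha, reference, mask=None):
    """Root-mean-square orientation error against a reference map, in degrees."""
    d = orientation_difference_deg(alpha, reference)
    if mask is not None:
        d = d[mask]
    if d.size == 0:
        raise ValueError("no pixels selected for circular RMS")
    return float(np.sqrt(np.mean(d**2)))


def wrapped_std_deg(alpha, reference=None):
    """Standard deviation of orientations about their circular mean.

    Differences are wrapped to (-90, 90] before the second moment, so a tight
    distribution reproduces the ordinary SD while a uniform axial distribution
    gives 180/sqrt(12) ~ 51.96 deg.
    """
    alpha = np.asarray(alpha, dtype=float)
    if reference is not None:
        alpha = orientation_difference_deg(alpha, reference)
    center = circular_mean_orientation_deg(alpha)
    d = orientation_difference_deg(alpha, center)
    return float(np.sqrt(np.mean(d**2)))


# ---------------------------------------------------------------------------
# FFT conventions: spectra are DC-centered 2-D arrays; images are real.
# ---------------------------------------------------------------------------

def centered_spectrum(image):
    """DC-centered 2-D FFT of a real image (no normalization)."""
    return np.fft.fftshift(np.fft.fft2(image))


def inverse_centered_spectrum(spectrum):
    """Inverse of :func:`centered_spectrum`; returns a complex image."""
    return np.fft.ifft2(np.fft.ifftshift(spectrum))


def freq_grids_cycles_px(shape):
    """(ky, kx) DC-centered frequency grids in cycles per pixel."""
    ky = np.fft.fftshift(np.fft.fftfreq(shape[0]))
    kx = np.fft.fftshift(np.fft.fftfreq(shape[1]))
    return np.meshgrid(ky, kx, indexing="ij")
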