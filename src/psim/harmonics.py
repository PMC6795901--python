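"""The SIM step: harmonic separation, pattern estimation, spectral shifting.

For one pattern direction with phases phi_1..3 the three raw spectra mix the
zeroth and +/- first spatial harmonics through the phase matrix

    M[j] = (I0 / 2) * [ 1,  (m/2) e^{+i phi_j},  (m/2) e^{-i phi_j} ],

so an exact per-frequency 3x3 inversion recovers

    C0(k)  = (I0/2) * G(k)        * OTF(k)
    C+(k)  = (I0/2) * G(k - k_s)  * OTF(k)
    C-(k)  = (I0/2) * G(k + k_s)  * OTF(k)

where G is the spectrum of the polarization-weighted specimen projection and
k_s the stripe vector.  Each component is still convolved along the angular
axis with the polarization term of its direction; that is resolved later by
the PM step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from ._utils import centered_spectrum, inverse_centered_spectrum

__all__ = [
    "SeparatedComponents",
    "sim_mixing_matrix",
    "separate_components",
    "estimate_pattern_params",
    "shift_component",
    "unshift_component",
    "widefield_from_phases",
    "PatternEstimate",
]


@dataclass
class SeparatedComponents:
    """Zeroth/+/- first spatial harmonics of one direction (DC-centered spectra)."""

    C0: np.ndarray
    Cplus: np.ndarray
    Cminus: np.ndarray
    k_cycles_px: Optional[np.ndarray] = None
    phase0: Optional[float] = None
    modulation: Optional[float] = None


@dataclass
class PatternEstimate:
    k_cycles_px: np.ndarray
    phase0: float
    modulation: float
    significance: float


def sim_mixing_matrix(phases_rad, modulation=1.0):
    """Per-direction SIM phase matrix; raises if two phases coincide mod 2 pi.

    The rows are [1, (m/2) e^{i phi_j}, (m/2) e^{-i phi_j}]; the separated
    components then carry the pattern's mean intensity I0/2, so the
    back-transformed zeroth component is directly comparable to the frame
    average.  The modulation is clamped to [0.05, 1] to avoid amplification
    blow-up when an estimated m is implausibly small.
    """
    phases = np.asarray(phases_rad, dtype=float)
    e = np.exp(1j * phases)
    for a in range(len(phases)):
        for b in range(a + 1, len(phases)):
            if abs(e[a] - e[b]) < 1e-9:
                raise ValueError(
                    f"phases {phases[a]:.6f} and {phases[b]:.6f} rad coincide "
                    "modulo 2 pi; the separation matrix is singular"
                )
    m = np.clip(modulation, 0.05, 1.0)
    return np.stack([np.ones_like(e), (m / 2.0) * e, (m / 2.0) * np.conj(e)], axis=1)


def separate_components(frames, phases_rad, modulation=1.0):
    """Solve the 3x3 phase system per spatial frequency (exact inverse).

    ``frames`` are the three real images of one direction.  Returns a
    :class:`SeparatedComponents` with DC-centered spectra.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.shape[0] != 3:
        raise ValueError("need exactly 3 frames per direction")
    M = sim_mixing_matrix(phases_rad, modulation)
    Minv = np.linalg.inv(M)
    spectra = np.stack([centered_spectrum(f) for f in frames])
    comps = np.tensordot(Minv, spectra, axes=(1, 0))
    return SeparatedComponents(C0=comps[0], Cplus=comps[1], Cminus=comps[2],
                               modulation=modulation)


def _cross_term(C0, Cplus):
    """Real-space product whose Fourier transform is the k-dependent overlap
    correlation  c(k) = sum_r p+(r) conj(p0(r)) e^{-2 pi i k . r}."""
    p0 = inverse_centered_spectrum(C0)
    pp = inverse_centered_spectrum(Cplus)
    return pp * np.conj(p0)


def _eval_correlation(x, k):
    ny, nx = x.shape
    ey = np.exp(-2j * np.pi * k[0] * np.arange(ny))
    ex = np.exp(-2j * np.pi * k[1] * np.arange(nx))
    return ey @ x @ ex


def estimate_pattern_params(
    frames,
    phases_rad=(0.0, 2 * np.pi / 3, 4 * np.pi / 3),
    otf: Optional[np.ndarray] = None,
    search=(0.1, 0.48),
    highpass_frac: float = 0.6,
    min_modulation: float = 0.05,
) -> PatternEstimate:
    """Estimate stripe vector, starting phase and modulation from 3 raw frames.

    The frames are separated with the nominal phase offsets; the stripe vector
    maximizes the magnitude of the overlap correlation between the shifted
    (+1) and unshifted (0) components, refined to sub-pixel precision by a
    simplex search over the continuous correlation.  The starting phase is the
    complex argument at the optimum, quoted at the field-center pixel
    (ny//2, nx//2), and the modulation is the magnitude ratio against the
    zeroth-order autocorrelation at the same shift.

    ``search`` is the coarse (k_min, k_max) annulus in cycles/pixel.  Before
    correlating, frequencies below ``highpass_frac * k_min`` are suppressed in
    both components: the low-frequency band is shared by all components and
    would otherwise bury the stripe peak under the scene's autocorrelation.

    Raises ``ValueError("no stripes detected")`` when the recovered modulation
    falls below ``min_modulation``.
    """
    sep = separate_components(frames, phases_rad, modulation=1.0)
    C0, Cp = sep.C0, sep.Cplus
    ny, nx = C0.shape
    ky = np.fft.fftshift(np.fft.fftfreq(ny))
    kx = np.fft.fftshift(np.fft.fftfreq(nx))
    kyg, kxg = np.meshgrid(ky, kx, indexing="ij")
    kr = np.hypot(kyg, kxg)

    # phase correlation: whitening removes the scene's spectral coloring, so
    # the stripe shift shows up as a sharp, scene-independent peak
    band = (otf > 1e-2) if otf is not None else np.ones_like(kr, bool)
    hp = kr >= highpass_frac * search[0]

    def _whiten(C):
        m = np.abs(C)
        eps = 1e-2 * np.median(m[m > 0]) if np.any(m > 0) else 1.0
        return C / (m + eps) * band * hp

    xw = _cross_term(_whiten(C0), _whiten(Cp))
    corr = np.fft.fftshift(np.fft.fft2(xw))
    mag = np.abs(corr)
    annulus = (kr >= search[0]) & (kr <= search[1])
    mag_in = np.where(annulus, mag, 0.0)
    iy, ix = np.unravel_index(np.argmax(mag_in), mag.shape)
    peak = mag_in[iy, ix]
    background = np.median(mag[annulus]) if np.any(annulus) else 0.0
    significance = peak / background if background > 0 else 0.0
    k0 = np.array([ky[iy], kx[ix]])

    res = optimize.minimize(
        lambda k: -np.abs(_eval_correlation(xw, k)),
        k0,
        method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-12, "maxiter": 400},
    )
    # second stage on the un-whitened overlap correlation: its peak sits at
    # the exact stripe vector and is insensitive to the whitening epsilon
    x = _cross_term(C0 * hp, Cp * hp)
    res = optimize.minimize(
        lambda k: -np.abs(_eval_correlation(x, k)),
        res.x,
        method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-15, "maxiter": 400},
    )
    k_hat = res.x

    # phase and modulation at the true (+1-component) peak; the phase is
    # referenced to the field center, where it is insensitive to the residual
    # k error (origin-referenced phase trades off against k times the scene
    # centroid position)
    c = _eval_correlation(x, k_hat)
    c00 = _eval_correlation(_cross_term(C0 * hp, C0 * hp), k_hat)
    center = np.array([ny // 2, nx // 2], dtype=float)
    phase0 = float(np.angle(c) + 2 * np.pi * (k_hat @ center))
    modulation = float(2.0 * np.abs(c) / np.abs(c00)) if np.abs(c00) > 0 else 0.0

    # canonical half-plane: kx > 0 (or ky > 0 on the kx ~ 0 axis); the pair
    # (k, phase) maps to the equivalent (-k, -phase).  The axis tolerance
    # absorbs noise jitter of near-axis stripe vectors.
    tol = 1e-3
    if k_hat[1] < -tol or (abs(k_hat[1]) <= tol and k_hat[0] < 0):
        k_hat = -k_hat
        phase0 = -phase0
    phase0 = float(np.angle(np.exp(1j * phase0)))

    if modulation < min_modulation or significance < 4.0:
        raise ValueError("no stripes detected: modulation below the noise floor")
    return PatternEstimate(
        k_cycles_px=np.asarray(k_hat, dtype=float),
        phase0=phase0,
        modulation=min(modulation, 1.0),
        significance=float(significance),
    )


def shift_component(C, k_cycles_px, upsample=2):
    """Translate a DC-centered spectrum by ``k_cycles_px`` on an enlarged grid.

    The spectrum is embedded in an ``upsample``-times larger frequency grid
    (to hold the doubled SIM support), inverse-transformed, multiplied by the
    sub-pixel phase ramp exp(+2 pi i k . r), and transformed back; features at
    frequency k0 end up at k0 + k.  Frequencies are in cycles per *original*
    pixel.
    """
    C = np.asarray(C)
    ny, nx = C.shape
    NY, NX = upsample * ny, upsample * nx
    Z = np.zeros((NY, NX), dtype=complex)
    y0, x0 = (NY - ny) // 2, (NX - nx) // 2
    Z[y0:y0 + ny, x0:x0 + nx] = C
    field = inverse_centered_spectrum(Z)
    yy = np.arange(NY)[:, None] / upsample  # original-pixel units
    xx = np.arange(NX)[None, :] / upsample
    ramp = np.exp(2j * np.pi * (k_cycles_px[0] * yy + k_cycles_px[1] * xx))
    return centered_spectrum(field * ramp)


def unshift_component(C_big, k_cycles_px, downsample=2):
    """Inverse of :func:`shift_component` (crop back to the original grid)."""
    NY, NX = C_big.shape
    ny, nx = NY // downsample, NX // downsample
    field = inverse_centered_spectrum(C_big)
    yy = np.arange(NY)[:, None] / downsample
    xx = np.arange(NX)[None, :] / downsample
    ramp = np.exp(-2j * np.pi * (k_cycles_px[0] * yy + k_cycles_px[1] * xx))
    S = centered_spectrum(field * ramp)
    y0, x0 = (NY - ny) // 2, (NX - nx) // 2
    return S[y0:y0 + ny, x0:x0 + nx]


def widefield_from_phases(frames, phases_rad):
    """Widefield image of one direction: the zeroth harmonic back-transformed.

    With the standard 2 pi / 3 phase design this equals the plain average of
    the three frames; for arbitrary (distinct) phases the exact zeroth-order
    solve is used, which the naive mean would get wrong.
    """
    sep = separate_components(frames, phases_rad, modulation=1.0)
    return np.real(inverse_centered_spectrum(sep.C0))
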