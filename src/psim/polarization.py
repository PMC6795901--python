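"""The PM step: angular-harmonic inversion and the per-pixel dipole cosine fit.

The polarization response of a pixel to excitation polarization theta is

    I(theta) = A * cos(2 (theta - alpha)) + B,

with A the modulation amplitude, B the offset, alpha the mean dipole
orientation, and polarization factor p = 2A / (A + B): p = 1 for a rigid
in-plane dipole (pure cos^2 response, A = B) and p = 0 for an isotropic or
freely wobbling emitter.

Equivalently, in the angular frequency domain the three per-direction zeroth
SIM components mix the angular harmonics through

    M_PM[i] = (eta / 2) * [ 1,  (1/2) e^{-2 i theta_i},  (1/2) e^{+2 i theta_i} ],

acting on [ s0, h, conj(h) ] where s0 is the angular DC (total density) and
h = sum_alpha S e^{+2 i alpha} d_alpha is the first angular harmonic.  Package
convention: arg(h) = +2 alpha, i.e. the "+1" harmonic is the coefficient
paired with e^{-2 i theta}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._utils import wrap_orientation_deg

__all__ = [
    "AngularHarmonics",
    "DipoleFit",
    "pm_mixing_matrix",
    "solve_angular_harmonics",
    "fit_dipole_cosine",
    "polarization_factor",
]


@dataclass
class AngularHarmonics:
    """Angular harmonics of the specimen (any consistent spatial representation).

    ``H0`` is the angular-DC part, ``Hplus``/``Hminus`` the +/- first angular
    harmonics; for a real specimen Hminus = conj(Hplus) pixel-wise in real
    space.
    """

    H0: np.ndarray
    Hplus: np.ndarray
    Hminus: np.ndarray


@dataclass
class DipoleFit:
    """Per-pixel cosine-fit maps: amplitude A, offset B, orientation, p, mask."""

    A: np.ndarray
    B: np.ndarray
    alpha_deg: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def intensity(self):
        """A + B, the intensity signal."""
        return self.A + self.B

    @property
    def p_overrange(self):
        """Pixels where noise pushed the polarization factor above 1."""
        return self.mask & (self.p > 1.0)


def pm_mixing_matrix(thetas_deg, eta=1.0):
    """Three-polarization mixing matrix; raises for degenerate angle sets."""
    thetas = np.asarray(thetas_deg, dtype=float)
    e = np.exp(-2j * np.deg2rad(thetas))
    for a in range(len(thetas)):
        for b in range(a + 1, len(thetas)):
            if abs(e[a] - e[b]) < 1e-9:
                raise ValueError(
                    f"excitation polarizations {thetas[a]} and {thetas[b]} deg "
                    "coincide modulo 180 deg; the PM matrix is singular"
                )
    M = np.stack([np.ones_like(e), 0.5 * e, 0.5 * np.conj(e)], axis=1)
    return (eta / 2.0) * M


def solve_angular_harmonics(c0_components, thetas_deg, eta=1.0) -> AngularHarmonics:
    """Invert the three-polarization system for the angular harmonics.

    ``c0_components`` are the three per-direction zeroth SIM components (any
    consistent arrays: spectra or real-space images).  Exact 3x3 inversion per
    element, no regularization.
    """
    c0 = np.stack([np.asarray(c) for c in c0_components])
    if c0.shape[0] != 3:
        raise ValueError("need exactly 3 zeroth components")
    M = pm_mixing_matrix(thetas_deg, eta)
    Minv = np.linalg.inv(M)
    comps = np.tensordot(Minv, c0.astype(complex), axes=(1, 0))
    return AngularHarmonics(H0=comps[0], Hplus=comps[1], Hminus=comps[2])


def fit_dipole_cosine(images, thetas_deg, mask_frac=0.05) -> DipoleFit:
    """Closed-form per-pixel fit of I = A cos(2 (theta - alpha)) + B.

    ``images`` is (n_theta, ny, nx) with n_theta >= 3 distinct polarizations.
    The fit solves the linear system for (B, A cos 2 alpha, A sin 2 alpha);
    A is the non-negative magnitude and alpha the half-argument reduced to
    [0, 180).  Pixels whose intensity A + B falls below ``mask_frac`` times
    the 99.9th percentile of the map are masked: orientation is meaningless at
    background level.  p is not clamped; values above 1 (possible under noise)
    are reported and flagged via :attr:`DipoleFit.p_overrange`.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim != 3 or images.shape[0] < 3:
        raise ValueError("images must be (n_theta >= 3, ny, nx)")
    thetas = np.asarray(thetas_deg, dtype=float)
    if thetas.shape[0] != images.shape[0]:
        raise ValueError("one polarization angle per image is required")
    if thetas.size == 3:
        pm_mixing_matrix(thetas)  # fail early, naming the offending angles
    t2 = 2.0 * np.deg2rad(thetas)
    X = np.stack([np.ones_like(t2), np.cos(t2), np.sin(t2)], axis=1)
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError(f"degenerate polarization set {thetas.tolist()} deg")
    pix = images.reshape(images.shape[0], -1)
    coef, *_ = np.linalg.lstsq(X, pix, rcond=None)
    B = coef[0].reshape(images.shape[1:])
    a = coef[1].reshape(images.shape[1:])
    b = coef[2].reshape(images.shape[1:])
    A = np.hypot(a, b)
    alpha = wrap_orientation_deg(np.rad2deg(0.5 * np.arctan2(b, a)))

    total = A + B
    hi = np.percentile(total, 99.9)
    threshold = mask_frac * hi
    mask = total > max(threshold, 0.0)
    if hi <= 0:
        mask = np.zeros_like(mask)
    # flat response: amplitude at numerical-noise level -> orientation undefined
    mask &= A > 1e-12 * max(hi, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, 2.0 * A / np.where(total > 0, total, 1.0), 0.0)
    return DipoleFit(A=A, B=B, alpha_deg=alpha, p=p, mask=mask,
                     meta={"mask_frac": mask_frac, "intensity_threshold": threshold})


def polarization_factor(A, B):
    """p = 2A / (A + B); 0 where A + B <= 0 (those pixels carry no signal)."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    total = A + B
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, 2.0 * A / np.where(total > 0, total, 1.0), 0.0)
    if p.ndim == 0:
        return float(p)
    return p
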