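"""Dipole specimens in spatio-angular hyperspace and the polarized illumination.

A specimen is represented as a non-negative emitter density S(x, y, alpha) on a
regular spatial grid and a periodic angular grid covering [0, 180) degrees:
each pixel carries a distribution over in-plane dipole orientations alpha.

Polarized excitation at angle theta weights a dipole at alpha by the Malus
absorption efficiency

    F_theta(alpha) = eta * cos^2(alpha - theta)
                   = (eta / 2) * [1 + cos(2 alpha - 2 theta)],

which is a sinusoid of period 180 deg in alpha -- structured illumination along
the angular axis with fixed frequency k_alpha = 1/pi per radian.  The spatial
stripes of a SIM pattern are the familiar

    I_{theta,phi}(r) = (I0 / 2) * [1 + m * cos(2 pi k . r + phi)].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .optics import OpticalModel
from ._utils import wrap_orientation_deg

__all__ = [
    "DipoleScene",
    "IlluminationState",
    "AcquisitionProtocol",
    "absorption_efficiency",
    "illumination_pattern",
    "render_scene",
    "DEFAULT_N_ANGLES",
]

#: Default number of angular bins.  180 / 15 = 12 deg spacing; the closest
#: uniform tiling of the half-turn to a 12.5 deg grid (which does not divide
#: 180 evenly).
DEFAULT_N_ANGLES = 15


def absorption_efficiency(alpha_deg, theta_deg, eta=1.0):
    """Malus absorption efficiency eta * cos^2(alpha - theta).

    Both angles are in degrees and are interpreted modulo 180 deg, so the
    response is 180-deg periodic in either argument.
    """
    if np.any(np.asarray(eta) <= 0):
        raise ValueError("eta must be positive")
    d = np.deg2rad(np.asarray(alpha_deg, dtype=float) - np.asarray(theta_deg, dtype=float))
    return eta * np.cos(d) ** 2


@dataclass
class DipoleScene:
    """Ground-truth emitter density over (y, x, alpha).

    ``density`` has shape (ny, nx, n_angles); ``angles_deg`` are the angular
    sample centers in degrees, equally spaced and wrapping at 180 deg.
    """

    density: np.ndarray
    pixel_nm: float
    angles_deg: np.ndarray

    def __post_init__(self):
        self.density = np.asarray(self.density, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.density.ndim != 3:
            raise ValueError("density must be (ny, nx, n_angles)")
        na = self.density.shape[2]
        if na < 3:
            raise ValueError("need at least 3 angular samples")
        if self.angles_deg.shape != (na,):
            raise ValueError("angles_deg length must match density's angular axis")
        d = np.diff(self.angles_deg)
        if np.any(d <= 0) or not np.allclose(d, d[0]):
            raise ValueError("angles must be strictly increasing and equally spaced")
        if not np.isclose(self.angles_deg[0] + 180.0, self.angles_deg[-1] + d[0]):
            raise ValueError("angular grid must tile [0, 180) exactly")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        if self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be positive")

    @property
    def shape(self):
        return self.density.shape[:2]

    @property
    def n_angles(self) -> int:
        return self.density.shape[2]

    @property
    def delta_alpha_rad(self) -> float:
        """Angular bin width in radians (midpoint-rule quadrature weight)."""
        return np.pi / self.n_angles

    def total_density(self):
        """Angular marginal: total emitter density per pixel (quadrature sum)."""
        return self.density.sum(axis=2) * self.delta_alpha_rad

    def angular_harmonic(self):
        """First angular Fourier coefficient h(r) = sum_alpha S e^{2 i alpha} d_alpha.

        arg(h)/2 is the mean dipole orientation of the pixel; |h| its
        modulation strength.  h == 0 for an isotropic pixel.
        """
        ph = np.exp(2j * np.deg2rad(self.angles_deg))
        return (self.density * ph).sum(axis=2) * self.delta_alpha_rad

    def mean_orientation_deg(self):
        return wrap_orientation_deg(np.rad2deg(np.angle(self.angular_harmonic()) / 2.0))


@dataclass
class IlluminationState:
    """One SIM pattern: stripe vector, phase, and excitation polarization.

    ``k_vec_nm`` is the stripe frequency vector (ky, kx) in cycles/nm; its
    direction is normal to the stripes.  ``polarization_deg`` is the linear
    excitation polarization theta; with s-polarized beams the field is parallel
    to the stripes.  The angular modulation frequency is fixed at 1/pi per
    radian (period 180 deg) by the physics of cos^2 absorption.
    """

    direction_index: int
    k_vec_nm: tuple
    phase_rad: float
    polarization_deg: float
    modulation: float = 1.0
    intensity: float = 1.0
    absorption_scale: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.modulation <= 1.0):
            raise ValueError("modulation must be in [0, 1]")
        if self.intensity < 0 or self.absorption_scale <= 0:
            raise ValueError("intensity must be >= 0 and absorption_scale > 0")

    @property
    def k_magnitude_nm(self) -> float:
        return float(np.hypot(*self.k_vec_nm))


def illumination_pattern(shape, pixel_nm, state: IlluminationState, origin_px=0.0):
    """Evaluate the sinusoidal stripe field on a grid.

    Returns (I0/2) * [1 + m * cos(2 pi k . r + phi)] with r in nm.  Raises if
    the stripe frequency exceeds the grid Nyquist limit.  ``origin_px`` shifts
    the coordinate origin (in grid pixels); a super-sampled acquisition uses
    it to center fine-grid blocks on the camera samples, keeping the pattern
    phase referenced to the camera grid.
    """
    ky, kx = state.k_vec_nm
    if np.hypot(ky, kx) * pixel_nm > 0.5 + 1e-12:
        raise ValueError("stripe frequency exceeds the grid Nyquist limit")
    y = (np.arange(shape[0])[:, None] - origin_px) * pixel_nm
    x = (np.arange(shape[1])[None, :] - origin_px) * pixel_nm
    arg = 2.0 * np.pi * (ky * y + kx * x) + state.phase_rad
    return (state.intensity / 2.0) * (1.0 + state.modulation * np.cos(arg))


@dataclass
class AcquisitionProtocol:
    """The 3-direction x 3-phase pSIM acquisition recipe.

    thetas_deg are the excitation polarizations; in an s-polarized SIM system
    the stripes are parallel to the polarization, so the stripe-normal (the
    direction of k) is theta + 90 deg.  phases_rad is the (3, 3) table of
    pattern phases phi_{i,j}.
    """

    optics: OpticalModel = field(default_factory=OpticalModel)
    thetas_deg: Sequence[float] = (0.0, 60.0, 120.0)
    phases_rad: Optional[np.ndarray] = None
    pattern_frac: float = 0.9
    modulation: float = 1.0
    intensity: float = 1.0
    eta: float = 1.0
    stripes_parallel_to_polarization: bool = True
    k_vecs_nm: Optional[np.ndarray] = None

    def __post_init__(self):
        self.thetas_deg = np.asarray(self.thetas_deg, dtype=float)
        if self.thetas_deg.shape != (3,):
            raise ValueError("exactly 3 pattern directions are required")
        if self.phases_rad is None:
            self.phases_rad = np.tile(np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3]), (3, 1))
        self.phases_rad = np.asarray(self.phases_rad, dtype=float)
        if self.phases_rad.shape != (3, 3):
            raise ValueError("phases_rad must be a (3, 3) table")
        if self.k_vecs_nm is None:
            kmag = self.pattern_frac * self.optics.cutoff_cycles_nm
            normal = self.thetas_deg + (90.0 if self.stripes_parallel_to_polarization else 0.0)
            rad = np.deg2rad(normal)
            self.k_vecs_nm = np.stack([kmag * np.sin(rad), kmag * np.cos(rad)], axis=1)
        self.k_vecs_nm = np.asarray(self.k_vecs_nm, dtype=float)
        if self.k_vecs_nm.shape != (3, 2):
            raise ValueError("k_vecs_nm must be (3, 2) as (ky, kx) rows")

    def state(self, direction: int, phase_index: int) -> IlluminationState:
        return IlluminationState(
            direction_index=direction,
            k_vec_nm=tuple(self.k_vecs_nm[direction]),
            phase_rad=float(self.phases_rad[direction, phase_index]),
            polarization_deg=float(self.thetas_deg[direction]),
            modulation=self.modulation,
            intensity=self.intensity,
            absorption_scale=self.eta,
        )

    def states(self):
        return [[self.state(i, j) for j in range(3)] for i in range(3)]


# ---------------------------------------------------------------------------
# Scene rendering
# ---------------------------------------------------------------------------

def _angle_bins(n_angles):
    return np.arange(n_angles) * (180.0 / n_angles)


def _deposit(density, ys, xs, alphas_deg, weights):
    """Splat point masses with bilinear spatial and wrapped-linear angular weights.

    The angular deposition splits each point's mass between the two nearest
    angular bins so that the first circular harmonic of the deposited mass
    preserves the true orientation to well under a tenth of a degree.
    """
    ny, nx, na = density.shape
    step = 180.0 / na
    ys = np.asarray(ys, dtype=float)
    xs = np.asarray(xs, dtype=float)
    alphas = np.mod(np.asarray(alphas_deg, dtype=float), 180.0)
    weights = np.broadcast_to(np.asarray(weights, dtype=float), ys.shape)

    a_idx = alphas / step
    a0 = np.floor(a_idx).astype(int)
    fa = a_idx - a0
    a0 = np.mod(a0, na)
    a1 = np.mod(a0 + 1, na)

    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    fy = ys - y0
    fx = xs - x0

    for dy, wy in ((0, 1 - fy), (1, fy)):
        for dx, wx in ((0, 1 - fx), (1, fx)):
            yy = y0 + dy
            xx = x0 + dx
            ok = (yy >= 0) & (yy < ny) & (xx >= 0) & (xx < nx)
            if not np.any(ok):
                continue
            wsp = (weights * wy * wx)[ok]
            np.add.at(density, (yy[ok], xx[ok], a0[ok]), wsp * (1 - fa[ok]))
            np.add.at(density, (yy[ok], xx[ok], a1[ok]), wsp * fa[ok])


def _draw_polyline(density, pixel_nm, points_nm, dipole_offset_deg, width_nm, amplitude):
    """Rasterize a polyline with per-point dipole orientation = tangent + offset."""
    if width_nm < pixel_nm:
        raise ValueError(
            f"structure width {width_nm} nm is thinner than one pixel ({pixel_nm} nm)"
        )
    pts = np.asarray(points_nm, dtype=float) / pixel_nm
    half_w = 0.5 * width_nm / pixel_nm
    step = 0.25  # centerline sampling, px
    for p0, p1 in zip(pts[:-1], pts[1:]):
        seg = p1 - p0
        length = np.hypot(*seg)
        if length == 0:
            continue
        # tangent angle measured CCW from +x; rows are y
        tangent = np.rad2deg(np.arctan2(seg[0], seg[1]))
        n_steps = max(int(np.ceil(length / step)), 1)
        t = (np.arange(n_steps) + 0.5) / n_steps
        centers = p0[None, :] + t[:, None] * seg[None, :]
        normal = np.array([seg[1], -seg[0]]) / length
        n_off = max(int(np.ceil(2 * half_w / step)), 1)
        offs = (np.arange(n_off) + 0.5) / n_off * 2 * half_w - half_w
        ys = (centers[:, 0][:, None] + offs[None, :] * normal[0]).ravel()
        xs = (centers[:, 1][:, None] + offs[None, :] * normal[1]).ravel()
        w = amplitude * (length / n_steps) * (2 * half_w / n_off)
        _deposit(density, ys, xs, np.full(ys.shape, tangent + dipole_offset_deg), w)


def render_scene(
    kind,
    *,
    shape=(256, 256),
    pixel_nm=20.0,
    n_angles=DEFAULT_N_ANGLES,
    width_nm=40.0,
    amplitude=1.0,
    dipole_offset_deg=0.0,
    normalize=True,
    rng=None,
    **params,
) -> DipoleScene:
    """Render a synthetic dipole specimen.

    ``kind`` selects the phantom:

    - ``"radial_star"``: ``n_lines`` radial spokes between ``inner_radius_nm``
      and ``outer_radius_nm``, dipoles along each spoke (+ offset).
    - ``"circles"``: concentric rings of ``radii_nm``, dipoles tangential.
    - ``"filament"``: polyline ``points_nm`` with tangential dipoles
      (+ ``dipole_offset_deg``; 90 makes them normal to the filament).
    - ``"ring_lattice"``: short transverse segments repeating every
      ``period_nm`` along x (``ring_length_nm`` long), dipoles along x.
    - ``"bead_field"``: ``n_beads`` isotropic point emitters at random
      positions (mass spread evenly over all angular bins).
    - ``"uniform"``: a uniform isotropic emitter layer.
    - ``"custom"``: pass ``density`` (and optionally ``angles_deg``) directly.

    Structures are drawn with finite ``width_nm``; widths below one pixel are
    rejected because they cannot be rasterized faithfully.  With ``normalize``
    (default) the density is rescaled so the brightest pixel's total emitter
    density equals ``amplitude``; the photon budget of a simulated frame is
    then ``photon_scale`` times the local (blurred, pattern-weighted) signal.
    """
    angles = _angle_bins(n_angles)
    density = np.zeros((shape[0], shape[1], n_angles), dtype=float)
    cy = (shape[0] - 1) / 2.0 * pixel_nm
    cx = (shape[1] - 1) / 2.0 * pixel_nm

    if kind == "custom":
        density = np.asarray(params["density"], dtype=float)
        angles = np.asarray(params.get("angles_deg", _angle_bins(density.shape[2])))
        return DipoleScene(density, pixel_nm, angles)

    if kind == "radial_star":
        n_lines = int(params.get("n_lines", 8))
        r_out = params.get("outer_radius_nm", 0.45 * min(shape) * pixel_nm)
        r_in = params.get("inner_radius_nm", 0.15 * r_out)
        for i in range(n_lines):
            phi = i * 180.0 / n_lines
            d = np.array([np.sin(np.deg2rad(phi)), np.cos(np.deg2rad(phi))])
            for sgn in (+1, -1):
                p0 = np.array([cy, cx]) + sgn * r_in * d
                p1 = np.array([cy, cx]) + sgn * r_out * d
                _draw_polyline(density, pixel_nm, [p0, p1], dipole_offset_deg,
                               width_nm, amplitude)
    elif kind == "circles":
        radii = params.get("radii_nm")
        if radii is None:
            raise ValueError("circles scene requires radii_nm")
        for r in np.atleast_1d(radii):
            n_seg = max(int(2 * np.pi * r / (0.25 * pixel_nm)), 64)
            t = np.linspace(0, 2 * np.pi, n_seg + 1)
            pts = np.stack([cy + r * np.sin(t), cx + r * np.cos(t)], axis=1)
            _draw_polyline(density, pixel_nm, pts, dipole_offset_deg, width_nm, amplitude)
    elif kind == "filament":
        pts = params.get("points_nm")
        if pts is None:
            raise ValueError("filament scene requires points_nm")
        _draw_polyline(density, pixel_nm, pts, dipole_offset_deg, width_nm, amplitude)
    elif kind == "ring_lattice":
        period = float(params.get("period_nm", 190.0))
        ring_len = float(params.get("ring_length_nm", 400.0))
        axis_angle = float(params.get("axis_angle_deg", 0.0))
        if axis_angle != 0.0:
            raise NotImplementedError("ring_lattice currently supports axis along x")
        x0 = params.get("margin_nm", 2 * width_nm)
        xs = np.arange(x0, shape[1] * pixel_nm - x0, period)
        for x in xs:
            p0 = [cy - ring_len / 2.0, x]
            p1 = [cy + ring_len / 2.0, x]
            # dipoles parallel to the lattice axis (side-by-side packing):
            # tangent of the drawn segment is 90 deg, so offset by -90 + user offset
            _draw_polyline(density, pixel_nm, [p0, p1],
                           dipole_offset_deg - 90.0, width_nm, amplitude)
    elif kind == "bead_field":
        n_beads = int(params.get("n_beads", 50))
        rng = np.random.default_rng(rng)
        margin = params.get("margin_px", 4)
        ys = rng.uniform(margin, shape[0] - 1 - margin, n_beads)
        xs = rng.uniform(margin, shape[1] - 1 - margin, n_beads)
        per_bin = amplitude / n_angles
        for a in range(n_angles):
            dens2 = density[:, :, a]
            y0 = np.floor(ys).astype(int)
            x0 = np.floor(xs).astype(int)
            fy, fx = ys - y0, xs - x0
            for dy, wy in ((0, 1 - fy), (1, fy)):
                for dx, wx in ((0, 1 - fx), (1, fx)):
                    np.add.at(dens2, (y0 + dy, x0 + dx), per_bin * wy * wx)
    elif kind == "uniform":
        density[:] = amplitude / n_angles
    else:
        raise ValueError(f"unknown scene kind: {kind!r}")

    scene = DipoleScene(density, pixel_nm, angles)
    if normalize:
        peak = scene.total_density().max()
        if peak > 0:
            scene.density *= amplitude / peak
    return scene
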