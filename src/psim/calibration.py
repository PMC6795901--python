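"""Bead-based calibration of excitation-intensity nonuniformity.

In a SIM system both the polarization and the stripes rotate with the pattern
direction, so the mean excitation intensity may differ across the field of
view between directions (up to tens of percent toward the FOV edge).  Because
the PM step compares intensities *across* directions, such nonuniformity
biases the fitted dipole orientation.  Sparse fluorescent beads are isotropic
emitters: their per-direction widefield intensities trace the excitation gain
directly.  A low-order 2-D polynomial (default quintic) is fit to each
direction's relative bead intensities and divided out before the PM step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

__all__ = ["CalibrationMap", "localize_beads", "build_nonuniformity_map",
           "apply_calibration"]


@dataclass
class CalibrationMap:
    """Per-direction relative excitation gain fields (unit mean, positive)."""

    gains: np.ndarray  # (3, ny, nx)
    degree: int
    n_beads: int
    residual: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.gains = np.asarray(self.gains, dtype=float)
        if self.gains.ndim != 3 or self.gains.shape[0] != 3:
            raise ValueError("gains must be (3, ny, nx)")
        if np.any(self.gains <= 0):
            raise ValueError("calibration gains must be strictly positive")


def localize_beads(image, min_distance=5, threshold_rel=0.2, window=7):
    """Detect sparse beads and localize them with sub-pixel precision.

    Local maxima above ``threshold_rel`` of the image maximum are refined by
    an intensity-weighted centroid in a ``window`` x ``window`` box after
    subtracting the median of the box border as local background.  Returns an
    (n, 3) array of (x, y, intensity); empty for a blank image.
    """
    image = np.asarray(image, dtype=float)
    if image.max() - image.min() <= 0:
        return np.zeros((0, 3))
    peaks = peak_local_max(image, min_distance=min_distance,
                           threshold_rel=threshold_rel, exclude_border=window // 2)
    half = window // 2
    out = []
    border = np.ones((window, window), dtype=bool)
    border[1:-1, 1:-1] = False
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    for py, px in peaks:
        win = image[py - half:py + half + 1, px - half:px + half + 1]
        if win.shape != (window, window):
            continue
        bg = np.median(win[border])
        w = np.clip(win - bg, 0, None)
        s = w.sum()
        if s <= 0:
            continue
        out.append((px + (w * xx).sum() / s, py + (w * yy).sum() / s, s))
    return np.asarray(out).reshape(-1, 3)


def _poly_design(x, y, degree, shape):
    """2-D polynomial design matrix on coordinates normalized to [-1, 1]."""
    xn = 2.0 * x / (shape[1] - 1) - 1.0
    yn = 2.0 * y / (shape[0] - 1) - 1.0
    cols = [xn**i * yn**j for i in range(degree + 1) for j in range(degree + 1 - i)]
    return np.stack(cols, axis=-1)


def n_poly_coefficients(degree):
    return (degree + 1) * (degree + 2) // 2


def build_nonuniformity_map(
    bead_tables: Sequence[np.ndarray],
    shape,
    degree: int = 5,
    match_radius_px: float = 1.0,
    gain_floor: float = 0.05,
) -> CalibrationMap:
    """Fit per-direction gain fields from per-direction bead tables.

    ``bead_tables`` holds three (n, 3) arrays of (x, y, intensity) from the
    three directions' widefield images.  Beads present in all three tables at
    the same position (within ``match_radius_px``) contribute one sample per
    direction: intensity divided by its cross-direction mean.  A least-squares
    2-D polynomial of the given degree is fit per direction, evaluated on the
    full grid, and normalized to unit mean.
    """
    if len(bead_tables) != 3:
        raise ValueError("need bead tables for exactly 3 directions")
    tables = [np.asarray(t, dtype=float).reshape(-1, 3) for t in bead_tables]
    ref = tables[0]
    trees = [cKDTree(t[:, :2]) if len(t) else None for t in tables[1:]]
    matches = []
    for x, y, inten in ref:
        row = [(x, y, inten)]
        ok = True
        for t, tree in zip(tables[1:], trees):
            if tree is None:
                ok = False
                break
            d, idx = tree.query([x, y])
            if d > match_radius_px:
                ok = False
                break
            row.append(tuple(t[idx]))
        if ok:
            matches.append(row)
    ncoef = n_poly_coefficients(degree)
    if len(matches) < ncoef:
        raise ValueError(
            f"under-determined fit: degree {degree} needs at least {ncoef} matched "
            f"beads, got {len(matches)}"
        )
    matches = np.asarray(matches)  # (n, 3 directions, 3)
    inten = matches[:, :, 2]
    rel = inten / inten.mean(axis=1, keepdims=True)
    # positions may differ by sub-pixel localization error; use the mean
    xs = matches[:, :, 0].mean(axis=1)
    ys = matches[:, :, 1].mean(axis=1)
    X = _poly_design(xs, ys, degree, shape)

    gy, gx = np.mgrid[0:shape[0], 0:shape[1]]
    Xg = _poly_design(gx.ravel(), gy.ravel(), degree, shape)
    gains = np.empty((3, shape[0], shape[1]))
    resid = 0.0
    for i in range(3):
        coef, *_ = np.linalg.lstsq(X, rel[:, i], rcond=None)
        resid += float(np.mean((X @ coef - rel[:, i]) ** 2))
        g = (Xg @ coef).reshape(shape)
        g = np.clip(g, gain_floor, None)
        gains[i] = g / g.mean()
    return CalibrationMap(gains=gains, degree=degree, n_beads=len(matches),
                          residual=resid / 3.0,
                          meta={"match_radius_px": match_radius_px})


def apply_calibration(
    frames,
    calib: CalibrationMap,
    otf: Optional[np.ndarray] = None,
    wiener_eps: float = 1e-3,
):
    """Compensate frames for excitation nonuniformity (optionally deconvolved).

    ``frames`` is (3, 3, ny, nx) direction-major (or (3, ny, nx) of one image
    per direction).  When ``otf`` (DC-centered) is given, each frame is first
    Wiener-divided by it, conj(OTF) / (|OTF|^2 + eps) -- the bare inverse
    filter is unstable at the cutoff -- then divided by its direction's gain
    field.  With ``otf=None`` only the gain division is applied.
    """
    frames = np.asarray(frames, dtype=float)
    squeeze = frames.ndim == 3
    if squeeze:
        frames = frames[:, None]
    if frames.shape[0] != 3:
        raise ValueError("expected 3 directions")
    if frames.shape[-2:] != calib.gains.shape[-2:]:
        raise ValueError("calibration grid does not match the frame grid")
    if np.any(calib.gains <= 0):
        raise ValueError("calibration gains must be strictly positive")
    out = np.empty_like(frames)
    if otf is not None:
        otf = np.asarray(otf)
        denom = np.abs(otf) ** 2 + wiener_eps
        filt = np.where(denom > 0, np.conj(otf) / np.where(denom > 0, denom, 1.0), 0.0)
        filt = np.fft.ifftshift(filt)
    for i in range(3):
        for j in range(frames.shape[1]):
            f = frames[i, j]
            if otf is not None:
                f = np.real(np.fft.ifft2(np.fft.fft2(f) * filt))
            out[i, j] = f / calib.gains[i]
    return out[:, 0] if squeeze else out
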