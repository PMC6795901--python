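"""Pseudocolor rendering of orientation maps.

Convention: hue encodes the doubled orientation (so 0 and 180 deg share a
color, respecting the axial periodicity of dipoles), saturation encodes the
polarization factor (clipped to [0, 1]), and value encodes intensity.  Masked
pixels are rendered gray (desaturated).  A color-wheel legend makes the
mapping self-documenting.
"""

from __future__ import annotations

import numpy as np
from matplotlib.colors import hsv_to_rgb

__all__ = ["colorize_orientation", "orientation_color_wheel", "decode_hue_to_orientation"]


def colorize_orientation(orientation_deg, intensity=None, polarization_factor=None,
                         mask=None, gamma=1.0):
    """Map (orientation, intensity, p) to an RGB image.

    hue = 2 * alpha mod 360; saturation = min(p, 1) (1 if p not given);
    value = normalized intensity ** gamma (1 if not given).  Masked pixels are
    desaturated to gray at their intensity value.
    """
    alpha = np.asarray(orientation_deg, dtype=float)
    h = np.mod(2.0 * alpha, 360.0) / 360.0
    if polarization_factor is None:
        s = np.ones_like(h)
    else:
        s = np.clip(np.asarray(polarization_factor, dtype=float), 0.0, 1.0)
    if intensity is None:
        v = np.ones_like(h)
    else:
        intensity = np.asarray(intensity, dtype=float)
        vmax = intensity.max()
        v = (np.clip(intensity, 0, None) / vmax) ** gamma if vmax > 0 else np.zeros_like(h)
    if mask is not None:
        s = np.where(mask, s, 0.0)  # gray where invalid
    return hsv_to_rgb(np.stack([h, s, v], axis=-1))


def decode_hue_to_orientation(rgb):
    """Inverse of the hue mapping: recover orientation (deg) from RGB."""
    from matplotlib.colors import rgb_to_hsv

    h = rgb_to_hsv(np.asarray(rgb, dtype=float))[..., 0]
    return np.mod(h * 360.0 / 2.0, 180.0)


def orientation_color_wheel(size=129):
    """Half-turn color wheel legend: angle -> hue, radius -> saturation."""
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - c, xx - c
    r = np.hypot(dy, dx) / c
    ang = np.mod(np.rad2deg(np.arctan2(-dy, dx)), 180.0)
    rgb = colorize_orientation(ang, polarization_factor=np.clip(r, 0, 1))
    rgb[r > 1] = 1.0
    return rgb
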