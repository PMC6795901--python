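"""Downstream quantifications: harmonic census, orientation statistics,
line-profile periodicity.

These are the measurements used to characterize a polarized structured
illumination: counting the spatial/angular/cross harmonics of the pattern
spectrum, comparing reconstructed dipole orientations against filament
directions, and extracting the dominant period of a line profile (e.g. the
~190 nm actin ring spacing of the neuronal membrane-associated periodic
skeleton).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import structure_tensor

from ._utils import (
    circular_mean_orientation_deg,
    orientation_difference_deg,
    wrap_orientation_deg,
    wrapped_std_deg,
)

__all__ = [
    "HarmonicCatalog",
    "count_harmonics",
    "merge_catalogs",
    "orientation_histogram",
    "OrientationHistogram",
    "structure_tensor_orientation",
    "line_profile_period",
    "PeriodEstimate",
]


@dataclass
class HarmonicCatalog:
    """Classified peaks of a pattern spectrum.

    Peaks are (index offsets from DC..., magnitude, class); the last axis of
    the input spectrum is the angular frequency axis, preceding axes are
    spatial.  Classes: ``dc``, ``spatial`` (angular index 0), ``angular``
    (all spatial indices 0), ``cross`` (both nonzero).
    """

    peaks: list = field(default_factory=list)
    threshold_rel: float = 1e-3

    @property
    def counts(self):
        out = {"dc": 0, "spatial": 0, "angular": 0, "cross": 0}
        for pk in self.peaks:
            out[pk["class"]] += 1
        return out

    @property
    def n_peaks(self):
        return len(self.peaks)


def _classify(offsets):
    spatial = offsets[:-1]
    angular = offsets[-1]
    sp = any(o != 0 for o in spatial)
    an = angular != 0
    if not sp and not an:
        return "dc"
    if sp and not an:
        return "spatial"
    if an and not sp:
        return "angular"
    return "cross"


def count_harmonics(pattern, threshold_rel=1e-3, is_spectrum=False) -> HarmonicCatalog:
    """Locate and classify the harmonics of a (noise-free) illumination pattern.

    ``pattern`` is a real array whose last axis is the angular dimension and
    whose other axes (0, 1 or 2 of them) are spatial; every bin of its
    DC-centered Fourier magnitude above ``threshold_rel`` times the global
    maximum counts as one harmonic.  This presumes a leakage-free (noise-free,
    frequency-grid-aligned) analytic pattern, whose spectrum is a set of
    isolated deltas -- note that the angular harmonics always occupy the bins
    immediately adjacent to DC (one cycle per half-turn), so a local-maximum
    census would miss them.  Pass ``is_spectrum=True`` if ``pattern`` is
    already a DC-centered magnitude spectrum.
    """
    pattern = np.asarray(pattern)
    if is_spectrum:
        mag = np.abs(pattern)
    else:
        mag = np.abs(np.fft.fftshift(np.fft.fftn(pattern)))
    peak = mag.max()
    if peak <= 0:
        return HarmonicCatalog(threshold_rel=threshold_rel)
    above = mag > threshold_rel * peak
    center = tuple(s // 2 for s in mag.shape)
    cat = HarmonicCatalog(threshold_rel=threshold_rel)
    for idx in zip(*np.nonzero(above)):
        offsets = tuple(int(i - c) for i, c in zip(idx, center))
        cat.peaks.append({
            "index": offsets,
            "magnitude": float(mag[idx]),
            "class": _classify(offsets),
        })
    return cat


def merge_catalogs(catalogs: Sequence[HarmonicCatalog], tol=0.5) -> HarmonicCatalog:
    """Union of harmonic positions across several patterns (e.g. 3 directions)."""
    merged = HarmonicCatalog()
    for cat in catalogs:
        for pk in cat.peaks:
            pos = np.asarray(pk["index"], dtype=float)
            for other in merged.peaks:
                if np.linalg.norm(pos - np.asarray(other["index"], float)) <= tol:
                    other["magnitude"] = max(other["magnitude"], pk["magnitude"])
                    break
            else:
                merged.peaks.append(dict(pk))
    return merged


# ---------------------------------------------------------------------------
# Orientation statistics
# ---------------------------------------------------------------------------

@dataclass
class OrientationHistogram:
    bin_centers_deg: np.ndarray
    counts: np.ndarray
    circular_mean_deg: float
    circular_sd_deg: float
    n: int


def structure_tensor_orientation(image, sigma=2.0):
    """Local filament direction from the Gaussian-gradient structure tensor.

    Returns the orientation (degrees, [0, 180)) of least intensity variation,
    i.e. along the ridge of a filament.
    """
    Ayy, Axy, Axx = structure_tensor(np.asarray(image, dtype=float), sigma=sigma,
                                     order="rc")
    # direction of maximal gradient energy; the filament runs perpendicular
    grad_dir = 0.5 * np.arctan2(2 * Axy, Axx - Ayy)
    return wrap_orientation_deg(np.rad2deg(grad_dir) + 90.0)


def orientation_histogram(orientation_deg, reference, roi=None,
                          bin_width_deg=5.0) -> OrientationHistogram:
    """Histogram of orientation minus reference, wrapped to (-90, 90].

    ``reference`` may be a scalar, a map of the same shape (e.g. ground-truth
    or structure-tensor filament directions), and ``roi`` a boolean mask
    restricting the statistics.  Reports the circular mean (via the doubled
    angle) and the wrapped standard deviation about it.
    """
    orientation = np.asarray(orientation_deg, dtype=float)
    diffs = orientation_difference_deg(orientation, reference)
    if roi is not None:
        diffs = diffs[np.asarray(roi, bool)]
    diffs = np.ravel(diffs)
    if diffs.size == 0:
        raise ValueError("empty ROI: no orientations to histogram")
    edges = np.arange(-90.0, 90.0 + bin_width_deg / 2, bin_width_deg)
    counts, _ = np.histogram(diffs, bins=edges)
    mean = circular_mean_orientation_deg(diffs)
    if mean > 90.0:
        mean -= 180.0
    sd = wrapped_std_deg(diffs)
    return OrientationHistogram(
        bin_centers_deg=(edges[:-1] + edges[1:]) / 2.0,
        counts=counts, circular_mean_deg=mean, circular_sd_deg=sd,
        n=int(diffs.size),
    )


# ---------------------------------------------------------------------------
# Periodicity of a line profile
# ---------------------------------------------------------------------------

@dataclass
class PeriodEstimate:
    period_nm: float
    frequency_cycles_nm: float
    significance: float
    profile: np.ndarray
    sample_nm: float


def line_profile_period(image, polyline_px, pixel_nm, oversample=4.0,
                        min_significance=4.0) -> Optional[PeriodEstimate]:
    """Dominant period (nm) of the intensity profile along a polyline.

    The profile is interpolated along the path (spline order 1), mean
    subtracted, Hann windowed and Fourier transformed; the strongest non-DC
    peak is refined by parabolic interpolation and converted to nm.
    ``significance`` is the peak magnitude over the median spectrum magnitude;
    ``None`` is returned when no peak reaches ``min_significance`` (e.g. a
    constant profile).
    """
    pts = np.asarray(polyline_px, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("polyline must be (n >= 2, 2) as (y, x) pixel points")
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    length_px = seg_len.sum()
    n_samples = max(int(np.ceil(length_px * oversample)), 16)
    if length_px < 4:
        raise ValueError("profile too short to estimate a period")
    t = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = np.linspace(0, length_px, n_samples)
    ys = np.interp(s, t, pts[:, 0])
    xs = np.interp(s, t, pts[:, 1])
    profile = ndimage.map_coordinates(np.asarray(image, dtype=float),
                                      [ys, xs], order=1, mode="nearest")
    sample_nm = (length_px * pixel_nm) / (n_samples - 1)

    x = (profile - profile.mean()) * np.hanning(n_samples)
    spec = np.abs(np.fft.rfft(x))
    if spec.size < 4:
        raise ValueError("profile too short to estimate a period")
    spec[0] = 0.0
    i = int(np.argmax(spec))
    med = np.median(spec[1:])
    significance = float(spec[i] / med) if med > 0 else np.inf
    if spec[i] <= 0 or significance < min_significance:
        return None
    # parabolic refinement of the peak bin
    if 1 <= i < spec.size - 1:
        a, b, c = spec[i - 1], spec[i], spec[i + 1]
        denom = a - 2 * b + c
        di = 0.5 * (a - c) / denom if denom != 0 else 0.0
    else:
        di = 0.0
    freq = (i + di) / (n_samples * sample_nm)  # cycles per nm
    return PeriodEstimate(period_nm=1.0 / freq, frequency_cycles_nm=freq,
                          significance=significance, profile=profile,
                          sample_nm=sample_nm)
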