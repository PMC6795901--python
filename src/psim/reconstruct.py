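"""Spectral assembly and the full pSIM reconstruction pipeline.

The pipeline mirrors the two-step algorithm: a SIM step (per-direction
harmonic separation, sub-pixel spectral shifting to an enlarged grid and
generalized-Wiener assembly) and a PM step (the three-polarization cosine
system for per-pixel dipole orientation and polarization factor).

Two assembly modes produce the orientation maps:

- ``"perdir"`` (default): each direction's zeroth and +/- first components
  are assembled into a super-resolved image of the sample under that
  direction's excitation polarization; the three SR images are then fit
  per-pixel to I = A cos(2 (theta - alpha)) + B.  This uses exactly the nine
  solvable components.
- ``"hyperspace"``: the literal reciprocal-space assembly -- all seven
  spatial spectra on the angular-DC plane plus the two angular harmonics
  solved by the PM inversion; the unsolvable spatio-angular cross harmonics
  are set to zero, which (as the ablation experiment shows) affects only the
  polarization factor, not intensity or orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from ._utils import centered_spectrum, inverse_centered_spectrum, wrap_orientation_deg
from .calibration import CalibrationMap, apply_calibration
from .forward import RawStack
from .harmonics import (
    SeparatedComponents,
    estimate_pattern_params,
    separate_components,
    shift_component,
    widefield_from_phases,
)
from .optics import OpticalModel
from .polarization import DipoleFit, fit_dipole_cosine, solve_angular_harmonics
from .scene import DipoleScene, AcquisitionProtocol

__all__ = [
    "PsimConfig",
    "PsimResult",
    "assemble_sim",
    "assemble_direction",
    "assemble_directions_equalized",
    "reconstruct_psim",
    "reconstruct_pm",
    "reconstruct_widefield",
    "ablate_cross_harmonics",
]


@dataclass
class PsimConfig:
    """Tunable reconstruction parameters.

    ``phases``: "estimate" recovers stripe vector/phase/modulation from the
    data (real systems drift); "nominal" trusts the protocol.  ``wiener`` is
    the generalized-Wiener regularizer relative to the normalized OTF^2.
    ``mask_frac`` masks pixels below that fraction of the 99.9th-percentile
    intensity.  ``calib_stage`` selects whether nonuniformity compensation is
    applied to the separated zeroth components (before the PM step) or to the
    raw frames; ``calib_deconvolve`` additionally Wiener-divides by the OTF
    during compensation.
    """

    phases: str = "estimate"
    assembly: str = "hyperspace"
    wiener: float = 0.05
    mask_frac: float = 0.05
    apodize: bool = True
    calib_stage: str = "c0"
    calib_deconvolve: bool = False
    calib_wiener_eps: float = 1e-3
    clip_negative: bool = True

    def __post_init__(self):
        if self.phases not in ("estimate", "nominal"):
            raise ValueError("phases must be 'estimate' or 'nominal'")
        if self.assembly not in ("perdir", "hyperspace"):
            raise ValueError("assembly must be 'perdir' or 'hyperspace'")
        if self.calib_stage not in ("c0", "frames"):
            raise ValueError("calib_stage must be 'c0' or 'frames'")


@dataclass
class PsimResult:
    """Super-resolved intensity, dipole orientation and polarization factor."""

    intensity: np.ndarray
    orientation_deg: np.ndarray
    polarization_factor: np.ndarray
    mask: np.ndarray
    pixel_nm: float
    A: Optional[np.ndarray] = None
    B: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)


def _stage(name):
    """Decorator-less stage tagging: wrap exceptions with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise type(exc)(f"[{name}] {exc}") from None
            return False

    return _Ctx()


def _component_entries(sep: SeparatedComponents, k_px, which=("0", "+", "-")):
    """(spectrum, shift in cycles/px) pairs registering each component.

    The '+' component carries the specimen spectrum G(k - k_s) inside the OTF
    passband, so translating it by -k_s registers it (it extends coverage
    toward -k_s); symmetrically for '-'.
    """
    k_px = np.asarray(k_px, dtype=float)
    entries = []
    if "0" in which:
        entries.append((sep.C0, np.zeros(2)))
    if "+" in which:
        entries.append((sep.Cplus, -k_px))
    if "-" in which:
        entries.append((sep.Cminus, +k_px))
    return entries


def _num_den(entries, optics: OpticalModel, pixel_nm, wiener):
    """Wiener numerator / denominator of a component set on the 2x grid."""
    n_shape = entries[0][0].shape
    big_shape = (2 * n_shape[0], 2 * n_shape[1])
    num = np.zeros(big_shape, dtype=complex)
    den = np.full(big_shape, float(wiener))
    for C, shift_px in entries:
        H = shift_component(C, shift_px, upsample=2)
        shift_nm = np.asarray(shift_px) / pixel_nm
        O = optics.otf_grid(big_shape, pixel_nm=pixel_nm / 2.0,
                            shift_cycles_nm=shift_nm)
        num += O * H  # OTF is real
        den += O**2
    return num, den


def _apodization_cone(big_shape, pixel_nm, kmax_cycles_nm):
    ky = np.fft.fftshift(np.fft.fftfreq(big_shape[0], d=pixel_nm / 2.0))
    kx = np.fft.fftshift(np.fft.fftfreq(big_shape[1], d=pixel_nm / 2.0))
    kyg, kxg = np.meshgrid(ky, kx, indexing="ij")
    return np.clip(1.0 - np.hypot(kyg, kxg) / kmax_cycles_nm, 0.0, None)


def _wiener_assemble(entries, optics: OpticalModel, pixel_nm, wiener, apodize,
                     extra_support_nm=0.0):
    """Generalized-Wiener sum of shifted components on the 2x grid."""
    num, den = _num_den(entries, optics, pixel_nm, wiener)
    spec = num / den
    spec *= 4.0  # keep the 2x-grid image on the camera-frame intensity scale
    if apodize:
        spec *= _apodization_cone(spec.shape, pixel_nm,
                                  optics.cutoff_cycles_nm + extra_support_nm)
    return inverse_centered_spectrum(spec)


def assemble_sim(seps, k_list_px, optics: OpticalModel, pixel_nm,
                 wiener=0.05, apodize=True, clip_negative=True):
    """Assemble the super-resolved SIM intensity image from 3 directions.

    Uses seven spatial spectra -- the zeroth component (averaged over the
    three directions, which cancels the polarization weighting for equally
    spaced excitation polarizations) and the six shifted first-order
    components -- weighted by their shifted OTFs, divided by the total
    OTF-power plus the Wiener constant, apodized by a cone to the doubled
    cutoff, and inverse-transformed on a 2x grid.
    """
    if len(seps) != 3 or len(k_list_px) != 3:
        raise ValueError("three directions are required")
    C0_mean = (seps[0].C0 + seps[1].C0 + seps[2].C0) / 3.0
    entries = [(C0_mean, np.zeros(2))]
    kmax_nm = 0.0
    for sep, k_px in zip(seps, k_list_px):
        entries.extend(_component_entries(sep, k_px, which=("+", "-")))
        kmax_nm = max(kmax_nm, np.hypot(*np.asarray(k_px)) / pixel_nm)
    img = np.real(_wiener_assemble(entries, optics, pixel_nm, wiener, apodize,
                                   extra_support_nm=kmax_nm))
    if clip_negative:
        img = np.clip(img, 0.0, None)
    return img


def assemble_direction(sep: SeparatedComponents, k_px, optics: OpticalModel,
                       pixel_nm, wiener=0.05, apodize=True):
    """Super-resolved image of one direction (its own 3 components only).

    This is the sample as seen under that direction's excitation
    polarization, resolution-doubled along the stripe axis; the three such
    images carry the per-pixel polarization response at super-resolution.
    Output is real but *not* clipped, so the subsequent cosine fit is not
    biased at dim pixels.
    """
    entries = _component_entries(sep, k_px)
    kmax_nm = np.hypot(*np.asarray(k_px)) / pixel_nm
    return np.real(_wiener_assemble(entries, optics, pixel_nm, wiener, apodize,
                                    extra_support_nm=kmax_nm))


def assemble_directions_equalized(seps, k_list_px, optics: OpticalModel, pixel_nm,
                                  wiener=0.05, apodize=True):
    """Three per-direction SR images with a common effective transfer.

    Each direction's Wiener estimate has an anisotropic effective transfer
    T_i(k) = sum_c OTF_c^2 / (sum_c OTF_c^2 + w) whose support extends only
    along its own stripe axis.  Fitting the dipole cosine across three images
    with *different* transfers biases the orientation by several degrees on
    structures not aligned with a polarization axis, so each spectrum is
    rescaled to the pointwise minimum transfer min_i T_i before the fit.  The
    common support still reaches beyond the widefield cutoff wherever at
    least the overlapping side lobes of all three directions contribute.
    """
    if len(seps) != 3:
        raise ValueError("three directions are required")
    nums, dens = [], []
    kmax_nm = 0.0
    for sep, k_px in zip(seps, k_list_px):
        num, den = _num_den(_component_entries(sep, k_px), optics, pixel_nm, wiener)
        nums.append(num)
        dens.append(den)
        kmax_nm = max(kmax_nm, np.hypot(*np.asarray(k_px)) / pixel_nm)
    T = np.stack([(d - wiener) / d for d in dens])
    T_common = T.min(axis=0)
    apod = (_apodization_cone(nums[0].shape, pixel_nm,
                              optics.cutoff_cycles_nm + kmax_nm)
            if apodize else 1.0)
    out = []
    for num, den, Ti in zip(nums, dens, T):
        with np.errstate(divide="ignore", invalid="ignore"):
            eq = np.where(Ti > 1e-12, T_common / np.where(Ti > 1e-12, Ti, 1.0), 0.0)
        out.append(np.real(inverse_centered_spectrum(4.0 * apod * eq * num / den)))
    return np.stack(out)


def _upsample_field(field):
    """Fourier interpolation of a (possibly complex) field to the 2x grid."""
    C = np.fft.fftshift(np.fft.fft2(field))
    ny, nx = C.shape
    Z = np.zeros((2 * ny, 2 * nx), dtype=complex)
    Z[ny // 2:ny // 2 + ny, nx // 2:nx // 2 + nx] = C
    return np.fft.ifft2(np.fft.ifftshift(Z)) * 4.0


def _pattern_params(stack: RawStack, cfg: PsimConfig):
    """Per-direction (phases, k_px, modulation), nominal or estimated."""
    proto = stack.protocol
    out = []
    for i in range(3):
        nominal = np.asarray(proto.phases_rad[i], dtype=float)
        if cfg.phases == "nominal":
            k_px = proto.k_vecs_nm[i] * stack.pixel_nm
            out.append((nominal, np.asarray(k_px, dtype=float), proto.modulation))
        else:
            otf = proto.optics.otf_grid(stack.shape, pixel_nm=stack.pixel_nm)
            est = estimate_pattern_params(stack.images[i], phases_rad=nominal,
                                          otf=otf)
            steps = nominal - nominal[0]
            # estimated phase is referenced to the field center; separation
            # works with origin-referenced phases
            center = np.array([stack.shape[0] // 2, stack.shape[1] // 2], float)
            ph0 = est.phase0 - 2 * np.pi * (est.k_cycles_px @ center)
            out.append((ph0 + steps, est.k_cycles_px, est.modulation))
    return out


def reconstruct_psim(stack: RawStack, calib: Optional[CalibrationMap] = None,
                     cfg: Optional[PsimConfig] = None) -> PsimResult:
    """Full pSIM reconstruction of a 9-frame stack.

    Pipeline: pattern parameters (estimated or nominal) -> per-direction
    harmonic separation -> optional nonuniformity compensation -> spectral
    assembly (per-direction SR polarization images, or the literal hyperspace
    assembly) -> per-pixel dipole cosine fit.
    """
    cfg = cfg or PsimConfig()
    proto = stack.protocol
    frames = stack.images

    if calib is not None and cfg.calib_stage == "frames":
        with _stage("calibration"):
            otf = (proto.optics.otf_grid(stack.shape, pixel_nm=stack.pixel_nm)
                   if cfg.calib_deconvolve else None)
            frames = apply_calibration(frames, calib, otf=otf,
                                       wiener_eps=cfg.calib_wiener_eps)

    with _stage("pattern estimation"):
        params = _pattern_params(
            RawStack(frames, proto, stack.pixel_nm), cfg)

    seps = []
    with _stage("separation"):
        for i in range(3):
            phases, k_px, m = params[i]
            sep = separate_components(frames[i], phases, m)
            sep.k_cycles_px = k_px
            seps.append(sep)

    if calib is not None and cfg.calib_stage == "c0":
        with _stage("calibration"):
            wfs = np.stack([np.real(inverse_centered_spectrum(s.C0)) for s in seps])
            otf = (proto.optics.otf_grid(stack.shape, pixel_nm=stack.pixel_nm)
                   if cfg.calib_deconvolve else None)
            wfs = apply_calibration(wfs, calib, otf=otf,
                                    wiener_eps=cfg.calib_wiener_eps)
            for s, wf in zip(seps, wfs):
                s.C0 = centered_spectrum(wf)

    with _stage("assembly"):
        if cfg.assembly == "perdir":
            sr = assemble_directions_equalized(
                seps, [s.k_cycles_px for s in seps], proto.optics, stack.pixel_nm,
                wiener=cfg.wiener, apodize=cfg.apodize)
            fit = fit_dipole_cosine(sr, proto.thetas_deg, mask_frac=cfg.mask_frac)
        else:
            B_sr = assemble_sim(seps, [s.k_cycles_px for s in seps], proto.optics,
                                stack.pixel_nm, wiener=cfg.wiener,
                                apodize=cfg.apodize, clip_negative=False)
            harm = solve_angular_harmonics([s.C0 for s in seps], proto.thetas_deg,
                                           eta=proto.eta)
            otf = proto.optics.otf_grid(stack.shape, pixel_nm=stack.pixel_nm)
            filt = otf / (otf**2 + cfg.wiener)
            h = _upsample_field(inverse_centered_spectrum(harm.Hplus * filt))
            # match the (eta/2) polarization weighting retained by the
            # angular-DC plane
            A = (proto.eta / 2.0) * np.abs(h)
            alpha = wrap_orientation_deg(np.rad2deg(np.angle(h) / 2.0))
            fit = _fit_from_ab(A, B_sr, alpha, cfg.mask_frac)

    intensity = fit.A + fit.B
    if cfg.clip_negative:
        intensity = np.clip(intensity, 0.0, None)
    prov = {"cfg": asdict(cfg), "mode": "psim",
            "k_cycles_px": [list(map(float, p[1])) for p in params],
            "modulation": [float(np.atleast_1d(p[2])[0]) for p in params],
            "calibrated": calib is not None}
    return PsimResult(intensity=intensity, orientation_deg=fit.alpha_deg,
                      polarization_factor=fit.p, mask=fit.mask,
                      pixel_nm=stack.pixel_nm / 2.0, A=fit.A, B=fit.B,
                      provenance=prov)


def _fit_from_ab(A, B, alpha_deg, mask_frac):
    total = A + B
    hi = np.percentile(total, 99.9)
    mask = (total > max(mask_frac * hi, 0.0)) if hi > 0 else np.zeros(total.shape, bool)
    mask = mask & (A > 1e-12 * max(hi, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, 2.0 * A / np.where(total > 0, total, 1.0), 0.0)
    return DipoleFit(A=A, B=B, alpha_deg=alpha_deg, p=p, mask=mask,
                     meta={"mask_frac": mask_frac})


def reconstruct_pm(stack: RawStack, calib: Optional[CalibrationMap] = None,
                   mask_frac=0.05) -> PsimResult:
    """Diffraction-limited polarization-modulation baseline.

    Per direction the widefield image (exact zeroth-order solve) is computed,
    optionally compensated for nonuniformity, and the three widefield images
    are fit per-pixel to the dipole cosine.  This is what a conventional PM
    microscope measures with the same data.
    """
    proto = stack.protocol
    wfs = np.stack([
        widefield_from_phases(stack.images[i], proto.phases_rad[i])
        for i in range(3)
    ])
    if calib is not None:
        wfs = apply_calibration(wfs, calib)
    fit = fit_dipole_cosine(wfs, proto.thetas_deg, mask_frac=mask_frac)
    return PsimResult(intensity=np.clip(fit.intensity, 0, None),
                      orientation_deg=fit.alpha_deg, polarization_factor=fit.p,
                      mask=fit.mask, pixel_nm=stack.pixel_nm, A=fit.A, B=fit.B,
                      provenance={"mode": "pm", "calibrated": calib is not None})


def reconstruct_widefield(stack: RawStack):
    """Plain widefield image: average of all nine raw frames."""
    return stack.images.mean(axis=(0, 1))


# ---------------------------------------------------------------------------
# Cross-harmonic ablation
# ---------------------------------------------------------------------------

def ablate_cross_harmonics(scene: DipoleScene, protocol: AcquisitionProtocol,
                           region: str = "psim_observable"):
    """Frequency-support ablation of the spatio-angular scene spectrum.

    The scene is Fourier-transformed over (x, y, alpha); components outside
    the chosen region are zeroed and the maps (intensity, orientation, p) are
    extracted from the inverse transform.

    ``region="psim_observable"`` keeps the nine solvable pedals: on the
    angular-DC plane the central circle plus the six stripe-shifted circles,
    and on the +/- first angular planes the central circle only.
    ``region="full_doubled"`` additionally keeps the twelve spatio-angular
    cross pedals (shifted circles on the angular planes), i.e. all 21
    components of the doubled region.
    """
    if region not in ("psim_observable", "full_doubled"):
        raise ValueError("region must be 'psim_observable' or 'full_doubled'")
    ny, nx = scene.shape
    na = scene.n_angles
    if ny * nx * na > 256 * 256 * 32:
        raise ValueError("scene too large for a dense spatio-angular transform")

    S = np.fft.fftn(scene.density, axes=(0, 1, 2))
    ky = np.fft.fftfreq(ny, d=scene.pixel_nm)
    kx = np.fft.fftfreq(nx, d=scene.pixel_nm)
    kyg, kxg = np.meshgrid(ky, kx, indexing="ij")
    kc = protocol.optics.cutoff_cycles_nm

    central = np.hypot(kyg, kxg) <= kc
    shifted = np.zeros_like(central)
    for kvec in protocol.k_vecs_nm:
        for sgn in (+1, -1):
            shifted |= np.hypot(kyg - sgn * kvec[0], kxg - sgn * kvec[1]) <= kc

    ka = np.rint(np.fft.fftfreq(na) * na).astype(int)  # cycles per half-turn
    mask = np.zeros(S.shape, dtype=bool)
    mask[:, :, ka == 0] = (central | shifted)[:, :, None]
    ang_plane = central | shifted if region == "full_doubled" else central
    for idx in np.nonzero(np.abs(ka) == 1)[0]:
        mask[:, :, idx] = ang_plane

    filtered = np.fft.ifftn(S * mask, axes=(0, 1, 2)).real
    d_alpha = np.pi / na
    s0 = filtered.sum(axis=2) * d_alpha
    ph = np.exp(2j * np.deg2rad(scene.angles_deg))
    h = (filtered * ph[None, None, :]).sum(axis=2) * d_alpha
    A = np.abs(h)
    alpha = wrap_orientation_deg(np.rad2deg(np.angle(h) / 2.0))
    total = s0 + A
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, 2.0 * A / np.where(total > 0, total, 1.0), 0.0)
    # the intensity image is the angular DC (total emitter density)
    return s0, alpha, p
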