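"""TIFF / JSON input-output and the acquisition metadata sidecar.

Raw stacks travel as 9-page multi-page TIFFs (float32 or uint16) with a JSON
sidecar carrying the acquisition descriptor: pixel size, wavelength, NA, the
three excitation polarizations, the 3 x 3 phase table and the declared frame
order.  In-memory order is always canonical direction-major
(d1p1, d1p2, d1p3, d2p1, ...).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from .forward import RawStack
from .optics import OpticalModel
from .scene import AcquisitionProtocol

__all__ = ["AcquisitionMeta", "write_raw_stack", "read_raw_stack",
           "write_float_tiff", "read_float_tiff"]

FRAME_ORDERS = ("direction_major", "phase_major")


@dataclass
class AcquisitionMeta:
    """Serializable acquisition descriptor for a 9-frame pSIM stack."""

    pixel_nm: float
    wavelength_nm: float
    numerical_aperture: float
    thetas_deg: list
    phases_rad: list  # 3 x 3
    frame_order: str = "direction_major"
    k_vecs_nm: Optional[list] = None
    modulation: float = 1.0
    seed: Optional[int] = None
    software: str = "psim"
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.frame_order not in FRAME_ORDERS:
            raise ValueError(f"frame_order must be one of {FRAME_ORDERS}")
        if len(self.thetas_deg) != 3:
            raise ValueError("exactly 3 excitation polarizations are required")
        phases = np.asarray(self.phases_rad, dtype=float)
        if phases.shape != (3, 3):
            raise ValueError("phases_rad must be a 3 x 3 table")

    def to_protocol(self) -> AcquisitionProtocol:
        optics = OpticalModel(wavelength_nm=self.wavelength_nm,
                              numerical_aperture=self.numerical_aperture,
                              pixel_nm=self.pixel_nm)
        kw = {}
        if self.k_vecs_nm is not None:
            kw["k_vecs_nm"] = np.asarray(self.k_vecs_nm, dtype=float)
        return AcquisitionProtocol(optics=optics, thetas_deg=self.thetas_deg,
                                   phases_rad=np.asarray(self.phases_rad),
                                   modulation=self.modulation, **kw)

    @classmethod
    def from_protocol(cls, protocol: AcquisitionProtocol, frame_order="direction_major",
                      seed=None):
        return cls(
            pixel_nm=protocol.optics.pixel_nm,
            wavelength_nm=protocol.optics.wavelength_nm,
            numerical_aperture=protocol.optics.numerical_aperture,
            thetas_deg=list(map(float, protocol.thetas_deg)),
            phases_rad=np.asarray(protocol.phases_rad).tolist(),
            frame_order=frame_order,
            k_vecs_nm=np.asarray(protocol.k_vecs_nm).tolist(),
            modulation=float(protocol.modulation),
            seed=seed,
        )

    def save(self, path):
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def load(cls, path):
        return cls(**json.loads(Path(path).read_text()))


def write_float_tiff(path, image, pixel_nm=None):
    """float32 TIFF with the physical pixel size recorded in its resolution tags."""
    kwargs = {}
    if pixel_nm is not None:
        # TIFF resolution in pixels per centimeter
        res = 1.0e7 / pixel_nm
        kwargs = {"resolution": (res, res), "resolutionunit": "CENTIMETER"}
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32), **kwargs)


def read_float_tiff(path):
    return tifffile.imread(str(path)).astype(float)


def write_raw_stack(tiff_path, stack: RawStack, meta_path=None,
                    frame_order="direction_major") -> AcquisitionMeta:
    """Write a RawStack as a 9-page TIFF plus its JSON metadata sidecar."""
    pages = stack.images.reshape(9, *stack.shape)
    if frame_order == "phase_major":
        pages = stack.images.transpose(1, 0, 2, 3).reshape(9, *stack.shape)
    elif frame_order != "direction_major":
        raise ValueError(f"frame_order must be one of {FRAME_ORDERS}")
    tifffile.imwrite(str(tiff_path), pages.astype(np.float32))
    meta = AcquisitionMeta.from_protocol(stack.protocol, frame_order=frame_order,
                                         seed=stack.seed)
    if meta_path is None:
        meta_path = Path(tiff_path).with_suffix(".json")
    meta.save(meta_path)
    return meta


def read_raw_stack(tiff_path, meta=None, **overrides) -> RawStack:
    """Read a 9-page TIFF (+ sidecar metadata) into a canonical RawStack.

    ``meta`` may be an :class:`AcquisitionMeta`, a path to its JSON file, or
    ``None`` to look for ``<tiff stem>.json``.  Keyword overrides update the
    metadata fields before interpretation.  Pages declared ``phase_major``
    are reordered to the canonical direction-major layout.
    """
    pages = tifffile.imread(str(tiff_path)).astype(float)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] != 9:
        raise ValueError(f"expected 9 pages (3 directions x 3 phases), got {pages.shape[0]}")
    if meta is None:
        meta = Path(tiff_path).with_suffix(".json")
    if not isinstance(meta, AcquisitionMeta):
        meta_path = Path(meta)
        if not meta_path.exists():
            raise ValueError(f"metadata file not found: {meta_path}")
        meta = AcquisitionMeta.load(meta_path)
    if overrides:
        d = asdict(meta)
        d.update(overrides)
        meta = AcquisitionMeta(**d)
    if meta.frame_order == "phase_major":
        images = pages.reshape(3, 3, *pages.shape[1:]).transpose(1, 0, 2, 3)
    else:
        images = pages.reshape(3, 3, *pages.shape[1:])
    protocol = meta.to_protocol()
    return RawStack(images, protocol, meta.pixel_nm, seed=meta.seed,
                    extras={"meta": meta})
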