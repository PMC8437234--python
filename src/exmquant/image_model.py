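"""Calibrated image volumes and the projections shared by every analysis stage.

The universal input is a confocal z-stack: a ``(z, y, x)`` grid of non-negative
fluorescence intensities with a physical pixel size in the imaging plane and a
z-step between planes, both in nanometres. Calibration is mandatory at
construction — there is no silent 1 px = 1 nm default — because every
downstream quantity (periodicities, diameters, centroid displacements) is
physical.

Conventions: plane axis order is ``(z, y, x)``; x increases rightward, y
downward (raster convention); all pixel/plane coordinates are 0-based.
Intensities are held as floating point regardless of the bit depth of the file
they came from.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "Image2D",
    "ReferenceConstants",
    "read_stack",
    "write_stack",
    "project",
    "InputError",
    "UnsupportedFormatError",
    "ValidationError",
]


class InputError(FileNotFoundError):
    """A required input file is missing."""


class UnsupportedFormatError(ValueError):
    """The file is not a single-channel grayscale TIFF."""


class ValidationError(ValueError):
    """An argument violates a documented precondition."""


def _check_intensities(arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValidationError("intensities must be finite")
    if arr.size and float(arr.min()) < 0:
        raise ValidationError("intensities must be non-negative")


@dataclass
class ImageStack:
    """A calibrated 3D intensity volume.

    Parameters
    ----------
    voxels : ndarray, shape (z, y, x)
        Non-negative intensities. A 1-plane stack is a valid 2D image.
    pixel_size_xy : float
        Lateral pixel size in nm.
    z_step : float
        Axial plane spacing in nm.
    channel_label : str
        Free-text channel description.
    """

    voxels: np.ndarray
    pixel_size_xy: float
    z_step: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim == 2:
            self.voxels = self.voxels[None, :, :]
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValidationError("voxels must be a (z, y, x) grid with >= 1 plane")
        if not (self.pixel_size_xy > 0 and self.z_step > 0):
            raise ValidationError("pixel_size_xy and z_step must be positive")
        _check_intensities(self.voxels)

    @property
    def n_planes(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def plane(self, index: int) -> "Image2D":
        return Image2D(self.voxels[index], self.pixel_size_xy)

    def substack(self, z0: int, z1: int) -> "ImageStack":
        """Planes ``z0..z1`` inclusive, calibration preserved."""
        if not (0 <= z0 <= z1 < self.n_planes):
            raise ValidationError(f"plane interval [{z0}, {z1}] out of bounds")
        return replace(self, voxels=self.voxels[z0 : z1 + 1].copy())


@dataclass
class Image2D:
    """A single calibrated 2D image (typically a projection of a stack)."""

    pixels: np.ndarray
    pixel_size_xy: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValidationError("pixels must be 2D")
        if not self.pixel_size_xy > 0:
            raise ValidationError("pixel_size_xy must be positive")
        _check_intensities(self.pixels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ReferenceConstants:
    """Physical reference values the expansion-factor arithmetic divides by.

    axoneme_diameter_ref : nm — native axoneme cross-section diameter (220 nm,
        the transmission-EM value for the 9+2 axoneme).
    corset_center_to_center_ref : nm — native centre-to-centre distance of
        adjacent corset microtubules (~50 nm: 24 nm inter-microtubule gap plus
        ~25 nm microtubule diameter, rounded as conventionally reported).
    lateral_blur : nm — lateral optical blur (PSF FWHM) of the acquisition.
    tilt_limit_deg : degrees — maximum tube tilt from the optical axis a
        5-plane axoneme window may have and still count as perpendicular.
    """

    axoneme_diameter_ref: float = 220.0
    corset_center_to_center_ref: float = 50.0
    lateral_blur: float = 200.0
    tilt_limit_deg: float = 5.0

    def __post_init__(self) -> None:
        for name in ("axoneme_diameter_ref", "corset_center_to_center_ref", "lateral_blur"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")
        if not 0 < self.tilt_limit_deg < 90:
            raise ValidationError("tilt_limit_deg must lie in (0, 90)")


def sidecar_path(path: str | Path) -> Path:
    """``<name>.meta.json`` next to a TIFF file."""
    p = Path(path)
    return p.parent / (p.stem + ".meta.json")


def read_stack(
    path: str | Path,
    pixel_size_xy: float | None = None,
    z_step: float | None = None,
    channel_label: str | None = None,
) -> ImageStack:
    """Read a single- or multi-page grayscale TIFF into a calibrated stack.

    Calibration arguments override (or supply, when the file has none) the
    values found in the JSON sidecar written by :func:`write_stack`. Plane
    order is preserved.
    """
    p = Path(path)
    if not p.exists():
        raise InputError(f"no such file: {p}")
    arr = tifffile.imread(p)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise UnsupportedFormatError(
            f"expected grayscale 2D/3D TIFF, got array of shape {arr.shape}"
        )
    # RGB(A) pages read as (..., y, x, 3|4); a genuine z-stack has many more
    # rows than 4 in its trailing axis.
    if arr.shape[-1] in (3, 4) and arr.shape[-2] > 8:
        raise UnsupportedFormatError("RGB/multi-channel TIFF is not supported")

    meta: dict = {}
    sp = sidecar_path(p)
    if sp.exists():
        meta = json.loads(sp.read_text())
    px = pixel_size_xy if pixel_size_xy is not None else meta.get("pixel_size_xy_nm")
    dz = z_step if z_step is not None else meta.get("z_step_nm", px)
    label = channel_label if channel_label is not None else meta.get("channel_label", "")
    if px is None:
        raise ValidationError("pixel_size_xy missing: not in sidecar and not supplied")
    if px <= 0 or (dz is not None and dz <= 0):
        raise ValidationError("calibration values must be positive")

    voxels = arr.astype(np.float64)
    scale = meta.get("intensity_scale", 1.0)
    offset = meta.get("intensity_offset", 0.0)
    if scale != 1.0 or offset != 0.0:
        voxels = voxels * scale + offset
    return ImageStack(voxels, float(px), float(dz), label)


def write_stack(
    stack: ImageStack,
    path: str | Path,
    ground_truth: dict | None = None,
) -> Path:
    """Write a stack as a 16-bit multi-page TIFF plus a JSON sidecar.

    Intensities are linearly rescaled into the uint16 range when needed; the
    scale and offset are recorded in the sidecar and undone by
    :func:`read_stack`, so integral data within range round trip bit-exactly.
    An optional ``ground_truth`` block (e.g. a synthetic generator record) is
    embedded verbatim in the sidecar.
    """
    p = Path(path)
    v = stack.voxels
    vmax = float(v.max()) if v.size else 0.0
    integral = bool(np.all(v == np.round(v)))
    if integral and vmax <= 65535:
        data = v.astype(np.uint16)
        scale, offset = 1.0, 0.0
    else:
        vmin = float(v.min())
        span = vmax - vmin
        scale = span / 65535.0 if span > 0 else 1.0
        offset = vmin
        data = np.round((v - offset) / scale).astype(np.uint16)
    try:
        tifffile.imwrite(
            p,
            data,
            photometric="minisblack",
            resolution=(1e7 / stack.pixel_size_xy, 1e7 / stack.pixel_size_xy),
            resolutionunit="CENTIMETER",
        )
    except OSError as exc:  # unwritable path
        raise OSError(f"cannot write TIFF to {p}: {exc}") from exc
    meta = {
        "pixel_size_xy_nm": stack.pixel_size_xy,
        "z_step_nm": stack.z_step,
        "channel_label": stack.channel_label,
        "intensity_scale": scale,
        "intensity_offset": offset,
    }
    if ground_truth is not None:
        meta["ground_truth"] = ground_truth
    sidecar_path(p).write_text(json.dumps(meta, indent=2))
    return p


def project(
    stack: ImageStack,
    method: str = "average",
    z_range: tuple[int, int] | None = None,
) -> Image2D:
    """Average- or maximum-intensity projection over an inclusive plane interval.

    ``z_range=None`` projects the whole stack. Calibration is propagated to
    the output image.
    """
    if z_range is None:
        z0, z1 = 0, stack.n_planes - 1
    else:
        z0, z1 = z_range
    if not (0 <= z0 <= z1 < stack.n_planes):
        raise ValidationError(f"z_range [{z0}, {z1}] empty or out of bounds")
    planes = stack.voxels[z0 : z1 + 1]
    if method == "average":
        out = planes.mean(axis=0)
    elif method == "max":
        out = planes.max(axis=0)
    else:
        raise ValidationError(f"unknown projection method {method!r}")
    return Image2D(out, stack.pixel_size_xy)
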