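"""Synthetic confocal stacks with known ground truth.

Three image classes drive the analysis and are emulated here:

* **parallel lines** — patches of the subpellicular corset where evenly spaced
  microtubules lie parallel to the image plane, the input of the Fourier
  spacing estimator;
* **tube** — an axoneme oriented (nearly) along the optical axis, one circular
  cross-section per z-plane, optionally tilted, anisotropically scaled in y,
  and drifting laterally plane to plane — the input of the isotropy pipeline;
* **filament** — a curved elongated object of known arc length standing in
  for a whole corset in a maximum-intensity projection, the input of the
  length measurement.

All generators rasterize an ideal fluorophore distribution, convolve it with a
separable anisotropic Gaussian PSF parameterized by FWHM (sigma = FWHM/2.3548),
and corrupt it with Poisson shot noise followed by additive Gaussian read
noise — the standard fluorescence imaging model. Identical parameters and seed
give bit-identical stacks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Any

import numpy as np
from scipy import ndimage

from .image_model import ImageStack, ValidationError

__all__ = [
    "SyntheticGroundTruth",
    "NoiseParams",
    "make_parallel_lines",
    "make_tube",
    "make_filament",
    "FWHM_TO_SIGMA",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # 1/2.3548

#: Defaults adopted throughout: 200 nm lateral blur (measured-bead PSF FWHM of
#: the acquisitions being emulated) and 500 nm axial blur (conventional
#: confocal axial resolution).
DEFAULT_PSF_LATERAL = 200.0
DEFAULT_PSF_AXIAL = 500.0


@dataclass(frozen=True)
class NoiseParams:
    """Poisson-Gaussian noise model.

    gaussian_sd : additive read-noise standard deviation, intensity units.
    poisson_scale : photons per unit intensity; 0 disables shot noise.
    """

    gaussian_sd: float = 0.0
    poisson_scale: float = 0.0

    @property
    def enabled(self) -> bool:
        return self.gaussian_sd > 0 or self.poisson_scale > 0


#: Mild noise used by default in recovery experiments: enough photons that the
#: intermeans threshold cleanly separates structure from background.
MILD_NOISE = NoiseParams(gaussian_sd=0.02, poisson_scale=200.0)


@dataclass
class SyntheticGroundTruth:
    """The generating parameters of a simulated stack — the recovery oracle."""

    kind: str  # {lines, tube, filament}
    psf_fwhm_lateral: float = DEFAULT_PSF_LATERAL
    psf_fwhm_axial: float = DEFAULT_PSF_AXIAL
    noise_gaussian_sd: float = 0.0
    noise_poisson_scale: float = 0.0
    seed: int = 0
    # lines
    spacing_true: float | None = None  # nm
    orientation_deg: float | None = None
    # tube
    diameter_true: float | None = None  # nm
    tilt_deg: float | None = None
    anisotropy_yx: float | None = None
    drift_per_plane: tuple[float, float] | None = None  # (dx, dy) nm
    # filament
    arc_length_true: float | None = None  # um

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        return {k: v for k, v in d.items() if v is not None}


def _apply_noise(img: np.ndarray, noise: NoiseParams, rng: np.random.Generator) -> np.ndarray:
    out = img
    if noise.poisson_scale > 0:
        out = rng.poisson(np.maximum(out, 0.0) * noise.poisson_scale) / noise.poisson_scale
    if noise.gaussian_sd > 0:
        out = out + rng.normal(0.0, noise.gaussian_sd, size=out.shape)
    # intensities are non-negative by contract; read noise can undershoot zero
    return np.maximum(out, 0.0)


def make_parallel_lines(
    spacing: float,
    orientation_deg: float = 0.0,
    n_lines: int | None = None,
    field_size: int = 256,
    pixel_size_xy: float = 70.0,
    psf_fwhm_lateral: float = DEFAULT_PSF_LATERAL,
    noise: NoiseParams | None = None,
    seed: int = 0,
) -> tuple[ImageStack, SyntheticGroundTruth]:
    """Evenly spaced unit-intensity lines, blurred and noised.

    ``orientation_deg`` is the direction of the periodic modulation (the wave
    vector); the line crests run perpendicular to it. 0 deg therefore gives
    vertical lines repeating along x, 90 deg the transposed pattern.

    Raises ``ValidationError`` when ``spacing < 2 * pixel_size_xy`` (the
    pattern would be below the Nyquist limit of the sampling).
    """
    if spacing < 2.0 * pixel_size_xy:
        raise ValidationError(
            f"spacing {spacing} nm is below the minimum resolvable spacing "
            f"{2.0 * pixel_size_xy} nm at pixel size {pixel_size_xy} nm"
        )
    if n_lines is None:
        # fill the field at any orientation (corset patches span the region)
        n_lines = int(math.ceil(1.5 * field_size * pixel_size_xy / spacing)) + 1
    if n_lines < 3:
        raise ValidationError("n_lines must be >= 3")
    noise = noise or NoiseParams()
    rng = np.random.default_rng(seed)

    t = math.radians(orientation_deg)
    c = (field_size - 1) / 2.0
    yy, xx = np.mgrid[0:field_size, 0:field_size].astype(np.float64)
    # coordinate along the modulation direction, in px
    u = (xx - c) * math.cos(t) + (yy - c) * math.sin(t)
    spacing_px = spacing / pixel_size_xy
    raster = np.zeros((field_size, field_size))
    for k in range(n_lines):
        u_k = (k - (n_lines - 1) / 2.0) * spacing_px
        raster += np.maximum(0.0, 1.0 - np.abs(u - u_k))  # 1-px triangular profile

    # the corset pattern continues beyond the patch: replicate edges so blur
    # does not bleed flux out of the field
    sigma_px = psf_fwhm_lateral * FWHM_TO_SIGMA / pixel_size_xy
    img = ndimage.gaussian_filter(raster, sigma_px, mode="nearest")
    img = _apply_noise(img, noise, rng)

    gt = SyntheticGroundTruth(
        kind="lines",
        spacing_true=spacing,
        orientation_deg=orientation_deg,
        psf_fwhm_lateral=psf_fwhm_lateral,
        noise_gaussian_sd=noise.gaussian_sd,
        noise_poisson_scale=noise.poisson_scale,
        seed=seed,
    )
    stack = ImageStack(img[None], pixel_size_xy, pixel_size_xy, "synthetic lines")
    return stack, gt


def make_tube(
    diameter: float,
    length_planes: int = 15,
    tilt_deg: float = 0.0,
    anisotropy_yx: float = 1.0,
    drift_per_plane: tuple[float, float] = (0.0, 0.0),
    field_size: int = 96,
    pixel_size_xy: float = 70.0,
    z_step: float = 100.0,
    psf_fwhm_lateral: float = DEFAULT_PSF_LATERAL,
    psf_fwhm_axial: float = DEFAULT_PSF_AXIAL,
    tilt_azimuth_deg: float = 0.0,
    annular: bool = False,
    noise: NoiseParams | None = None,
    seed: int = 0,
) -> tuple[ImageStack, SyntheticGroundTruth]:
    """A tube seen in cross-section: one (anti-aliased) disc per z-plane.

    The cross-section is circular before anisotropy; ``anisotropy_yx`` scales
    the y-extent, so the raster-level aspect ratio is exactly that value.
    A tilt of ``tilt_deg`` from the optical axis displaces the centre by
    ``z_step * tan(tilt_deg)`` nm per plane along ``tilt_azimuth_deg``;
    ``drift_per_plane`` adds a cumulative (dx, dy) nm lateral drift.
    ``annular=True`` renders a hollow ring (doublet-wall look) instead of the
    default filled disc.
    """
    if diameter < 3.0 * pixel_size_xy:
        raise ValidationError(
            f"diameter {diameter} nm under-samples at pixel {pixel_size_xy} nm "
            f"(minimum {3.0 * pixel_size_xy} nm)"
        )
    if not 0.0 <= tilt_deg < 90.0:
        raise ValidationError("tilt_deg must lie in [0, 90)")
    if anisotropy_yx <= 0:
        raise ValidationError("anisotropy_yx must be positive")
    noise = noise or NoiseParams()
    rng = np.random.default_rng(seed)

    r = diameter / 2.0
    ax_px = r / pixel_size_xy                      # x semi-axis
    ay_px = r * anisotropy_yx / pixel_size_xy      # y semi-axis
    c = (field_size - 1) / 2.0
    step_nm = z_step * math.tan(math.radians(tilt_deg))
    az = math.radians(tilt_azimuth_deg)
    dx_nm, dy_nm = drift_per_plane

    yy, xx = np.mgrid[0:field_size, 0:field_size].astype(np.float64)
    planes = np.empty((length_planes, field_size, field_size))
    margin = 3.0 * psf_fwhm_lateral * FWHM_TO_SIGMA / pixel_size_xy + 1.0
    for z in range(length_planes):
        off = z - (length_planes - 1) / 2.0
        cx = c + (off * step_nm * math.cos(az) + z * dx_nm) / pixel_size_xy
        cy = c + (off * step_nm * math.sin(az) + z * dy_nm) / pixel_size_xy
        if not (
            ax_px + margin <= cx <= field_size - 1 - ax_px - margin
            and ay_px + margin <= cy <= field_size - 1 - ay_px - margin
        ):
            raise ValidationError(f"tube exits the field at plane {z}")
        rho = np.sqrt(((xx - cx) / ax_px) ** 2 + ((yy - cy) / ay_px) ** 2)
        # signed edge distance (px, approx) -> anti-aliased coverage
        d = (rho - 1.0) * ax_px
        disc = np.clip(0.5 - d, 0.0, 1.0)
        if annular:
            wall_px = max(1.5, 0.08 * ax_px)
            d_in = (rho - 1.0) * ax_px + wall_px
            disc = disc - np.clip(0.5 - d_in, 0.0, 1.0)
        planes[z] = disc

    sig_xy = psf_fwhm_lateral * FWHM_TO_SIGMA / pixel_size_xy
    sig_z = psf_fwhm_axial * FWHM_TO_SIGMA / z_step
    # the tube extends beyond the imaged volume: replicate along z so axial
    # blur does not bleed flux out of the end planes
    img = ndimage.gaussian_filter(
        planes, (sig_z, sig_xy, sig_xy), mode=("nearest", "constant", "constant")
    )
    img = _apply_noise(img, noise, rng)

    gt = SyntheticGroundTruth(
        kind="tube",
        diameter_true=diameter,
        tilt_deg=tilt_deg,
        anisotropy_yx=anisotropy_yx,
        drift_per_plane=tuple(drift_per_plane),
        psf_fwhm_lateral=psf_fwhm_lateral,
        psf_fwhm_axial=psf_fwhm_axial,
        noise_gaussian_sd=noise.gaussian_sd,
        noise_poisson_scale=noise.poisson_scale,
        seed=seed,
    )
    stack = ImageStack(img, pixel_size_xy, z_step, "synthetic tube")
    return stack, gt


def _curve_points(
    curve: dict[str, Any], arc_length_um: float, pixel_size_xy: float
) -> np.ndarray:
    """Sample a curve spec densely (~0.3 px spacing); returns (n, 2) px (x, y)
    coordinates relative to an arbitrary origin."""
    arc_px = arc_length_um * 1000.0 / pixel_size_xy
    n = max(int(arc_px / 0.3), 16)
    s = np.linspace(0.0, arc_px, n)
    kind = curve.get("kind", "straight")
    if kind == "straight":
        theta = math.radians(curve.get("orientation_deg", 0.0))
        return np.column_stack([s * math.cos(theta), s * math.sin(theta)])
    if kind == "arc":
        radius_um = curve.get("radius_um")
        if radius_um is None:
            raise ValidationError("arc curve spec requires radius_um")
        r_px = radius_um * 1000.0 / pixel_size_xy
        angle = arc_px / r_px  # radians subtended
        if angle >= 2.0 * math.pi:
            raise ValidationError("arc subtends >= 360 degrees: self-intersecting")
        phi = s / r_px
        return np.column_stack([r_px * np.sin(phi), r_px * (1.0 - np.cos(phi))])
    raise ValidationError(f"unknown curve kind {kind!r}")


def make_filament(
    arc_length: float,
    curve: dict[str, Any] | None = None,
    width: float = 150.0,
    pixel_size_xy: float = 70.0,
    psf_fwhm_lateral: float = DEFAULT_PSF_LATERAL,
    noise: NoiseParams | None = None,
    seed: int = 0,
) -> tuple[ImageStack, SyntheticGroundTruth]:
    """A smooth open curve of known arc length rendered as a blurred band.

    Parameters
    ----------
    arc_length : float
        True arc length in micrometres — recorded in the ground truth.
    curve : dict
        ``{"kind": "straight", "orientation_deg": ...}`` or
        ``{"kind": "arc", "radius_um": ...}``. Default: straight along x.
    width : float
        Band width in nm (microtubule bundle + label, pre-blur).
    """
    if arc_length * 1000.0 <= width:
        raise ValidationError("arc_length must exceed the band width")
    noise = noise or NoiseParams()
    rng = np.random.default_rng(seed)
    curve = curve or {"kind": "straight"}

    pts = _curve_points(curve, arc_length, pixel_size_xy)
    w_px = width / pixel_size_xy
    pad = int(math.ceil(w_px / 2 + 3.0 * psf_fwhm_lateral * FWHM_TO_SIGMA / pixel_size_xy + 4))
    mins = pts.min(axis=0)
    pts = pts - mins + pad
    nx = int(math.ceil(pts[:, 0].max())) + pad + 1
    ny = int(math.ceil(pts[:, 1].max())) + pad + 1

    # rasterize the centre line, then band = pixels within width/2 of it
    canvas = np.zeros((ny, nx), dtype=bool)
    ix = np.clip(np.round(pts[:, 0]).astype(int), 0, nx - 1)
    iy = np.clip(np.round(pts[:, 1]).astype(int), 0, ny - 1)
    canvas[iy, ix] = True
    dist = ndimage.distance_transform_edt(~canvas)
    raster = np.clip(0.5 + (w_px / 2.0 - dist), 0.0, 1.0)

    sigma_px = psf_fwhm_lateral * FWHM_TO_SIGMA / pixel_size_xy
    img = ndimage.gaussian_filter(raster, sigma_px, mode="constant")
    img = _apply_noise(img, noise, rng)

    gt = SyntheticGroundTruth(
        kind="filament",
        arc_length_true=arc_length,
        psf_fwhm_lateral=psf_fwhm_lateral,
        noise_gaussian_sd=noise.gaussian_sd,
        noise_poisson_scale=noise.poisson_scale,
        seed=seed,
    )
    stack = ImageStack(img[None], pixel_size_xy, pixel_size_xy, "synthetic filament")
    return stack, gt
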