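"""Amplitude beamforming: delay-and-sum, envelope detection, log compression
and scan conversion for convex arrays."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import hilbert

from .io_core import ArrayGeometry, ImageGrid, ValidationError

__all__ = ["BeamformedImage", "das_beamform", "envelope_detect", "log_compress",
           "scan_convert"]


@dataclass
class BeamformedImage:
    """Image on a defined grid, carried in linear amplitude.

    ``linear_amplitude`` is nonnegative after envelope detection (DAS) or
    negative-clamping (coherence beamformers); the signed pre-clamp values,
    when they differ, are kept in ``raw``.
    """

    linear_amplitude: np.ndarray
    grid: ImageGrid
    beamformer_tag: str = "DAS"
    raw: np.ndarray | None = None
    flags: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.linear_amplitude = np.asarray(self.linear_amplitude, dtype=float)
        if not np.all(np.isfinite(self.linear_amplitude)):
            raise ValidationError("image contains non-finite values")

    @property
    def normalization(self) -> float:
        """Maximum linear amplitude, the 0 dB reference of the log view."""
        return float(np.max(self.linear_amplitude))


def das_beamform(aperture: np.ndarray, valid: np.ndarray | None = None) -> np.ndarray:
    """Coherent sum over the receive aperture, per pixel.

    Parameters
    ----------
    aperture : (Nz, Nx, n_elements) or (Nz, n_elements)
        Time-aligned channel signals s_i(n) (one frame, all lines or one line).
    valid : boolean array, same shape
        Channel-sample validity; the sum is normalized by the count of valid
        channels so images are comparable across aperture masks.  Pixels with
        no valid channel are 0.

    Returns the signed RF image (no envelope applied).
    """
    aperture = np.asarray(aperture, dtype=float)
    if valid is None:
        valid = np.ones(aperture.shape, dtype=bool)
    count = valid.sum(axis=-1)
    total = np.where(valid, aperture, 0.0).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rf = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    return rf


def envelope_detect(rf_image: np.ndarray, grid: ImageGrid,
                    tag: str = "DAS") -> BeamformedImage:
    """Magnitude of the axial analytic signal of a beamformed RF image."""
    rf_image = np.asarray(rf_image, dtype=float)
    if not np.all(np.isfinite(rf_image)):
        raise ValidationError("rf image must be finite")
    env = np.abs(hilbert(rf_image, axis=0))
    return BeamformedImage(linear_amplitude=env, grid=grid, beamformer_tag=tag,
                           raw=rf_image)


def log_compress(image: BeamformedImage, dynamic_range_db: float = 25.0) -> np.ndarray:
    """20*log10(v / max), clipped to [-DR, 0] dB."""
    v = image.linear_amplitude
    vmax = image.normalization
    if vmax <= 0:
        raise ValidationError("cannot log-compress an all-zero image")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(v / vmax)
    return np.clip(db, -dynamic_range_db, 0.0)


def scan_convert(image: BeamformedImage, geometry: ArrayGeometry,
                 pixel_size_mm: float | None = None) -> BeamformedImage:
    """Map a convex-array beam-space image (range x beam angle) to Cartesian.

    For a convex geometry the input grid is interpreted in beam space:
    ``axial_coords`` is range from the array surface along each beam [mm] and
    ``lateral_coords`` is the beam angle [rad] about the center of curvature
    (0 = straight down from the apex).  A beam-space sample (theta, range)
    sits at Cartesian ``x = (R + range) sin(theta)``,
    ``z = (R + range) cos(theta) - R`` with R the curvature radius (center of
    curvature at (0, -R)).  Bilinear interpolation; pixels outside the sector
    are 0 and flagged in ``flags``.  Linear geometry is an identity
    pass-through.
    """
    if geometry.is_linear:
        return image
    r0 = geometry.curvature_radius
    theta = image.grid.lateral_coords  # rad
    rng = image.grid.axial_coords  # mm from array face
    if pixel_size_mm is None:
        pixel_size_mm = geometry.wavelength / 2.0
    radii = r0 + rng
    th_edge = max(abs(float(theta.min())), abs(float(theta.max())))
    x_min = float(radii.max() * np.sin(theta.min()))
    x_max = float(radii.max() * np.sin(theta.max()))
    z_top = max(0.0, float(radii.min() * np.cos(th_edge) - r0))
    if theta.min() <= 0 <= theta.max():
        z_bot = float(radii.max() - r0)
    else:
        z_bot = float(radii.max() * np.cos(min(abs(theta.min()), abs(theta.max()))) - r0)
    out_grid = ImageGrid.from_extent(x_min, x_max, z_top, max(z_bot, z_top + 2 * pixel_size_mm),
                                     pixel_size_mm, pixel_size_mm)
    xx = out_grid.lateral_coords[None, :]
    zz = out_grid.axial_coords[:, None]
    r_c = np.sqrt(xx ** 2 + (zz + r0) ** 2)  # distance from center of curvature
    rng_q = r_c - r0
    th_q = np.arctan2(xx * np.ones_like(zz), zz + r0)
    # fractional indices into the beam-space image
    iz = (rng_q - rng[0]) / (rng[1] - rng[0])
    ix = (th_q - theta[0]) / (theta[1] - theta[0])
    inside = (iz >= 0) & (iz <= rng.size - 1) & (ix >= 0) & (ix <= theta.size - 1)
    cart = map_coordinates(image.linear_amplitude, [iz.ravel(), ix.ravel()],
                           order=1, mode="constant", cval=0.0).reshape(iz.shape)
    cart[~inside] = 0.0
    return BeamformedImage(linear_amplitude=cart, grid=out_grid,
                           beamformer_tag=image.beamformer_tag, flags=~inside)
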