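"""Bone-structure segmentation and landmark extraction from beamformed images.

Pipeline: amplitude threshold (fraction of the image maximum) -> morphological
opening (isolated-pixel removal) and closing (hole filling) -> 8-connected
component labeling -> per-component amplitude-weighted centers of mass, which
serve as the fiducial landmarks for ultrasound/photoacoustic-to-CT
registration.  Thickness profiles integrate a mask along each axis to compare
segmented bone boundaries between modalities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology

from .das import BeamformedImage
from .io_core import ImageGrid, ValidationError
from .metrics import box_stats

logger = logging.getLogger("vertebeam")

__all__ = ["BinaryMask", "Component", "ComponentSet", "threshold_mask",
           "morphological_clean", "extract_components", "select_contour_nearest",
           "integrated_thickness", "thickness_difference"]


@dataclass
class BinaryMask:
    pixels: np.ndarray  # bool, (Nz, Nx)
    grid: ImageGrid

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.shape != self.grid.shape:
            raise ValidationError("mask shape does not match grid")

    @property
    def area_mm2(self) -> float:
        return float(self.pixels.sum() * self.grid.dx * self.grid.dz)


@dataclass
class Component:
    label: int
    pixel_count: int
    center_of_mass: tuple[float, float]  # (x, z) mm
    bounding_box: tuple[int, int, int, int]  # (z0, x0, z1, x1), half-open


@dataclass
class ComponentSet:
    labels: np.ndarray  # int, 0 = background
    components: list[Component]
    grid: ImageGrid


def _image_and_grid(image, grid):
    if isinstance(image, BeamformedImage):
        return image.linear_amplitude, grid or image.grid
    return np.asarray(image, dtype=float), grid


def threshold_mask(image, fraction: float, grid: ImageGrid | None = None) -> BinaryMask:
    """Mask of pixels at or above ``fraction`` of the image-wide maximum
    linear amplitude (0.5 for the bone-boundary contours, 0.3 for the
    landmark masks)."""
    img, grid = _image_and_grid(image, grid)
    if not (0 < fraction < 1):
        raise ValidationError("fraction must lie in (0, 1)")
    vmax = img.max()
    if vmax <= 0:
        raise ValidationError("cannot threshold an all-zero image")
    return BinaryMask(pixels=img >= fraction * vmax, grid=grid)


def _square(size_mm: float, dz: float, dx: float) -> np.ndarray:
    """Square structuring element in mm; rectangular in pixels on
    anisotropic grids."""
    pz = max(1, round(size_mm / dz))
    px = max(1, round(size_mm / dx))
    return np.ones((pz, px), dtype=bool)


def morphological_clean(mask: BinaryMask, open_size_mm: float = 0.38,
                        close_size_mm: float = 0.63) -> BinaryMask:
    """Opening (removes isolated pixels) then closing (fills small holes)
    with structuring elements that are square in physical units."""
    if open_size_mm <= 0 or close_size_mm <= 0:
        raise ValidationError("structuring-element sizes must be positive")
    dz, dx = mask.grid.dz, mask.grid.dx
    opened = morphology.opening(mask.pixels, _square(open_size_mm, dz, dx))
    closed = morphology.closing(opened, _square(close_size_mm, dz, dx))
    return BinaryMask(pixels=closed, grid=mask.grid)


def extract_components(mask: BinaryMask, image,
                       grid: ImageGrid | None = None) -> ComponentSet:
    """8-connected labeling with per-component amplitude-weighted centers of
    mass; amplitudes are normalized to each component's own maximum before
    weighting.  An empty mask yields an empty set."""
    img, grid = _image_and_grid(image, grid or mask.grid)
    labels = measure.label(mask.pixels, connectivity=2)
    comps: list[Component] = []
    xx = grid.lateral_coords
    zz = grid.axial_coords
    for lab in range(1, labels.max() + 1):
        sel = labels == lab
        amp = img[sel]
        amax = amp.max()
        a_norm = amp / amax if amax > 0 else np.ones_like(amp)
        zi, xi = np.nonzero(sel)
        wsum = a_norm.sum()
        com = (float((a_norm * xx[xi]).sum() / wsum),
               float((a_norm * zz[zi]).sum() / wsum))
        comps.append(Component(label=lab, pixel_count=int(sel.sum()),
                               center_of_mass=com,
                               bounding_box=(int(zi.min()), int(xi.min()),
                                             int(zi.max()) + 1, int(xi.max()) + 1)))
    return ComponentSet(labels=labels, components=comps, grid=grid)


def select_contour_nearest(mask: BinaryMask, reference_point: tuple[float, float],
                           image=None) -> tuple[BinaryMask, np.ndarray]:
    """Keep only the component whose boundary is nearest a reference point
    (e.g. the vertebral foramen); returns the single-component mask and its
    boundary polyline as (n, 2) (x, z) mm coordinates.

    Equidistant components tie-break to the lower label (logged).
    """
    comp_set = extract_components(mask, image if image is not None
                                  else mask.pixels.astype(float))
    if not comp_set.components:
        raise ValidationError("mask has no components")
    rx, rz = reference_point
    grid = mask.grid
    best_lab, best_dist, best_poly = None, np.inf, None
    for comp in comp_set.components:
        sel = comp_set.labels == comp.label
        contours = measure.find_contours(sel.astype(float), 0.5)
        poly = max(contours, key=len)
        px = np.interp(poly[:, 1], np.arange(grid.lateral_coords.size),
                       grid.lateral_coords)
        pz = np.interp(poly[:, 0], np.arange(grid.axial_coords.size),
                       grid.axial_coords)
        dist = float(np.min(np.hypot(px - rx, pz - rz)))
        if dist < best_dist - 1e-12:
            best_lab, best_dist = comp.label, dist
            best_poly = np.column_stack([px, pz])
        elif abs(dist - best_dist) <= 1e-12 and best_lab is not None:
            logger.info("select_contour_nearest: tie at %.6f mm, keeping "
                        "label %d", dist, best_lab)
    out = BinaryMask(pixels=comp_set.labels == best_lab, grid=grid)
    return out, best_poly


def integrated_thickness(mask: BinaryMask) -> tuple[np.ndarray, np.ndarray]:
    """Integrated segmentation thickness profiles.

    Returns ``(lateral_profile, axial_profile)``: at each lateral position
    the summed axial extent of the mask in mm (column sum times dz), and at
    each axial position the summed lateral extent (row sum times dx).
    """
    m = mask.pixels
    lateral = m.sum(axis=0) * mask.grid.dz
    axial = m.sum(axis=1) * mask.grid.dx
    return lateral, axial


def overall_thickness(profile: np.ndarray) -> float:
    """Mean profile value over positions where the mask is present."""
    nz = profile[profile > 0]
    return float(nz.mean()) if nz.size else 0.0


def thickness_difference(mask_test: BinaryMask, mask_reference: BinaryMask) -> dict:
    """Per-position differences of integrated thickness (test - reference)
    in both dimensions, restricted to positions where either mask is present,
    with box-plot summaries."""
    if mask_test.grid.shape != mask_reference.grid.shape:
        raise ValidationError("masks must share a grid")
    lat_t, ax_t = integrated_thickness(mask_test)
    lat_r, ax_r = integrated_thickness(mask_reference)
    out = {}
    for name, t, r in (("lateral", lat_t, lat_r), ("axial", ax_t, ax_r)):
        present = (t > 0) | (r > 0)
        diffs = (t - r)[present]
        out[name] = {"differences": diffs,
                     "summary": box_stats(diffs) if diffs.size else None}
    return out
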