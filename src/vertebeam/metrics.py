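"""Image-quality and discrimination metrics.

All metrics operate on linear (pre-log-compression) amplitude:

* gCNR = 1 - sum_bins min(p_in, p_out), histogram overlap of the inside and
  outside ROI amplitude distributions (256 shared-range bins); bounded [0,1].
* CNR = |S_in - S_out| / sqrt(var_in + var_out).
* SNR = mean(target ROI) / std(background ROI); acquisitions with SNR <= 3
  are treated as out-of-plane and discarded.
* -6 dB contour area: area of the connected region around the target whose
  amplitude exceeds half (10^(-6/20)) of the local ROI maximum — compact for
  a fiber tip on cortical bone, diffuse for one in cancellous bone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage import measure

from .das import BeamformedImage
from .io_core import ImageGrid, ValidationError

logger = logging.getLogger("vertebeam")

__all__ = ["ROI", "gcnr", "cnr", "snr", "filter_out_of_plane",
           "contour_area_6db", "box_stats", "compare_bone_contact",
           "peak_to_com_distance"]

N_BINS = 256
SNR_THRESHOLD = 3.0
DB6 = 10.0 ** (-6.0 / 20.0)  # amplitude ratio of the -6 dB contour


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest in physical coordinates [mm]."""

    x_min: float
    x_max: float
    z_min: float
    z_max: float

    @classmethod
    def centered(cls, center_x: float, center_z: float, size_mm: float) -> "ROI":
        h = size_mm / 2.0
        return cls(center_x - h, center_x + h, center_z - h, center_z + h)

    def pixel_values(self, image: np.ndarray, grid: ImageGrid) -> np.ndarray:
        """Flat array of image values inside the ROI."""
        xi = (grid.lateral_coords >= self.x_min) & (grid.lateral_coords <= self.x_max)
        zi = (grid.axial_coords >= self.z_min) & (grid.axial_coords <= self.z_max)
        if not xi.any() or not zi.any():
            raise ValidationError("ROI resolves to no pixels on this grid")
        return np.asarray(image)[np.ix_(zi, xi)].ravel()


def _roi_values(image, roi, grid) -> np.ndarray:
    if isinstance(image, BeamformedImage):
        return roi.pixel_values(image.linear_amplitude, grid or image.grid)
    return roi.pixel_values(image, grid)


def gcnr(image, roi_in: ROI, roi_out: ROI, grid: ImageGrid | None = None) -> float:
    """Generalized contrast-to-noise ratio of two ROIs.

    Histograms use 256 equal-width bins spanning the pooled min..max of both
    ROIs.  A degenerate pooled range (both ROIs a single constant) returns 0.
    """
    a = _roi_values(image, roi_in, grid)
    b = _roi_values(image, roi_out, grid)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi <= lo:
        return 0.0
    edges = np.linspace(lo, hi, N_BINS + 1)
    p_in, _ = np.histogram(a, bins=edges)
    p_out, _ = np.histogram(b, bins=edges)
    overlap = np.minimum(p_in / a.size, p_out / b.size).sum()
    return float(1.0 - overlap)


def cnr(image, roi_in: ROI, roi_out: ROI, grid: ImageGrid | None = None) -> float:
    """Contrast-to-noise ratio |S_in - S_out| / sqrt(var_in + var_out)."""
    a = _roi_values(image, roi_in, grid)
    b = _roi_values(image, roi_out, grid)
    if a.size < 2 or b.size < 2:
        raise ValidationError("CNR needs at least 2 pixels per ROI")
    num = abs(a.mean() - b.mean())
    den = np.sqrt(a.var() + b.var())
    if den == 0:
        if num == 0:
            return 0.0
        raise ValidationError("CNR undefined: zero variance with unequal means")
    return float(num / den)


def snr(image, target_roi: ROI, background_roi: ROI,
        grid: ImageGrid | None = None) -> float:
    """SNR = mean(target) / std(background) on linear amplitude."""
    t = _roi_values(image, target_roi, grid)
    b = _roi_values(image, background_roi, grid)
    if b.size < 2:
        raise ValidationError("background ROI needs at least 2 pixels")
    sb = b.std()
    if sb == 0:
        raise ValidationError("SNR undefined: zero background standard deviation")
    return float(t.mean() / sb)


def filter_out_of_plane(snr_values, threshold: float = SNR_THRESHOLD
                        ) -> tuple[list[int], list[int]]:
    """Partition frame indices by the out-of-plane SNR rule.

    Frames whose SNR is ``threshold`` *or less* are discarded (the boundary
    value itself is out-of-plane); returns ``(kept, discarded)`` index lists.
    """
    kept, discarded = [], []
    for i, v in enumerate(snr_values):
        (discarded if v <= threshold else kept).append(i)
    return kept, discarded


def contour_area_6db(image, target_center: tuple[float, float],
                     roi_size_mm: float = 10.0,
                     grid: ImageGrid | None = None) -> float:
    """Area [mm^2] enclosed by the -6 dB contours around a photoacoustic
    target.

    A ``roi_size_mm`` square ROI is centered on ``target_center`` (x, z) —
    in practice the brightest pixel of the LW-SLSC image.  The area counts
    every ROI pixel whose amplitude exceeds 10^(-6/20) of the ROI maximum,
    times the pixel area: a diffuse multi-lobed pattern (fiber tip in
    cancellous bone) accumulates the area of all its lobes, a compact one
    (cortical contact) only its single lobe.
    """
    if isinstance(image, BeamformedImage):
        grid = grid or image.grid
        image = image.linear_amplitude
    roi = ROI.centered(target_center[0], target_center[1], roi_size_mm)
    xi = np.where((grid.lateral_coords >= roi.x_min) & (grid.lateral_coords <= roi.x_max))[0]
    zi = np.where((grid.axial_coords >= roi.z_min) & (grid.axial_coords <= roi.z_max))[0]
    if xi.size == 0 or zi.size == 0:
        raise ValidationError("ROI resolves to no pixels")
    sub = np.asarray(image)[np.ix_(zi, xi)]
    vmax = sub.max()
    if vmax <= 0:
        raise ValidationError("ROI is all zero; -6 dB contour undefined")
    above = sub >= DB6 * vmax
    return float(above.sum() * grid.dx * grid.dz)


def box_stats(values) -> dict:
    """Box-plot summary: median, quartiles, min/max, 1.5*IQR outliers."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    out_mask = (v > q3 + 1.5 * iqr) | (v < q1 - 1.5 * iqr)
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "min": float(v.min()), "max": float(v.max()),
            "mean": float(v.mean()), "std": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "outliers": v[out_mask].tolist(), "n": int(v.size)}


def compare_bone_contact(areas_a, areas_b) -> dict:
    """Two-group comparison of -6 dB contour areas (e.g. cancellous vs
    cortical fiber contact).

    Welch's two-sided t-test (the group spreads are typically very unequal)
    plus a box-plot summary per group.  Identical groups give t = 0, p = 1.
    """
    a = np.asarray(areas_a, dtype=float)
    b = np.asarray(areas_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need at least 2 values per group")
    if np.array_equal(a, b) or (a.std() == 0 and b.std() == 0 and a.mean() == b.mean()):
        t_stat, p_val = 0.0, 1.0
    else:
        if a.std() == 0 and b.std() == 0:
            raise ValidationError("t-test undefined: both groups have zero variance")
        t_stat, p_val = stats.ttest_ind(a, b, equal_var=False)
    return {"mean_difference": float(a.mean() - b.mean()),
            "t_statistic": float(t_stat), "p_value": float(p_val),
            "group_a": box_stats(a), "group_b": box_stats(b)}


def peak_to_com_distance(image, roi: ROI | None = None,
                         grid: ImageGrid | None = None) -> float:
    """Euclidean distance [mm] between the amplitude-weighted center of mass
    and the brightest pixel of an ROI (whole image if ``roi`` is None).

    A shorter distance means a more compact, less diffuse target.  Ties for
    the brightest pixel take the first in row-major order (logged).
    """
    if isinstance(image, BeamformedImage):
        grid = grid or image.grid
        image = image.linear_amplitude
    image = np.asarray(image, dtype=float)
    if roi is not None:
        xi = np.where((grid.lateral_coords >= roi.x_min) & (grid.lateral_coords <= roi.x_max))[0]
        zi = np.where((grid.axial_coords >= roi.z_min) & (grid.axial_coords <= roi.z_max))[0]
        sub = image[np.ix_(zi, xi)]
        x_coords = grid.lateral_coords[xi]
        z_coords = grid.axial_coords[zi]
    else:
        sub = image
        x_coords = grid.lateral_coords
        z_coords = grid.axial_coords
    if sub.max() <= 0:
        raise ValidationError("ROI maximum must be positive")
    flat = np.argmax(sub)
    if np.count_nonzero(sub == sub.max()) > 1:
        logger.info("peak_to_com_distance: brightest-pixel tie, taking first "
                    "in row-major order")
    pz, px = np.unravel_index(flat, sub.shape)
    peak = np.array([x_coords[px], z_coords[pz]])
    total = sub.sum()
    com_x = float((sub * x_coords[None, :]).sum() / total)
    com_z = float((sub * z_coords[:, None]).sum() / total)
    return float(np.hypot(com_x - peak[0], com_z - peak[1]))
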