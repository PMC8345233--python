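"""End-to-end orchestration: focusing -> beamforming -> metrics/segmentation.

These functions are the library surface behind the command-line interface;
each is deterministic given (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import coherence, das, focusing, metrics
from .io_core import (BeamformerParams, ChannelData, ImageGrid, Modality,
                      RunConfig, ValidationError)

logger = logging.getLogger("vertebeam")

__all__ = ["default_grid", "beamform_frame", "beamform_all", "bone_contact_analysis"]


def default_grid(data: ChannelData, x_span: tuple[float, float] | None = None,
                 z_span: tuple[float, float] = (5.0, 40.0),
                 dx: float | None = None, dz: float = 0.04) -> ImageGrid:
    """Imaging grid covering the aperture laterally.

    Lateral spacing defaults to the array pitch (one image line per
    element); axial sampling is fine (dz ~ lambda/10 at 4 MHz) so RF
    correlation kernels are well resolved.
    """
    if x_span is None:
        half = data.geometry.aperture_width / 2
        x_span = (-half, half)
    if dx is None:
        dx = data.geometry.pitch
    return ImageGrid.from_extent(x_span[0], x_span[1], z_span[0], z_span[1], dx, dz)


def _axial_kernel_samples(params: BeamformerParams, data: ChannelData,
                          grid: ImageGrid) -> int:
    lam = data.geometry.wavelength
    return max(2, round(params.axial_kernel_wavelengths * lam / grid.dz))


def beamform_frame(data: ChannelData, grid: ImageGrid, params: BeamformerParams,
                   beamformer: str = "das", frame: int = 0,
                   aperture: np.ndarray | None = None,
                   valid: np.ndarray | None = None) -> das.BeamformedImage:
    """Beamform one frame with DAS, SLSC or LW-SLSC.

    ``aperture``/``valid`` may carry a precomputed focused frame to share
    the focusing step across beamformers.
    """
    params.validate()
    beamformer = beamformer.lower().replace("-", "").replace("_", "")
    if aperture is None:
        aperture, valid = focusing.focus_frame(data, grid, frame=frame)
    if beamformer == "das":
        rf = das.das_beamform(aperture, valid)
        return das.envelope_detect(rf, grid)
    kern = _axial_kernel_samples(params, data, grid)
    stack = coherence.coherence_stack(aperture, params.n_lags, kern,
                                      valid=valid, grid=grid)
    if beamformer == "slsc":
        return coherence.slsc_image(stack, params.slsc_lag)
    if beamformer == "lwslsc":
        spec = coherence.KernelSpec.from_mm(params.kernel_axial_mm,
                                            params.kernel_lateral_mm, grid,
                                            params.overlap)
        ops = coherence.build_tv_operators(params.n_lags, spec.kz, spec.kx,
                                           params.alpha)
        return coherence.lwslsc_image(stack, spec, ops)
    raise ValidationError(f"unknown beamformer {beamformer!r}")


def beamform_all(data: ChannelData, grid: ImageGrid, params: BeamformerParams,
                 frame: int = 0) -> dict[str, das.BeamformedImage]:
    """DAS, SLSC and LW-SLSC images of one frame sharing one focusing pass."""
    t0 = time.perf_counter()
    aperture, valid = focusing.focus_frame(data, grid, frame=frame)
    out = {}
    for bf in ("das", "slsc", "lwslsc"):
        out[bf] = beamform_frame(data, grid, params, bf, frame=frame,
                                 aperture=aperture, valid=valid)
        logger.info("beamform %s frame=%d elapsed=%.2fs", bf, frame,
                    time.perf_counter() - t0)
    return out


def bone_contact_analysis(groups: dict[str, list[ChannelData]], grid: ImageGrid,
                          params: BeamformerParams, cfg: RunConfig | None = None,
                          beamformer_for_area: str = "das") -> dict:
    """Cortical-vs-cancellous discrimination from photoacoustic frames.

    Per frame: the LW-SLSC image locates the target center (brightest
    pixel); the in-plane SNR test (10 mm target ROI on that center, equally
    sized background ROI 25 mm above — clipped into the image — SNR > 3)
    discards out-of-plane frames; the -6 dB contour area is then measured on
    the requested amplitude image (DAS by default).  A Welch t-test compares
    the two groups' areas.

    ``groups`` maps group label (e.g. "cancellous", "cortical") to a list of
    single-frame :class:`ChannelData`.
    """
    cfg = cfg or RunConfig(beamformer=params)
    rows = []
    areas: dict[str, list[float]] = {}
    for label, frames in groups.items():
        areas[label] = []
        for k, data in enumerate(frames):
            imgs = {}
            aperture, valid = focusing.focus_frame(data, grid)
            for bf in ("lwslsc", beamformer_for_area):
                if bf not in imgs:
                    imgs[bf] = beamform_frame(data, grid, params, bf,
                                              aperture=aperture, valid=valid)
            lw = imgs["lwslsc"].linear_amplitude
            pz, px = np.unravel_index(np.argmax(lw), lw.shape)
            cx_mm = float(grid.lateral_coords[px])
            cz_mm = float(grid.axial_coords[pz])
            target_roi = metrics.ROI.centered(cx_mm, cz_mm, cfg.roi_size_mm)
            # background 25 mm above the target, clipped into the grid but
            # never overlapping the target ROI
            half = cfg.roi_size_mm / 2
            bg_z = max(cz_mm - 25.0, float(grid.axial_coords[0]) + half)
            bg_z = min(bg_z, cz_mm - cfg.roi_size_mm)
            if bg_z - half < float(grid.axial_coords[0]) - 1e-9:
                raise ValidationError(
                    "grid too shallow to place a disjoint background ROI "
                    f"above the target at z={cz_mm:.1f} mm")
            bg_roi = metrics.ROI.centered(cx_mm, bg_z, cfg.roi_size_mm)
            amp_img = imgs[beamformer_for_area]
            frame_snr = metrics.snr(amp_img, target_roi, bg_roi)
            kept = frame_snr > cfg.snr_threshold
            row = {"group": label, "frame": k, "snr": frame_snr,
                   "kept": kept, "center_x_mm": cx_mm, "center_z_mm": cz_mm}
            if kept:
                area = metrics.contour_area_6db(amp_img, (cx_mm, cz_mm),
                                                cfg.roi_size_mm)
                row["area_mm2"] = area
                areas[label].append(area)
            rows.append(row)
    labels = list(groups)
    for lab in labels:
        if len(areas[lab]) < 2:
            raise ValidationError(
                f"group {lab!r}: fewer than 2 frames survive the SNR filter")
    comparison = metrics.compare_bone_contact(areas[labels[0]], areas[labels[1]])
    return {"per_frame": pd.DataFrame(rows), "areas": areas,
            "comparison": comparison,
            "n_discarded": int(sum(not r["kept"] for r in rows))}


def report_provenance(cfg: RunConfig) -> dict:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return {"config_hash": hashlib.sha256(blob).hexdigest()[:16],
            "seed": cfg.seed}
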