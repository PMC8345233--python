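"""Receive focusing: per-pixel delay computation and channel alignment.

Produces the time-aligned, zero-mean aperture-domain signals s_i(n) that
every beamformer in this package consumes.  Delays are one-way for
photoacoustic data (the source emits, elements receive) and two-way for
pulse-echo ultrasound, where the transmit path is approximated by the pixel
depth (unsteered focused/plane transmit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import ArrayGeometry, ChannelData, ImageGrid, Modality, ValidationError

__all__ = ["DelayedAperture", "compute_delays", "delay_channels", "focus_frame"]


@dataclass
class DelayedAperture:
    """Time-aligned, zero-mean samples for one lateral image line.

    values : (n_depth, n_elements) float array
    valid  : boolean mask; samples interpolated outside the recorded window
             are exactly 0 and flagged False.
    """

    values: np.ndarray
    valid: np.ndarray


def compute_delays(geometry: ArrayGeometry, grid: ImageGrid, sound_speed: float,
                   modality: Modality) -> np.ndarray:
    """Per-pixel receive delay table, shape (Nz, Nx, n_elements), in us.

    One-way (photoacoustic): tau = |r_pixel - r_element| / c.
    Two-way (ultrasound): tau = (z_pixel + |r_pixel - r_element|) / c.
    """
    if sound_speed <= 0:
        raise ValidationError("sound_speed must be positive")
    if np.any(np.asarray(grid.axial_coords) < 0):
        raise ValidationError("grid contains pixels behind the array face (z < 0)")
    c_mm_us = sound_speed * 1e-3  # mm per us
    elem = geometry.element_positions  # (N, 2)
    x = grid.lateral_coords[None, :, None]  # (1, Nx, 1)
    z = grid.axial_coords[:, None, None]  # (Nz, 1, 1)
    dist = np.sqrt((x - elem[None, None, :, 0]) ** 2 + (z - elem[None, None, :, 1]) ** 2)
    tau = dist / c_mm_us
    if Modality(modality) is Modality.ULTRASOUND:
        tau = tau + z / c_mm_us
    return tau


def delay_channels(data: ChannelData, delays: np.ndarray, line_index: int,
                   frame: int = 0) -> DelayedAperture:
    """Apply the delay table to one lateral line of one frame.

    Linear (fractional-sample) interpolation; samples requested outside the
    recorded window are zeroed and flagged invalid; the per-channel DC over
    the line's valid samples is removed.
    """
    tau = delays[:, line_index, :]  # (Nz, N)
    if not np.all(np.isfinite(tau)):
        raise ValidationError("delay table contains non-finite entries")
    nt, n_elem = data.n_time, data.geometry.n_elements
    idx = (tau - data.start_time) * data.sampling_frequency  # fractional sample
    valid = (idx >= 0) & (idx <= nt - 1)
    out = np.zeros_like(tau)
    rf = data.samples[:, :, frame]
    base = np.arange(nt, dtype=float)
    for i in range(n_elem):
        out[:, i] = np.interp(idx[:, i], base, rf[:, i], left=0.0, right=0.0)
    out[~valid] = 0.0
    # zero-mean enforcement over the imaging window, per channel
    n_valid = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n_valid > 0, out.sum(axis=0) / np.maximum(n_valid, 1), 0.0)
    out -= mean[None, :]
    out[~valid] = 0.0
    return DelayedAperture(values=out, valid=valid)


def focus_frame(data: ChannelData, grid: ImageGrid, frame: int = 0,
                delays: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Focus a whole frame onto the grid.

    Returns ``(aperture, valid)`` with shapes (Nz, Nx, n_elements); slice
    ``[:, j, :]`` is the delayed aperture of lateral line j.
    """
    if delays is None:
        delays = compute_delays(data.geometry, grid, data.sound_speed, data.modality)
    nz, nx = grid.shape
    aperture = np.empty((nz, nx, data.geometry.n_elements))
    valid = np.empty((nz, nx, data.geometry.n_elements), dtype=bool)
    for j in range(nx):
        ap = delay_channels(data, delays, j, frame=frame)
        aperture[:, j, :] = ap.values
        valid[:, j, :] = ap.valid
    return aperture, valid
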