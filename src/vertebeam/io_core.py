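"""Data containers, file I/O and configuration.

Units convention (used throughout the package): distances in mm, times in
microseconds, frequencies in MHz, sound speed in m/s (converted to mm/us,
= m/s * 1e-3, only inside delay computations). Axes: axial z is depth from
the array face, lateral x runs along the array; array indices are 0-based
and pixel centers sit on the grid coordinates.

The raw-channel-data HDF5 container is defined by this package (no community
standard exists for raw RF).  Layout::

    /rf          float array, (n_time, n_elements, n_frames)
    /fs          scalar, sampling frequency [MHz]
    /c           scalar, sound speed [m/s]
    /modality    string, "ultrasound_two_way" | "photoacoustic_one_way"
    /start_time  scalar, time of first sample [us]
    /geometry/n_elements        int
    /geometry/pitch             scalar [mm]
    /geometry/kerf              scalar [mm]
    /geometry/curvature_radius  scalar [mm], NaN for a linear array
    /geometry/center_frequency  scalar [MHz]
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("vertebeam")

SOUND_SPEED_DEFAULT = 1540.0  # m/s, soft tissue


class FormatError(ValueError):
    """Raised when a file does not follow the documented layout."""


class ValidationError(ValueError):
    """Raised when data violates a container invariant."""


class Modality(str, enum.Enum):
    ULTRASOUND = "ultrasound_two_way"
    PHOTOACOUSTIC = "photoacoustic_one_way"


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArrayGeometry:
    """Transducer array geometry.

    Parameters
    ----------
    n_elements : int
        Number of elements N in the receive aperture.
    pitch : float
        Element center-to-center spacing [mm].
    kerf : float
        Gap between elements [mm]; must be smaller than the pitch.
    center_frequency : float
        Nominal center frequency [MHz].
    sound_speed : float
        Sound speed [m/s] used to derive the wavelength.
    curvature_radius : float or None
        Radius of a convex array [mm]; ``None`` for a linear array.
    """

    n_elements: int
    pitch: float
    kerf: float
    center_frequency: float
    sound_speed: float = SOUND_SPEED_DEFAULT
    curvature_radius: float | None = None

    def __post_init__(self) -> None:
        if self.n_elements < 2:
            raise ValidationError("n_elements must be >= 2")
        if not (self.pitch > self.kerf >= 0):
            raise ValidationError("require pitch > kerf >= 0")
        if self.center_frequency <= 0 or self.sound_speed <= 0:
            raise ValidationError("center_frequency and sound_speed must be positive")

    @property
    def wavelength(self) -> float:
        """Wavelength lambda = c / f0 [mm]."""
        return (self.sound_speed * 1e-3) / self.center_frequency

    @property
    def aperture_width(self) -> float:
        """Lateral extent of the element centers [mm]."""
        return (self.n_elements - 1) * self.pitch

    @property
    def element_positions(self) -> np.ndarray:
        """(n_elements, 2) array of (x, z) element-center positions [mm].

        Linear arrays are centered on x=0 at z=0.  Convex arrays place the
        elements on an arc of the given radius bulging toward the tissue
        (center of curvature at (0, -radius), apex element at the origin),
        pitch measured along the arc.
        """
        n = self.n_elements
        if self.curvature_radius is None:
            x = (np.arange(n) - (n - 1) / 2.0) * self.pitch
            return np.column_stack([x, np.zeros(n)])
        r = self.curvature_radius
        dtheta = self.pitch / r
        theta = (np.arange(n) - (n - 1) / 2.0) * dtheta
        return np.column_stack([r * np.sin(theta), r * (np.cos(theta) - 1.0)])

    @property
    def is_linear(self) -> bool:
        return self.curvature_radius is None


@dataclass(frozen=True)
class ImageGrid:
    """Cartesian image grid; coordinates are pixel centers [mm]."""

    lateral_coords: np.ndarray
    axial_coords: np.ndarray

    def __post_init__(self) -> None:
        for name, c in (("lateral", self.lateral_coords), ("axial", self.axial_coords)):
            c = np.asarray(c, dtype=float)
            if c.ndim != 1 or c.size < 2:
                raise ValidationError(f"{name}_coords must be 1-D with >= 2 entries")
            d = np.diff(c)
            if np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-9, atol=1e-12):
                raise ValidationError(f"{name}_coords must be strictly increasing and uniform")
            object.__setattr__(self, f"{name}_coords", c)

    @classmethod
    def from_extent(cls, x_min: float, x_max: float, z_min: float, z_max: float,
                    dx: float, dz: float) -> "ImageGrid":
        return cls(np.arange(x_min, x_max + dx / 2, dx),
                   np.arange(z_min, z_max + dz / 2, dz))

    @property
    def dx(self) -> float:
        return float(self.lateral_coords[1] - self.lateral_coords[0])

    @property
    def dz(self) -> float:
        return float(self.axial_coords[1] - self.axial_coords[0])

    @property
    def shape(self) -> tuple[int, int]:
        """(Nz, Nx)."""
        return self.axial_coords.size, self.lateral_coords.size


@dataclass
class ChannelData:
    """Raw per-element RF data before receive focusing.

    samples has shape (n_time, n_elements, n_frames).
    """

    samples: np.ndarray
    sampling_frequency: float  # MHz
    sound_speed: float  # m/s
    modality: Modality
    geometry: ArrayGeometry
    start_time: float = 0.0  # us

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 3:
            raise ValidationError("samples must be (n_time, n_elements, n_frames)")
        if self.samples.shape[1] != self.geometry.n_elements:
            raise ValidationError(
                f"samples have {self.samples.shape[1]} element columns but geometry "
                f"declares {self.geometry.n_elements} elements")
        if self.sampling_frequency <= 2 * self.geometry.center_frequency:
            raise ValidationError("sampling_frequency must exceed 2 x center_frequency")
        if self.samples.shape[2] < 1:
            raise ValidationError("need at least one frame")
        self.modality = Modality(self.modality)

    @property
    def n_time(self) -> int:
        return self.samples.shape[0]

    @property
    def n_frames(self) -> int:
        return self.samples.shape[2]


# ---------------------------------------------------------------------------
# HDF5 channel-data container
# ---------------------------------------------------------------------------

_REQUIRED_DATASETS = ("/rf", "/fs", "/c", "/modality", "/geometry/n_elements",
                      "/geometry/pitch", "/geometry/kerf",
                      "/geometry/center_frequency")


def save_channel_data(path: str | Path, data: ChannelData) -> None:
    """Write a :class:`ChannelData` to the documented HDF5 layout."""
    g = data.geometry
    with h5py.File(path, "w") as f:
        f.create_dataset("rf", data=data.samples)
        f["fs"] = data.sampling_frequency
        f["c"] = data.sound_speed
        f["modality"] = data.modality.value
        f["start_time"] = data.start_time
        geo = f.create_group("geometry")
        geo["n_elements"] = g.n_elements
        geo["pitch"] = g.pitch
        geo["kerf"] = g.kerf
        geo["curvature_radius"] = np.nan if g.curvature_radius is None else g.curvature_radius
        geo["center_frequency"] = g.center_frequency


def load_channel_data(path: str | Path) -> ChannelData:
    """Read channel data from the documented HDF5 layout.

    Raises
    ------
    FormatError
        If a required dataset is missing.
    ValidationError
        If the contents violate a container invariant (e.g. element-count
        mismatch between /rf and /geometry).
    """
    with h5py.File(path, "r") as f:
        for name in _REQUIRED_DATASETS:
            if name.lstrip("/") not in f:
                raise FormatError(f"channel-data file {path} is missing dataset {name}")
        geo = f["geometry"]
        radius = float(geo["curvature_radius"][()]) if "curvature_radius" in geo else np.nan
        c = float(f["c"][()])
        geometry = ArrayGeometry(
            n_elements=int(geo["n_elements"][()]),
            pitch=float(geo["pitch"][()]),
            kerf=float(geo["kerf"][()]),
            center_frequency=float(geo["center_frequency"][()]),
            sound_speed=c,
            curvature_radius=None if np.isnan(radius) else radius,
        )
        modality = f["modality"][()]
        if isinstance(modality, bytes):
            modality = modality.decode()
        return ChannelData(
            samples=f["rf"][()],
            sampling_frequency=float(f["fs"][()]),
            sound_speed=c,
            modality=Modality(modality),
            geometry=geometry,
            start_time=float(f["start_time"][()]) if "start_time" in f else 0.0,
        )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class BeamformerParams:
    """Parameters of the SLSC / LW-SLSC beamformers.

    slsc_lag
        M, the upper lag of the short-lag sum.
    n_lags
        N_L, the total number of lags carried in the coherence stack.
    axial_kernel_wavelengths
        Length of the axial correlation kernel, in wavelengths.
    kernel_lateral_mm, kernel_axial_mm
        LW-SLSC moving-kernel size.
    overlap
        Fractional kernel overlap in [0, 1).
    alpha
        TV regularization factor applied to the lag-weight gradient.
    """

    slsc_lag: int = 9
    n_lags: int = 28
    axial_kernel_wavelengths: float = 2.0
    kernel_lateral_mm: float = 1.20
    kernel_axial_mm: float = 1.92
    overlap: float = 0.5
    alpha: float = 0.12

    def validate(self) -> None:
        if self.alpha < 0:
            raise ValidationError("alpha must be >= 0")
        if not (0 <= self.overlap < 1):
            raise ValidationError("overlap must lie in [0, 1)")
        if not (1 <= self.slsc_lag <= self.n_lags):
            raise ValidationError("slsc_lag (M) must satisfy 1 <= M <= n_lags")
        if self.axial_kernel_wavelengths <= 0:
            raise ValidationError("axial_kernel_wavelengths must be positive")
        if self.kernel_lateral_mm <= 0 or self.kernel_axial_mm <= 0:
            raise ValidationError("kernel sizes must be positive")


@dataclass
class RunConfig:
    """Full pipeline configuration with the validity checks of each consumer."""

    beamformer: BeamformerParams = field(default_factory=BeamformerParams)
    segmentation_threshold: float = 0.3
    open_size_mm: float = 0.38
    close_size_mm: float = 0.63
    snr_threshold: float = 3.0
    roi_size_mm: float = 10.0
    dynamic_range_db: float = 25.0
    rois: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "results"

    def validate(self) -> None:
        self.beamformer.validate()
        if not (0 < self.segmentation_threshold < 1):
            raise ValidationError("segmentation_threshold must lie in (0, 1)")
        if self.snr_threshold < 0:
            raise ValidationError("snr_threshold must be >= 0")


#: Named parameter presets mirroring the two published acquisition setups.
PRESETS: dict[str, BeamformerParams] = {
    # caprine vertebra, L3-8 linear array ultrasound
    "caprine": BeamformerParams(slsc_lag=9, n_lags=28, axial_kernel_wavelengths=2.0,
                                kernel_lateral_mm=1.20, kernel_axial_mm=1.92,
                                overlap=0.5, alpha=0.12),
    # human cadaver, SC1-6 convex array, ultrasound
    "cadaver_us": BeamformerParams(slsc_lag=5, n_lags=15, axial_kernel_wavelengths=1.0,
                                   kernel_lateral_mm=2.0, kernel_axial_mm=3.1,
                                   overlap=0.6, alpha=1.0),
    # human cadaver, photoacoustic
    "cadaver_pa": BeamformerParams(slsc_lag=15, n_lags=25, axial_kernel_wavelengths=1.0,
                                   kernel_lateral_mm=2.0, kernel_axial_mm=3.1,
                                   overlap=0.6, alpha=1.0),
}


def _config_to_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML pipeline configuration.

    Absent keys take their defaults; a ``preset`` key selects one of the
    shipped beamformer parameter sets before explicit ``beamformer`` keys
    are applied on top.
    """
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"config {path} must be a mapping")
    preset = raw.pop("preset", None)
    bf_kwargs = raw.pop("beamformer", {}) or {}
    base = dataclasses.asdict(PRESETS[preset]) if preset else {}
    base.update(bf_kwargs)
    known = {f.name for f in dataclasses.fields(RunConfig)} - {"beamformer"}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    try:
        cfg = RunConfig(beamformer=BeamformerParams(**base), **raw)
    except TypeError as exc:
        raise ValidationError(str(exc)) from exc
    cfg.validate()
    return cfg


def save_config(path: str | Path, cfg: RunConfig) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(_config_to_dict(cfg), f, sort_keys=True)


# ---------------------------------------------------------------------------
# result export
# ---------------------------------------------------------------------------

def _to_uint(img: np.ndarray, dtype) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    lo, hi = float(np.nanmin(img)), float(np.nanmax(img))
    if hi <= lo:
        return np.zeros(img.shape, dtype=dtype)
    scaled = (img - lo) / (hi - lo) * np.iinfo(dtype).max
    return scaled.astype(dtype)


def save_results(images: dict[str, np.ndarray], masks: dict[str, np.ndarray],
                 metrics: pd.DataFrame, out_dir: str | Path) -> list[str]:
    """Export images (16-bit PNG + NIfTI), masks (8-bit PNG) and a metrics CSV.

    Returns the manifest: the sorted list of files written, relative to
    ``out_dir``.  Re-running with identical inputs overwrites deterministically.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        manifest: list[str] = []
        for name, img in images.items():
            png = out / f"{name}.png"
            iio.imwrite(png, _to_uint(img, np.uint16))
            nii = out / f"{name}.nii"
            nib.save(nib.Nifti1Image(np.asarray(img, dtype=np.float32), np.eye(4)), nii)
            manifest += [png.name, nii.name]
        for name, mask in masks.items():
            png = out / f"{name}_mask.png"
            iio.imwrite(png, (np.asarray(mask, bool).astype(np.uint8) * 255))
            manifest.append(png.name)
        csv = out / "metrics.csv"
        metrics.to_csv(csv, index=False)
        manifest.append(csv.name)
        return sorted(manifest)
    except OSError as exc:
        raise OSError(f"cannot write results to {out}: {exc}") from exc
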