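"""Synthetic channel-data and phantom generation.

Far-field point-source superposition with a Gaussian-modulated sinusoid
pulse (default 4 MHz center, 60 % fractional bandwidth) emulates four
acquisition regimes:

* ``point_source`` — a compact coherent photoacoustic emitter, the signal
  class of a fiber tip in contact with dense cortical bone;
* ``diffuse_target`` — many randomly placed, randomly phased sub-sources
  within a small radius, emulating the multiple reflections of a fiber tip
  surrounded by porous cancellous bone;
* ``bone_scene`` — a pulse-echo ultrasound scene with dense coherent
  specular reflectors along a bone-surface polyline, diffuse sub-resolution
  speckle scatterers in the soft tissue above it, and acoustic shadow below;
* ``out_of_plane`` — spatially incoherent channel noise with weak, randomly
  delayed wavefronts, emulating acquisitions whose source lies outside the
  imaging plane.

Every generator is a pure function of (spec, seed): identical reruns are
byte-identical.  No element directivity, attenuation or aberration is
modeled; the goal is to exercise the beamformers' coherence structure, not
to replicate tissue acoustics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import gausspulse

from .io_core import ArrayGeometry, ChannelData, ImageGrid, Modality, ValidationError
from .landmarks import LandmarkSet, RigidTransform

__all__ = ["SceneSpec", "simulate_point_source", "simulate_diffuse_target",
           "simulate_bone_scene", "simulate_out_of_plane",
           "ground_truth_surface_mask", "synth_vertebra_phantom",
           "default_linear_geometry"]

DEFAULT_FS = 40.0  # MHz; 10x the 4 MHz pulse, comfortably beyond Nyquist


@dataclass
class SceneSpec:
    """Parameters of a synthetic acquisition.

    positions : (n, 2) (x, z) mm — sources (photoacoustic) or the bone
        surface polyline vertices (bone scene).
    noise_level : channel-noise standard deviation relative to the peak
        signal amplitude across the aperture.
    """

    kind: str = "point_source"
    positions: np.ndarray = field(default_factory=lambda: np.array([[0.0, 25.0]]))
    amplitudes: np.ndarray | None = None
    center_frequency: float = 4.0  # MHz
    fractional_bandwidth: float = 0.6
    noise_level: float = 0.1
    seed: int = 0
    n_frames: int = 1
    # diffuse-target parameters
    radius_mm: float = 2.0
    n_subsources: int = 30
    delay_min_us: float = 1.8  # multipath arrives after the direct path
    delay_spread_us: float = 1.5  # multipath reverberation time spread
    direct_amplitude: float = 0.12  # direct (unreverberated) fiber-tip emission
    channel_jitter_us: float = 0.15  # per-channel aberration of reverberant paths
    # bone-scene parameters
    n_speckle: int = 4000
    speckle_amplitude: float = 0.1
    surface_amplitude: float = 1.0
    n_fascia: int = 10
    fascia_amplitude: float = 0.35
    fascia_width_mm: float = 2.5
    surface_depth_mm: float = 1.5  # subsurface scattering depth of the bone echo
    # out-of-plane parameters
    wavefront_amplitude: float = 0.25
    n_wavefronts: int = 4

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.noise_level < 0:
            raise ValidationError("noise_level must be >= 0")


def default_linear_geometry(n_elements: int = 64, sound_speed: float = 1540.0
                            ) -> ArrayGeometry:
    """Reduced-aperture version of the L3-8 linear array (0.3 mm pitch,
    0.06 mm kerf, 4 MHz) used for desk-scale simulation."""
    return ArrayGeometry(n_elements=n_elements, pitch=0.3, kerf=0.06,
                         center_frequency=4.0, sound_speed=sound_speed)


def _check_in_fov(positions: np.ndarray, geometry: ArrayGeometry) -> None:
    half = geometry.aperture_width / 2 + 5.0
    if np.any(np.abs(positions[:, 0]) > half) or np.any(positions[:, 1] <= 0):
        raise ValidationError("source position outside the array's field of view")


def _synthesize(positions: np.ndarray, amplitudes: np.ndarray,
                phases: np.ndarray, geometry: ArrayGeometry, fs: float,
                sound_speed: float, fc: float, bw: float, two_way: bool,
                n_time: int | None = None,
                extra_delays: np.ndarray | None = None,
                channel_jitter: np.ndarray | None = None) -> np.ndarray:
    """Sum of pulses over sources; returns (n_time, n_elements)."""
    c_mm_us = sound_speed * 1e-3
    elem = geometry.element_positions
    dist = np.sqrt((positions[:, None, 0] - elem[None, :, 0]) ** 2
                   + (positions[:, None, 1] - elem[None, :, 1]) ** 2)  # (S, N)
    tau = dist / c_mm_us
    if two_way:
        tau = tau + positions[:, None, 1] / c_mm_us
    if extra_delays is not None:
        tau = tau + np.asarray(extra_delays)[:, None]
    if channel_jitter is not None:
        tau = tau + channel_jitter  # (S, N) per-source per-channel aberration
    pulse_halfwidth = 3.0 / (bw * fc)  # us, covers the Gaussian tails
    if n_time is None:
        # record a few us past the last echo so deep pixels see noise, not a
        # truncated window
        n_time = int(np.ceil((tau.max() + pulse_halfwidth + 4.0) * fs)) + 1
    t = np.arange(n_time) / fs  # us
    rf = np.zeros((n_time, geometry.n_elements))
    att = 1.0 / np.maximum(dist, 1.0)  # spherical spreading, clamped near field
    for s in range(positions.shape[0]):
        for i in range(geometry.n_elements):
            dt = t - tau[s, i]
            near = np.abs(dt) <= pulse_halfwidth
            if not near.any():
                continue
            yi, yq = gausspulse(dt[near], fc=fc, bw=bw, retquad=True)
            rf[near, i] += amplitudes[s] * att[s, i] * (
                np.cos(phases[s]) * yi + np.sin(phases[s]) * yq)
    return rf


def _finalize(rf_clean: np.ndarray, spec: SceneSpec, geometry: ArrayGeometry,
              fs: float, sound_speed: float, modality: Modality,
              rng: np.random.Generator) -> ChannelData:
    peak = np.abs(rf_clean).max()
    scale = peak if peak > 0 else 1.0
    frames = np.empty(rf_clean.shape + (spec.n_frames,))
    for f in range(spec.n_frames):
        noise = rng.standard_normal(rf_clean.shape) * spec.noise_level * scale
        frames[:, :, f] = rf_clean + noise
    return ChannelData(samples=frames, sampling_frequency=fs,
                       sound_speed=sound_speed, modality=modality,
                       geometry=geometry, start_time=0.0)


def simulate_point_source(spec: SceneSpec, geometry: ArrayGeometry,
                          fs: float = DEFAULT_FS,
                          sound_speed: float = 1540.0) -> ChannelData:
    """One compact photoacoustic source: each channel receives the pulse at
    its one-way delay with 1/distance amplitude, plus i.i.d. Gaussian
    channel noise."""
    if spec.positions.shape[0] != 1:
        raise ValidationError("point_source takes exactly one source position")
    _check_in_fov(spec.positions, geometry)
    rng = np.random.default_rng(spec.seed)
    amp = np.ones(1) if spec.amplitudes is None else np.asarray(spec.amplitudes)
    rf = _synthesize(spec.positions, amp, np.zeros(1), geometry, fs, sound_speed,
                     spec.center_frequency, spec.fractional_bandwidth, two_way=False)
    return _finalize(rf, spec, geometry, fs, sound_speed, Modality.PHOTOACOUSTIC, rng)


def simulate_diffuse_target(spec: SceneSpec, geometry: ArrayGeometry,
                            fs: float = DEFAULT_FS,
                            sound_speed: float = 1540.0) -> ChannelData:
    """Superposition of randomly positioned, randomly phased sub-sources
    within ``radius_mm`` of the nominal target, each with a random extra
    arrival delay up to ``delay_spread_us`` emulating the multipath
    reverberation of a source surrounded by porous trabecular bone.  The
    time spread smears the amplitude image into a broad diffuse pattern and
    breaks the aperture-domain alignment that coherence beamformers rely
    on.  A weaker direct (unreverberated) emission from the fiber tip is
    superposed at the nominal position: it is buried in the reverberation in
    amplitude images but remains the dominant spatially coherent component,
    which is what lets coherence beamformers localize the tip."""
    if spec.n_subsources < 10:
        raise ValidationError("diffuse target needs >= 10 sub-sources")
    _check_in_fov(spec.positions, geometry)
    rng = np.random.default_rng(spec.seed)
    center = spec.positions[0]
    r = spec.radius_mm * np.sqrt(rng.uniform(size=spec.n_subsources))
    th = rng.uniform(0, 2 * np.pi, size=spec.n_subsources)
    pos = center[None, :] + np.column_stack([r * np.cos(th), r * np.sin(th)])
    amps = rng.uniform(0.5, 1.0, size=spec.n_subsources) / np.sqrt(spec.n_subsources)
    phases = rng.uniform(0, 2 * np.pi, size=spec.n_subsources)
    delays = rng.uniform(spec.delay_min_us,
                         spec.delay_min_us + spec.delay_spread_us,
                         size=spec.n_subsources)
    jitter = rng.normal(0.0, spec.channel_jitter_us,
                        size=(spec.n_subsources, geometry.n_elements))
    pos = np.vstack([center[None, :], pos])
    amps = np.concatenate([[spec.direct_amplitude], amps])
    phases = np.concatenate([[0.0], phases])
    delays = np.concatenate([[0.0], delays])
    jitter = np.vstack([np.zeros((1, geometry.n_elements)), jitter])
    rf = _synthesize(pos, amps, phases, geometry, fs, sound_speed,
                     spec.center_frequency, spec.fractional_bandwidth,
                     two_way=False, extra_delays=delays, channel_jitter=jitter)
    return _finalize(rf, spec, geometry, fs, sound_speed, Modality.PHOTOACOUSTIC, rng)


def _resample_polyline(poly: np.ndarray, spacing: float) -> np.ndarray:
    """Points along a polyline at fixed arc-length spacing."""
    seg = np.diff(poly, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = np.arange(0, arc[-1] + spacing / 2, spacing)
    x = np.interp(s, arc, poly[:, 0])
    z = np.interp(s, arc, poly[:, 1])
    return np.column_stack([x, z])


def simulate_bone_scene(spec: SceneSpec, geometry: ArrayGeometry,
                        fs: float = DEFAULT_FS,
                        sound_speed: float = 1540.0) -> ChannelData:
    """Pulse-echo ultrasound scene of a bright bone surface.

    ``spec.positions`` is the bone-surface polyline.  Strong reflectors are
    laid along it every half wavelength with random phases — at 4 MHz a bone
    interface is rough on the wavelength scale, so it scatters diffusely
    rather than acting as a mirror, which is exactly what preserves its high
    short-lag receive coherence.  The soft tissue above the surface holds
    weak diffuse speckle scatterers plus a few compact echogenic
    fascia/muscle-interface reflectors (weaker and laterally wider than the
    bone, so their receive coherence dies at mid lags while the bone's
    persists across the full lag range); nothing lies below the surface
    (acoustic shadow).
    """
    if spec.positions.shape[0] < 2:
        raise ValidationError("bone scene needs a surface polyline (>= 2 vertices)")
    rng = np.random.default_rng(spec.seed)
    lam = (sound_speed * 1e-3) / spec.center_frequency
    line = _resample_polyline(spec.positions, lam / 2.0)
    # the bone echo has depth: surface roughness plus subsurface scattering
    # spread the reflectors over surface_depth_mm below the surface line
    n_layers = max(1, round(spec.surface_depth_mm / (lam / 2.0)))
    surf = np.vstack([line + [0.0, k * spec.surface_depth_mm / n_layers]
                      for k in range(n_layers)])
    surf_amp = spec.surface_amplitude * rng.uniform(0.7, 1.3, size=surf.shape[0])
    surf_phase = rng.uniform(0, 2 * np.pi, size=surf.shape[0])
    # speckle fills the soft tissue across the whole field of view; beyond
    # the bone's lateral extent it reaches the full depth (no shadow there)
    half_fov = geometry.aperture_width / 2 + 2.0
    x_lo, x_hi = -half_fov, half_fov
    sx = rng.uniform(x_lo, x_hi, size=spec.n_speckle)
    z_deep = spec.positions[:, 1].max() + 8.0
    z_surf = np.interp(sx, spec.positions[:, 0], spec.positions[:, 1],
                       left=z_deep, right=z_deep)
    sz = rng.uniform(2.0, np.maximum(z_surf - 1.0, 2.5))
    keep = sz < z_surf - 0.5
    speckle = np.column_stack([sx[keep], sz[keep]])
    spk_amp = rng.rayleigh(spec.speckle_amplitude, size=keep.sum())
    spk_phase = rng.uniform(0, 2 * np.pi, size=keep.sum())
    # compact fascia-like reflectors in the tissue
    fas_pos, fas_amp, fas_phase = [], [], []
    for _ in range(spec.n_fascia):
        fx = rng.uniform(x_lo, x_hi)
        fz = rng.uniform(3.0, max(float(z_surf.min()) - 2.5, 4.0))
        seg = np.column_stack([
            np.arange(fx - spec.fascia_width_mm / 2, fx + spec.fascia_width_mm / 2,
                      lam / 2.0),
        ])
        seg = np.column_stack([seg[:, 0], np.full(seg.shape[0], fz)])
        fas_pos.append(seg)
        fas_amp.append(spec.fascia_amplitude
                       * rng.uniform(0.7, 1.3, size=seg.shape[0]))
        fas_phase.append(rng.uniform(0, 2 * np.pi, size=seg.shape[0]))
    fas_pos = np.vstack(fas_pos) if fas_pos else np.zeros((0, 2))
    fas_amp = np.concatenate(fas_amp) if fas_amp else np.zeros(0)
    fas_phase = np.concatenate(fas_phase) if fas_phase else np.zeros(0)
    pos = np.vstack([surf, speckle, fas_pos])
    amp = np.concatenate([surf_amp, spk_amp, fas_amp])
    phase = np.concatenate([surf_phase, spk_phase, fas_phase])
    rf = _synthesize(pos, amp, phase, geometry, fs, sound_speed,
                     spec.center_frequency, spec.fractional_bandwidth, two_way=True)
    return _finalize(rf, spec, geometry, fs, sound_speed, Modality.ULTRASOUND, rng)


def ground_truth_surface_mask(polyline: np.ndarray, grid: ImageGrid,
                              band_mm: float | None = None) -> np.ndarray:
    """Boolean mask of a band around the bone-surface polyline (ground truth
    for segmentation tests); band thickness defaults to 2 grid rows."""
    if band_mm is None:
        band_mm = 2 * grid.dz
    z_surf = np.interp(grid.lateral_coords, polyline[:, 0], polyline[:, 1],
                       left=np.nan, right=np.nan)
    zz = grid.axial_coords[:, None]
    with np.errstate(invalid="ignore"):
        mask = np.abs(zz - z_surf[None, :]) <= band_mm / 2
    return np.where(np.isnan(z_surf[None, :]), False, mask)


def simulate_out_of_plane(spec: SceneSpec, geometry: ArrayGeometry,
                          fs: float = DEFAULT_FS,
                          sound_speed: float = 1540.0,
                          n_time: int | None = None) -> ChannelData:
    """Noise-only acquisition: spatially incoherent channel noise plus a few
    weak wavefronts with random per-channel delays (no coherent alignment at
    any pixel), sized so the in-plane SNR test fails (SNR <= 3)."""
    rng = np.random.default_rng(spec.seed)
    if n_time is None:
        depth = max(40.0, spec.positions[:, 1].max() + 10.0)
        n_time = int(np.ceil(depth / (sound_speed * 1e-3) * fs)) + 1
    fc, bw = spec.center_frequency, spec.fractional_bandwidth
    t = np.arange(n_time) / fs
    frames = np.empty((n_time, geometry.n_elements, spec.n_frames))
    for f in range(spec.n_frames):
        rf = rng.standard_normal((n_time, geometry.n_elements)) * spec.noise_level
        for _ in range(spec.n_wavefronts):
            t0 = rng.uniform(0.1, 0.9) * t[-1]
            jitter = rng.uniform(-1.5, 1.5, size=geometry.n_elements)  # us, incoherent
            for i in range(geometry.n_elements):
                dt = t - (t0 + jitter[i])
                near = np.abs(dt) <= 3.0 / (bw * fc)
                if near.any():
                    rf[near, i] += spec.wavefront_amplitude * spec.noise_level * \
                        gausspulse(dt[near], fc=fc, bw=bw)
        frames[:, :, f] = rf
    return ChannelData(samples=frames, sampling_frequency=fs,
                       sound_speed=sound_speed, modality=Modality.PHOTOACOUSTIC,
                       geometry=geometry, start_time=0.0)


# ---------------------------------------------------------------------------
# vertebra phantom for registration testing
# ---------------------------------------------------------------------------

def synth_vertebra_phantom(shape: tuple[int, int, int] = (64, 64, 64),
                           seed: int = 0) -> tuple[np.ndarray, LandmarkSet,
                                                   RigidTransform]:
    """Synthetic vertebra-like binary volume with known landmarks and pose.

    The cross-section is an annulus (vertebral body around the canal) with a
    posterior spinous-process bar and two lateral transverse-process bars,
    extruded along the third axis.  This is a synthetic stand-in for a CT
    bone volume.  Returns ``(volume, landmarks, pose)`` where ``landmarks``
    are canonical-frame anatomical loci [voxel mm units] and ``pose`` is a
    seeded random rigid transform; ``pose.apply(landmarks.points)`` gives the
    world-frame targets for registration round-trips.
    """
    if min(shape) < 32:
        raise ValidationError("volume dims must be >= 32 in each axis")
    nx, ny, nz = shape
    rng = np.random.default_rng(seed)
    cx, cy = nx / 2.0, ny * 0.38
    r_out, r_in = min(nx, ny) * 0.22, min(nx, ny) * 0.11
    X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    rr = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2)
    section = (rr <= r_out) & (rr >= r_in)
    # posterior spinous process
    section |= ((np.abs(X - cx) <= max(2, nx * 0.03))
                & (Y >= cy + r_in) & (Y <= cy + r_out + ny * 0.25))
    # transverse processes
    section |= ((np.abs(Y - (cy + r_out * 0.6)) <= max(2, ny * 0.03))
                & (np.abs(X - cx) <= r_out + nx * 0.18))
    z0, z1 = int(nz * 0.3), int(nz * 0.7)
    vol = np.zeros(shape, dtype=np.uint8)
    vol[:, :, z0:z1] = section[:, :, None]
    zc = (z0 + z1) / 2.0
    pts = np.array([
        [cx, cy, zc],                                   # canal center
        [cx, cy + r_out + ny * 0.25, zc],               # spinous tip
        [cx - (r_out + nx * 0.18), cy + r_out * 0.6, zc],  # left transverse tip
        [cx + (r_out + nx * 0.18), cy + r_out * 0.6, zc],  # right transverse tip
        [cx, cy - r_out, zc],                           # anterior body wall
        [cx, cy, float(z0)],                            # canal, caudal end
    ])
    lm = LandmarkSet(points=pts, labels=["canal", "spinous", "transverse_L",
                                         "transverse_R", "anterior", "canal_caudal"],
                     frame="phantom")
    # seeded random proper rotation (QR of a Gaussian matrix) + translation
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-10, 10, size=3)
    pose = RigidTransform(rotation=Q, translation=t)
    return vol, lm, pose
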