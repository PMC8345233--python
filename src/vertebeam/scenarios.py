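"""Canonical study scenes: the fixed synthetic acquisition conditions used
for end-to-end evaluation of the pipeline.

Three scenes mirror the three experimental questions:

* :func:`bone_scene_study` — an ultrasound scene with a compact bony
  structure under soft tissue (speckle + fascia clutter), for the
  DAS/SLSC/LW-SLSC contrast comparison (caprine parameter set);
* :func:`bone_contact_frames` — matched groups of photoacoustic frames with
  the fiber tip on cortical bone (compact source) vs inside cancellous bone
  (reverberant diffuse source), for the -6 dB-area discriminator (cadaver
  photoacoustic parameter set);
* :func:`out_of_plane_frames` — noise-only frames for the SNR > 3
  in-plane filter.

All scene parameters are fixed study conditions; only the random seed
varies.  Seeds are derived from a single base seed so a whole evaluation is
reproducible from one integer.
"""

from __future__ import annotations

import numpy as np

from .io_core import ArrayGeometry, ChannelData, ImageGrid
from .pipeline import default_grid
from .simulator import (SceneSpec, default_linear_geometry, simulate_bone_scene,
                        simulate_diffuse_target, simulate_out_of_plane,
                        simulate_point_source)

N_ELEMENTS = 48  # reduced aperture of the 0.3 mm pitch linear array
PA_NOISE = 0.05  # channel-noise level of in-plane photoacoustic frames
US_NOISE = 0.25  # channel-noise level of the ultrasound bone scene
TARGET_MM = (0.0, 25.0)  # nominal photoacoustic target position


def study_geometry() -> ArrayGeometry:
    return default_linear_geometry(N_ELEMENTS)


def bone_scene_study(seed: int) -> tuple[ChannelData, ImageGrid, dict]:
    """Bone-under-tissue ultrasound scene with fixed ROIs.

    The bony structure is a 1.2 mm-wide process cross-section at 24.8 mm
    depth with a 1.5 mm-thick echo band.  Returns (channel data, imaging
    grid, ROI dict) where the ROIs target the bone band and the soft tissue
    above it.
    """
    geometry = study_geometry()
    poly = np.array([[-0.6, 24.8], [0.6, 24.8]])
    spec = SceneSpec(kind="bone_scene", positions=poly, noise_level=US_NOISE,
                     seed=seed)
    data = simulate_bone_scene(spec, geometry)
    grid = default_grid(data, x_span=(-5.1, 5.1), z_span=(16, 30), dx=0.3)
    rois = {"bone": dict(x_min=-1.0, x_max=1.0, z_min=24.6, z_max=26.2),
            "tissue": dict(x_min=-1.0, x_max=1.0, z_min=18.0, z_max=22.0)}
    return data, grid, rois


def point_source_frames(n: int, base_seed: int,
                        noise_level: float = PA_NOISE) -> list[ChannelData]:
    """Compact photoacoustic frames: fiber tip against cortical bone."""
    geometry = study_geometry()
    return [simulate_point_source(
        SceneSpec(kind="point_source", positions=[list(TARGET_MM)],
                  noise_level=noise_level, seed=base_seed + k), geometry)
        for k in range(n)]


def diffuse_frames(n: int, base_seed: int,
                   noise_level: float = PA_NOISE) -> list[ChannelData]:
    """Diffuse photoacoustic frames: fiber tip inside cancellous bone."""
    geometry = study_geometry()
    return [simulate_diffuse_target(
        SceneSpec(kind="diffuse_target", positions=[list(TARGET_MM)],
                  noise_level=noise_level, seed=base_seed + k), geometry)
        for k in range(n)]


def bone_contact_frames(n_per_group: int, base_seed: int
                        ) -> tuple[dict[str, list[ChannelData]], ImageGrid]:
    """Matched cancellous/cortical frame groups plus the imaging grid."""
    groups = {"cancellous": diffuse_frames(n_per_group, base_seed + 1000),
              "cortical": point_source_frames(n_per_group, base_seed)}
    grid = default_grid(groups["cortical"][0], x_span=(-5.1, 5.1),
                       z_span=(8, 32), dx=0.3)
    return groups, grid


def pa_grid(data: ChannelData) -> ImageGrid:
    return default_grid(data, x_span=(-5.1, 5.1), z_span=(8, 32), dx=0.3)


def out_of_plane_frames(n: int, seed: int) -> tuple[ChannelData, ImageGrid]:
    """One multi-frame noise-only acquisition plus a coarse grid for the
    SNR measurement (envelope metrics need no fine axial sampling)."""
    geometry = study_geometry()
    spec = SceneSpec(kind="out_of_plane", positions=[list(TARGET_MM)],
                     noise_level=1.0, seed=seed, n_frames=n)
    data = simulate_out_of_plane(spec, geometry)
    grid = default_grid(data, x_span=(-5.1, 5.1), z_span=(5, 32),
                        dx=0.3, dz=0.08)
    return data, grid
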