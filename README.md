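# vertebeam

Coherence-based ultrasound and photoacoustic beamforming for image-guided
spinal pedicle cannulation, with bone segmentation, fiducial registration
and cortical-vs-cancellous bone-contact discrimination.

## The problem

Pedicle screws are placed by drilling through a vertebra's pedicle; the
failure mode is breaching the dense cortical wall that surrounds the
pedicle's porous cancellous core. Two imaging questions arise during
cannulation:

1. **Where is the bone?** Conventional delay-and-sum (DAS) ultrasound shows
   bone boundaries buried in soft-tissue speckle and clutter, which makes
   segmentation for ultrasound-to-CT registration unreliable.
2. **What is the drill/fiber tip touching?** A photoacoustic source (an
   optical fiber at the bottom of the pedicle hole) produces a compact
   signal against cortical bone but a large diffuse pattern inside
   cancellous bone, where multipath reverberation scrambles the arriving
   wavefronts.

This package implements the full analysis chain for both questions on raw
RF channel data, including a simulator that emulates the relevant signal
classes so everything runs end to end without proprietary scanner data.

## Methods at the core

With time-aligned, zero-mean channel signals `s_i(n)`, the normalized
spatial coherence at element lag `m` over an axial kernel `[n1, n2]` is

    R(m) = 1/(N-m) * Σ_i  Σ_n s_i(n) s_{i+m}(n)
                   / sqrt( Σ_n s_i(n)²  ·  Σ_n s_{i+m}(n)² )

* **SLSC** displays the short-lag integral `Σ_{m=1..M} R(m)`.
* **LW-SLSC** keeps all `N_L` lags and, within a small moving kernel `R_i`
  of the coherence stack, picks nonnegative lag weights `w` (summing to 1)
  that minimize the total variation of the weighted lag sum plus an L2
  penalty on the weight gradient:

      min_w  ‖B R_i w‖² + α² ‖D w‖²    s.t.  Σw = 1,  0 ≤ w ≤ 1

  with `D` the 1-D first-difference operator on the weights and `B` the 2-D
  first-difference operator on the vectorized kernel. This is a convex QP
  with Hessian `H = (B R_i)ᵀ(B R_i) + α² DᵀD`, solved here by a primal-dual
  interior-point method; the image is the pixel-wise median of the
  overlapping weighted kernels.
* **Metrics**: gCNR `1 − Σ min(p_in, p_out)` (256-bin histogram overlap),
  CNR `|S_i − S_o| / sqrt(σ_i² + σ_o²)`, SNR `μ_t / σ_b` (all on linear,
  pre-log-compression amplitude), and the −6 dB contour area around a
  photoacoustic target. Acquisitions with SNR ≤ 3 are discarded as
  out-of-plane.
* **Segmentation/registration**: fractional-maximum thresholding,
  morphological cleaning, 8-connected components with amplitude-weighted
  centers of mass, and closed-form (SVD) rigid landmark registration with
  fiducial registration error reporting.

## Worked example

Discriminate cortical from cancellous fiber-tip contact on simulated
photoacoustic channel data:

```python
import numpy as np
import vertebeam as vb
import vertebeam.pipeline as P

geometry = vb.default_linear_geometry(48)

# fiber tip against cortical bone: one compact photoacoustic source
compact = vb.simulate_point_source(
    vb.SceneSpec(kind="point_source", positions=[[0.0, 25.0]],
                 noise_level=0.05, seed=7), geometry)
# fiber tip inside cancellous bone: reverberant diffuse source
diffuse = vb.simulate_diffuse_target(
    vb.SceneSpec(kind="diffuse_target", positions=[[0.0, 25.0]],
                 noise_level=0.05, seed=7), geometry)

grid = P.default_grid(compact, x_span=(-5.1, 5.1), z_span=(8, 32), dx=0.3)
params = vb.PRESETS["cadaver_pa"]

for name, data in [("cortical", compact), ("cancellous", diffuse)]:
    images = P.beamform_all(data, grid, params)
    lw = images["lwslsc"].linear_amplitude
    pz, px = np.unravel_index(np.argmax(lw), lw.shape)
    center = (grid.lateral_coords[px], grid.axial_coords[pz])
    for bf in ("das", "slsc", "lwslsc"):
        area = vb.contour_area_6db(images[bf], center)
        print(f"{name:10s} {bf:7s} -6 dB area = {area:5.2f} mm^2")
```

prints

```
cortical   das     -6 dB area =  0.44 mm^2
cortical   slsc    -6 dB area =  1.66 mm^2
cortical   lwslsc  -6 dB area =  3.37 mm^2
cancellous das     -6 dB area =  1.84 mm^2
cancellous slsc    -6 dB area =  0.91 mm^2
cancellous lwslsc  -6 dB area =  1.82 mm^2
```

The DAS area grows about fourfold when the fiber sits in cancellous bone
(1.84 vs 0.44 mm² here; over 10 frames per group the separation is
significant at p < 0.01), while the coherence beamformers shrink the
diffuse pattern — they localize the tip but deliberately discard the
incoherent reverberation that carries the contact signature. That is why
the amplitude- and coherence-based images are complementary: DAS answers
*what the tip is touching*, LW-SLSC answers *where the tip is* (its
brightest pixel above recovers the true target position (0, 25) mm).

There is also a CLI (`vertebeam simulate|beamform|segment|bone-contact|
register-landmarks`); see `vertebeam --help`.

## Raw channel-data container

HDF5 layout (axis order time × element × frame, units mm/µs/MHz, m/s for
sound speed):

| dataset | content |
|---|---|
| `/rf` | float array `(n_time, n_elements, n_frames)` |
| `/fs` | sampling frequency [MHz] |
| `/c` | sound speed [m/s] |
| `/modality` | `ultrasound_two_way` or `photoacoustic_one_way` |
| `/start_time` | time of first sample [µs] |
| `/geometry/*` | `n_elements`, `pitch` [mm], `kerf` [mm], `curvature_radius` [mm, NaN = linear], `center_frequency` [MHz] |

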