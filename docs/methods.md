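# Methods

This note documents the models implemented in `vertebeam`, the synthetic
study conditions under which they are exercised, and the numerical choices
made where the method description leaves freedom.

## 1. Receive focusing

Images are formed on a Cartesian grid (lateral x along the array, axial z =
depth from the array face, pixel centers on the grid coordinates). For each
pixel and element the receive delay is

* photoacoustic (one-way): `τ = |r_pixel − r_element| / c`,
* pulse-echo ultrasound (two-way): `τ = (z_pixel + |r_pixel − r_element|) / c`,

i.e. the transmit path is approximated by the pixel depth, as for an
unsteered plane or focused transmit. This is a configurable modeling
assumption: the package does not model steered or multi-angle transmits.
Channel samples are linearly interpolated at the fractional delay; samples
requested outside the recorded window are zeroed and flagged invalid, and
the per-channel DC over the imaging window is removed (the coherence
function presumes zero-mean signals). No receive apodization and no
f-number aperture growth are applied by default; the full aperture is used.

Default grids use lateral line spacing equal to the array pitch (0.3 mm),
the line-per-element convention of linear-array scanners. This matters for
LW-SLSC: at pitch spacing the coherence noise of neighboring lines is
decorrelated, so noisy lag slices carry visible total variation, which is
what the TV fidelity term discriminates on. Oversampling laterally makes
all slices spatially smooth and starves the objective of information.
Axial sampling defaults to 0.04 mm (≈ λ/10 at 4 MHz), fine enough to
correlate RF.

## 2. Beamformers

**DAS** sums valid channels per pixel and normalizes by the valid-channel
count (prevents edge-of-aperture brightness bias); envelopes are magnitudes
of the axial analytic signal; display uses `20 log10(v/max)` clipped to a
dynamic range of 25 dB for photoacoustic images (published setting) and
50 dB for ultrasound (common practice; the source setting is unstated).

**SLSC** sums the normalized coherence `R(m)` (axial kernel of 2λ for the
"caprine" preset, 1λ for the "cadaver" presets, centered on the pixel) over
lags 1..M. Pair correlations with zero kernel energy contribute 0; the
average is always over the N−m pairs. The lag cutoff M is an integer count.

**LW-SLSC** solves, per moving kernel of the coherence stack,
`min_w ‖B R_i w‖² + α²‖Dw‖²` on the box-constrained simplex. Design
choices:

* Kernels are top-left anchored with stride `round(size·(1−overlap))`;
  trailing kernels are shifted to abut the image edge so coverage is
  complete. mm→pixel conversion is `round(size/d)`, minimum 2.
* The kernel is vectorized column-major; B lists all vertical (in-column)
  differences first, then all horizontal ones. Any fixed row order gives
  the same `BᵀB`; the order is documented for reproducibility of
  intermediates.
* α is applied to coherence values on their natural [−1, 1] scale.
* The QP is solved by a primal-dual path-following interior-point method
  (the box constraints contribute a diagonal barrier, so each Newton step
  is one dense (N_L+1) solve). The Hessian is ridge-regularized by
  `1e-10·trace(H)/N_L` (flat kernels make `(BR)ᵀ(BR)` rank-deficient) and
  trace-normalized before solving so tolerances are scale-free; duality-gap
  tolerance 1e-8, dual-residual tolerance 1e-6 (relative to the gradient
  scale), at most 100 iterations, with an SLSQP fallback on non-convergence
  (logged). All-zero kernels return uniform weights: every feasible point
  is optimal and uniform is the reproducible tie-break.
* The image is the pixel-wise median of all overlapping weighted kernels
  (full kernel extent); pixels covered by no full kernel copy the nearest
  covered pixel.

Negative SLSC/LW-SLSC sums are clamped to 0 in `linear_amplitude` (log
compression is undefined for negatives and displays are nonnegative); the
signed values remain accessible in `.raw`.

Shipped presets (verbatim acquisition settings): `caprine` (M=9, 2λ kernel,
N_L=28, 1.20×1.92 mm kernel, 50 % overlap, α=0.12), `cadaver_us` (M=5, 1λ,
N_L=15, 2.0×3.1 mm, 60 %, α=1), `cadaver_pa` (M=15, 1λ, N_L=25, 2.0×3.1 mm,
60 %, α=1).

## 3. Metrics

All metrics operate on linear (pre-log-compression) amplitude. gCNR uses
256 equal-width bins spanning the pooled min..max of both ROIs; a
degenerate pooled range returns 0. CNR is `|S_i−S_o|/√(σ_i²+σ_o²)`; SNR is
`μ_target/σ_background` with a 10 mm target ROI centered on the target
(located from the LW-SLSC brightest pixel) and an equal background ROI
25 mm above it, clipped into the image but never overlapping the target
ROI. Frames with SNR of 3 *or less* are discarded as out-of-plane (the
boundary value is discarded).

The −6 dB contour area counts **every** ROI pixel above `10^(−6/20)` of the
ROI maximum, times the pixel area — the enclosed area of all −6 dB
contours. A single connected component was considered and rejected:
single-frame speckle and reverberation envelopes always contain −6 dB nulls
at the resolution-cell scale, so the connected region around the peak
saturates at about one resolution cell and cannot express the diffuse
cancellous signature; the all-contours definition recovers it.

Group comparison uses Welch's two-sided t-test (the two groups have very
unequal spreads) plus box-plot summaries with the 1.5·IQR outlier rule.

## 4. Segmentation and registration

Masks threshold at a fraction of the image-wide maximum amplitude (0.5 for
bone-boundary contours, 0.3 for landmark masks), then morphological opening
(0.38 mm) and closing (0.63 mm) with structuring elements that are square
in physical units (`round(size/dz) × round(size/dx)` pixels, minimum 1 —
rectangular in pixels on anisotropic grids). Components are 8-connected (avoids
splitting thin diagonal boundaries); per-component centers of mass weight
pixel positions by amplitude normalized to the component's own maximum.
Nearest-contour selection measures the Euclidean distance from a reference
point to each component boundary (sub-pixel contour from marching squares)
and tie-breaks to the lower label. Integrated thickness profiles are
column/row sums times pixel size; they conserve mask area exactly.

Rigid landmark registration is the closed-form SVD (Procrustes) solution on
label-matched pairs with a reflection guard (det = +1 enforced by sign
correction); the interactive marker placement of a clinical workflow cannot
be reproduced, but the geometry can. With isotropic per-axis noise σ on N
landmarks the expected total squared fiducial registration error is
σ²(3N−6) — six rigid degrees of freedom are absorbed — which the tests
verify by Monte Carlo.

## 5. Synthetic study conditions

The simulator is far-field point-source superposition with a
Gaussian-modulated sinusoid pulse (4 MHz center — the published transmit —
and 60 % fractional bandwidth, a typical value; bandwidth is not stated in
the source acquisitions), sound speed 1540 m/s, sampling 40 MHz. Element
directivity, attenuation and aberration of the *direct* paths are omitted.
Desk-scale runs use a 48-element slice of the 0.3 mm-pitch linear array.
All generators are pure functions of (scene spec, seed).

**Bone scene (ultrasound).** Bone interfaces at 4 MHz are rough on the
wavelength scale, so the surface is a line of random-phase reflectors at
λ/2 spacing; the echo band is given 1.5 mm of subsurface scattering depth
(cortical surfaces return a roughly 2 mm-thick echo — the reference
segmentation thickness of the imaged vertebra is ~1.8 mm). The canonical
structure is a compact 1.2 mm process cross-section at 24.8 mm depth: its
receive-coherence support then spans all 28 lags of the caprine preset,
which is the regime the published parameters imply. Soft tissue holds 4000
diffuse speckle scatterers across the field of view plus ~10 compact
fascia-like reflectors (2.5 mm wide, 0.35 relative amplitude): partially
coherent clutter that pollutes short-lag SLSC but is suppressed by the
full-lag LW-SLSC weighting — the mechanism behind the published contrast
ordering. Channel noise is 25 % of the peak RF. Below the surface is
acoustic shadow. Under these conditions DAS gCNR ≈ 0.5–0.75 and both
coherence beamformers reach ≈ 0.96–1.0, bracketing the published values.

**Photoacoustic targets.** Cortical contact is a single coherent point
source (amplitude ∝ 1/distance, 5 % channel noise). Cancellous contact is
the same direct fiber-tip emission (relative amplitude 0.12) plus 30
multipath sub-sources within a 2 mm radius, each with random phase, a
random extra arrival delay of 1.8–3.3 µs (multipath is always longer than
the direct path, which keeps the direct arrival's correlation window
clean), and 0.15 µs rms per-channel delay jitter (trabecular-path
aberration decorrelates the reverberant wavefronts across the aperture).
The reverberation then dominates the amplitude image — large diffuse −6 dB
areas under DAS — while the direct component dominates the coherence
images, which localize the tip compactly. Out-of-plane frames are
channel noise plus weak randomly-delayed wavefronts with no coherent
alignment at any pixel; a pure-noise envelope has mean/std ≈ 1.91
(Rayleigh), safely under the SNR > 3 filter.

**What the simulator does not model**, hence what passing tests do not
show: tissue attenuation and dispersion, element directivity, sound-speed
heterogeneity and refraction at the bone interface, transmit beam shapes,
reverberation between distinct anatomical interfaces, and real trabecular
microstructure. The generators are built to exercise the beamformers'
coherence structure, not to replicate tissue acoustics; direction-of-effect
results (orderings, discrimination significance) are the claims being
checked, not absolute image-quality numbers.

**Vertebra phantom.** Registration utilities are tested against a binary
vertebra-like volume (annulus + posterior and transverse processes,
extruded; a synthetic stand-in for a CT bone volume) with labeled
anatomical loci and a seeded random proper pose.

## 6. Problem sizes and runtime choices

End-to-end checks run at reduced scale chosen as this package's standard
desk configuration: 48 elements, ~10 × 24 mm grids, 10 frames per group for
the bone-contact comparison, 100 frames for the out-of-plane filter rate,
and 3 bone-scene realizations averaged in the acceptance summary. Envelope
metrics that need no RF-rate sampling (the out-of-plane SNR screen) use
0.08 mm axial pixels; coherence imaging uses 0.04 mm.

## 7. Known limitations

* The two-way transmit model is depth-only; steered/focused transmit
  sequences would change the delay table and the specularity of smooth
  interfaces.
* The LW-SLSC solution is unique only up to the QP's numerical tolerance
  when the Hessian is near-singular; reruns agree to the solver tolerance
  (1e-6 on the objective), and exactly in practice on fixed hardware.
* Scan conversion supports convex arrays only as beam-space (range ×
  angle) → Cartesian resampling; it does not implement vendor-specific
  sector geometries.
* The out-of-plane class is a statistical stand-in: real out-of-plane
  signals include partially coherent elevation-lobe echoes that this
  generator only approximates with randomly delayed wavefronts.
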