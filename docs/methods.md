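# Methods

## Scope and model

`qmrikit` implements the quantitative-MRI relaxometry workflow used to
validate a multispectral mapping sequence against conventional mapping
sequences on phantoms: forward signal models, per-voxel inversion to T1/T2/PD
maps, synthetic weighted-image generation, QA-phantom metrology, and the
agreement/repeatability statistics that tie it together. All times are in
milliseconds, angles enter the API in degrees, and image magnitudes are in
arbitrary units.

### Signal models

Three closed-form models drive both simulation and fitting (K is a global
intensity scale covering coil sensitivity and amplification; ρ is proton
density; B1 a dimensionless transmit-field scale on nominal flip angles):

* **Spoiled gradient echo (VFA/DESPOT1 family)**

  S = K·ρ·sin(B1θ)·(1 − E1)·e^(−TE/T2\*) / (1 − cos(B1θ)·E1),  E1 = e^(−TR/T1)

  With a single TE the T2\* factor cannot be separated from the amplitude;
  unless `t2_star_ms` is set explicitly it is treated as unity and absorbed
  into the fitted M0.

* **Multi-echo spin echo**

  S = K·ρ·(1 − e^(−TR/T1))·e^(−TE/T2)

* **Multispectral saturation-recovery (QRAPMASTER/MAGiC family)**

  S = K·ρ·e^(−TE/T2) · [1 − (1 − cos B1θ)·e^(−TI/T1) − cos B1θ·e^(−TR/T1)]
      / [1 − cos B1α − cos B1θ·e^(−TR/T1)]

  θ is the saturation pulse (default 120°), α the excitation pulse (default
  90°); the sequence's 180° refocusing pulses do not appear in the signal
  expression. The scanner records magnitude, so simulation takes |S| and the
  fitter models A·|R(TI,T1)|·e^(−TE/T2).

### Default protocols

| Parameter | VFA | ME-SE | Multispectral |
|---|---|---|---|
| TR (ms) | 8 | 1000 | 4000 |
| TE (ms) | 2.2 | 8.1 … 64.5 (8 echoes) | 21.8, 87.1 |
| Flip angles (deg) | 3, 10, 20, 30 | 90 | 120 (sat) / 90 (exc) |
| Saturation delays (ms) | — | — | 170, 620, 1970, 3720 |
| Pixel (mm) | 1.02 × 1.02 | 1.02 × 1.02 | 1.02 × 1.02 |
| Slice (mm) | 2.5 | 2.5 | 2.5 |

The saturation delays are not part of the published protocol of the source
acquisition; the four defaults span the TR and are fully configurable
(`MagicProtocol.sat_delays_ms`).

## Fitting

All fitters are per-voxel and share the masking policy: voxels whose maximum
frame signal is below 1% of the stack's 99th percentile are background;
voxels whose intermediate quantities leave the physical domain (DESPOT1
slope outside (0,1), non-positive log ratios, parameters outside bounds
T1 ∈ [1, 10⁴] ms, T2 ∈ [0.1, 5·10³] ms) are masked, never clipped — clipping
would silently bias VOI statistics. Exported maps hold 0 at masked voxels.

* **VFA T1** — linearized DESPOT1 regression of S/sin(B1θ) on S/tan(B1θ);
  slope = E1, intercept = M0(1−E1). Exact on noiseless data. No transmit
  correction is applied by default (matching the validated acquisition
  setting, where B1 errors were within ±2%); a `b1` argument exists for
  sensitivity studies.
* **ME-SE T2** — weighted log-linear regression of ln S on TE with weights
  ∝ S², countering the noise amplification of the log transform.
* **Multispectral** — staged: (1) T2 from the per-delay weighted log-linear
  echo decay, slopes pooled with signal-power weights; (2) echo dimension
  projected out by least squares onto e^(−TE/T2); (3) T1 by variable
  projection — for any candidate T1 the amplitude solves linearly, leaving a
  1-D profiled residual minimized by an 80-point log grid plus 60
  golden-section iterations per voxel (vectorized); (4) PD from the
  amplitude. There is no exact linearization in T1 because the recovery
  term's denominator also depends on T1, which is why the 1-D search is used
  instead of a regression.
* **Refinement** — every fitter optionally runs trust-region nonlinear least
  squares per voxel (relative tolerance 1e-8, ≤200 iterations), initialized
  from the direct solve; failures fall back to the direct estimate and raise
  a per-voxel flag. The direct solves are already exact on noiseless data,
  so refinement is off by default and intended for noisy ROI-scale work.

Whether the reference multispectral implementation fits jointly or in
stages is not public; both are available here (staged default, joint via
`refine=True`).

## Synthetic contrast

Weighted images are computed from maps with the spin-echo form
S = PD·(1 − e^(−TR/T1))·e^(−TE/T2); the presets are TE=25/TR=600 (T1w) and
TE=65/TR=1900 (T2w). The vendor synthesis equation is not published; the
spin-echo form is this package's documented choice, consistent with both
presets being applied identically to maps from either method.

## QA metrology

Metrics are 2-D per slice, computed on a standard feature layout whose
positions are fixed fractions of the phantom radius (see `QaLayout`):

* **Diameter/distortion** — Otsu segmentation, mean caliper width over 36
  directions through the centroid; distortion = 100·|d − d_nom|/d_nom.
* **Spatial linearity** — landmark dots detected in the central 0.75·R
  region; centroids are intensity-weighted over a 2-px-expanded bounding box
  so partially covered edge pixels contribute (sub-pixel exact for
  area-coverage-rendered dots); linearity = mean signed relative error of
  adjacent inter-landmark distances vs nominal spacing.
* **Pixel size** — physical landmark spacing divided by mean pixel spacing,
  per axis.
* **Slice thickness/increment** — the 45° ramp insert's in-plane bar width
  equals thickness/tan(angle); width is estimated as the equivalent width
  (integral/peak) of the baseline-subtracted profile, which is exact for
  rectangular and trapezoidal profiles and insensitive to where pixel
  boundaries fall, unlike literal half-maximum interpolation on a ~2-px-wide
  bar. Increment comes from the slice-to-slice displacement of a diagonal
  rod, scaled by the same tangent. Bars narrower than ~2 px (very steep
  ramps) are plateau-undersampled and quantization-limited.
* **High-contrast detectability** — highest line-pair group whose
  column-profile modulation (peak−trough)/(peak+trough) ≥ 0.2, after
  trimming half a period from each side of the group (the partially covered
  block-boundary columns would mimic a deep trough). At the default 1.02 mm
  pixels all default groups (5–10 pl/cm) are at or beyond Nyquist; resolving
  them requires a finer render.
* **SNR / noise%** — mean/SD and 100·SD/mean of a feature-free uniform ROI.
* **Uniformity** — integral uniformity 100·(1 − (Smax−Smin)/(Smax+Smin))
  over the central ROI covering 75% of the phantom area, after 3×3 mean
  smoothing.

The modulation threshold (0.2), the 36-direction caliper, and the 75%-area
ROI with 3×3 smoothing are documented defaults; the underlying QA protocol
leaves these constants to the implementation.

## Statistics

* Relative difference: 100·(measured − reference)/reference.
* Bland–Altman: percent differences with the reference denominator for
  phantom-vs-reference comparisons and the pairwise-mean denominator for
  method-vs-method comparisons; limits of agreement are bias ± 1.96·SD
  (n−1 denominator).
* Repeatability: CV over sessions with a 95% CI by McKay's chi-square
  approximation (the CI method is this package's documented default — the
  validation protocol it models does not state one), plus a five-number
  summary of relative differences of sessions 2..n against session 1.

## Synthetic data: what it does and does not emulate

The insert phantom reproduces the published geometry (eight 1 cm × 5 cm
inserts, here laid out two rows of four — the in-box arrangement is not
published) with piecewise-constant reference T1/T2 (29.1–2385.7 /
24.7–1311.3 ms) in a water-like background (T1 2800, T2 1500 ms, a
package default). The QA phantom renders a 190 mm disk with the feature set
above; sub-pixel features (ramp, rod, dots, line pairs) use exact
area-coverage weighting — the through-plane integration a scanner performs —
while the disk edge stays binary so geometric targets are
quantization-exact; an optional Gaussian blur adds realism.

Noise is Gaussian or Rician (magnitude of two independent Gaussian
channels); `target_snr` defines σ as the stack's 99th-percentile signal
divided by the target. Session drift applies one multiplicative gain and one
T1/T2 scale factor per session (session-wise, not frame-wise, so gain
cancels in ratio-based fits); session 1 is always the unperturbed reference.

Not emulated: slice-profile effects, stimulated echoes/EPG corrections,
k-space sampling artifacts, susceptibility, motion, multi-component decay.
Passing tests therefore demonstrate correctness of the estimators under the
stated signal models, not robustness to sequence non-idealities of real
scanners — which is why scanner-measured biases (e.g. short-T1 breakdown of
the multispectral method) are reproduced only qualitatively where the model
supports them (e.g. the negative median bias of long-T2 fits with a
truncated echo train under Rician noise, driven by domain masking of
near-zero decay slopes).

## Problem sizes and numerical choices

Default phantom rasters are 128×128 (insert, 1.02 mm pixels) and 200×200×5
(QA); all end-to-end checks, including the dense grid-search
cross-validation of the fitters (≤100 random draws, profiled-amplitude grid
with recursive zoom), complete in seconds on one core. Golden-section
(60 iterations on a one-grid-cell bracket in log T1) localizes the
multispectral T1 to well below float-visible error on noiseless data. Ties
and degenerate inputs: all-zero stacks return fully masked maps without
error; a vanishing saturation-recovery denominator raises a
`NumericDegeneracyError` naming the (θ, α, TR, T1) combination; VOI
statistics over an empty valid-voxel set raise with the VOI name.
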