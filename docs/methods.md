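# Methods

## Scientific scope

`granulekit` quantifies the material state of RNP granules (P bodies,
stress granules and related condensates) from fluorescence microscopy. A
liquid-like condensate exchanges components rapidly with the cytoplasm,
is rounded by surface tension, mixes internally after a partial bleach,
and is dispersed by 1,6-hexanediol; a solid, amyloid-like assembly does
none of these. Each of these four operational criteria maps onto one
analysis stage, and each stage has a matching synthetic generator with
analytic ground truth so that the whole pipeline is testable by parameter
recovery.

## FRAP model and procedure

A FRAP (or photoconversion) measurement yields three ROI-mean traces per
cell: the bleached focus I_F(t), a reference focus in a neighboring cell
I_R(t), and a background area I_B(t), with f_prebleach baseline frames
before the bleach.

**Double normalization.** With pre-bleach means
I_F,pre = Σ_{t<t_bleach}(I_F − I_B)/f_prebleach (and likewise I_R,pre),

    I_F,norm(t) = [(I_F(t) − I_B(t)) / I_F,pre] / [(I_R(t) − I_B(t)) / I_R,pre].

Division by the identically-acquired reference cancels acquisition
bleaching exactly, and the construction is invariant under any common
gain or offset of the three channels. Traces with a nonpositive
pre-bleach mean or a nonpositive background-subtracted reference on any
post-bleach frame are *rejected* (unusable measurement) — a distinct
outcome from QC *exclusion* below.

**Reference QC.** In small, densely packed cells, the bleach pulse aimed
at one cell can photoconvert the reference focus of its neighbor. To
detect this, y = A·e^{p·x} is fitted to the background-subtracted
post-bleach reference (p unconstrained in sign; x measured from the
bleach), the fitted curve is evaluated at the pre-bleach time points and
averaged (I_R,estimate — like-for-like with the measured baseline
I_R,measured), and the cell is excluded when

    I_R,estimate < I_R,measured · (1 − qc_tolerance).

`qc_tolerance` defaults to 0.02 so that measurement noise alone does not
exclude cells; 0 restores the literal inequality.

**Recovery fit and half-time.** The post-bleach normalized signal is fit
with y = A·(1 − e^{−p·x}) by trust-region nonlinear least squares
(tolerances 1e-10, ≤1000 function evaluations), initialized with A₀ =
mean of the last 10% of points and p₀ = ln2 / (first time the curve
exceeds A₀/2), falling back to 4/span. The half-recovery time is
t_1/2 = ln2/p. An optional additive offset term accommodates residual
signal at the bleach frame; the default (no offset) matches the
generative model's default residual of zero. Fits that do not converge
or return p ≤ 0 (or A ≤ 0) are flagged non-recovering and dropped from
group summaries. Only post-bleach frames enter the fit.

**Group statistics.** Per-group medians and 25th/75th percentiles are
reported alongside a two-sided, equal-variance two-sample t-test on the
raw per-cell half-times — medians for robust location, the t-test for
the conventional significance call. With fewer than two values in a
group the test is skipped with a warning.

## Synthetic FRAP traces

The generator is the exact inverse of the analysis model:
I_F = B + D(t)·F·S(t) with D(t) = e^{−r_acq·t} shared by focus and
reference, S(t) = 1 pre-bleach and
S(t) = residual + A·(1 − e^{−ln2·(t−t_b)/t_½}) after it; the reference
optionally loses a crosstalk step at the bleach; independent Gaussian
noise is added to every channel. Time starts at the first acquired
frame; the bleach falls between frames n_prebleach−1 and n_prebleach, so
the first post-bleach frame sits at elapsed time 0 of the recovery —
consistent with the zero-intercept fit form.

Key defaults, with reasoning:

| parameter | default | why |
|---|---|---|
| focus/reference scale | 1000 counts | EMCCD-range signal |
| background_level | 100 counts | typical camera offset + cellular background |
| noise_sd | 10 counts | per-pixel SNR ≈ 20 averaged over a 5×5 px ROI (traces are ROI means, so trace-level noise is per-pixel noise / √25) |
| acq_decay_rate | 0.002 s⁻¹ | a few-fold loss over the longest (900 s) acquisitions |
| n_prebleach | 10 frames | typical published baseline at 1 s intervals |
| frame_interval | 1 s | the acquisition rate of the experiments emulated |
| plateau_A_true | 0.8 | immobile fraction of 0.2, typical for granule proteins |

The noise model is additive Gaussian (read-noise proxy); Poisson shot
noise is omitted because every downstream statistic is a ratio of ROI
means at SNRs where the distinction is immaterial. Noise is added to
traces, not rendered images, for the FRAP pathway; image-space generators
add pixel noise directly.

**Acquisition envelope.** At the default bleaching rate, a 900 s
acquisition decays the reference to ~16% of its initial level — still
well above the noise floor. Much longer experiments (e.g. 2000 s at 1 s
frames) exhaust the reference focus, and the positivity precondition
then correctly rejects the traces; simulated experiments therefore stay
within a 900 s window, matching the slowest structures analyzed (the
amyloid-like states). This is a property of the modeled photophysics,
not of the fitting.

## Granule fields and morphometry

Synthetic fields place non-overlapping granules (bounded rejection
sampling) inside an elliptical cell. Disks carry analytic truth
(area πr², perimeter 2πr, circularity 1); irregular aggregates are
radial-perturbation polygons r(θ) = r₀(1 + Σ_{m=2..6} a_m cos(mθ+φ_m))
with Σ|a_m| equal to the roughness parameter, and their truth
area/perimeter are computed on the polygon *before* rasterization, so
pixel effects never contaminate the ground truth.

Segmentation is thresholding (Otsu on the within-mask histogram, or
manual) followed by 8-connected particle analysis with size and
circularity windows; the defaults (0..∞, 0..1) pass everything. For
window filtering, measured circularity is capped at 1 so discretization
overshoot cannot exclude a round object; measurement output reports the
uncapped value.

**Perimeter estimator.** Circularity = 4π·Area/Perimeter² is exquisitely
sensitive to the perimeter convention. Pixel-edge counting inflates
perimeters by up to 4/π (circularity ~0.6 for a large disk);
marching-squares contour length retains a persistent ~5% staircase bias
(circularity plateaus near 0.91). The Crofton formula with 4 directions
is asymptotically unbiased for smooth outlines — rasterized disks
measure within ±0.015 of circularity 1 for r ≥ 10 px — and is used
throughout. Known trade-off: Crofton under-measures shapes with long
axis-aligned straight edges (an axis-aligned square reads ~0.90 instead
of π/4); since the statistic is used to grade the roundness of blob-like
granules, the smooth-shape regime is the relevant one.

The foci-to-cytoplasm ratio is (mean foci − background)/(mean of
cell∖foci − background), using mean (not integrated) ROI intensity.
Fusion detection links objects frame-to-frame by greedy nearest-centroid
matching (default max displacement 5 px/frame, adequate for slow granule
motion) and calls a fusion when ≥2 tracks converge on one object whose
area matches the summed parent areas within 25%.

## Half-bleach and dissolution

The half-bleach generator and analysis share a two-compartment model:
after bleaching one half of a droplet to depth d, the half-to-half
difference obeys d(u−b)/dt = −2k(u−b), so the asymmetry
A(t) = (mean_unbleached − mean_bleached)/(sum), on background-subtracted
means, decays as e^{−2kt}. The analysis fits A(t) = A₀e^{−rate·t} and
recovers rate = 2k; a rate below 0.01/(time span) — or a failed fit —
classifies the structure as solid-like. A(t) is exactly gain-invariant.
No spatial reaction–diffusion model is attempted: the scalar metric is
what the acceptance of liquid vs solid needs, and it reduces to the
closed-form two-compartment solution on the simulator.

Dissolution analysis normalizes each structure's background-subtracted
mean intensity (static masks by default — structures barely move during
minutes-long treatments) to its value at a pre-treatment reference
frame, and reports per-structure curves plus the population mean ± SD
per frame. Structures at background level in the reference frame are
dropped with a warning. The generator holds structures constant until a
treatment-onset frame and then decays each as e^{−(t−t_onset)/τ_i}, with
τ = ∞ modeling treatment-resistant (amyloid) controls.

## Numerical and interface conventions

- Seconds and µm throughout; coordinates 0-based (row, col); ROI
  rectangles inclusive; 8-connectivity for particles.
- All nonlinear fits: `scipy.optimize.least_squares`, trust-region
  reflective, ftol = xtol = gtol = 1e-10, max 1000 evaluations.
- Every generator consumes a `numpy` `default_rng` seeded from
  (config seed, cell index), so outputs are bit-reproducible and
  per-cell streams are independent.
- Trace CSVs are read with round-trip float parsing, so a
  write-then-read cycle reproduces traces exactly.
- The pipeline's outputs embed a hash of the analysis parameters
  (output path excluded) plus the seed; identical config + seed gives
  byte-identical tables.

## Validation design and its limits

Parameter-recovery experiments use the published group medians as
generative ground truth: cohorts of 6 (P-body state, 22 s, 300 s
window), 4 (amyloid-like, 131 s, 900 s), and 4 + 4 (stress-granule 42 s
at 600 s vs amyloid-like 113 s at 900 s) traces, at the defaults above.
These sizes mirror the original experiments, so the acceptance checks
probe small-n behavior, not asymptotics.

Passing these tests shows the pipeline inverts its own generative
model accurately at realistic noise, sample sizes and acquisition
lengths. It does not certify behavior on real microscopy beyond that
model: the generators omit shot noise, focus drift, z-sectioning,
motion of foci during acquisition, non-exponential (diffusion-limited)
recovery shapes, and segmentation challenges like touching or dim
granules. The QC stage in particular assumes the crosstalk appears as a
step loss at the bleach frame; gradual reference loss is absorbed into
the decay fit by design.
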