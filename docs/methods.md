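# Methods

## The axial readout

In a biplane detection scheme the emitted fluorescence is split 50/50 onto
two detectors whose imaging lenses are offset along the optical axis, so
the two images of one emitter are defocused by different amounts. When both
spots are fitted with a Gaussian of *fixed* width (FWHM 300 nm), the fitted
photon intensities I₁ (transmitted) and I₂ (reflected) depend on the
emitter's axial position z, and their normalized contrast

γ(z) = (I₂ − I₁) / (I₂ + I₁)

is monotone in z over a working range of several hundred nm. Because γ is a
ratio of simultaneously measured intensities, common factors (emitter
brightness, blinking state, laser fluctuations) cancel; no aperture
photometry or reference intensity is needed. The sign convention is
(I₂ − I₁); the calibration absorbs either ordering, so only consistency
between calibration and assignment matters.

### Calibration

A calibration scan sweeps a single-molecule surface linearly through focus
and records (stage z, I₁, I₂) triplets. γ is computed per triplet and
reduced to a running median over non-overlapping 25 nm z-bins; bins with
fewer than 5 pairs are dropped. A polynomial (default order 7, configurable
3–11; odd orders track a sigmoid trend without endpoint oscillation) is
fitted to the bin medians, and the lookup table (LUT) covers the largest
contiguous interval on which the polynomial is strictly monotone with
|γ| < 1, sampled at 1 nm. An interval shorter than 100 nm is treated as a
failed calibration.

One numerical detail: the abscissa of each bin is the *median z of the
pairs in the bin*, not the geometric bin center. For discretely sampled
scans the bin's median γ corresponds to its median sampled z; anchoring it
at the geometric center biases partially filled edge bins by up to half a
bin width, which is the difference between ~0.01 nm and ~2.5 nm median
inversion error at the defaults.

### Assignment

The two channels are registered with a similarity transform (translation,
rotation, scale) estimated from mutual-nearest-neighbour control pairs
after a coarse translation from the cross-correlation of the 2D
localization histograms. Localizations are then matched frame by frame:
candidate pairs within 500 nm are accepted greedily in ascending distance
order, one-to-one ("linear nearest neighbour" is implemented as this
deterministic greedy mutual matching; ties break toward lower record
index). Each pair's γ is inverted by linear interpolation between the
bracketing 1 nm LUT nodes; γ outside the LUT span is rejected rather than
extrapolated. A single scalar (config `ri_factor`, default 1.0) rescales z
for the refractive-index mismatch; it is a property of the optical setup
that the user must calibrate.

## Drift, tilt and precision

The basal membrane layer is its own fiducial. Per non-overlapping window of
500 frames the *median* z of all localizations is recorded (the median is
robust against localizations on protrusions above the layer; on the
synthetic membrane model it differs from the mean by well under 2 nm). The
trace is fitted with a polynomial in time (default order 6) weighted by
window counts, and z is linearized by subtracting the polynomial relative
to its value at the first window. Residual sample tilt is then removed by
fitting a plane to the per-pixel mean-z image (100 nm pixels) and
subtracting the local plane value, keeping the global mean. Drift
correction always runs before the tilt test, and both corrections conserve
localization count and lateral coordinates.

Localization precision is estimated from blinking: consecutive-frame 3D
nearest-neighbour links form tracks, which grow only while the cumulative
inter-localization path length stays below 75 nm. Per axis, deviations from
each track's mean are pooled and fitted with a Gaussian whose σ is the
precision. Deviations are deliberately not rescaled for track length, so
the estimate carries the √((n−1)/n) within-track shrinkage (−29% for
2-frame tracks, −5% for 10-frame tracks); this matches the plain
"deviation from the mean coordinate" definition, and the bias is visible in
the recovery tests.

## Quantifying the axial distribution

Corrected localizations are rendered into a z-stack with 20 nm voxels
(half-open bins; voxel value = localization count). The cell interior is
tiled with non-overlapping 2 × 2 µm² squares anchored at the master-mask
bounding box; a square is kept when the mask covers more than 75% of its
area and its footprint is clipped by the mask. Each ROI's axial histogram
is fitted with a bi-Gaussian

y = a₁ exp(−½((x − m₁)/s₁)²) + a₂ exp(−½((x − m₂)/s₂)²)

by bounded least squares (a ≥ 0, s ∈ [10, 1000] nm, means inside the
profile range), initialized from the two most separated local maxima of the
3-bin-smoothed profile (fallback: single peak ± one bin; ties toward lower
z) and relabeled so m₁ ≤ m₂. Derived parameters, with FWHM = 2.355 s:

* z_w = (m₂ + FWHM₂/2) − (m₁ − FWHM₁/2) — overall axial spread;
* p-p = |m₂ − m₁| — separation of the two populations;
* Δ_FWHM = |FWHM₁ − FWHM₂| — how much broader one population is.

These satisfy z_w ≥ p-p and z_w ≥ (FWHM₁ + FWHM₂)/2 identically.

Across many ROIs, the histograms of these parameters are modeled by user
choice: mono- or bi-Gaussian (reported as µ, σ and the range
µ ± FWHM/2 = µ ± 2.355σ/2, rounded half-up to integer nm) or a
mono-exponential decay (reported as τ, the distribution mean). Model
selection is user-specified, not automatic.

### Master mask

A production analysis uses a manually drawn cell-interior mask. The
automatic default thresholds the 100 nm-pixel localization density at ≥ 1,
closes with a 1 µm disk, fills holes, takes the convex hull of the
footprint and erodes by 1 µm. The convex-hull step is deliberate: receptors
may legitimately concentrate on sparse surface features (protrusion tips),
leaving empty membrane between them that still belongs to the cell
interior; closing alone fragments such masks.

## Homogeneity score

For cell-contact images the GLCM homogeneity pipeline is: min–max 8-bit
conversion → ISODATA threshold (value-domain midpoint iteration; values
below T set to 0) → 256×256 co-occurrence matrices at offset 1 for angles
0, π/4, π/2, 3π/4 → zero the first row and column (background pairs) →
normalize to sum 1 → weight entries by 1/(1 + |i − j|) → sum per angle →
average the four angles. Directions with no surviving pairs contribute 0.
The weight is the standard inverse-absolute-difference homogeneity kernel;
1/(1 + (i − j)²) is available behind the `weight="sq_diff"` switch. The
ISODATA iteration is implemented directly on gray values (not histogram
bins) so that small discrete images have the exact midpoint fixed point.

## Synthetic data model

The generator emulates the study conditions end to end. Optical model:
Gaussian axial responses at focal offsets c₁ = −200 nm and c₂ = +200 nm,
width w = 300 nm, mean total budget 2000 photons per appearance split
between channels in proportion to the responses — with these defaults
γ(z) = tanh(z(c₂ − c₁)/2w²) = tanh(z/450 nm), near-linear over ±300 nm and
monotone over roughly ±400 nm, consistent with a working depth within
~1 µm of the coverslip. Poisson noise on the two channel intensities
propagates to σ_γ ≈ √(4I₁I₂/(I₁+I₂)³) ≈ 0.022 at 2000 photons, i.e. an
axial scatter near 10 nm.

Surface model: a flat base level plus protrusion tips (density 2/µm²,
radius 50 nm) at a configurable level (default 150 nm above base), a
configurable fraction of emitters on tips and 25 nm axial placement jitter.
Emitters blink with geometric on-times (mean 3 frames); per appearance,
lateral noise (σ 10 nm) and Poisson-noised biplane intensities are drawn at
z_true + drift(frame) + tilt(x, y). Both channel tables share the same
lateral noise per appearance, so pairing is exercised on transform and
density effects rather than on re-drawn noise; drift/tilt injection and the
known reflected-channel affine are recorded in the ground truth.

What the generator does **not** model: dark-state photophysics and
re-activation kinetics, EMCCD excess noise and camera gain, vectorial/
aberrated PSFs, axially varying background, lateral drift, or the
between-cell variability of real membranes. Passing tests therefore
demonstrate the correctness and internal consistency of the algorithms
under controlled conditions, not instrument-level performance on cells.

## Problem sizes and numerical choices

The test and acceptance workloads use desk-scale sizes chosen as the
smallest that make the statistical assertions stable: calibration scans of
10 nm steps × 10 repeats, 1000 noisy repeats per precision level, 3000 ×
10-appearance membrane runs for topography comparisons, and 100k
localizations over 50k frames for the drift/tilt recovery. Population
means over ROI histograms from real cells (hundreds of ROIs over dozens of
cells) are emulated qualitatively only: the synthetic scenarios reproduce
the *ordering* of tip-clustered versus dispersed receptor topographies,
not the absolute per-cell values.

Degenerate inputs are handled explicitly: empty tables render nothing and
raise; constant-γ scans and constant images raise; collinear tilt pixels
raise a rank error; a single-Gaussian profile fitted with the bi-Gaussian
model converges to an a₂ ≈ 0 or m₁ ≈ m₂ solution whose derived z_w is
stable to within a few percent across re-runs.
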