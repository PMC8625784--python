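# Methods

## Signal model

A photographed Coomassie-stained gel is treated colorimetrically: stain
intensity is taken to be directly proportional to the protein mass under it.
RGB photographs are collapsed to luminance with BT.709 weights and inverted
once, `signal = white_reference − luminance`, clipped at zero. The linear
inversion (rather than decadic optical density, available as `mode="od"`) is
the default because the downstream calibration absorbs any mild
non-linearity of the stain response in its quadratic term. Source pixels at
the camera's full-scale code value are carried in a saturation mask; a peak
whose support is more than 1 % saturated is flagged in every report and never
silently quantified.

`white_reference` defaults to the 99.5th percentile of the luminance — the
bright unstained background. A histogram-mode estimate was considered and
rejected: when the background is graded (illumination falloff, uneven
staining) the mode sits *inside* the background range, and the clip at zero
then removes band tails wherever the local background is brighter than the
mode; faint bands lose a large fraction of their area. The high-quantile
estimate leaves a small constant pedestal instead, which the background
flattening removes.

Orientation convention: wells at row 0, migration increases with the row
index; column intervals are half-open, indices 0-based. Images oriented
otherwise are rotated via the run config.

## Background flattening

Per column, the background is estimated with a *quantile opening*: a moving
10th-percentile filter along the migration axis followed by a moving
90th-percentile filter with the same window (default 25 % of the image
height). The pair is exact on linear ramps — the downward shift of the first
pass is undone by the second — while bands much narrower than the window are
rejected. Edges are padded by odd (point) reflection, which continues
gradients, so ramps stay exact at the first and last row.

One refinement matters quantitatively: on a sloped background a band casts a
"shadow" — windows whose low end falls inside the band see an elevated
quantile — which clips up to a few percent of the band's area. After the
first estimate, rows more than 3 robust standard deviations (1.4826·MAD per
column) above it are bridged by straight interpolation between the flanking
background and the opening is re-run on the bridged signal. On noise-free
synthetic gels with the generator's default gradients this keeps per-lane
integrals within ~1.5 % of truth across a 16-fold dilution range.

## Densitograms and peaks

A lane's densitogram is the mean signal across its columns at each row; the
mean (not the sum) makes profiles comparable across lanes of different
widths. Densitograms are then processed like chromatograms:

* **Baseline.** `valley_chords` (default) joins prominent minima of a
  strongly smoothed copy of the profile (window = length/20) by straight
  chords; prominence filtering (2 % of the smoothed range) rejects noise
  ripples riding on band tops, and knot heights are local 5-row medians of
  the raw profile so chords anchor on the true floor rather than on the
  deepest noise excursions. `smooth_floor` iteratively clips the profile
  against its running mean, converging to a smooth lower envelope.
* **Detection.** Apexes and valleys are located on a lightly smoothed copy
  (Gaussian, σ = min_width_rows/2): on a noisy profile the raw apex has only
  noise-scale prominence and every width test fails. Peaks must exceed
  `min_height_frac` (default 0.05) of the profile maximum and be at least
  `min_width_rows` (default 3) wide. Bounds follow the valley-to-valley
  convention: the deepest point between adjacent peaks, and on outer flanks
  the first point below 5 % of the peak height. The reported apex is the
  maximum of the *raw* profile within the bounds, earliest row on ties.
* **Integration.** Trapezoid rule. The area over the half-open interval
  [s, e) is defined through the cumulative trapezoid as the integral of the
  piecewise-linear interpolant from sample s to sample min(e, n−1); with
  this convention areas over any contiguous partition add up to the
  whole-interval area exactly, which plain per-slice trapezoid sums do not
  satisfy.
* **Diffuse smears** defeat valley logic by design; they are quantified only
  through explicitly declared integration regions, and unwanted bands are
  excluded by simply not declaring regions for them. No deconvolution of
  overlapping peaks is attempted; overlaps split at the valley.

## Calibration

`Q = a·S² + b·S` with no intercept (zero protein, zero stain), fitted by
weighted least squares. The default weighting is 1/Q² (relative error):
a twofold serial dilution spans a 16-fold mass range, and unweighted fitting
lets the most loaded lane dominate the fit. Unweighted and 1/Q modes are
exposed and recorded in the calibration report. The fit-quality figure,
`relative_deviation_pct`, is the mean (optionally max) absolute relative
residual in percent. Inversion uses the citardauq form
`S = 2Q/(b + √(b² + 4aQ))`, stable when `4aQ ≪ b²` and continuous as a → 0.

Calibration points and unknowns must come from the same gel image, so
background staining and gel-concentration variation cancel; externally
supplied coefficients are refused unless `allow_cross_gel` is set.

## Molecular weight

Rf = apex_row / front_row with a user-declared front row (dye front or gel
end). The ladder maps Rf to log₁₀(MW/kDa) either piecewise — monotone
log-linear interpolation, exact at every anchor, terminal segments extended
and flagged for out-of-range queries — or as a single least-squares line.
Piecewise is the default: real gels deviate from a global log-linear law at
the range ends.

## Degradation degree

`α = (S₀ − S_t)/S₀ × 100` from the native-protein band areas of a
control/treated lane pair. α is scale-free, so it needs no calibration. The
treated lane's native band is matched to the control apex within
`native_match_rows` (default 15 rows); if the band has vanished entirely, the
control's bounds are integrated on the treated profile instead, so complete
degradation reads ~100 % rather than failing. `S_t > S₀` yields a negative α
with a warning (apparent gain happens with noisy areas near zero
degradation). Reports carry both the native-band and the total-lane area so
either basis can be inspected; the headline α uses the native band.

## Synthetic gels

The generator emulates the study design the pipeline targets: dark bands on
a light background, a twofold serial-dilution calibration series
(0.2 mg/mL × 10 µL top load → 2.0, 1.0, 0.5, 0.25, 0.125 µg by default), an
8-anchor marker lane spanning 14.4–116 kDa (conventional unstained-ladder
masses; the intermediate values are configurable), and degradation series in
which treated lanes retain a declared fraction of the native band, the
balance optionally redistributed into a broad diffuse smear with total
deposited signal conserved exactly.

Bands are Gaussian along migration and uniform across the lane width,
discretely normalised so the deposited signal equals `mass_ug × response`
exactly before noise; closed-form oracles follow. Band centres obey
`rf = intercept + slope·log₁₀(mw)` (defaults −0.94, 2.04, placing 116 kDa
near the well and 14.4 kDa near the front at row 0.93·n_rows). The background
is a base level plus linear row/column gradients (defaults 200 + 300 + 150
counts on a 16-bit scale, i.e. below 1 % illumination non-uniformity, as a
decent photographic bench achieves); sensor noise is additive Gaussian
(default sd 5 counts, which puts the faintest default band at a
signal-to-noise ratio of about 50) applied before quantisation; Poisson shot
noise and photorealistic artefacts (texture, cracks, keystone) are out of
scope. Rendering is bit-exact reproducible for a fixed seed via numpy's
seeded Generator.

What passing on synthetic gels does *not* show: robustness to perspective
distortion, spatially correlated staining artefacts, ladder-law curvature, or
stain saturation at high loads — real photographs need the saturation flags
and manual regions the tool exposes.

## Numerical and design choices

* Default gel sizes in tests and the acceptance script are 600×~330 px —
  small enough to iterate quickly, large enough that discretisation error of
  a σ = 5-row band is negligible.
* Lane auto-detection thresholds at 20 % of the 95th percentile of the
  smoothed column-mean signal and splits runs at clear interior minima. A
  16-fold dilution series intentionally defeats any single global threshold
  (the faintest lane is ~6 % of the brightest); explicit lane geometry in
  the run config is the supported path for such gels, and a declared
  `expected_n` turns silent mis-detection into a hard error.
* The published calibration coefficients used in the worked example are
  treated as a given forward curve: `from_coefficients` evaluates them but
  the package does not claim any particular fitting scheme reproduces them
  from the reported dilution table (none of the standard weightings does).
* Degenerate inputs fail loudly: images smaller than 16×16, windows outside
  range, reversed bounds, non-monotone ladders, calibrations with fewer than
  3 distinct areas, α with S₀ ≤ 0.
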