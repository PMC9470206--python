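# Methods

## The assay

A single adult zebrafish swims in a square test tank (15 cm side; the inner
12 × 12 cm is tracked) while point-light displays are shown on one or two
walls. Recording covers a 1-minute baseline with no stimuli and a 4-minute
test period, analysed whole and in four 1-minute bins. Attraction to a
stimulus is read out from three variables per region of interest (ROI) — a
band one adult body length deep (20% of the tank side, 3 cm at the defaults)
along each stimulus wall:

* **time%** — tracked frames with the centroid inside the band, as a percent
  of all tracked frames in the period;
* **orientation%** — among in-band frames, the percent whose heading unit
  vector has a strictly positive dot product with the band's inward normal
  (a ±90° tolerance; the endpoints are a measure-zero set and count as
  not-toward);
* **Rproj** — the per-frame heading unit vectors averaged over in-band
  frames and projected onto the inward normal. This is the scalar projection
  of the mean resultant vector of circular statistics: +1 = always facing
  the screen, −1 = always facing away, 0 = no net directionality, and
  |Rproj| is bounded by the mean resultant length.

Test-period values are baseline-normalised per fish (Δ = test − baseline).
A fish that never enters a band in a period produces a missing value that
propagates into the Δs and is deleted pairwise in the statistics, so
per-comparison sample sizes vary.

Fish position is the blob **centroid** (the standard choice when "the fish"
is not otherwise defined), and ROI membership uses closed rectangles; the
denominator of time% is tracked (ok) frames, since nothing can be said about
the fish's position in failed frames.

## Stimulus transforms

Point-light sequences (six dots along the body, 60 fps, 3600 frames per
minute of recording) are stored as delimited text in either a long
(`frame,dot,x,y`) or wide (`frame,x1,y1,…`) dialect; y is Cartesian (up)
internally, with a reader flag for image-convention files. Inversion
reflects y about the midline of the global bounding box — this keeps the
stimulus inside its original vertical footprint and is an involution. The
non-BM control keeps the dot count but replaces the body with a rigid
collinear chain: adjacent spacing equals the recording's mean inter-dot
distance pooled over frames and adjacent pairs, and the chain translates at
the recording's mean per-frame centroid displacement. "Average speed" is
deliberately defined from the centroid (not a per-dot average); the chain
moves horizontally by default and reflects elastically off the display
edges, with the reflection rectangle inset by the chain half-span so every
dot stays on screen. At bounce frames the chord displacement is necessarily
shorter than the straight-line step; the constant-speed and
zero-acceleration guarantees hold exactly on straight segments.

## Gravity signature

Vertical velocity and acceleration are computed per dot by central
differences (`v[t] = (y[t+1] − y[t−1])/2 · fps`,
`a[t] = (y[t+1] − 2y[t] + y[t−1]) · fps²`), chosen for symmetry and
second-order accuracy; a forward scheme and an optional moving-average
pre-smoother are available for sensitivity checks because tracking jitter
inflates accelerations. Samples are pooled over all six dots and the
interior frames, then split by sign: the gravity signature is the mean
magnitude of the positive (upward) and negative (downward) samples, with
zero-valued samples belonging to neither side and an empty side reported as
missing with count 0. Vertical reflection negates y exactly, so inversion
swaps the up/down entries of the signature; on dyadic-grid coordinates
(e.g. pixel-quantised data) the swap is exact in double precision, which is
how the property tests check it.

## Tracking

Per frame: (1) Otsu thresholding inside the predefined tracked region, with
polarity auto-detected (the minority intensity class is the fish) and a
minimum foreground/background mean separation (default 20 intensity units)
so that fish-absent frames — where Otsu will happily split sensor noise —
yield an empty mask; the largest connected component above 30 px is kept.
(2) The centroid is the mask's center of mass; the body axis is the
principal second-moment eigenvector; each endpoint is the mean of the pixels
within 1.5 px of the extreme axial projection (robust to single off-axis tip
pixels). The head end is identified by front-heaviness via the *third*
moment of the axial projection — the long thin tail forms the skew lobe, so
the head lies opposite the skew. (The naive rule "head = side with greater
area about the centroid" fails: the center of mass nearly bisects the area
by construction.) A temporal-continuity override swaps head and tail if the
implied heading would jump more than 90° from the previous detection.
(3) Failed frames are flagged, never dropped, so trajectory length always
equals stream length. Coordinates are region-local pixels with y up; the
renderer uses the same transform, making tracker output directly comparable
with ground truth and with arena coordinates.

## Exclusion rules

Applied to the baseline behaviour: (a) **frozen** — a run of consecutive
sub-threshold steps (centroid displacement < 0.1 cm/frame) lasting strictly
more than 4 s (at 2 fps: 9 or more steps excludes, 8 = 4.0 s is kept);
(b) **restricted** — the fish visits fewer than 25% of the 1-cm grid cells
of the tracked area during baseline (no published threshold exists for
"staying within a restricted area"; 25% coverage is this package's declared
convention, configurable); (c) **missing** — strictly more than 500
tracking-failure frames over the recording.

## Statistics

Shapiro–Wilk at α = 0.05 gates each comparison (on the paired differences,
or on both groups for independent comparisons) between a parametric t-test
(paired, or pooled-variance independent; Welch behind a flag) and a
permutation t-test. The permutation null uses random sign-flips of the
paired differences or label shuffles between groups, with exhaustive
enumeration whenever the full group (2ⁿ sign patterns or all label splits)
fits within `n_perm` (default 10,000); the Monte-Carlo p-value uses the +1
correction so it is never exactly zero. BH-FDR is applied to the family of
four 1-minute-bin comparisons within each metric × ROI, separately from the
whole-period comparison; the family definition is a declared convention.
Degenerate inputs are defined rather than erroneous: zero variance with zero
mean difference gives t = 0, p = 1; constant samples skip the normality gate
and take the parametric branch.

The experiment drivers mirror the two designs: **within** (dual display,
both stimuli shown to every fish) runs paired test-vs-baseline comparisons
per ROI and paired ROI 1 vs ROI 2 contrasts; **between** (single display,
each fish sees one stimulus) runs paired test-vs-baseline within each group
and an independent, pooled-variance contrast of the two groups' stimulus-ROI
Δs.

## Synthetic data

The trajectory generator is a correlated random walk: the new heading is a
von Mises draw (concentration κ, default 4) around the direction of
`previous-heading-unit-vector + λ · inward-normal-of-the-target-wall`, where
λ is the attraction weight (0 = no stimulus); step length is a normal speed
draw (4 ± 1.5 cm/s, truncated at 0) divided by the frame rate; walls reflect
elastically; a two-state Markov chain (off by default) produces freeze
episodes with near-zero displacement to exercise the frozen-exclusion rule;
frames drop to missing with probability 0.01. Cohort simulations prepend a
5-minute unrecorded habituation segment before the baseline, mirroring the
assay procedure; without it the walk's initial transient biases baseline
against test period and inflates the type-I error of the Δ comparisons
(measured: 0.09 instead of 0.05). The default speed/concentration values
were chosen once as plausible adult-zebrafish swimming parameters; they are
not fitted to data. The generator reproduces the assay's structural features
(two-choice geometry, binning, missing frames, freezing) but not real fish
behaviour — thigmotaxis, burst-glide gaits, social context — so passing
tests certify the pipeline's correctness and calibration, not any biological
claim.

The renderer paints a teardrop (disks along the body axis with the radius
peak forward of center) at each pose, plus Gaussian pixel noise, and returns
the silhouette's exact center of mass and nominal head/tail/heading for
tracker scoring. The point-light generator double-sums a blockwise
acceleration waveform — blocks of `+base·(1+κ)` alternate with
`−base·(1−κ)`, lengths balanced so velocity stays bounded — so the central
second difference recovers the prescribed magnitudes exactly and the
up/down acceleration asymmetry of the output is known by construction
(`base_acc` default 600 a.u./s², the scale of recorded fish sequences).

## Parameter recovery

No closed form links λ to the per-fish Δtime% effect size, so
`calibrate_attraction` maps it empirically: a pilot grid
(λ ∈ {0.02…0.2}, 2500 fish each) yields Cohen's d of the ROI-1 Δtime%
distribution per λ, the target d is interpolated, and two Newton-style
refinement passes — using the slope of the grid interval bracketing the
target and progressively larger batches — shrink the interpolation and
Monte-Carlo error to about ±0.015 in d.
`recovery_experiment` then simulates cohorts of 24 fish, runs the preference
pipeline and the normality-gated paired comparison on each, and reports
rejection rates: the type-I error at λ = 0 (nominal 0.05) and the power at
the calibrated λ, which is compared against the closed-form noncentral-t
power of a paired t-test at d = 0.5, n = 24 (≈ 0.65). Problem sizes (2000
null datasets for the permutation calibration; 500 null and 500 effect
cohorts for recovery; 100 rendered poses for tracking) were chosen to keep
Monte-Carlo standard errors a few times smaller than the corresponding
acceptance tolerances.

## Known limitations

* The tracker handles a single fish on a clean background; reflections
  larger than the fish, occlusions and multi-fish scenes are out of scope.
* The head/tail rule needs visible front-heaviness or temporal context; a
  perfectly symmetric blob with no history resolves arbitrarily.
* The swim simulator's stationary spatial distribution is only approximately
  uniform; cohort-level guarantees are calibrated (via the habituation
  burn-in), not analytic.
* Gravity-signature magnitudes depend on the differencing scheme and any
  smoothing applied to the source coordinates; cross-dataset comparisons
  should fix both.
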