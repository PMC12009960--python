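# Methods

## Coordinate frame and geometry

All positions are device coordinates in micrometres: x runs along the
microchannel axis, increasing from the forward to the reverse chamber;
the barrier occupies `[0, 1000]` µm by default (the chambers are 1 mm
apart), so retrograde motion has dx/dt < 0.  Images are placed by an
`offset` and a `pixel_size` calibration; pixel `(i, j)` is centred at
`offset + (j + 0.5, i + 0.5) · pixel_size`.  The magnification
calibration is configuration, never hard-coded: 0.325 µm/px (20×
objective, 6.5 µm camera pixels) is the conventional default, and most of
the test suite and the acceptance script run at 0.65 µm/px so fields stay
small.

ROI bands are closed distance intervals from the barrier edge on one
chamber side: `[400, 1600]` µm for the main chamber quantification (the
central culture area) and `[0, 400]` µm for near-channel and CFSE
analyses, because forward-originating axons — and the CFSE signal they
carry — are sparse beyond 400 µm.

## Fragment detection

Each channel is binarised by a threshold: per-image Otsu by default, or a
manual level.  Threshold levels in this kind of assay are typically
optimised manually per dataset and do not transfer between setups, so
every applied level is logged and the manual path is a first-class
option; the synthetic-data workflows use manual levels
matched to the generator's intensity scale (pSyn 1200, tubulin 150, CFSE
150 counts) because Otsu is unreliable when the foreground occupies a
tiny pixel fraction.  The tubulin level sits just below the blurred peak
of the thinnest (1 px) rendered neurites; a higher level fragments their
mask and silently breaks colocalisation.

Connected components of the pSyn mask (8-connectivity by default, so
thin diagonal fragments stay intact) are kept iff

* the fraction of component pixels overlapping the βIII-tubulin mask,
  dilated by 1 px to absorb chromatic/registration offset, is ≥ 0.5
  (object-wise colocalisation), and
* the component area is ≥ 8 µm², converted to pixels by ceiling so that
  nothing below 8 µm² can pass; a component of exactly 8 µm² is kept
  (the exclusion applies to fragments *below* the cutoff).

Fragment length is the graph diameter of the morphological skeleton with
8-neighbour edges weighted 1 (axial) and √2 (diagonal) pixels; a
single-pixel fragment has length 0.  Because fragments are small, the
diameter is computed by all-pairs Dijkstra, which stays exact for
skeletons containing cycles.

CFSE classification is per fragment: positive iff ≥ 50% of its pixels
fall in the thresholded CFSE mask; fragments outside the `[0, 400]` µm
band are left `unevaluated`, since the linear CFSE decay reaches zero
there and positivity would be unmeasurable.

## Metrics and statistics

Per field, fragment area and count are scaled by `0.25 / ROI_area_mm²`
to the reported per-0.25 mm² units; pathology is alternatively expressed
as a percentage of the neurite mask area within the ROI (flagged NaN when
that area is zero).  Per chamber and device, each metric is aggregated as
the median of the field values after an iterative two-sided Grubbs test
(α = 0.05): the most extreme value is removed while
`G = max|xᵢ − x̄|/s` exceeds the critical value built from the Student-t
quantile at `α/(2n)`, stopping when nothing is flagged or the sample
would shrink below 7 values — a cap that, for the standard 10 fields per
chamber, limits removals to three.  Outlier sets are decided per metric,
so a field extreme in area still contributes its count.  Zero-variance
samples contain no outliers.

Time trends are ordinary least squares across device summaries (one
point per device), reported as slope, intercept, `F(1, n−2) =
(R²/(1−R²))(n−2)`, p and R²; no mixed-effects modelling is used.  Group
comparisons use the two-sided Mann-Whitney U test: exact enumeration for
small untied samples (n₁+n₂ ≤ 16), otherwise the tie- and
continuity-corrected normal approximation (both via scipy).  The
propagation ratio divides the unseeded-chamber pathology level by the
seeded-chamber level; devices whose seeded level is zero get NaN with a
warning rather than being silently dropped.

## Kymographs and puncta tracing

A kymograph is the per-frame maximum over a lane's width, excluding
pixels inside leaf polygons; a position whose lane pixels are all
excluded becomes NaN.  Trace detection separates moving from stationary
signal by per-position temporal median subtraction.  Moving puncta are
localised per frame as intensity-weighted centroids of thresholded runs
(a symmetric operation, which is what makes the mirror-reflection
property exact) and linked by greedy nearest-neighbour matching against a
constant-velocity prediction; when crossing puncta merge into one run, a
track left unmatched may share the claimed candidate, and track segments
split by a dropout are re-joined if one's fitted line extrapolates onto
the other's start with a consistent velocity.  Stationary puncta are
detected on the temporal-median profile itself and reported with speed 0.

The detection threshold is `max(k·σ, 0.2·peak)` with σ a robust (MAD)
noise scale and k = 8: the lane max-projection thickens the upper noise
tail to ~7σ extremes on a blank movie, so k = 5 would hallucinate
traces.  Tracks need ≥ 3 frames and survive ≤ 2 missed frames.

Speed is the least-squares slope of position on time (an optional
pause-exclusion pass drops steps slower than the stationary threshold
first, so the fitted speed reflects undisturbed runs).  |v| < 0.1 µm/s is
classified stationary, otherwise the sign decides retrograde (negative)
vs anterograde.  A barrier exit is an observed position reaching the
forward edge, or a trace that disappears within 15 µm of the field's
forward edge before the recording ends and whose fitted line reaches the
edge by the final frame — a spot sliding out of view drops below
threshold slightly before its centre crosses.

## Synthetic data generator

The generator renders what the analysis assumes, with recorded truth:

* **Neurites** — persistent random walks (4 µm steps, heading noise
  σ = 0.25 rad, lengths 100–500 µm) rasterised at 1–3 px width, plus soma
  disks; half the neurites are flagged forward-originating and enter from
  the barrier-side edge.
* **Pathology** — elongated segments (length 2–20 µm, width ~1 µm,
  intensity 3000) placed *on* neurite skeletons without overlap.  In
  `area` mode fragments are added until the filter-passing (≥ 8 µm²)
  truth area matches `max(0, 53.828·t − 137.706) · device_factor` per
  0.25 mm², with the final fragment stochastically rejected so the
  expectation is unbiased; `count` mode analogously targets
  `max(0, 12.941·t − 16.656)`.  The two default growth curves are
  mutually inconsistent with the 8 µm² exclusion (they would imply a mean
  fragment area below the cutoff), which is why they are alternative
  targets rather than jointly enforced.  Device-to-device scatter is a
  multiplicative log-normal factor with CV 30%.  Unseeded controls carry
  a constant background level of 35 µm²/0.25 mm².  Each image also gets
  sub-8 µm² on-neurite specks and soft-edged off-neurite blobs (low
  intensity, Gaussian profile) so both filters are exercised; truth
  records which is which.
* **Transfer** — a configurable fraction (default 20%) of pathology area
  is hosted on reverse-native neurites.  Host classes are drawn
  proportionally to each class's remaining area quota, so the realised
  split tracks the configured fraction instead of drifting binomially,
  and transferred placements that ride along a forward axon (> 25% of
  path pixels within 2 px of one) are rejected — such fragments would be
  ambiguous even in the real assay, and truth must be unambiguous.
* **CFSE** — intensity on forward-originating neurites only, decaying
  with barrier distance: linearly to zero at 400 µm by default
  ("proportional" decay), exponential as an alternative.
* **Movies** — Gaussian spots (σ 0.8 µm, amplitude 2000) at
  `x(t) = x₀ + v·t` with 0.2 µm localisation jitter, 5 s frames over
  10 min (121 frames) in a 10 µm lane; truth records per-frame positions,
  speed, direction and the barrier-exit time.
* **Noise** — Poisson shot noise on signal plus baseline (100 counts)
  and Gaussian read noise (σ = 8); a noise-free preset exists for
  exactness tests.

Determinism: every image derives from `SynthConfig.seed` through
`SeedSequence` children (per purpose, per device, per field), so
identical configurations are bit-identical and study generation is
order-independent.

What the generator does **not** emulate: 3D structure and optical PSFs
beyond Gaussian blur, intensity heterogeneity within fragments,
neurite fasciculation/bundling, soma-filling pathology, pathology
elongation/merging over time, and motor-driven pause/run dynamics of
puncta (pauses can be composed from multiple puncta specs but are not
generated by default).  Passing recovery tests therefore demonstrates
the correctness of the measurement chain under these idealised
conditions, not robustness to every artefact of real microscopy.

## Problem sizes

Synthetic studies in the tests and acceptance script use 332.8 µm fields
at 0.65 µm/px with 4 fields per chamber (8 for the CFSE study's devices,
matching that assay's n = 8); the slope-recovery study keeps the full
n = 69 devices spread uniformly over 2.9–12.6 weeks and the 30% device
CV.  These sizes preserve the statistical structure (device-level CV
dominates the regression, so the slope CI is driven by n and CV, not by
field size) while keeping each study's render-plus-analysis in the
tens-of-seconds range.

## Known limitations

* Otsu thresholding is offered but poorly suited to sparse-foreground
  fluorescence fields; quantitative runs should set audited manual
  levels.
* Fragment width appears among the originally optimised parameters but
  no width-filter rule is published; no width filter is applied.
* Whether the original Grubbs exclusion was single-pass or iterative is
  unstated; both are available (`iterative=True` default).
* Crossing-puncta resolution relies on velocity prediction; puncta with
  near-identical speeds that merge for many frames can swap identities.
* The CFSE assay's sensitivity vanishes as the decay approaches zero at
  400 µm; fragments beyond the band are deliberately left unevaluated.
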