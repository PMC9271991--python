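# Methods

`mesotrack` reconstructs the fine-scale movement of a small nocturnal
ground-dwelling arthropod (its design case is an earwig carrying a ~1 mm
retro-reflective tag) from fixed-camera infrared video of a 1 × 1 m arena
filmed at 1 frame per second, and compares movement between two ground
types: bare soil and soil partly covered with plant-residue units under
which the animal can hide. This note documents the models, the defaults and
their units, the numerical choices, and what the synthetic tests do and do
not establish.

## Video treatments

Frames are 8-bit grayscale. Within every window of `preprocess.window_s`
seconds (default 1800 s = 30 min; a shorter final window is treated on its
own) two subtractions are applied:

1. **Stationary background**: the per-pixel temporal *median* over the
   window is subtracted from each frame, clamped at zero. The median is
   robust to the tag passing through a pixel, so the moving tag survives
   while the static scene does not.
2. **Residual noise**: the per-pixel temporal *mean* of the
   background-subtracted window is subtracted in turn, clamped at zero. A
   pixel that flickers persistently accumulates a large mean and is
   suppressed; a transient present in one frame of an *n*-frame window loses
   at most 1/*n* of its amplitude. The rescaling of the accumulated sum by
   the window length keeps the noise image in intensity units; the divisor
   is configurable (`divisor="none"` keeps the raw sum).

Both treatments are computed on float promotions of the integer frames;
re-quantization to 8 bits happens only when frames are written. The
residual-noise image is computed from the background-subtracted frames (not
the raw ones), which matches its interpretation as *residual* dark-gray
noise left by the first treatment.

## Detection and linking

The tag is detected as a bright blob of nominal diameter 3 px with a
difference-of-Gaussians filter, σ₁ = d/(2√2) and σ₂ = √2·σ₁ — the standard
two-scale convention for a target of diameter d. Local maxima of the DoG
response above `detector.quality_threshold` (default 15, on the 0–255
intensity scale) are emitted; sub-pixel positions come from independent 1-D
quadratic peak interpolation in x and y (clamped to ±0.5 px). Flat-plateau
ties are broken deterministically: only the first tied pixel in row-major
order emits. The quality scale is this package's raw DoG response; other
trackers normalize differently, so the threshold should be re-calibrated
when porting settings.

Linking is the linear-assignment recipe: consecutive frames are matched by
the Hungarian algorithm on squared displacement, gated at `linker.d_g_px`
(default 30 px ≈ 4.3 cm); afterwards track ends are joined to later track
starts (gap closing) when the silent interval is ≤ `linker.t_g_s` (default
5 s) and the jump ≤ d_g, resolving competing candidates by smallest time
difference, then smallest distance, then lowest track index. The
implementation is single-hypothesis: no merging, splitting or appearance
model.

## Cleaning

Tracks that overlap in time within one recording are conflicts — residual
noise or a second animal. Rules, in order, per conflicting pair:

* if the two tracks come within 5 cm of each other while simultaneous
  (`cleaning.mutual_delete_cm`, converted through the calibration:
  5 × 6.82 = 34.1 px), identity is ambiguous and both overlapping portions
  are dropped;
* overlaps of at most `cleaning.max_auto_points` seconds (default 10): the
  track with fewer total points is presumed noise and loses its overlapping
  points;
* anything larger is written to a review file and execution halts until the
  offending trajectory ids are listed in `cleaning.exclusion_list` — the
  deliberate stand-in for visual inspection, which keeps the decision
  explicit and reproducible instead of interactive.

## Junction, edge removal, interpolation, rediscretization

After cleaning, trajectories are rebuilt with less restrictive junction
gates (`junction.d_g_px` = 50 px ≈ 7.3 cm, `junction.t_g_s` per procedure):
fragments are merged chronologically whenever a fragment starts within t_g
seconds and d_g pixels of another's end, nearest-in-time first. Points
within `arena.edge_buffer_px` (default 35 px ≈ 5.1 cm) of the border are
then removed — always *after* junction; the two operations do not commute —
splitting trajectories at the removed runs.

A **procedure** is the triple (junction time gap t_g ∈ {10, 30, 60, 300} s,
rediscretization step τ ∈ {1, 5, 10, 20, 30, 40, 50, 60} s, interpolation
on/off). Interpolation fills every missing second between a trajectory's
endpoints linearly (never extrapolating) and flags the filled points.
Rediscretization cuts segments of exactly τ seconds:

* **without interpolation** a re-anchoring walk over the observed points is
  used: if a point exists exactly τ s after the current anchor, the segment
  is emitted and the anchor moves there; otherwise the anchor advances to
  the next observed point. This maximizes usable segments among successive
  direct observations. The text sources this package follows leave a
  fixed-absolute-grid reading open; that variant is available as
  `grid_mode="fixed"` but is not the default.
* **with interpolation** the gap-free trajectory is tiled at t₀, t₀+τ, …;
  segments covering any interpolated point are flagged so statistics can
  stratify by provenance.

Distances are segment lengths in px; speeds are distance/(τ · px_per_cm)
with the calibration `arena.px_per_cm` = 6.82 px/cm. Turning angles are
signed heading changes between segments sharing their vertex in time,
computed in a y-up frame (image y negated) so positive = left turn, wrapped
to (−π, π] with exact reversals mapped to +π (deterministic tie-break).
Segment pairs separated by skipped seconds yield no angle, and zero-length
segments (undefined heading) skip the pair with a counter. Turning angles
are only computed for procedures without interpolation, because interpolated
runs are exactly collinear and would fabricate zero turns.

## Activity metrics

Per individual and night, from all cleaned (pre-edge-removal) points:
*apparent intensity of activity* = number of distinct seconds with a
detection; *estimated intensity* = number of distinct clock minutes
(60-s bins aligned to the recording origin) containing at least one such
second; *total activity period* = seconds between first and last detection.

## Statistics

**Speed.** For each eligible procedure, √(distance_px) is modelled with a
linear mixed model: ground type as fixed effect, a random intercept per
individual, REML. The square root stabilizes the right-skewed distances.
Predicted per-ground-type distances are the squared predicted means of
√distance — no smearing correction, a deliberate bias-aware choice so the
reported ratio is the ratio of predicted distances; at fixed τ it equals the
speed ratio. The Powell optimizer is used first: with a near-zero random
intercept variance the default gradient optimizers can stall at the boundary
far from the optimum, while Powell reaches it reliably; a gradient fit is a
fallback. Eligibility requires ≥ `stats.min_individuals` (10) individuals
with ≥ `stats.min_records` (10) values per ground type, data-poor
individuals being dropped first.

**Sinuosity.** Per-individual concentration is the mean resultant length
R̄ = |mean e^{iθ}| of the turning angles (1 − circular variance; low =
sinuous). Ground types are compared with the Wallraff dispersion procedure:
each ground type's mean direction is estimated on its pooled angles, every
angle's circular distance π − |π − |θ − μ̂|| to its group's mean direction is
ranked across both groups, and the tie-corrected Kruskal–Wallis H between
ground types is the statistic (cross-checked against `scipy.stats.kruskal`).
Pooling per ground type (rather than per individual) is the default because
the null hypothesis re-estimates the nuisance mean directions; the
per-individual variant is available (`pool="individual"`). Significance
comes from a randomization test permuting whole individuals between ground
types (group sizes preserved, mean directions re-estimated every
permutation), which respects unequal angle counts per individual;
p = (1 + #{perm ≥ obs}) / (1 + n_perm), the add-one correction avoiding
p = 0. When fewer distinct label permutations exist than requested the
permutations are sampled with replacement and a warning is issued.

Angle procedures fix the junction gap at 10 s: without interpolation the
junction gap does not change which angles exist, so testing one gap avoids
redundant rows. The grid report always contains 64 distance rows and 8
angle rows; ineligible procedures are reported as such with their counts.
No multiple-testing correction is applied across the grid; rows are
reported as-is.

## Synthetic mesocosm

The generator supplies ground truth with the statistical structure the
analysis assumes, so every stage is testable without the original
recordings.

* **Movement**: a correlated random walk at one step per second. Step
  lengths are exponential (positive, realistically variable, one
  parameter); the per-ground-type means default to the study's estimates,
  0.85 cm/s on bare soil and 0.36 cm/s on residues. Turning angles are
  wrapped normal parameterized directly by the target mean resultant length
  ρ via σ = √(−2 ln ρ) — a monotone one-parameter control of the
  concentration metric — with defaults 0.77 (bare soil) and 0.40
  (residues). Walls reflect specularly (the walk is computed unbounded and
  folded into the arena), so edges do not absorb; edge effects are then
  removed downstream like in real data.
* **Concealment**: each second spent inside a residue unit starts a
  concealment bout with probability 0.3; bout durations are geometric with
  mean 60 s, truncated when the walker leaves the unit. The study reports
  no per-event concealment durations, only that junctions up to 5 min
  matter, so these two values are free choices on that order of magnitude.
  Movement is unchanged while concealed — concealment is purely
  observational (missing detections), which is the one mechanism the
  trajectory operations are designed to absorb.
* **Residue layout**: square 3 × 3 cm units on an even grid, default 6 cm
  center-to-center pitch (≈25% cover) with free space between units.
* **Rendering**: one 8-bit frame per second; a static smoothed Gaussian
  random-field texture (mean 40, sd 10 gray levels), a Gaussian tag blob
  (sd 1.5 px ≈ 3 px diameter) added at the position of every non-concealed
  second, and independent per-frame Gaussian pixel noise (sd 5). The tag
  peak defaults to 150 gray levels above background: a retro-reflective tag
  under infrared illumination is by far the brightest object in the scene,
  and this peak puts the DoG response (≈24) safely above the default
  quality threshold of 15, mirroring the high-contrast imaging the method
  presumes.

What the generator does **not** emulate: anisotropic or drifting
illumination, substrate micro-movements, multi-animal interactions, tag
occlusion by the animal's own posture, lens distortion (the calibration is
a single scalar), or diurnal light cycling. Passing the synthetic recovery
tests therefore shows the chain is correct and well-calibrated under the
stated noise model, not that the detector settings transfer to arbitrary
field footage.

## Validation experiments and problem sizes

`mesotrack.experiments` packages three end-to-end checks, used by the test
suite and `scripts/acceptance.py`:

* **Speed-ratio recovery**: 10 individuals per ground type are simulated at
  the default movement parameters (true ratio 0.85/0.36 ≈ 2.36), rendered
  at full arena resolution (682 × 682 px), tracked, cleaned, rebuilt
  (junction 10 s / 50 px), rediscretized at τ = 1 s and fed to the mixed
  model. Recordings of 10–15 min per individual are used — the recovered
  ratio is a ratio of per-second step means and does not depend on
  recording length, which only shrinks its Monte-Carlo error; at these
  sizes the estimate sits well within ±15% of the truth. τ = 1 s is used
  because at the step scale the expected displacement ratio equals the
  speed ratio exactly, whereas longer τ confound it with the sinuosity
  contrast.
* **Type-I error**: 200 datasets of two exchangeable groups (8 individuals
  × 60 angles each, ρ = 0.6), randomization test with 500 permutations;
  the empirical size at α = 0.05 is ~0.04–0.05.
* **Power**: 100 datasets at the study contrast (ρ 0.77 vs 0.40, 8
  individuals × 100 angles, 1000 permutations); rejection is essentially
  certain.

## Degenerate inputs and numerical conventions

Coordinates are 0-based with the origin at the top-left pixel center, x
rightward, y downward; sub-pixel positions are real-valued. ρ = 0 and ρ = 1
map to the uniform distribution and the point mass. Trajectories shorter
than τ + 1 s rediscretize to an empty segment list (not an error). Empty
angle sets make `concentration` raise. A procedure whose model cannot be
fit records its error message in its grid row without aborting the grid.
All randomness flows from explicit seeds (`numpy.random.SeedSequence`
spawning per individual / per dataset); identical seeds give bit-identical
outputs, recorded in a run manifest together with package versions.

## Known limitations

* TrackMate-style quality normalization is not reproduced; thresholds are
  comparable only within this package.
* The manual/visual part of trajectory cleaning is replaced by the
  review-file + exclusion-list mechanism; borderline multi-animal scenes
  still require a human decision, just an explicit one.
* The mixed model's back-transform by squaring the predicted mean of
  √distance is biased low for the mean distance; ratios are far less
  affected, and the choice keeps the reported quantity interpretable.
* Video codecs are out of scope: stacks are multi-page TIFF or PNG
  sequences.
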