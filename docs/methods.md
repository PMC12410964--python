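# Methods

## Coordinate conventions

All positions are 0-based pixel coordinates in the image convention:
origin at the top-left of the (cropped) frame, y increasing downward.
Every rectangle — crop cells and chambers alike — is half-open,
`[min, max)`, so adjacent crop cells never share a pixel and a point on
the far edge of a chamber is outside it. Distances are reported in pixels
(the native unit of the tracking tables); millimetre conversion is applied
only where a `mm_per_px` scale is configured.

## Crop-grid computation

The camera frame is divided into `rows × cols` cells after subtracting
outer margins and inter-chamber gaps. Integer cell widths within a row
differ by at most one pixel; remainder pixels are assigned to the
lowest-index rows/columns, deterministically, so the same layout always
produces the same manifest. With zero margins and gaps the cells tile the
frame exactly (tested property).

## Misdetection control

Trackers occasionally report the fly outside its chamber, almost always
with low confidence. Cleaning proceeds in three steps:

1. **Chamber limits.** Unless geometry is supplied, the chamber rectangle
   is inferred as the per-axis `[Q(0.001) − 2 px, Q(0.999) + 2 px]` span of
   the detections at or above the likelihood floor (default 0.9). The
   quantiles tolerate rare confident strays; the likelihood floor removes
   the bulk of misdetections before the quantiles see them. Inference
   requires ≥ 100 confident detections and ≥ 5 px extent per axis;
   otherwise it raises and the caller must supply geometry.
2. **Flagging.** A frame is flagged when its position is outside the
   chamber, its likelihood is below the floor, or its coordinates are
   missing. Setting the floor to 0 disables confidence filtering.
3. **Interpolation.** Every frame of a flagged run receives the unweighted
   coordinate-wise midpoint of the nearest preceding and following
   unflagged detections. This is deliberate: a run of k flagged frames
   becomes a constant-position segment contributing exactly zero distance,
   biasing activity conservatively rather than inventing motion. Leading
   and trailing runs copy the nearest unflagged position. Time-weighted
   linear interpolation is available (`mode="linear"`) for users who
   prefer to spread the displacement across the gap; midpoint is the
   default because downstream crossing counts should not be generated by
   imputed motion.

Cleaning is idempotent, never touches unflagged frames, and its output is
verified against a brute-force flanking-scan reference on random
contaminated series.

## Activity metrics

**Binned distance.** Frame-to-frame Euclidean distances; the interval
between frames *i* and *i+1* belongs to the bin containing frame *i*'s
timestamp; the incomplete trailing bin is dropped, making the binned sum
exactly equal to the trajectory distance over complete bins (tested at 1,
10, 30 and 60-min widths). Gaps in the frame index contribute the
straight-line distance across the gap. Bins are anchored at recording
start; the average day re-anchors at ZT0.

**Virtual beam.** The long axis of the chamber is the longer dimension
unless configured; the beam sits at the configured midline (default: the
long-axis centre). Each frame holds a side (−1/+1); a frame exactly on the
midline keeps the previously held side (hysteresis), and −1 when no side
was ever held, so grazing the beam cannot register a crossing. A crossing
completes whenever the held side changes between consecutive frames.
Because interpolated runs are constant-position, they can produce
crossings only at their boundaries. An alternative band-occupancy counter
(frames within ± w px of the midline) is provided for comparison but the
crossing count is the primary statistic. The count is invariant to
reflecting or uniformly rescaling the long axis (tested properties).

**Sleep.** The operational definition inherited from beam-monitor
studies: every maximal beam-quiescent interval of ≥ 300 s — including the
recording edges — is one sleep bout spanning the whole interval. Sleep per
time bin is the overlap of bouts with the bin, in minutes. Note the caveat
that motivates video tracking in the first place: a fly feeding or
egg-laying away from the midline is beam-quiescent but not asleep, so
beam-defined sleep overstates sleep in food-proximate animals. The package
computes the statistic; interpreting it is the user's responsibility.

**Average day.** Requires an integer number of bins per 24 h and at least
`n_full_days` complete cycles from the first ZT0-aligned bin; the profile
is the per-ZT-bin mean across those days.

## Group statistics

Day/night totals sum a fly's bin values over complete 12 h phases; phases
not fully covered by the recording are excluded. Group comparisons use the
Welch (unequal-variance) two-sided t-test by default — group sizes and
variances in these assays are rarely matched — with the pooled-variance
test available via `equal_var=True`. Hour-by-hour comparisons of average
days use two-sided Mann–Whitney U tests (asymptotic, tie-corrected; an
all-tied hour is assigned p = 1), with discoveries declared by
Benjamini–Hochberg FDR at q = 0.05 across the 24 hours; the two-stage
Benjamini–Krieger–Yekutieli procedure is available via
`method="fdr_tsbky"`. For each discovered hour the group with the higher
median is recorded. Statistics are degenerate — and raise — below two
flies per group or with zero variance in both groups.

Occupancy analyses (heatmap, longitudinal preference histogram) use the
cleaned positions, so interpolated frames count at their interpolated
position, matching the pipeline order; a flag excludes them. The
preference histogram divides the long axis into 10 equal bins (~5 mm in
the standard 50 mm chamber); "the bin closest to a food" is the bin
abutting the chamber wall nearest that food region, and per-fly occupancy
fractions in those bins are compared across groups with Welch t-tests
(per-fly fractions, not pooled frames, so the test's unit matches the
biological replicate).

## The synthetic generator

The simulator emulates what the camera-plus-tracker stack produces, so the
pipeline can be validated against known ground truth. The behavioural
model is a two-state Markov walker: at rest the position is fixed; the fly
enters a move bout with per-frame probability
`r(t) = base_rate(phase) × startle(t) × siesta(t)` and leaves it with
probability `move_exit_rate`. While moving it takes half-normal steps
(scale `step_scale` px) with a diffusing heading (`turn_sd` rad),
optionally redrawn toward a food wall with probability `food_bias`, and
reflects off the chamber walls. Misdetections replace the reported
position with a uniform point in a 20 px band outside the chamber at
likelihood U(0, 0.5); genuine detections carry likelihood U(0.95, 1).

Defaults model a virgin female under 12:12 LD at 5 fps in a 23 × 15 mm
chamber (0.1 mm/px): day entry rate 0.01/frame, night 0.005, exit rate
0.3 (bouts of ~3 frames), step scale 5 px (~2.5 mm/s while moving —
ordinary walking speed), startle ×3 for 10 min after each light switch,
siesta ×0.5 over ZT5–9, misdetection rate 0.002. Scenario constructors in
`flybeam.scenarios` define the validation conditions: a night-shifted
cohort (night rate exactly twice day rate — note the realised distance
ratio is slightly below 2 because move-state occupancy is `r/(r+exit)`,
and slightly perturbed by the asymmetric count of startle windows), an
arrhythmic constant-rate cohort in DD, and a two-food preference pair
(`food_bias` 0.6 vs 0.0, target yeast).

Per-fly randomness derives from
`SeedSequence((master_seed, group_index, fly_index))`, stable across runs
and versions; the same seed yields bit-identical tracking tables.

What the generator does **not** emulate: wall-following and thigmotaxis,
inter-fly behavioural heterogeneity beyond seed variation, tracking jitter
on genuine detections, likelihood drift, grooming/feeding micromovements,
or egg laying. Passing the validation suite therefore shows the *analysis*
is correct and sensitive under realistic magnitudes — it does not certify
any biological claim about real flies.

## Problem sizes for validation

The validation suite and `scripts/acceptance.py` run the locomotion
scenarios at n = 16 flies × 3 days (the cohort size used for locomotion
comparisons) and the preference scenario at n = 12 + 12 flies per
replicate with 30-minute recordings — a deliberate scale-down of the
multi-day assay chosen so that per-fly occupancy fractions are estimated
tightly enough for the designed effect (0.6 vs 0.0 bias) to be essentially
always detectable, while replicated null experiments keep the test's
false-positive rate at its nominal 5%. Oracle checks use 100 random
series/walks each; FDR behaviour is characterised over hundreds of
simulated null and shifted experiments with hourly values drawn N(0, 1)
per fly, since the screen operates on arbitrary per-hour summaries.

## Numerical and degenerate-input choices

- Quantiles use numpy's default (linear interpolation) definition.
- Bin counts are `floor(duration / bin)`; a recording shorter than one bin
  yields an empty binned series rather than an error.
- `phase_at` intervals are half-open; ZT is periodic with period 24 h.
- Fewer than two frames yields empty distances; an all-flagged series
  raises rather than fabricating a trajectory.
- Occupancy normalisation is exact to 1e-9 by construction (counts divided
  by the frame total).
- A fly whose final-day activity is exactly zero can optionally be flagged
  as dead and excluded from group aggregates; this is off by default.

## Known limitations

- The cleaning rule cannot recover genuine excursions mislabelled as
  misdetections: a real position outside the inferred rectangle (e.g. the
  pad is too tight) is replaced like any other flagged frame.
- Beam-crossing counts at 5 fps undercount very fast midline traffic
  (multiple crossings within 200 ms collapse to at most one per frame
  transition).
- The average day assumes the schedule's ZT0 is commensurate with the bin
  grid; off-grid ZT0 values raise rather than resampling.
- No rhythmicity statistics (periodograms) and no multi-animal tracking
  dialects; one fly per chamber is assumed throughout.
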