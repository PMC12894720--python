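# Methods

## Data model

A *chronogram* is a cohort of oocytes, each carrying the sperm observed in
its perivitelline space (PVS). Every event is a closed `TimeWindow` in
minutes post-insemination: a degenerate window (zero width) is a directly
observed time, anything wider is interval censoring from the observation
process. The default horizon is 240 min (a 4 h recording); windows are
clipped to `[0, horizon]`. An oocyte's fate is derived, never stored:
fertilized iff at least one sperm fused, penetrated-unfertilized iff sperm
entered but none fused, unpenetrated otherwise.

Sperm of a fertilized oocyte are displayed in four categories relative to
the *first fertilizing sperm* (the fused sperm with the smallest
fusion-window lower bound; ties broken by sperm id — a deterministic
convention, since nothing in the data distinguishes simultaneous lower
bounds): fused sperm are `fertilizing`; a non-fused sperm is
`pre_fertilization` if its penetration window certainly precedes the
reference sperm's penetration window (upper ≤ that lower),
`post_fertilization` if it certainly follows the reference fusion window,
and `ambiguous` otherwise. Only certain (window-level) ordering is used
here; probabilistic ordering is delegated to the realization engine below.
Boundary equality counts as certain: the windows are closed and the overlap
is a single point of measure zero.

## Fusion-window refinement from landmarks

Fusion triggers a stereotyped sequence whose delays were calibrated as
mean ± SD: head disappearance 24 ± 3 min, PB2 protrusion onset 28 ± 2 min,
PB2 contact-angle crossover (90°) 49 ± 6 min, PB2 extrusion complete
73 ± 10 min. Taking mean + SD as the latest and mean − SD as the earliest
plausible delay turns the stage observed at time t_obs into an interval for
the fusion time t_F:

| observed state | window for t_F |
|---|---|
| still motile, unfused | [t_obs, horizon] |
| arrest seen live | [t_obs − 1, t_obs + 1] |
| fused, head still visible | [t_obs − 27, t_obs] |
| flagellum only | [0, t_obs − 21] |
| PB2 protruding, angle > 90° | [t_obs − 55, t_obs − 26] |
| PB2 extracting, angle < 90° | [t_obs − 83, t_obs − 43] |
| PB2 complete | [0, t_obs − 63] |

The refined fusion window is the intersection over all observation rounds,
further bounded below by the penetration window's lower bound. For a rule
anchored at a round, t_obs is the round midpoint: rounds last up to
~10 min and no anchor within the round is canonically right, so the
midpoint minimizes the worst-case anchor error. One-sided rules are closed
by clipping at 0 and the horizon. Correctly identified states always yield
a non-empty intersection; an empty one raises an error naming the
conflicting rounds rather than guessing. A live arrest contributes its ±1
min window and is intersected with the landmark windows like any other
round.

## Uniform-within-window realization and count curves

Within its window each event time is imputed uniformly — the censoring
mechanism (which round you happened to be on) carries no information about
where in the gap the event fell. For a fused sperm whose fusion window
overlaps its penetration window, the pair is uniform on the part of the
window rectangle with fusion ≥ penetration (sampled by rejection from the
product uniform; the constrained region has positive measure whenever the
record is valid, otherwise a data error is raised first).

Cumulative count curves (penetrations, extra fusions, or PVS occupancy =
penetrants not yet fused) are computed per realization on a 1-min grid —
matching the minute-scale resolution of the observations — relative to the
alignment event (first fusion, first penetration, or absolute time). The
alignment time is realized per draw, so its uncertainty propagates into the
curve. When aligning to the first fusion and counting penetrations or
fusions, events at or before the alignment are excluded (the curves
describe what happens after fertilization; for fusions this drops the
fertilizing fusion itself). Means are taken over oocytes, then over
realizations (R = 1000 by default).

The 95% band is a 2.5/97.5 percentile bootstrap over oocytes (B = 1000 by
default), with the window realizations shared across resamples. This
captures both between-oocyte sampling variation and within-window
uncertainty; resampling only realizations would ignore the cohort size,
resampling only oocytes at fixed imputations would ignore the censoring.
The bootstrap curves are kept on the `CountCurve`, so model fits can
propagate the same uncertainty by refitting each resample curve.

## Block-model fits

* Penetration block: unweighted least squares of f(t) = A(1 − e^(−t/τ_PB))
  on the mean curve, multistart over τ ∈ {5, 15, 50, 150} min with A
  initialized at the curve plateau. Grid points are strongly
  autocorrelated, so per-point weighting would be arbitrary; uncertainty
  comes from bootstrap refits instead. The implied initial penetration rate
  is the analytic derivative at zero, A/τ_PB, reported per hour. A curve
  that is identically zero returns A = 0 with τ flagged unidentified.
* Fusion block: the amplitude (extra fusions per fertilized oocyte) is a
  directly observed count ratio, so it is held fixed and only τ_FB is
  fitted. A fitted τ below the grid step is flagged as a boundary estimate
  (indistinguishable from an instantaneous step at the data's resolution).
* Constant-rate baseline (unfertilized cohort): least-squares slope through
  the origin, per hour.

## Mechanistic simulator

Per oocyte, candidate ZP crossings are a homogeneous Poisson process at λ₀
(default 1.21 sperm/oocyte/h). Each penetrant at P draws a delay D and
attempts fusion at P + D; the chronologically first attempt succeeds and
defines the fertilization time T1. After T1:

* entries are thinned with probability e^(−(t−T1)/τ_PB) — chosen because
  the expected cumulative post-T1 count is then exactly
  λ₀τ_PB(1 − e^(−Δt/τ_PB)), the penetration-block model;
* a later attempt at time A succeeds with probability e^(−(A−T1)/τ_FB) and
  a failed sperm never re-attempts — chosen because the extra-fusion event
  rate then decays as e^(−Δt/τ_FB), the fusion-block model. A
  single-attempt mechanism is one consistent choice among several (e.g. a
  persistent attempt hazard); the data constrain only the decay of the
  realized extra-fusion rate.

Either time constant may be infinite (block disabled). Delays default to a
gamma distribution moment-matched to 15.8 ± 5.7 min — positive support and
two free moments; lognormal, exponential and fixed are available. The
15.8 ± 5.7 spread is treated as the between-sperm SD of the delay (not the
uncertainty of its mean); this is configurable. Scenario toggles transform
the parameters (τ_FB→∞, τ_PB→∞, λ₀×3, delay mean and SD ×0.5) and rerun the
cohort. Reproducibility: one master seed, per-oocyte substreams spawned by
counter-based splitting, so results are independent of iteration order,
and the fixed draw order (entries, delays, thinning, attempts) couples
scenarios that share a seed.

## Synthetic observation process

Observation schedules are drawn independently per oocyte: round lengths
uniform on 0.5–10 min, inter-round gaps uniform on 3–70 min ("a few
minutes to more than an hour"), until the horizon. Real sessions
interleaved ~5 oocytes, which couples their schedules; that session-level
coupling is not modelled. A penetration during a round is dated exactly;
between rounds it is bracketed by the gap; after the last round it is
censored out. Fused sperm get landmark times fusion + delay with delays
drawn as independent normals **truncated to mean ± 1 SD** and redrawn if
their ordering inverts. The truncation matters: the refinement rules span
exactly mean ± SD, so heavier-tailed landmark draws would produce states
whose windows exclude the true fusion time — whereas the empirical
observation behind the rules is that all per-oocyte windows overlap. The
truncation breadth is configurable (`truncate_sd`) for studying that
failure mode deliberately. Consequently, passing containment tests show
the censoring/refinement arithmetic is exact *given* states consistent
with the rule calibration; they say nothing about misclassified states or
landmark outliers in real recordings.

## Parameter recovery

`recovery_experiment` generates a cohort, censors it, estimates curves,
fits the blocks and reports bias/spread/CI coverage per replicate. At the
default kinetics with 57-oocyte cohorts the pipeline recovers τ_PB with
small upward bias (a few minutes — window imputation smears the aligned
curve) and well-calibrated bootstrap CIs (coverage ≥ 0.9 over 100
replicates). τ_FB is estimated from ~3 extra fusions per cohort, so its
point estimate is strongly biased upward at this size (fusion windows are
2–5× wider than τ_FB itself) and only its wide CIs are meaningful. The
pooled delay mean is biased ~2 min high for the same reason; its narrow
CI under-covers, so treat it as descriptive. Recovery runs use R = 300
realizations and B = 300 bootstrap resamples per replicate — the
estimates stabilize well below that, and the defaults (R = B = 1000)
change nothing but runtime at this cohort size.

## Numerical choices and degenerate inputs

* Grid step 1 min; events are binned by ceiling, so the count at grid time
  t is the number of events with Δt ≤ t.
* Percentile bands are clipped to contain the point estimate (relevant
  only in degenerate no-randomness cases, where low = mean = high).
* Rejection sampling of constrained pairs is batched with a hard iteration
  cap as a safety net; the cap is unreachable for valid records.
* Ties: simultaneous first-fusion lower bounds resolve by sperm id;
  simultaneous fusion attempts (measure zero) both succeed.
* Empty chronograms, missing alignment events, unfertilized oocytes passed
  to fertilization-aligned estimators, and amplitude ≤ 0 all raise typed
  errors rather than returning NaN curves.

## Known limitations

* The uniform-imputation estimator is not a maximum-likelihood
  interval-censored survival fit; with strongly informative censoring the
  two differ. Here censoring is by design non-informative.
* Fits are least squares on autocorrelated mean curves; their RSS is not a
  goodness-of-fit statistic across models.
* The simulator has no spatial or mechanical structure (flagellar beating
  phases, ZP traversal mechanics, molecular CD9/JUNO dynamics) and a
  single-attempt fusion mechanism; only the realized event kinetics are
  claimed to match.
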