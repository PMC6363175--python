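# Methods

This note documents the models and procedures implemented in `cvaffect`, the
assumptions behind them, the synthetic data they are validated on, and the
numerical choices that were genuinely open.

## Problem setting

Human coders can rate the positive and negative affect intensity of a facial
expression on 1–7 Likert scales with high inter-rater reliability, but manual
coding does not scale. Automated AU (action unit) detectors emit, for every
video frame, a signed evidence score per AU (here treated as spanning roughly
−16 to +16). The pipeline asks: given only per-frame AU evidence, how well can
a model reproduce the coder panel's intensity ratings, and which AUs (and AU
pairs) carry the information?

## Featurization

Each recording's per-AU evidence series is reduced to a **normalized AUC**:
the trapezoidal integral of evidence over every maximal run of consecutive
face-detected frames, summed and divided by the total face-detected time.
This is a time-weighted average of signed evidence, invariant to how much of
the clip had a detectable face, and bounded by the detected-frame evidence
range. Runs of a single frame span zero time and are dropped from numerator
and denominator. Evidence is kept signed; no probability transform is applied
(the detector's evidence scale is not a probability, so we deliberately treat
the point estimate as a mean evidence level), and no per-subject baseline
correction is used, so the model applies to novel recordings without any
human annotation.

**Quality filter.** A recording is excluded when its longest contiguous
face-undetected span lasts ≥ 1 s. Span duration is measured from timestamps:
each frame occupies the interval up to the next frame's timestamp (the
terminal frame is assigned the median inter-frame interval), so a 30-frame gap
at 30 Hz is exactly 1.0 s and is excluded; the comparison uses a 1 ns
tolerance so exact ties survive float timestamp arithmetic. If ≥ 50% of a
participant's recordings are excluded, all of that participant's recordings
are dropped (ties at exactly 50% trigger exclusion).

## Rating model

The outcome is the arithmetic mean of the coder panel's ratings per recording
(per-coder models use one coder's own ratings). The regressor is a random
forest with `n_trees = 500` and `m_try = floor(p/3)` candidate predictors per
split (6 for the standard 20-AU set), bootstrap-resampled per tree, delegated
to scikit-learn's `RandomForestRegressor`. Forest predictions are averages of
training outcomes, hence bounded by the training outcome range; predictions
are not clipped to [1, 7].

**Split design.** Train/test splits are stratified within participant:
`round(0.66 · nᵢ)` of each participant's recordings (round half up, clamped so
both sets are non-empty) are assigned to training. Every participant thus
contributes to both sets, which matches a use case where the model
generalizes to new recordings of known participants. A participant with a
single recording is assigned to training with a warning. Split-sensitivity
analysis repeats (split, fit, evaluate) with independent random sub-streams
per repetition; both the split and the forest are re-seeded each time, so the
reported variability pools split and forest randomness.

## Agreement statistics

Pearson correlations get Fisher-z 95% CIs, `tanh(atanh(r) ± 1.96/√(n−3))`.
Zero-variance inputs raise an explicit undefined-correlation signal rather
than silently reporting 0. ICCs are computed from ANOVA mean squares using
the McGraw–Wong estimators (all six model/unit variants; formulas in the
module docstring). Negative ICCs are reported as computed. Variant usage is
pinned per call site: model-vs-human item agreement uses ICC(1, single)
(one-way random — absolute agreement regardless of participant/condition);
coder-panel and importance-profile agreement use ICC(3, average); the
subsampling reliability test uses ICC(2, average). ICC confidence intervals
are out of scope.

## Interpretation layer

**Partial dependence (PD).** PD(v) is the mean model prediction with one
feature (or a pair) forced to v, averaged over the observed values of all
other features — computed exactly, by substitution, never by the approximate
node-weight recursion. Two code paths produce identical results (to float
summation order): a naive brute-force substitution loop, and a single-pass
tree-traversal kernel (numba) that partitions the sorted grid at splits on
the target feature and accumulates leaf values into grid intervals. The
kernel replicates scikit-learn's float32 input casting so branch decisions
match `predict` exactly. PD grids are 25 equally spaced empirical quantiles
between the 2.5th and 97.5th percentiles (quantile grids keep evaluation
inside the data's bulk); grids outside the training range trigger an
extrapolation warning but are still computed.

**Importance.** A feature's importance is the sample SD (ddof = 1) of its PD
curve over the grid; for a linear predictor `f(x) = βx` this equals
`|β|·SD(grid)`, which anchors the measure to regression beta weights.
Normalized profiles divide by the sum across AUs.

**Pairwise interactions.** For each of the p(p−1)/2 unordered pairs (190 for
20 AUs), the 2-D PD surface is summarized by the two-direction conditional-SD
statistic: the SD across one axis is computed at each grid value of the other
axis, the SD of those conditional SDs is taken, and the two directions are
averaged. A purely additive model scores exactly 0. The pair grid is 10
points per axis, and PD averaging subsamples to 300 rows (fixed seed; 1,000
rows for 1-D importance) — at these sizes the Monte-Carlo error of the PD
mean is far below the score differences that determine pair rankings, and the
full 190-pair scan of a 500-tree forest stays tractable on one CPU.

## Coder-specific analyses

A forest is fit per coder per valence using that coder's own ratings, and its
PD importance profile extracted. The subsampling reliability (randomization)
test asks how many rated recordings are needed to recover a coder's profile:
for each subsample size n, draw n recordings without replacement, refit,
extract the profile, and compute its ICC(2, average) against the full-data
profile; repeat (default 30 iterations, each with its own sub-stream for both
the subsample and the forest seed) and trace mean ± SE. Sampled indices are
sorted, so at n = N with a pinned forest seed the curve terminates at exactly
1. The 0.75 "excellent" reference level is a reporting threshold
(`crossing_n`), never hard-coded into the computation.

## Synthetic study generator

The generator emulates the study design the pipeline targets: 125
participants × 6 blocks (3 instructions × 2 image valences) × 7 trials, 10-s
recordings at 30 Hz, three coders. Defaults (all configurable):

| Parameter | Default | Meaning |
| --- | --- | --- |
| `baseline_mean` | −4 evidence units | resting AU evidence |
| `baseline_sd` | 1.5 | stationary SD of AR(1) frame noise |
| `autocorrelation` | 0.95 | lag-1 coefficient at 30 Hz |
| `amplitude` | 6 | peak expression amplitude above baseline |
| `activation_gain` | 1.5 / 1.0 / 0.5 | enhance / normal / suppress multiplier |
| `negative_amplitude_scale` | 0.25 | negative expressions are subtler |
| `coder_noise_sd` | 0.7 | per-coder rating noise (1–7 units) |
| `occlusion_rate` | 0.15 | recordings with a face-undetected span |
| `occlusion_duration_range` | 0.5–2.0 s | straddles the 1-s exclusion rule |

Evidence dynamics are stationary AR(1) noise around recording-specific
activation levels, clipped to [−16, 16] — the simplest autocorrelated choice
consistent with 30 Hz smoothness. Positive expressions load a shared
per-recording evocativeness drive (half shared, half per-AU, so smile
components are correlated but distinguishable) on AUs 12, 6, 25; an
independent lip-pucker action (AU18) carries a negative main weight (−0.35)
and a mean-centred negative AU12×AU18 product term (−0.3) — high AU12 with
low AU18 predicts the highest positive intensity (the masking structure).
Negative expressions are subtler and idiosyncratic: strong AUs 4, 5, 9, 10
plus ten weakly informative AUs, each with an independent drive, which
spreads negative importance across AUs, makes negative profiles harder to
estimate from few recordings, and drives the positive-vs-negative importance
ICC(3) negative. Per-participant expressivity is Gamma-distributed (mean 1,
shape 9), which produces the between-participant spread that the
within-participant performance analyses rely on.

Latent intensities are deterministic functions of the noiseless (clip-
adjusted) activations. Coders apply an affine map sending the 2nd/98th latent
percentiles to the scale endpoints 1 and 7 (rare extremes saturate rather
than compressing the bulk of the scale), add Gaussian noise, round
half-to-even, and clip to {1..7}. With `coder_noise_sd = 0.7` the closed-form
reliability of a 3-rater average, τ²/(τ² + (σ² + 1/12)/3), puts panel ICC(3)
in the high .80s/low .90s, which the tests confirm empirically.

One global seed spawns independent sub-streams per participant and per
recording, so any recording is reproducible regardless of generation order;
ratings and occlusions use separate top-level streams.

**What the generator does not emulate.** Real AU detectors produce
non-Gaussian, heteroscedastic errors correlated across AUs (shared head-pose
and lighting failures); real expressions have onset/apex/offset temporal
structure rather than stationary levels; coder errors drift and correlate
across recordings; occlusions can recur within a recording. Passing the
recovery tests therefore shows the pipeline is correct and well-calibrated
under its stated assumptions — not that a specific accuracy level will be
attained on any real dataset.

## Problem sizes used in validation

The importance-recovery check runs 20 independent replicates at the full
default scale (125 × 42). The subsample-reliability and directionality checks
run on a 30-participant study (≈1,100 retained recordings) with a reduced
subsample grid (10–700) and 6 iterations per size, and PD extraction during
curve estimation uses a 15-point grid over 400 subsampled rows; these sizes
give stable means and SEs while keeping the validation suite fast. The
acceptance script reports split sensitivity over 8 replications and coder
curves over a 7-point grid with 4 iterations for the same reason.

## Known limitations

- ICC confidence intervals and significance tests are not implemented.
- The participant-disjoint folding scheme is available via
  `split_by_participant(..., participant_disjoint=True)`, but the packaged
  pipeline always uses the within-participant 66/34 design.
- PD-based importance inherits PD's assumption that features can be varied
  independently; with strongly correlated AU activations, importance can leak
  between correlated AUs (visible in the synthetic recovery as small AU6/AU25
  shadows of AU12's interaction).
- The rating model treats recordings as exchangeable; no participant-level
  random effects are modelled.
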