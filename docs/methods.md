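# Methods

This note documents the models, numerical choices and limitations behind
each analysis stage, and what the synthetic generators do and do not
emulate.

## FMD analysis

A recording is a synchronized diameter/velocity time series with t = 0
at cuff deflation, conventionally spanning [−30 s, +120 s] (5-min
forearm occlusion at 250 mmHg precedes it; the occlusion itself is not
recorded).

- **Baseline diameter** is the arithmetic mean over the full 30-s
  pre-deflation window. The averaging rule is a package choice — the
  window is the protocol's; using all of it maximizes noise suppression.
  At least 5 pre-deflation samples are required.
- **Peak diameter** is the maximum of a centered moving-average-smoothed
  diameter (default window 3 s, shrinking at the recording edges) over
  t > 0, ties resolved to the earliest time. Whether reference analyses
  smooth before taking the max is not standardized across vendors, so
  the window is configurable (0 disables smoothing).
- **Cumulative shear rate** integrates SR = 8 v_mean / D by the
  trapezoidal rule over [t_release, t_peak], using the samples inside
  the closed interval. Integration starts at cuff release (not at
  hyperaemia onset a few seconds later); this choice is configurable via
  `t_release`. The trapezoidal sum is exact for piecewise-linear SR and
  is verified against a brute-force per-interval oracle.
- **Retrograde flow**: negative instantaneous velocities are clipped to
  0 with a logged warning wherever a series is converted to flow or SR —
  the formulas assume antegrade mean velocity. The scalar functions
  reject negative velocity outright.
- **Flow AUC** integrates the per-sample flow (ml/min) over the
  post-release window with time in minutes, so the AUC is in ml. For the
  cross-recording hyperaemia curve, flows are bin-averaged (default 2-s
  bins) over [0, 120 s], averaged across recordings, and integrated with
  the first/last bin values extended to the window edges — a constant
  flow F then yields exactly 2F ml over 120 s.
- **Allometric ratio-scaling check**: OLS of ln(peak) on ln(baseline);
  the two-sided (1−α) CI of the slope uses the t distribution on n−2 df
  (α default 0.05). Ratio scaling (%FMD) is accepted when the upper
  limit reaches 1 (a 1e−9 tolerance absorbs roundoff when residuals are
  ~0 and the CI is degenerate). With fewer than 3 pairs the cohort gate
  is skipped with a logged reason and treated as a pass-through; a
  failed check flags, never suppresses, the %FMD output.

## HRV analysis

- **Segment selection** stands in for the operator's choice of the
  "cleanest" 5 minutes: candidate windows start at every beat and span ≥
  the segment length; the score is the number of beats whose |ΔRR|
  exceeds 20 % of a centered 11-beat rolling median of RR; ties break to
  the lowest RR variance, then the earliest start. The 20 % threshold is
  an explicit, configurable artifact criterion.
- **Band powers**: the tachogram is converted to ms, cubic-spline
  interpolated onto a uniform 4-Hz grid, mean-removed, and its PSD
  estimated by Welch with 120-s Hann windows at 50 % overlap
  (detrending disabled — the mean is already removed, and per-window
  detrending would distort VLF content). Band powers are rectangle sums
  of PSD bins with lo < f ≤ hi, so adjacent bands partition the analysis
  range exactly and LF n.u. + HF n.u. = 100 by construction. An
  autoregressive spectrum would be a defensible alternative; Welch is
  the default because it needs no order selection.
- **Degenerate segments** (total LF+HF power below 1e−10 ms²) return a
  zero-power result with normalized units and LF/HF undefined and a
  `degenerate` flag, rather than raising: a constant tachogram is a
  legitimate, if extreme, input.

## Reliability

ICC is the two-way mixed-model, consistency, single-measures form
ICC(3,1) = (MS_S − MS_E)/(MS_S + (k−1) MS_E), computed from explicit
sums of squares (subjects × trials). This is the standard companion of
the SEM/MDC chain; the absolute-agreement form ICC(2,1) is available via
`form="agreement"`. An all-equal matrix returns 1.0 by convention
(logged). SEM defaults to SD_pooled·√(1−ICC) with SD_pooled the root
mean per-trial variance; √MS_E is available via `method="mse"` — the two
agree to rounding on typical test–retest tables, and which one produced
any given printed table is generally not recoverable. MDC95% =
1.96·√2·SEM%. Classification treats the printed band edges as inclusive
interval boundaries: very high > 0.90, high in [0.70, 0.90], moderate in
[0.50, 0.70), low below 0.50.

## Prescription

The device dose is anchored to spirometry: V_T = 0.5·FVC and a
minute-ventilation target of 0.6·MVV, converted to breath frequency by
f_b = 0.6·MVV / (1.3 · 0.5 · FVC). The 1.3 duty-cycle factor is a named
constant (`DUTY_CYCLE_FACTOR`), not an inline literal. Note the product
V_T · f_b equals the target divided by 1.3; the dataclass exposes both
(`minute_ventilation` = V_T·f_b, `target_minute_ventilation` = 1.3×
that), keeping the identity f_b·(1.3·0.5·FVC) = 0.6·MVV exact.
Progression multiplies alternately V_T (even weeks) or f_b (odd weeks ≥
3) by 1.15 — alternation order is configurable since either convention
is defensible — so workload grows by exactly 1.15^(w−1) either way.
Per-week adaptability adjustments are an optional override map.

## Group statistics

The "training × time" design is a split-plot: group between subjects,
time within. The ANOVA is delegated to pingouin's mixed ANOVA and
verified in tests against the balanced-design identity F_interaction =
t² of the unpaired t on per-subject gain scores. When the interaction is
significant at α (default 0.05), four simple-effect contrasts (pre vs
post within each group; group difference at each time) are reported with
Holm–Šidák step-down adjustment. Paired t on identical samples returns
t = 0, p = 1 (no change is a valid observation); zero-variance
differences with nonzero mean raise instead, since they admit no error
estimate. Shapiro–Wilk normality is reported for information only and
never switches the pipeline to a non-parametric branch.

## Synthetic generators

The generators define the study conditions under which everything is
tested; their defaults emulate a 12 + 12 two-group pre/post trial of
young healthy women.

- **FMD traces**: diameter is flat at baseline, rises along a normalized
  logistic from release to a flat top of width `peak_plateau` (default
  3 s) centred at `time_to_peak` (default 30 s, matching observed 28–35 s
  values), then relaxes exponentially (τ = 40 s). The plateau width
  equals the peak detector's default smoothing window by design: the
  smoothed maximum then equals the true peak exactly and occurs exactly
  at `time_to_peak`, so noiseless traces round-trip the programmed %FMD
  and time-to-peak to machine precision — a strictly curved peak could
  not, under any nonzero smoothing. Velocity steps to `peak_velocity` at
  release and decays exponentially (τ = 30 s) toward baseline,
  reproducing the hyperaemic surge-and-return shape. Gaussian noise
  (defaults 0.002 cm, 1 cm/s) approximates edge-detection and Doppler
  noise. Not emulated: probe drift, breathing artifacts, diastolic gating
  jitter, or retrograde diastolic flow — so passing tests show correct
  arithmetic and noise behaviour, not robustness to scan-quality
  pathology.
- **RR series**: RR_i = mean_rr + A_LF sin(2π f_LF t_i) + A_HF
  sin(2π f_HF t_i) + N(0, σ), evaluated at the cumulative beat time;
  non-positive draws are redrawn, not clipped, to avoid spectral
  artifacts. Deterministic sinusoids with beat noise emulate band-limited
  autonomic modulation, not real point-process dynamics (no respiratory
  sinus arrhythmia coupling, ectopy, or 1/f background).
- **Cohorts**: per subject and variable, (log pre, log post) is
  bivariate normal with correlation ρ (default 0.7 — the within-subject
  pre/post correlation is a free simulation parameter, not an inferred
  quantity) and log-moments matched to the programmed pre mean/SD;
  training effects shift the post log-mean, so mean(post)/mean(pre)
  equals the programmed multiplier and variables stay positive.
  Default effects: MIP ×1.31 and MVV ×1.16 in the trained group
  (×1.00/×1.03 in SHAM), lung volumes ≈ unchanged.
- **Pipeline defaults**: the trained group's post-training recordings
  scale the entire post-release velocity profile by 0.69, so each
  subject's cumulative SR (and hyperaemic flow) falls by 31 % while the
  programmed %FMD is untouched — the shear-normalized response %FMD/SR
  then rises by ≈ 1/0.69 − 1 ≈ +45 %. The reliability stage reuses the
  cohort generator with unit effects and ρ = 0.95 as the trial-1/trial-2
  correlation.

## Problem sizes and determinism

Every stochastic path takes a seed (numpy `default_rng`); the pipeline
derives independent per-stage streams from one seed via `SeedSequence`,
and identical configs give byte-identical CSV outputs. The default
study runs 12 subjects/group (48 FMD traces at 10 Hz, 48 × 10-min RR
series) in a few seconds on one CPU. Simulation-based checks use sizes
chosen to keep the whole suite under a minute of simulation time:
1000 replicates for coverage and type-I rates of scalar tests, 200–250
for the mixed ANOVA, 60 for Monte-Carlo %FMD recovery, 500 subjects ×
30 replicates for ICC consistency.

## Known limitations

- No image-plane processing: diameter/velocity series are taken as
  given (vendor edge-detection output), with no Doppler-angle or
  Womersley-profile correction.
- Only frequency-domain HRV; no RMSSD/SDNN beyond mean HR, no nonlinear
  indices, no R-peak detection from raw ECG.
- The reliability module handles complete matrices only (no imputation)
  and the MDC formula is the 1.96√2 two-trial form.
- The mixed ANOVA assumes a complete balanced 2 × 2 design; unbalanced
  or missing cells raise a design error rather than falling back to a
  mixed-effects model.
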