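# Methods

This note records the models, numerical choices and limitations behind
`eegisc`, in the order the pipeline runs.

## Signal model and preprocessing

The analysis assumes each subject's recording is a linear mixture of
stimulus-locked sources shared across subjects, subject-specific background
activity, ocular artifacts, and sparse gross outliers.  Preprocessing
targets the last two nuisances and standardizes the sampling grid:

- **Resampling** to 125 Hz uses polyphase filtering
  (`scipy.signal.resample_poly`), which applies its own anti-alias filter.
- **Filtering**: 1 Hz high-pass, then a 59–61 Hz band-stop, both Butterworth
  of prototype order 4.  Both are applied forward–backward
  (`sosfiltfilt`), so the effective magnitude response is that of an
  order-8 filter and the phase response is exactly zero.  Zero-phase
  filtering is a deliberate choice: ISC compares sub-second temporal
  structure across subjects, and a causal filter's group delay/dispersion
  would deflate those correlations.  The cost is acausal edge transients;
  the narrow stopband rings for roughly 2 s at each end, which matters for
  filter-response measurements but is negligible against minutes-long
  recordings.
- **EOG regression** removes the joint least-squares projection of all EOG
  channels from every scalp channel.  Both sides are mean-removed before
  fitting, and the residual is returned zero-mean (the high-pass has
  already removed any meaningful offset).  If the EOG channels carry no
  variance the scalp data are returned unchanged with a warning.
- **Bad channels** (flagged upstream by visual inspection and delivered via
  the channel-role table) are carried as all-zero rows, which removes them
  from every covariance without disturbing matrix shapes.

## Robust PCA

Sparse gross artifacts are removed by decomposing each recording's
channels-by-samples matrix as `M = A + E`, minimizing
`‖A‖_* + λ‖E‖₁`, with the inexact augmented Lagrange multipliers (IALM)
iteration: singular-value thresholding for `A`, entrywise soft-thresholding
for `E`, multiplier update, `μ ← 1.5 μ`.  Defaults are the standard ones —
`λ = 1/√max(m,n)`, `μ₀ = 1.25/‖M‖₂`, stop when
`‖M−A−E‖_F/‖M‖_F ≤ 1e-7` (cap 500 iterations).  RPCA runs per recording
(channels as rows, D ≪ T), not on concatenated sessions, so one subject's
artifacts cannot leak into another's decomposition.

Two numerical points worth knowing:

- The diagnostic `objective_trace_` logs the objective of the *feasible*
  point `(A, M−A)`.  The raw iterates are infeasible until convergence and
  their objective starts artificially low, so only the feasible-point
  objective is meaningfully monotone.
- Exact recovery of an uncorrupted low-rank matrix holds only when the
  singular vectors are incoherent relative to `λ`; for very elongated
  matrices (e.g. 20×200 at rank 2) the convex optimum genuinely moves a few
  coherent entries into `E`.  This does not affect artifact removal — only
  the interpretation of recovery benchmarks, which the tests run at
  100×200.

## Correlated components and per-subject ISC

Pair covariances are computed exactly as un-normalized sums over time (all
downstream quantities are ratios, so any common normalization cancels; a
test verifies rescaling by `1/(T−1)` changes no `C_ik`).  The generalized
eigenproblem `R_B v = λ R_W v` is solved by whitening within the principal
subspace of `R_W` above `rank_tol = 1e-9` (relative): eigen-directions of
zero within-subject variance — zeroed bad channels — are excluded, which
both regularizes the problem and guarantees those channels contribute
nothing.  Eigenvalues are sorted descending with first-occurrence
tie-breaks; projections are unit-norm with the largest-magnitude entry made
positive (eigenvector sign is otherwise arbitrary).  K = 3 components are
kept by default, configurable.

Per-subject correlations use the literal formulas

    C_ik = v_iᵀ R_{b,k} v_i / v_iᵀ R_{w,k} v_i,
    R_{b,k} = (1/(N−1)) Σ_{l≠k} (R_kl + R_lk),
    R_{w,k} = (1/(N−1)) Σ_{l≠k} (R_kk + R_ll),

including the within-term that sums *other* subjects' variances; other
papers normalize per-subject ISC differently, but this package implements
the printed definition and asserts `|C_ik| ≤ 1` (provable by
Cauchy–Schwarz) on every call.  A degenerate component variance
(`v_iᵀR_{w,k}v_i = 0`) yields `C_ik = 0` with a warning.

Component models can be fitted on all subjects or within age / sex /
age-and-sex subgroups (`fit_groups`); group comparisons in the stats stage
use within-group fits so a majority group cannot bias the components.
When topographies from different group models are compared, components are
matched by index after the eigenvalue sort and similarity is `|cosine|`
(sign-free); nothing in the data identifies a better matching, and the
dominant components are stable enough across groups for index matching to
be meaningful.

A note on bias: fitting components and evaluating ISC on the same small
cohort overfits slightly, so null (Rest) ISC has a small positive offset
that shrinks with N, D/T.  At the simulator's default scale it is ≈ 0.03 on
the [−3, 3] ISC scale; null-behavior tests therefore compare against
Monte-Carlo replicate bands rather than exactly zero.

## SSVEP band power

Flicker trials (2.4 s at 25 Hz drive) are cleaned per subject: a trial is
rejected when its mean-square power *or* peak absolute amplitude on any
electrode exceeds the across-trial mean + 3 SD for that electrode (an
electrode with zero SD never rejects).  The first 200 ms of each trial is
dropped to skip the onset transient, leaving 2.2 s → 0.4545 Hz DFT
resolution, so the 0.5 Hz band centered on 25 Hz contains exactly the
25.0 Hz bin.  Per-bin one-sided power is normalized as `2|X_f|²/T²`
(rectangular window, no padding): a sinusoid of amplitude `a` on a bin
center carries `a²/2`.  Power is averaged over all retained trials
regardless of contrast/background condition, then over the configured
occipital electrodes (`ssvep.electrodes`, default `O1–O5`; real caps should
set this to their montage's occipital names).

## Eigenvalue spectrum

The spectrum stage eigendecomposes each subject's channel covariance,
normalized by `T−1` (here the absolute scale matters: total power is the
per-sample variance summed over channels, and group comparisons of power
are meaningful).  The dimensionality index is the OLS slope of
`log10 λ_i` on `log10 i`, using eigenvalues above `1e-9 × λ₁` — exact
zeros from zeroed channels would make the log undefined and are excluded.
A shallower (less negative) slope means appreciable power in more spatial
dimensions.

## Group statistics

- Pearson correlations with age; FDR control across the stimulus family by
  Benjamini–Hochberg (the step-up procedure; not the
  Benjamini–Yekutieli variant).
- Median split: at-or-below the cohort median age → "young", above →
  "old"; a `fixed_boundary` option reproduces a previously chosen split
  (e.g. 14/15 years) for replication runs.
- Two-way ANOVAs are additive (main effects only) with Type II sums of
  squares, the appropriate choice for the unbalanced group sizes an
  observational cohort produces.
- Post hoc comparisons use Tukey–Kramer (studentized range with the
  unequal-n harmonic correction); groups of size 1 are excluded.
- Residual ISC regresses ISC on SSVEP amplitude (OLS with intercept, inner
  join on subject id) and analyses the zero-mean residuals.

The suite calibrates the machinery empirically: under 200 seeded null
replicates the type-I error rate of the ANOVA main effect and the Pearson
test at α = 0.05 must land in [0.02, 0.09].

## The synthetic cohort generator

`SimConfig` defaults define the simulated study: 16 subjects, 24 scalp +
2 EOG channels, 120 s at 125 Hz, ages uniform on 6–44 yr, balanced sexes.
Each subject's scalp data is
`gain(age, sex) · (mixing · sources) + noise + EOG leakage + spikes` where:

- **sources** are 3 shared band-limited (0.5–15 Hz) Gaussian time courses —
  aperiodic stimulus-locked structure, as a film drives, rather than
  periodic signals;
- **gain** is `1.0 − 0.02·(age − 6) + 0.15·[male]`, clipped at zero: ISC
  falls with age and is slightly elevated in males, the two planted group
  effects;
- **mixing** columns are unit-norm random topographies scaled by
  `signal_scale = 0.3` (the leading column ×1.5), putting per-subject ISC
  in a realistic sub-1 range rather than near saturation;
- **noise** is `1/f` (exponent 1) spectrally shaped Gaussian noise smeared
  across neighboring channels (`spatial_corr`), per subject, unit RMS;
- **EOG** traces are heavy low-frequency noise leaking into scalp channels
  through random non-negative vectors (`eog_leak = 0.2`);
- **spikes** are single-sample ±20 RMS outliers at 2/min — the target of
  the robust-PCA stage;
- **Rest** forces gain 0 (no shared signal at all); **Flash** adds a 25 Hz
  sinusoid gated 2.4 s on / 1 s off on the occipital channels.

Demographics, mixing and noise geometry derive from the config seed;
sources, noise and spikes additionally derive from a per-condition
substream, so different stimuli share the cohort but not the signals.
Flicker trials for the SSVEP stage are generated separately
(`simulate_flicker_trials`, 128 trials of 2.4 s, 12 cycling
contrast/background labels) with per-subject drive amplitude from the same
gain model.

What the generator does *not* emulate: biophysical head geometry (mixing is
abstract), non-stationarity, alpha rhythms or any oscillatory background
structure, electrode drift, or realistic EOG waveforms (blinks/saccades are
approximated by heavy 1/f² noise).  Passing tests therefore demonstrate
that the estimators recover the statistical structure they assume —
shared low-rank signal in correlated noise with planted demographic
effects — not that real developmental EEG behaves this way.

## Problem sizes

Tests and the acceptance script run desk-scale versions of the study:
cohorts of 8–16 subjects, 8–24 channels, 24–120 s at 125 Hz, and 10–20
Monte-Carlo replicates per null or recovery claim.  These sizes were chosen
so every planted effect is comfortably powered (verified: 20/20 detection
for the age effect, 0/20 false positives under the null at the chosen
gains) while the full suite runs in well under a minute of CPU per module.

## Known limitations

- ISC is computed once per subject/condition; there is no time-resolved
  (windowed) variant.
- The per-subject ISC normalization follows the printed definition above;
  comparisons with implementations using `R_kk`-only normalization will
  differ by a subject-specific factor.
- EDF support covers reading EDF/EDF+ (annotations ignored) and writing
  plain 16-bit EDF with a single data record; recordings of unequal length
  entering one cohort are truncated to the shortest (logged), since nothing
  in the data justifies imputation.
- No ICA-based artifact removal, no scalp-map rendering, no
  contrast-response modelling of the flicker protocol, and no
  entropy/complexity measures beyond the eigenspectrum slope.
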