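# eegisc — intersubject correlation of EEG responses to shared stimuli

`eegisc` measures how similarly different people's brains respond to the
same time-locked stimulus (a film clip, a flickering grating, or nothing at
all) from multi-subject EEG, and tests how that similarity varies with age
and sex.  It is aimed at researchers analysing developmental or cohort EEG
datasets where every subject watched the same material, and at anyone who
needs a tested, self-contained implementation of correlated component
analysis with per-subject intersubject correlation (ISC).

## The method

Let `x_k(t) ∈ R^D` be subject *k*'s scalp voltages (D electrodes).  With the
un-normalized pair covariances

```
R_kl = Σ_t (x_k(t) − x̄_k)(x_l(t) − x̄_l)ᵀ
```

define the average within-subject covariance `R_W = (1/N) Σ_k R_kk` and the
average between-subject cross-covariance
`R_B = (1/(N(N−1))) Σ_k Σ_{l≠k} R_kl`.  Correlated component analysis
(CorrCA) finds projections `v` — virtual sensors — that maximize correlation
*between* subjects: they are the eigenvectors of `R_W⁻¹ R_B`, solved here as
a symmetric generalized eigenproblem on the whitened principal subspace of
`R_W` so that zeroed bad channels contribute exactly nothing.  Per subject
and component,

```
C_ik = v_iᵀ R_{b,k} v_i / v_iᵀ R_{w,k} v_i
R_{b,k} = (1/(N−1)) Σ_{l≠k} (R_kl + R_lk)
R_{w,k} = (1/(N−1)) Σ_{l≠k} (R_kk + R_ll)
```

and a subject's ISC is `Σ_{i=1..3} C_ik` — how strongly that subject's
components correlate with everyone else's.  `|C_ik| ≤ 1` always (Cauchy–
Schwarz); the package asserts it on every run.  Forward models
`a_i = R_W v_i / (v_iᵀ R_W v_i)` map components back to scalp topographies.

Around this core the package provides the full analysis chain:

- **preprocess** — polyphase downsampling to 125 Hz, 1 Hz Butterworth
  high-pass, 59–61 Hz band-stop (order 4, zero-phase), least-squares EOG
  regression;
- **rpca** — robust PCA by inexact augmented Lagrange multipliers
  (`min ‖A‖_* + λ‖E‖₁ s.t. A+E=M`) to strip sparse gross artifacts;
- **ssvep** — steady-state visual evoked potential power at 25 Hz from
  2.4 s flicker trials (3-SD trial rejection, 200 ms onset trim, 0.5 Hz DFT
  band, occipital average);
- **spectrum** — per-subject covariance eigenvalue spectra: total power and
  the log-log slope as an effective-dimensionality index;
- **stats** — age correlations with Benjamini–Hochberg FDR control, young/old
  median splits, Type II two-way ANOVAs, Tukey–Kramer post hocs, and
  SSVEP-residualized ISC;
- **simulate** — a synthetic cohort generator (shared band-limited sources
  mixed to scalp with age/sex-dependent gain, spatially correlated 1/f
  noise, EOG leakage, sparse spikes, a zero-gain Rest condition and 25 Hz
  flicker trials) so the whole pipeline is testable without any data
  download.

`CorrCA` and `RobustPCA` are scikit-learn-style estimators (`fit`,
`transform`, trailing-underscore fitted attributes) and compose with
sklearn tooling; every operation is also exposed as a plain function.

## Worked example

Run the bundled demo configuration (a simulated 12-subject cohort, four
conditions, full pipeline):

```bash
eegisc all --config examples/demo.yaml --out demo_out
python - <<'PY'
import json
stats = json.load(open("demo_out/group_stats.json"))
for cond in ("Wimpy", "DesMe", "Flash", "Rest"):
    c = stats["age_correlation"][cond]
    print(f"{cond:6s} r(age, ISC) = {c['r']:+.3f}  p = {c['p']:.2e}")
print("rest mean ISC =", round(stats["rest_mean_isc"], 4))
PY
```

which prints

```
Wimpy  r(age, ISC) = -0.901  p = 6.22e-05
DesMe  r(age, ISC) = -0.902  p = 6.03e-05
Flash  r(age, ISC) = -0.898  p = 7.34e-05
Rest   r(age, ISC) = +0.163  p = 6.12e-01
rest mean ISC = 0.0351
```

ISC correlates negatively with age for every stimulus condition (the
simulator plants a shared-signal gain that falls with age), while the Rest
condition — which carries no shared signal — shows ISC near zero and no age
relation.  `demo_out/` also contains `isc_per_subject.csv` (per-subject
C1–C3 and ISC for every condition and model fit group),
`ssvep_power.csv`, `spectrum.csv`, `models.h5` (projections and forward
topographies) and `ground_truth.json` from the simulator.

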