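# bimeter

Tools for the *biphasic meter* paradigm in auditory psychophysics: sequences
of band-limited noise bursts that carry a triple-meter cue in one acoustic
attribute and a quadruple-meter cue in another, so that listeners hear a
different musical meter depending on which attribute they attend to.

The package covers the whole workflow of such an experiment:

* **Stimulus synthesis** — every stimulus is 12 noise bursts at a fixed
  300 ms inter-onset interval (3.6 s total). Center frequencies alternate
  between 1500 ± Δf/2 Hz in a high-low-low cycle and durations between
  100 ± Δd/2 ms in a long-short-short-short cycle (or the mirror
  assignment). The study grid crosses Δf ∈ {102, 128, 160, 200, 250} Hz with
  Δd ∈ {51, 64, 80, 100, 125} ms, giving 25 conditions per assignment type.
  Bursts are band-limited noise with full bandwidth 1.2·f_c and 10 ms
  raised-cosine ramps, rendered deterministically from a seed to 16-bit WAV.
* **Acoustic validation** — burst onsets, durations, spectral centroids and
  cue periodicities are measured back from the rendered audio and checked
  against the design.
* **Synthetic raters** — a cohort generator that emulates the published
  effect structure: 16 participants (8 unexperienced / 2 experienced /
  6 tapping-trained), 11 of whom switch their perceived meter with
  attention. A switcher's latent quadruple-minus-triple rating difference
  follows the linear surface
  `β₀ + β_f·(Δf−168) + β_d·(Δd−84) + β_fd·(Δf−168)(Δd−84) + u_i`
  with β_f = 0.89×10⁻³ points/Hz, β_d = 4.82×10⁻³ points/ms,
  β_fd = 0.06×10⁻³ and participant random intercepts u_i; ratings are
  discretized to the 1–5 scale.
* **Analysis** — trials are categorized as triple- or quadruple-targeted by
  (assignment × instruction); per-condition rating differences are tested
  against zero with an **exact one-sample Wilcoxon signed-rank test** (full
  null distribution, midranks under ties) and modelled with a
  **random-intercept linear mixed model**

  `rating_difference ~ freq_c + dur_c + freq_c:dur_c + (1 | participant)`

  fitted by profiled REML (or ML), with marginal and conditional GLMM R²,
  predicted main effects over the grid spans, and experience-group
  summaries. The mixed model follows the statsmodels idiom: a
  `RandomInterceptLM` model object whose `fit()` returns a results object
  with `params`, `bse`, `tvalues`, `r2_glmm()` and `summary()`.

## Worked example

```python
from bimeter import CohortConfig, analyze_trials, generate_cohort, simulate_experiment

cohort = generate_cohort(CohortConfig(), seed=42)   # 16 raters, 11 switchers
trials = simulate_experiment(cohort, seed=42)       # 6 blocks x 100 trials each
result = analyze_trials(trials)

w = result.wilcoxon_switchers
print(f"switchers: n={w.n}, V={w.statistic:.0f}, p={w.p_value:.2g}")
print(result.fit.summary())
```

prints

```
switchers: n=11, V=66, p=0.00098
Random-intercept linear mixed model (REML)
  observations: 275   groups: 11   df: 261
  sigma_u^2: 0.08177   sigma_e^2: 0.04003   logLik: 6.06
  R2 marginal: 0.123   conditional: 0.712

  term                         slope          SE    df       t         p
  intercept                    3.048     0.08706   261   35.02 1.29e-100
  freq_c                   0.0004505   0.0002299   261    1.96    0.0511
  dur_c                     0.003995   0.0004599   261    8.69  4.16e-16
  freq_c:dur_c             5.437e-05   8.763e-06   261    6.20  2.15e-09
```

The 11 switchers' rating differences are all positive, so the signed-rank
statistic reaches its maximum V = n(n+1)/2 = 66 and the exact two-sided
p-value is 2/2¹¹ ≈ 0.001. The duration slope (~4×10⁻³ points/ms on this
draw) dominates the frequency slope, and the conditional R² (fixed effects
plus participant intercepts) sits near 0.71 — the structure the generator
was calibrated to produce.

## Command line

```
biphasic synthesize --out stimuli/ --seed 1          # 50 WAVs + manifest
biphasic validate   --in stimuli/ --report report.json
biphasic simulate   --seed 1 --out trials.csv
biphasic analyze    --trials trials.csv --out analysis/ [--plots]
biphasic reproduce  --seed 1 --out run/              # all stages + manifest
```

`reproduce` writes every artifact with a SHA-256 manifest; identical seeds
give identical artifacts.

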