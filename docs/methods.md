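# Methods

## The paradigm

A biphasic meter stimulus is an isochronous sequence of 12 band-limited
noise bursts (inter-onset interval 300 ms, total 3.6 s) whose two acoustic
attributes carry conflicting metrical cues. One attribute repeats with
period 3 (accent-weak-weak, a triple meter) and the other with period 4
(accent-weak-weak-weak, a quadruple meter); 12 = lcm(3, 4), so a stimulus
holds exactly one full cycle of the joint pattern. Under the
`freq_triple` assignment the high-frequency bursts sit at indices
{0, 3, 6, 9} and the long bursts at {0, 4, 8}; `dur_triple` exchanges the
roles. Both patterns begin with their accented element at burst 0.

A listener attending to frequency in a `freq_triple` stimulus is attending
to the triple cue (a *triple-targeted* trial); attending to duration in the
same stimulus targets the quadruple cue. Ratings are collected on an
integer 1–5 scale from "strong triple" to "strong quadruple"; the primary
outcome is the *rating difference*: the mean rating on quadruple-targeted
trials minus that on triple-targeted trials, per participant and grid
condition, pooled over blocks and both assignment types.

## Stimulus synthesis

Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| baseline frequency | 1500 Hz | center of the high/low pair; bursts at 1500 ± Δf/2 |
| baseline duration | 100 ms | center of the long/short pair; bursts at 100 ± Δd/2 |
| Δf grid | 102, 128, 160, 200, 250 Hz | frequency-difference conditions |
| Δd grid | 51, 64, 80, 100, 125 ms | duration-difference conditions |
| inter-onset interval | 300 ms | fixed; configurable as a parameter |
| bandwidth | 1.2 · f_c | arithmetic full width, band edges 0.4·f_c and 1.6·f_c |
| ramps | 10 ms | raised-cosine, counted inside the stated duration |
| sample rate | 44100 Hz | PCM 16-bit mono WAV output |

Noise is constructed in the frequency domain: unit magnitude on every FFT
bin inside the band, i.i.d. uniform random phase, inverse real FFT. This
pins the spectral support exactly (no filter-design ambiguity); the only
out-of-band energy is ramp leakage, more than 40 dB below the in-band
level. The bandwidth is read as an *arithmetic* full width symmetric about
f_c — the simplest literal reading; an octave-based alternative would be
defensible but is not used.

Each burst is normalized to a common RMS *after* ramping, so the RMS over
any burst's nominal span is identical across bursts of a stimulus (exactly,
not approximately); the plateau level then varies by a few percent with the
ramp-to-duration ratio. The assembled stimulus is peak-normalized to
−3 dBFS. Absolute playback level (the original experiment used ≈70 dB SPL)
is a hardware property and is not modelled.

Sample counts round half-away-from-zero (140 ms at 44.1 kHz → 6174
samples; a full stimulus → 158760). Determinism: one master seed;
per-condition seeds derive from a CRC of the condition name, so any single
stimulus is reproducible in isolation; per-burst streams are spawned from
the condition seed. The same seed reproduces the waveform bit-for-bit;
different seeds change the noise tokens but not the envelope timing.

## Acoustic validation

Validation measures the rendered audio and compares it with the burst plan
implied by the condition (tolerances: timing ±2 ms, duration ±5 ms,
centroid ±50 Hz; all in one config object).

*Timing.* The envelope is the rectified waveform lowpassed at 50 Hz
(zero-phase). Bursts are located as supra-threshold runs at half the
envelope maximum, merging gaps under 20 ms; each burst's edges are then
refined at 0.1 of its own plateau level (the run median). Low-threshold
edges are used because envelope fluctuations of a noise carrier are
multiplicative: near the ramp foot the envelope is almost silent and the
crossing time is an order of magnitude more precise than at half-peak,
where it is about ±3 ms for this bandwidth. The deterministic offset
between a nominal burst edge and the threshold crossing is computed once by
passing a clean ramp template through the identical smoothing and is
subtracted, so measured onsets are unbiased.

*Spectrum.* Spectral windows are placed at the nominal burst positions
(timing is verified separately, and a window misplaced by a few
milliseconds breaks the FFT-grid alignment the estimator exploits). The
known raised-cosine envelope is divided out of the segment, which restores
the construction's exactly flat in-band spectrum; the centroid is the
power-weighted mean frequency over the supra-threshold region of the
periodogram, and band edges are taken at −20 dB relative to the in-band
median. Residual centroid error is the deterministic bin-grid asymmetry,
under 50 Hz even for 37.5 ms bursts.

*Cue structure.* The 12 measured centroids and durations are binarized at
the midpoint of their range (the classes are unbalanced — 4 of 12 and 3 of
12 — so a median split would cut through the majority class) and the
dominant period is read from the DFT magnitude at 1–6 cycles per sequence,
restricted to cycle counts that divide 12. A period-3 cue peaks at 4
cycles, a period-4 cue at 3. A deliberately scrambled stimulus (rolled by
one inter-onset slot) fails validation, as required.

## Synthetic rater cohort

No trial-level human data are available, so the generator reproduces the
*published statistics*, not any individual's data. The default cohort is
16 raters in three prior-experience groups (8 unexperienced, 2 experienced,
6 tapping-trained); 11 are switchers, with all 6 trained raters among them
and the remaining 5 spread 4/1 over the other groups by largest-remainder
apportionment. Experience influences nothing except this allocation — the
original study ran no statistical test of the group effect and neither does
the package.

A switcher's latent rating difference for condition (Δf, Δd) is

    d_i = β₀ + β_f (Δf − 168) + β_d (Δd − 84) + β_fd (Δf − 168)(Δd − 84) + u_i

with β₀ = 2.98 (the difference of the published switcher targeted means,
4.43 − 1.45), the published slopes β_f = 0.89×10⁻³ points/Hz,
β_d = 4.82×10⁻³ points/ms, β_fd = 0.06×10⁻³, and u_i ~ N(0, σ_u²).
Non-switchers have a flat difference of 0.196 points: their targeted means
(2.698, 2.894) are forced by the mixture identity
11·(switcher mean) + 5·x = 16·(overall mean) applied to the published
overall means 1.84 and 3.95.

A single trial's latent rating is `center + s/2 + ε`, where `s = +d_i` on
quadruple-targeted and `−d_i` on triple-targeted trials,
ε ~ N(0, σ_t²) i.i.d. per trial, and `center` is the midpoint of the
group's targeted means (2.94 for switchers, 2.796 for non-switchers — the
published means are not symmetric about the scale midpoint 3, so a centered
generator could not reproduce them). Latent ratings are rounded
half-away-from-zero and clipped to 1–5. Each simulated block is a random
permutation of the full 25 × 2 × 2 crossing; six blocks per rater.

### Variance calibration

The two dispersion parameters have no closed form after discretization
(rounding adds variance, clipping compresses the extremes and attenuates
slopes), so they were chosen by a grid search
(`scripts/calibrate_variance.py`) over σ_u × σ_t against the published
statistics, computed on simulated data exactly as the analysis pipeline
computes them. The selected defaults are **σ_u = 0.35** (rating-difference
points) and **σ_t = 0.40** (rating points per trial), which give switcher
targeted means ≈ 1.47 / 4.42, a full-cohort quadruple-targeted mean ≈ 3.95,
mean conditional R² ≈ 0.76–0.77 on 11 × 25 fits, and recovery of both
generating slopes within two standard errors in ~90 % of replicates.

One published statistic is deliberately not matched: the between-participant
SD of the switcher targeted means (≈ 0.29–0.33 in print, ≈ 0.15 here).
Raising σ_u enough to match it pushes the conditional R² far above 0.74
unless trial noise grows to the point where clipping breaks the targeted
means and the slope recovery. The published spread plausibly reflects
per-participant sensitivity differences (random slopes), which this
generator intentionally omits — as it omits the nonlinear dip of the
rating difference from Δd = 100 to 125 ms, the dynamic-attending process
itself, and any musician-covariate effect. Passing tests therefore show
that the *pipeline* recovers a known linear-with-intercepts structure
from discretized ratings; they do not show that human rating surfaces are
linear.

## Statistical pipeline

*Wilcoxon.* The one-sample signed-rank test drops exact zeros, ranks
|values| with midranks under ties, and sums the positively-signed ranks
into V. For n ≤ 20 the two-sided p-value is exact: the null distribution
of V over all 2ⁿ equiprobable sign patterns is built by polynomial
convolution over the doubled ranks (doubling keeps midranks integral), and
p = P(V ≥ v_hi) + P(V ≤ T − v_hi) with v_hi the larger of v and T − v,
T = ΣR. Larger samples use the normal approximation with the midrank
variance ΣR²/4. Eleven all-positive differences give V = 66 and
p = 2/2¹¹ < 0.001.

*Switcher classification.* The original report does not state its
criterion for "clear switching"; the package uses overall rating difference
> 1.0 point (half the midpoint-to-extreme distance of the scale), exposed
as `--switch-threshold`. The simulated groups sit near 3.0 and 0.2 points,
so the partition is insensitive to the exact value, though a non-switcher
intercept draw crosses 1.0 in a few percent of seeds.

*Mixed model.* `RandomInterceptLM` fits
`y_ij = x_ij'β + u_i + e_ij` by profiling both variance components onto
the ratio λ = σ_u²/σ_ε²: the marginal covariance is σ_ε²(I + λZZ'), block
diagonal with the closed-form inverse I − λ/(1+λn_g)·J per group, so each
candidate λ costs O(N); β and σ_ε² have closed forms at fixed λ and the
restricted (or full) likelihood is maximized by a bounded scalar search
over log λ (λ ∈ [e⁻¹², e¹²]). REML is the default, ML a flag. If the
criterion at λ → 0 matches the interior optimum, σ_u² is clamped to zero
with a warning (the fit then equals OLS exactly). Fixed-effect covariance
is σ̂²(X'V⁻¹X)⁻¹; t statistics use df = N − rank(X) − (n_groups − 1),
which evaluates to 261 for 11 × 25 tables — matching the printed df of the
reference analysis, though other df conventions (Satterthwaite) exist and
are not implemented. Frequency and duration are centered at their observed
grid means (168 Hz, 84 ms) before fitting; the interaction uses the
centered products.

*GLMM R².* With var_f the population variance of the fitted fixed-effect
predictions over the observed design, marginal R² = var_f/(var_f + σ_u² +
σ_ε²) and conditional R² = (var_f + σ_u²)/(var_f + σ_u² + σ_ε²). The
comparison statistic of the pipeline is the conditional R² (the published
single R² value is consistent with the conditional one under the
calibrated components; the marginal one is ≈ 0.12).

*Predicted effects.* Main-effect predictions over the grid spans,
β_f · 148 Hz and β_d · 74 ms, rounded to two decimals for reporting; with
the published slopes these are 0.13 and 0.36 points.

The implementation is validated against statsmodels' MixedLM (parameters,
standard errors, variance components and log-likelihood agree to ≤ 1e-3
relative) and against an OLS oracle at the σ_u² = 0 boundary; statsmodels
is never used in the pipeline itself.

## Pipeline and problem sizes

`biphasic reproduce` runs synthesize → validate → simulate → analyze from
one JSON config and records a SHA-256 manifest of every artifact; stage
outputs are pure functions of (config, master seed). A full default run —
50 stimuli at 44.1 kHz, their validation, a 16-rater experiment (9600
trials) and the complete analysis — takes well under a minute on one CPU.
The acceptance script uses 100 replicate 11-rater experiments for the
slope/R² summaries and a 200-rater cohort (138 switchers, preserving the
11:16 proportion) for the calibration means; these sizes keep Monte-Carlo
error well inside the comparison tolerances while running in seconds.

## Known limitations

* The rating model is linear in the centered condition variables with a
  single random intercept; no random slopes, no ordinal (cumulative-link)
  response model, no nonlinear response surface.
* The switcher criterion is a documented guess (threshold 1.0).
* Validation assumes the synthesis conventions (10 ms raised-cosine ramps
  inside the stated duration, arithmetic bandwidth); stimuli produced under
  other conventions would need the tolerances revisited.
* Whether the two successive presentations of a trial in the original
  procedure used identical or fresh noise tokens is unknown; the package
  models one rating per trial and draws fresh tokens per stimulus seed.
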