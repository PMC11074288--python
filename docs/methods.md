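# Methods

This note documents the models, defaults and numerical choices behind
`dcpot`, and what the synthetic cohorts do and do not establish about real
recordings.

## Signal model of the synthetic cohorts

Each subject-session is a continuous multichannel trace in microvolts at
500 Hz, built by superposition:

```
signal = pink noise + slow sinusoidal drift
       + Σ_events [ AEP kernel + channel_scale · slow-shift kernel ]
       + movement artifacts
       + (conditioning, rewarded events) MFB stimulation burst at +1000 ms
```

**Event schedule.** Each session presents 150 rewarded and 150 unrewarded
tones (configurable) in random order with equal ratio. Inter-onset gaps are
uniform on [10, 14] s for the independent and conditioning sessions (mean
12 s) and uniform on [2, 6] s for extinction (mean 4 s); the experiment
states means and the conditioning range but not the distribution, so
uniform on mean ± 2 s is used throughout. Onsets are rounded to 1 ms so the
on-disk event files (ms precision) are identical to the in-memory schedule.

**AEP kernel.** Three raised-cosine (Hann) lobes — P1 positive at 47 ms,
N1 negative at 90 ms, P2 positive at 170 ms, half-widths 20/22/16 ms —
with per-channel amplitudes chosen so that P1-to-N1 peak-to-peak is
~132 µV frontally, ~108 µV parietally and ~78 µV temporally, and temporal
P1 is ~40 µV, the magnitude regime of epidural rat recordings. Hann lobes
(rather than Gaussians) have compact, non-overlapping supports, so the
kernel is exactly zero at tone onset and in the baseline, each component's
peak equals its configured amplitude exactly, and superposition recovery is
exact — which is what makes the noise-free oracle tests sharp.

**Slow-shift kernel.** Zero until `onset_ms` (300), linear ramp to the
plateau amplitude `A` at `plateau_ms` (600), then either held to 1000 ms
("sustained") or decaying as `A·exp(−Δt/τ)` with τ = 400 ms ("reduced").
This is the simplest shape that reproduces the two qualitative response
profiles; the experiment describes them only diagrammatically.

**Effect schedule.** Default plateau amplitudes (µV, frontal scale):

| session | rewarded | unrewarded |
|---|---|---|
| independent | −15 sustained | −15 sustained |
| conditioning 1/2 | −25 / −35 sustained | identical to rewarded |
| conditioning 3 | −50 sustained | −35 reduced |
| conditioning 4 | −60 sustained | −38 reduced |
| conditioning 5 | −55 sustained | −36 reduced |
| extinction 1 | −35 sustained | −25 reduced |
| extinction 2–5 | −20/−17/−16/−15 reduced | identical to rewarded |

The schedule encodes the qualitative trajectory the analysis must detect:
growth of the negative shift across conditioning, tone divergence from
day 3, peak at day 4, persistence into extinction day 1 and collapse to
tone equality by extinction day 2. Channel scales default to frontal 1.0,
parietal 0.6, temporal 0.4 (frontal-dominant effect). A per-subject
multiplicative gain ~N(1, 0.1²) (floored at 0.2) emulates inter-animal
amplitude variability; effect sizes are set so a cohort of n = 6 reaches
significance at the reduced trial counts used in testing.

**Noise and artifacts.** Background is 1/f (exponent 1) noise, SD 20 µV —
a realistic level for epidural screw electrodes — generated by spectral
shaping with the DC bin zeroed, plus a 15 µV slow sinusoidal drift
(period 120 s, random phase). Movement artifacts are square deflections of
random sign (default 500 µV, 200 ms) at Poisson times (0.5/min), applied to
all channels and logged as ground truth. The MFB stimulation artifact is a
saturating alternating pulse train (20 pulses, 10 ms on, 20 ms spacing,
±2000 µV) starting 1000 ms after each rewarded conditioning tone — placed
exactly outside the half-open analysis epoch, as in the experiment, where
stimulation-period data are unusable. One subject per cohort (the last,
when `include_noisy_subject`) carries 10× noise to exercise the QC rule.

**Determinism.** All randomness derives from
`SeedSequence([rng_seed, session_index, subject_index])`; identical
(config, seed) pairs give bit-identical recordings, event tables and
artifact logs.

## Analysis stages

**Epoching.** Epochs are half-open sample windows `[onset−500 ms,
onset+1000 ms)` (750 samples at 500 Hz); the onset sample is the nearest
sample at-or-after the event time. Events whose window does not fit in the
recording are excluded with a warning, never padded — padding would bias DC
means. Counts always satisfy accepted + rejected + edge-excluded = events.

**Artifact rejection.** An epoch is rejected iff its peak-to-peak
amplitude on any channel exceeds a threshold (default 300 µV). A
peak-to-peak screen is the simplest auditable stand-in for manual "marked
movement noise" exclusion; the generator's artifact log provides exact
ground truth, and the acceptance suite verifies precision = recall = 1
under the planted-artifact regime.

**Averaging and baseline.** Accepted epochs are averaged per tone and
channel first, then the mean of the averaged waveform over [−500, 0) ms is
subtracted (correcting the average, not the trials, is the default;
per-trial correction is available). Correction is idempotent.

**DC metrics.** The integrated area statistic interpolates both averages
onto a 1-ms grid over 300–999 ms (the native grid is 2 ms; linear
interpolation adds no invented structure) and sums the absolute trapezoid
of the difference over the 699 intervals. Windowed areas integrate the
signed trapezoid over 300–600 and 600–1000 ms; grid points past the last
sample of the half-open epoch (999 and 1000 ms) take the final sample's
value. The relative-DC reference is the grand mean at 300 ms over subjects
and tones, computed per (session, channel) — whether the experiment pooled
across days is not recoverable, and per-session is the conservative
choice. Ratios guard the 300-ms denominator with ε = 1 µV and propagate
NaN, never ±inf (note that a shift with onset exactly at 300 ms is zero at
300 ms, so ratios of pure synthetic kernels are flagged by design).
Profile classification compares the late window [900, 1000) ms against the
mid window [550, 650] ms: "flat" below 10 µV at mid, "sustained" if the
late mean retains ≥ 70% of the mid mean with the same sign, else
"reduced". The 10 µV and 70% thresholds are package choices validated
against the generator (noise-free recovery is exact; ≥95% at default noise
with 150-trial averages).

**AEP detection.** Sequential constrained search: P1 = positive maximum in
[20, 80) ms, N1 = negative minimum after P1 up to 150 ms, P2 = positive
maximum after N1 up to 300 ms; ties break to the earliest sample, and an
extremum on a window edge yields a low-confidence flag rather than a
missing value, keeping cohort tables rectangular. The average is smoothed
with a 5-point quadratic Savitzky–Golay filter before peak picking:
quadratic-preserving smoothing leaves the curvature of the evoked lobes
essentially unbiased (<1% on the default kernels) while suppressing the
sample-level noise that would otherwise jitter the argmax by more than one
sample. Search windows are package defaults anchored to the ~47 ms P1 of
rodent AEPs and are configurable per channel.

**Quality control.** A subject is excluded when (i) the baseline-window SD
of its session averages exceeds 3× the cohort median, or (ii) artifact
screening rejects every trial of some (session, tone) stratum. The second
clause is what catches a grossly unstable recording, whose trials never
survive the peak-to-peak screen in the first place; the 3× factor is a
package default (no quantitative criterion is published).

## Statistics

**Two-way repeated-measures ANOVA** uses the classical univariate
partitioning (each within effect against its subject-by-effect
interaction), computed via `pingouin.rm_anova` and cross-checked in the
test suite against an independent brute-force sums-of-squares oracle to
1e−8 relative tolerance. No sphericity correction is applied by default
(the design's power settings assume ε = 1); the Greenhouse–Geisser ε is
reported descriptively per effect.

**Tukey HSD** collapses to subject × level cell means, forms the one-way
within-subject error term MS(subject × level), and refers
q = |mean_i − mean_j| / √(MS/n) to the studentized range with k levels and
(k−1)(n−1) df. For k = 2 this reproduces the paired t-test p exactly
(q = √2·|t|). Stars: \*p<0.05, \*\*p<0.01, \*\*\*p<0.001, \*\*\*\*p<0.0001.

**Log Bayes factors** are BIC approximations,
logBF₁₀ ≈ (BIC_null − BIC_full)/2, from maximum-likelihood mixed models
with subject random intercepts (statsmodels MixedLM; optimizer falls back
from L-BFGS to Powell/BFGS on near-singular random-effect variances, and a
failed fit returns a flagged result). This approximates the sampling-based
default-prior analysis that dedicated Bayesian ANOVA software performs; the
trustworthy output is the evidence *category*, not the third decimal. Bands
follow the published criteria — anecdotal [0, 1.1), substantial [1.1, 2.3),
strong [2.3, 3.4] — with the unnamed gap (3.4, 4.6] labeled "very strong",
decisive above 4.6, and negative values mirrored as "favors null (…)".

**Power** for a within-subjects factor with m measurements uses the
noncentral-F convention df₁ = (m−1)ε, df₂ = (n−1)(m−1)ε,
λ = f²·n·m·ε/(1−ρ). The a priori mode returns the smallest n with power ≥
target. The function is validated against a vectorized Monte-Carlo oracle
(exchangeable-correlation normal model, one-way within-subject F) to
±0.03. Published "actual power" values for this paradigm cannot be
recomputed uniquely because the measurement count per test is unstated, so
no numeric equality with them is claimed.

## Problem sizes used in testing

Test and acceptance runs scale the simulations down, as their own design
choice, to: 60 trials/tone and frontal-only channels for the
20-cohort conditioning-trajectory check; 30 trials/tone, two extinction
sessions and 400 cohorts for type-I calibration; 150 trials/tone with a
shortened inter-trial interval (2–6 s) for AEP recovery (the ITI carries no
signal; only trial count and noise level matter for recovery); and 50
trials/tone for the full-schedule run in `scripts/acceptance.py`. Effect
amplitudes, noise levels and thresholds are never changed between test
regimes.

## What the synthetic cohorts do not show

The generator's kernels are smooth, stationary and exactly time-locked;
real DC recordings contain electrode drift nonstationarity, state-dependent
(arousal, movement) modulation, latency jitter, and artifact waveforms far
richer than square pulses. Passing tests therefore demonstrate that the
pipeline's arithmetic, contracts and statistical calibration are correct
under the stated model — not that the biological effect sizes or the QC
thresholds are right for any particular laboratory's data. The
sustained/reduced classifier and the rejection threshold in particular
should be re-examined against real averages before scientific use.

## Known limitations

- EDF output is 16-bit; signals spanning more than ~6.5 mV cannot be
  stored at 0.1 µV resolution and must use the HDF5 container.
- The integrated-area statistic is an absolute sum, hence positively biased
  under the null; it is analyzed across subjects (as in the original
  design), never tested against zero.
- The BIC Bayes factor ignores random slopes; models with strong
  subject-by-condition heterogeneity will be summarized optimistically.
- Ratios to the 300-ms value are undefined (NaN) whenever that value is
  within ε of zero, which is the norm for kernels whose shift begins
  exactly at 300 ms.
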