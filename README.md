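# dcpot

Analysis of **cortical direct-current (DC) potential responses during
reward-prediction conditioning** in rodents — from continuous event-marked
recordings through averaged event-related waveforms, DC and
auditory-evoked-potential (AEP) metrics, to the repeated-measures
statistical layer — together with a synthetic-data generator that emulates
the experiment so every stage is testable without animal data.

## The experiment and the statistics it needs

In the paradigm this package analyzes, an awake rat hears two tones
(e.g. 7 and 11 kHz) in random order, 150 presentations each per 1-h
session. During five daily *conditioning* sessions one tone (the
**rewarded** tone) is followed 1000 ms later by electrical stimulation of
the medial forebrain bundle (MFB), a classic reward pathway; the other
(**unrewarded**) tone is not. Five daily *extinction* sessions then present
both tones without stimulation. DC-coupled EEG (infinite time constant,
500 Hz) is recorded from frontal, parietal and temporal epidural
electrodes; unlike AC-coupled EEG it preserves the slow negative potential
shift that develops between tone and expected reward — the rodent analogue
of the human contingent negative variation.

For every subject × session × tone × channel the pipeline computes, from
the 150-trial average of epochs spanning −500…+1000 ms around tone onset
(baseline: mean of the 500 ms before the tone):

- **mean DC amplitude** over 600–1000 ms (µV), where tone discrimination is
  expressed;
- **integrated area** of the rewarded−unrewarded difference: the absolute
  sum of trapezoidal areas of the difference waveform every 1 ms from 300
  to 999 ms (µV·ms) — the discrimination statistic;
- **windowed DC areas** over 300–600 and 600–1000 ms (the "area" factor);
- **relative DC profiles** at 300…1000 ms re-referenced to the cohort
  grand mean at 300 ms, and the 600-ms / 1000-ms to 300-ms **ratios**;
- a **profile label**: *sustained* (negative shift held up to the expected
  stimulation time) vs *reduced* (shift returning toward baseline) vs
  *flat*;
- **AEP components** P1/N1/P2: P1 amplitude vs baseline, N1 (P1-to-N1) and
  P2 (N1-to-P2) peak-to-peak amplitudes, latencies from tone onset.

Inference is fully within-subject: two-way repeated-measures ANOVA over
factor pairs (session × condition, session × area, time × condition) with
each effect tested against its subject-by-effect interaction, Tukey
studentized-range post hocs, BIC-approximated log Bayes factors banded as
anecdotal (0–1.1), substantial (1.1–2.3), strong (2.3–3.4), very strong
(3.4–4.6] and decisive (>4.6), and noncentral-F power for within factors
(λ = f²·n·m·ε/(1−ρ)).

The synthetic generator reproduces the study conditions (11-session
schedule, 150 trials/tone, inter-trial intervals of 10–14 s during
conditioning and ~4 s during extinction, 1/f background, movement
artifacts, MFB stimulation artifact bursts, a planted high-noise subject
for the QC exclusion rule) and exposes a noise-free mode in which every
analysis stage can be checked against closed-form kernels.

## Worked example

```python
import dcpot as d

cfg = d.SimConfig(n_subjects=7, n_trials_per_tone=40,
                  channels=("frontal",), rng_seed=42)
bundle = d.run_full_experiment(
    cfg, sessions=["conditioning1", "conditioning3", "conditioning4",
                   "extinction1", "extinction2"])

print("excluded:", bundle.excluded_subjects)
aov = bundle.stats["conditioning_anova"].interaction
print(f"session x condition interaction: F({aov['df1']:.0f}, {aov['df2']:.0f})"
      f" = {aov['F']:.2f}, p = {aov['p']:.2e}")
for day in ("conditioning1", "conditioning4"):
    row = bundle.stats["conditioning_tukey_by_day"][day].table.iloc[0]
    print(f"{day}: rewarded-unrewarded = {row.mean_diff:+.1f} uV, "
          f"Tukey p = {row.p_tukey:.4f} {row.stars}")
row = bundle.stats["extinction_tukey_by_day"]["extinction2"].table.iloc[0]
print(f"extinction2: rewarded-unrewarded = {row.mean_diff:+.1f} uV, "
      f"Tukey p = {row.p_tukey:.4f} {row.stars}")
prof = bundle.metric("profile", subjects=bundle.included_subjects,
                     channel="frontal", session="conditioning4")
labels = {0.0: "flat", 1.0: "reduced", 2.0: "sustained"}
for tone in ("rewarded", "unrewarded"):
    print(f"day-4 {tone} profiles:",
          [labels[v] for v in prof[prof.tone == tone]["value"]])
bf = bundle.stats["conditioning_logbf"]
print(f"logBF10 = {bf.logbf10:.2f} ({bf.category})")
```

prints

```
excluded: ['S07']
session x condition interaction: F(2, 10) = 168.75, p = 1.97e-08
conditioning1: rewarded-unrewarded = -0.7 uV, Tukey p = 0.5867 ns
conditioning4: rewarded-unrewarded = -34.2 uV, Tukey p = 0.0000 ****
extinction2: rewarded-unrewarded = +0.5 uV, Tukey p = 0.7253 ns
day-4 rewarded profiles: ['sustained', 'sustained', 'sustained',
                          'sustained', 'sustained', 'sustained']
day-4 unrewarded profiles: ['reduced', 'reduced', 'reduced',
                            'reduced', 'reduced', 'reduced']
logBF10 = 46.80 (decisive)
```

Reading: the planted high-noise animal is removed by quality control,
leaving n = 6. On conditioning day 1 the two tones evoke indistinguishable
negative shifts; by day 4 the rewarded tone's shift is ~34 µV more negative
over 600–1000 ms (Tukey p < 0.0001) and every subject shows the
*sustained*-vs-*reduced* profile split — the electrophysiological signature
of learned reward prediction. By extinction day 2 the difference is gone.

A command-line interface wraps the same stages:

```sh
dcpot all --config config.yaml --seed 7 --outdir run/   # simulate + analyze
dcpot analyze run/data --outdir run/report              # your own data
```

Recordings are read/written as HDF5 (lossless) or 16-bit EDF (≤0.1 µV
quantization); events are BIDS-style TSV (`onset  tone  session_day
stim_followed`).

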