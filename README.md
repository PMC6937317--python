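# lfpbeta

Analysis pipeline for learning-related beta-band (17–28 Hz) oscillations in
multi-site LFP recordings, driven by a synthetic-data generator so every
stage is testable end to end without any recorded data.

Stages:

- **simulate** — task-structured multichannel sessions (1/f background,
  respiration-locked slow wave, Gaussian-envelope beta bursts with per-trial
  gain schedules and controllable cross-channel phase coupling, optional
  broadband movement artifacts) with full ground truth.
- **timefreq** — Morlet wavelet time-frequency maps computed in the
  spectral domain (σ = 5π analysis, unit-amplitude normalization), plus
  anti-aliased downsampling to the 200 Hz analysis rate.
- **artifacts** — MAD-threshold detection of high-frequency (90–250 Hz)
  transients at native sampling rate (threshold = median + 25·MAD) and the
  two trial-exclusion window rules.
- **beta** — per-trial log-normalized beta amplitude (frequency-max /
  time-average in the [−400, +100] ms window around nose-poke end, ratio to
  a 240 s baseline of 500 ms periods), 20-trial odor-balanced blocks, and
  the per-trial time of maximal beta.
- **connectivity** — debiased WPLI² between structure pairs at nose-poke
  start vs time of maximal beta (trials 11–40 after exclusions), with a
  2000-surrogate label-swap max-statistic test and network/hub summaries.
- **behavior** — session performance, 30-trial block criterion (80% on two
  consecutive blocks, three consecutive days), S/LC0–LC3 labeling, reversal
  pre-learning detection.
- **stats** — percentile bootstrap CIs (per-rat medians before across-rat
  means), Spearman hub-vs-amplitude correlation, tidy CSV exports.

## CLI

```sh
# simulate an 8-session acquisition sequence to HDF5 + CSV + ground truth
lfpbeta simulate --scenario acquisition --n-sessions 8 --seed 1 --out sim_out

# full pipeline on a simulated scenario (tables + manifest in run_out/)
lfpbeta all --scenario acquisition --n-sessions 4 --seed 1 --out run_out

# or on recorded/stored sessions
lfpbeta validate sim_out/session_00.h5
lfpbeta all --out run_out sim_out/session_*.h5

lfpbeta report run_out
```

Config files (YAML/JSON) mirror the `RunConfig`/`SimConfig` fields; the
`--seed` flag overrides the master seed. Exit codes: 0 ok, 2 config error,
3 data error. Outputs are tidy CSVs (`beta_trials`, `beta_blocks`,
`connectivity`, `network`, `session_labels`, `artifact_epochs`) plus a
`manifest.json` recording config and versions; reruns with identical
config and seed are byte-identical.

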