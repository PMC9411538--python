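# evlock

Event-locked analysis of basal-forebrain-style in-vivo recordings and the
accompanying nociceptive behavior assays, packaged as a tested, reusable
pipeline:

- **`evlock.lfp`** — LFP preprocessing (3rd-order Chebyshev-I low-pass,
  0.5 dB ripple, 200 Hz edge, decimation to 1 kHz), complex-Morlet power
  spectrograms on a 0.5-Hz grid at 1-ms resolution, per-trial baseline
  normalization to percent change, band summaries (theta 4–8, alpha 8–14,
  beta 14–30, gamma 30–100 Hz) over the 2-s post-stimulus window, 100-ms
  time courses, and per-filament-force response curves.
- **`evlock.units`** — stimulation-responsive unit detection (250-ms PSTH
  bins, z-scored against the 3-s pre-stimulus baseline, |z| > 3.09 rule,
  ≥1 Hz / ≥3 withdrawal-trial inclusion filters, max/min z magnitudes) and
  waveform-based unit typing (six firing/waveform parameters; k-means k=2
  on asymmetry × trough-to-return, or t-SNE + k-means in exploratory mode).
- **`evlock.behavior`** — Dixon up-down 50% withdrawal thresholds on the
  7-filament von Frey set, stimulus–response curves, thermal latencies with
  a 30-s cutoff, and nocifensive-duration tallies over a 5-min window.
- **`evlock.stats`** — one-sample t, repeated-measures one-way ANOVA with
  Dunnett many-to-one comparisons, two-way ANOVA with Sidak post-hoc
  contrasts, Pearson chi-square contingency tests (with pairwise mode),
  ROUT outlier identification (Q = 0.5%), and normal critical values.
- **`evlock.synth`** — a deterministic synthetic-session generator (LFP
  with band-specific stimulus-locked power gains, excited / inhibited /
  unresponsive Poisson units, broad / narrow waveform templates, trial
  tables, psychometric up-down sequences) so the full pipeline is testable
  without any recorded data.
- **`evlock.io` / `evlock.pipeline` / `evlock.cli`** — flat-binary + JSON
  session format, CSV tables, schema-checked configuration, and the
  end-to-end driver.

## CLI

```sh
evlock simulate   --config sim.yaml --out session/ --seed 1
evlock spectrogram --session session/ --out spectral/
evlock units      --session session/ --out unitout/
evlock classify   --features unitout/unit_features.csv --out classes.csv
evlock behavior   --in behavior_inputs/ --out behavior_out/
evlock report     --config run.yaml --out report/ --seed 1   # full pipeline
```

Exit codes: 0 ok, 2 validation error, 3 stage failure. Every output file
carries the package version, a configuration hash, and the seed.

A session directory contains `lfp.bin` (float32 LE) + `lfp.json`
(sampling rate, sample count, unit metadata), `spikes.csv`,
`waveforms.csv`, `trials.csv` (onset_s, force_g, withdrawal, latency_s)
and, for synthetic sessions, `ground_truth.json`.

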