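# ppdbs

Analysis pipeline for subcortical local field potentials evoked by **paired
deep-brain-stimulation pulses**, together with a synthetic-session generator
that provides ground truth for every stage:

- **`ppdbs.simulate`** — paired-pulse sessions at 100 kHz: randomized
  log-spaced ISI schedule (0.18–30 ms, charge-balanced polarity reversal),
  polarity-locked stimulus artifact, biphasic early response (R1) with
  absolute/relative refractory dynamics and latency delays, late damped
  oscillation (ERNA) with ISI-dependent facilitation and latency hastening,
  per-channel beta background. Fully deterministic per seed.
- **`ppdbs.core_io`** — domain types (recording, stimulus events, feature
  tables) and EDF + CSV-sidecar readers/writers (millivolts internally,
  microvolts in EDF).
- **`ppdbs.preprocess`** — bipolar / common-average re-referencing, epoching
  with pair-anchored baselines, polarity-fold artifact cancellation,
  conditioning-template construction and subtraction.
- **`ppdbs.features`** — R1 peak/trough and ERNA peak detection, rectified
  response areas, paired-pulse-ratio (PPR) curves, absolute/relative
  refractory-period estimation (run-of-3 threshold scan rules), latency
  shifts.
- **`ppdbs.spectral`** — analytic Morlet wavelet filter bank (log-spaced,
  12 voices/octave), beta-band (14–30 Hz) power, within-subject z-scores,
  beta ↔ evoked-feature association across directional contacts.
- **`ppdbs.stats_report`** — Freeman–Halton r×c exact test by full
  enumeration (seeded Monte Carlo fallback), two-tailed binomial test,
  paired-t and percent-change summaries, bundled per-trajectory reference
  tables, and the end-to-end `run_pipeline` orchestrator.

## CLI

```sh
# synthetic session -> EDF + events.csv + ground_truth.json
ppdbs simulate --seed 1 --out session/

# epoch, fold polarity, build the conditioning template
ppdbs preprocess --in session/ --montage bipolar_rings --out pre/

# resting beta power per channel
ppdbs spectral --in session/ --band 14:30 --out beta.csv

# full chain on a fresh simulated session (features.csv, refractory.json, stats.json)
ppdbs simulate-run --seed 1 --out rundir/

# exact tests + summaries over the bundled reference tables
ppdbs stats --out stats.json

# markdown report from a run directory
ppdbs report --in rundir/ --out report.md
```

Generator parameters can be overridden with `--config cfg.json` (JSON object
of `SimConfig` fields).

## Layout

```
src/ppdbs/          package (one module per pipeline stage; data/ holds the
                    bundled reference CSVs)
tests/              pytest suite incl. acceptance criteria
scripts/acceptance.py
```
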