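# fidgetkit

Quantify fidgeting from task-synchronized actigraphy. The package turns
raw 3-axis accelerometer recordings into band-limited movement signals and
computes three per-trial fidget variables, fits ex-Gaussian reaction-time
models for Flanker sessions, and runs the companion trial-grouped and
correlation analyses — all validated end-to-end against a seeded synthetic
generator with planted ground truth.

## Pipeline

1. **differentiate** — per-axis forward first difference of the position
   samples, scaled by the sampling interval.
2. **band_reconstruct** — FFT, zero every bin outside a configurable
   frequency band (default 1–20 Hz), inverse FFT.
3. **detect_peaks** — strict local maxima above a threshold (default:
   3 × SD of a band-limited stationary calibration recording).
4. **epoch_metrics** — per trial (default window: 1000 ms stimulus +
   1000 ms ITI) compute:
   - *number of fidgets*: peak count,
   - *fidget time variability*: population variance (ms²) of consecutive
     inter-peak intervals (undefined below 3 peaks),
   - *fidget intensity*: mean peak height (undefined with no peaks).
   Axes are combined by summation; the same rule combines sensors
   (arm + leg).
5. **analysis** — paired correct/incorrect and Q1/Q4 (first/last 30
   trials) comparisons, median splits on ex-Gaussian mu/sigma/tau, and
   six-predictor linear-model correlations to rating-scale totals
   (BAARS-IV, BDEFS Section 5, ARI).

## CLI

```sh
fidgetkit simulate out/session --seed 1            # synthetic session (CSV + JSON)
fidgetkit calibrate out/cal.csv --kind stationary  # calibration + threshold hint
fidgetkit extract out/session/actigraphy_wrist.csv out/session/events.csv \
    out/metrics.csv --band-low 1 --band-high 20 --threshold 0.2
fidgetkit fit-rt out/session/events.csv out/rt.json
fidgetkit report out/session out/report            # full pipeline
fidgetkit analyze participants.csv out/analysis.json
```

All commands honor `--seed`; reports embed the resolved configuration.

## Notes

- Signal units are arbitrary: device amplitude scales are not
  standardized, so only conventions (not absolute magnitudes) are
  reproducible.
- The synthetic generator writes the *movement* signal first and
  integrates it into position samples, so the pipeline's derivative step
  recovers planted bouts exactly.
- Filtering is applied to the whole-session movement signal once, then
  epoched; per-trial filtering is possible via `band_reconstruct` on
  epoch slices but is not the default.
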