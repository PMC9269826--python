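# rppgvitals

Contactless heart-rate (HR) and blood-oxygenation (SpO2) estimation from
camera recordings of a face. The package consumes per-region, per-channel
*pooled* skin-pixel time series — the mean intensity of each face region
(forehead, right/left cheek, cheeks+nose, lips) in five channels (R, G, B,
grey, infrared) per frame, with timestamps and face-to-camera distance — and
turns them into per-window vital-sign estimates. It is aimed at researchers
working on remote photoplethysmography (rPPG) who need a reproducible,
hardware-free post-processing chain: a synthetic-signal generator with known
ground truth makes every stage testable without any camera data.

## Method

Blood volume changes with each heartbeat modulate how much light skin
reflects, so the pooled intensity of a skin region carries a small cardiac
oscillation. For every 15-s window, slid by 1 s:

1. **Align** — each region's five channels are linearly interpolated onto the
   colour stream's even time grid (the IR stream may run on its own clock).
2. **Pre-process** — one of seven numbered step combinations; the default
   rule is fps-adaptive: detrend → interpolate → Hamming window → L2-normalise
   (technique 6) at ≥ 15 fps, with an extra 2× FFT upsampling step
   (technique 7) below 15 fps.
3. **Separate** — candidate pulse components via FastICA (default), PCA,
   PCA→ICA, JADE (fourth-order cumulant joint diagonalisation, implemented
   here), spectral embedding, or none.
4. **Score** — each candidate's magnitude spectrum is masked to the cardiac
   passband 0.66–3.33 Hz (39–200 BPM) and its dominant peak is scored by

   SNR = peak magnitude / mean in-band magnitude.

   The best-SNR candidate across all regions × components wins the window and
   HR = 60 × peak frequency.
5. **SpO2** — the winning region's band-filtered grey waveform is inverse
   transformed; at each pulse peak the raw red/IR/distance samples give a
   ratio r = (ε_red_oxy/ε_ir_oxy)·(IR·d/RED)/52, converted through
   oxy-/deoxy-haemoglobin extinction coefficients:
   SpO2 = 100·(ε_red_deoxy − r·ε_ir_deoxy)/(ε_ir_oxy + ε_red_deoxy −
   ε_ir_deoxy − ε_red_oxy) − C, with C = 6 %.
6. **Gate** — a new estimate is held back (the previous one is re-emitted,
   flagged `accepted=False`) when its SNR is below 5.0 or either vital jumps
   more than 18 % from the previous value: vitals change gradually, so a
   one-second doubling is noise.

Estimates are compared against a per-second reference trace (mean difference,
mean absolute difference, population-σ of the differences, RMSE, Pearson r),
aligning each window to the reference value of its last second by default.

## Worked example

```
$ rppgvitals simulate --out demo --seed 42
wrote demo/region_store.csv and demo/ground_truth.csv
$ rppgvitals process --store demo/region_store.csv --out demo/estimates.csv --seed 42
wrote 46 window estimates to demo/estimates.csv
$ head -3 demo/estimates.csv
window_end_s,hr_bpm,spo2_pct,snr,region,provenance,accepted
15,72.00303369082353,96.00055637237514,8.114464453541771,forehead,T6/fastica[joint]:comp1,True
16,72.00640746974527,96.00085428561664,8.55971203813242,forehead,T6/fastica[joint]:comp1,True
```

The simulated recording is 60 s at 30 fps with HR 72 BPM and SpO2 96 %; a
60-s recording yields 46 sliding 15-s windows. Each row is one window: the
estimated HR and SpO2, the winning candidate's SNR (here ≈ 8, comfortably
above the 5.0 acceptance threshold), which region and component produced it
(`T6/fastica[joint]:comp1` = technique 6, FastICA on all five channels
jointly, component 1), and whether the gate accepted the new measurement.

```
$ rppgvitals evaluate --estimates demo/estimates.csv --truth demo/ground_truth.csv --out demo/report.csv
```

reports RMSE 0.008 BPM for HR and 0.002 % for SpO2 on this clean synthetic
recording (Pearson r is undefined — NaN — because the reference is constant).
`rppgvitals grid` sweeps technique × separation combinations and writes one
metric row per configuration and vital.

The same API is available in Python (`rppgvitals.process_participant`,
`rppgvitals.SimulationConfig`, ...), and `rppgvitals simulate --config
sim.yaml` accepts a YAML file mirroring `SimulationConfig` (HR/SpO2
trajectories, frame rates, noise, distance).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
generates a seeded synthetic recording, runs the full pipeline on it, and
prints the HR and SpO2 error metrics against the generated ground truth. The
JSON output is a manifest of numeric reporting targets, which is empty for
this package.
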