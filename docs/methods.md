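# Methods

## Signal model

The pooled intensity of a skin region in channel *c* at time *t* is modelled
as

    v_c(t) = B_c + A_c · sin(2π φ(t)) + s·t + ε,    ε ~ N(0, σ²)

where `B_c` is the DC reflectance level, `A_c` the cardiac (pulsatile)
amplitude, `s` a slow illumination trend and `φ(t) = ∫ HR(u)/60 du` the
cumulative cardiac phase (piecewise-constant instantaneous frequency per
second). The pipeline only uses the fundamental spectral peak of the pulse,
so the simulator's waveform is a pure sinusoid; real PPG waveforms carry
harmonics and a dicrotic notch that this generator deliberately omits (an
in-band harmonic would only matter if it beat the fundamental's SNR, which
the pure-sine model cannot probe).

Oxygen saturation enters through the ratio of IR to red reflectance. The
forward conversion used by the estimator is, per pulse peak,

    r    = (ε_red_oxy / ε_ir_oxy) · (IR · d / RED) / 52
    SpO2 = 100 · (ε_red_deoxy − r·ε_ir_deoxy) / (ε_ir_oxy + ε_red_deoxy − ε_ir_deoxy − ε_red_oxy) − C

with distance `d` in metres, the empirical IR/R scaler 52, offset `C = 6 %`,
and molar extinction coefficients ε of oxy-/deoxy-haemoglobin (860 nm row for
IR; arithmetic mean over 600–700 nm for the red band). The simulator sets the
per-second IR DC level by algebraically inverting this conversion at the
configured SpO2 and distance, so generator → pipeline is the identity on SpO2
in the noise-free limit. This encodes oxygenation in the DC ratio rather than
in AC ratios (as finger oximeters do), because the estimator consumes raw
intensities at pulse-peak indices of a DC-dominated series.

### Extinction coefficients

`rppgvitals.spo2` embeds the red-band rows at 10 nm spacing plus the 860 nm
row, transcribed from the standard public compilation of haemoglobin molar
extinction spectra (units cm⁻¹/M). The red-band means are recomputed from the
embedded rows at load time. Transcription was done from memory of that table
rather than from a fresh download; the values satisfy the physical ordering
constraints (ε_ir_oxy > ε_ir_deoxy above the ~800 nm isosbestic point,
ε_red_deoxy > ε_red_oxy in the red band) and the package's results depend on
them only through the ratio conversion, which the simulator inverts with the
*same* table — so round-trip accuracy is exact by construction, while absolute
agreement with any particular published SpO2 calibration is not claimed.

## Parameters that matter

| Parameter | Default | Units | Why |
|---|---|---|---|
| window / step | 15 / 1 | s | 15 s gives 1/15 Hz = 4 BPM spectral resolution; 1 s step matches per-second references |
| passband | 0.66–3.33 | Hz | plausible cardiac range, 39–200 BPM |
| SNR threshold | 5.0 | — | below it a window's estimate is held |
| deviation factor | 0.18 | — | max relative change of HR/SpO2 between consecutive windows |
| technique rule | auto | — | 7 (with 2× upsampling) below 15 fps, else 6 |
| ICA repeats | 1 (≤ 3) | — | re-running FastICA on its own output; more than three passes has no effect, so repeats are clamped |
| scaling / offset C | 52 / 6 | — / % | empirical constants of the ratiometric conversion |

Simulator defaults state a realistic home recording: 60 s, 30 fps colour and
IR, 2 ms timestamp jitter, HR 72 BPM, SpO2 96 %, distance 0.6 m, baselines
70–120 camera units with pulsatile amplitudes 1–2 % of baseline (the
pulsatile fraction of skin reflectance is of order 1 %), noise σ = 0.15
(10 % of the strongest amplitude), no trend. Region gains (forehead 1.0 …
lips 0.8) reflect that perfusion-rich central regions give stronger pulse
signals.

## Numerical and design choices

- **SNR denominator.** The spectral SNR divides the dominant peak magnitude
  by the *mean of in-band magnitudes after bandpass* (peak bin included).
  Including out-of-band or DC bins would make the score depend on trends the
  bandpass already rejects. A flat in-band spectrum scores exactly 1.
- **Bandpass as a frequency-domain mask**, not a time-domain filter: the
  pipeline works on spectra, and a mask is idempotent and phase-exact for the
  inverse transform used by the SpO2 path.
- **Peak detection** uses local maxima with no prominence threshold; a flat
  two-bin plateau resolves to the lower-frequency bin, and the downstream SNR
  threshold provides the quality gate.
- **Ties** in best-candidate selection keep the earliest candidate in
  region-order × channel-order, making runs deterministic.
- **fps per window** is the minimum per-second frame count across the colour
  and IR streams inside the window (conservative: the slowest stream limits
  the usable resolution).
- **Recording duration** for windowing is the ceiling of the last timestamp,
  so a nominal 60-s recording whose final frame lands at 59.98 s still yields
  the full 46 windows.
- **Degenerate separation.** Non-finite components are flagged, never
  silently dropped; if a window yields no finite candidate at all the raw
  channel rows are used as candidates, so the first window (which has no
  previous estimate to inherit) always produces a value.
- **First window** is accepted unconditionally — there is no previous value
  for the gate to compare against.
- **Per-peak SpO2 values are averaged** (not medianed) within a window, and
  the HR candidate's SNR serves as the joint quality proxy for both vitals in
  the gate.
- **Distance lookup** (and raw red/IR lookup at pulse-peak times) is
  nearest-timestamp; the streams run on different clocks and no alignment
  rule is canonical.
- **Outputs are clipped** to [0, 100] % for SpO2; HR is inherently confined
  to the passband (39.6–199.8 BPM) when accepted.
- **Detrending** is least-squares linear. Note that a sampled sinusoid is not
  exactly orthogonal to a line on a finite grid, so detrending a clean tone
  perturbs it slightly; only the removal of an *added* line is exact.
- **"Smooth"** in techniques 3–5 is a centred moving average (window 5); those
  techniques are registered for completeness but are not recommended — heavy
  smoothing plus median filtering suppresses the pulse band itself.
- **FastICA settings**: unit-variance whitening, parallel estimation,
  tolerance 1e-4, max 500 iterations, seeded from the pipeline config for
  determinism. Spectral embedding uses a nearest-neighbour affinity with as
  many components as channels, treated as candidate time series exactly like
  ICA components.

## What a green test establishes — and what it does not

The synthetic generator produces exactly the structure the pipeline assumes:
a sinusoidal pulse, Gaussian noise, linear trends, per-second piecewise
constant vitals, and an IR/red DC ratio consistent with the estimator's own
conversion. Green tests therefore establish internal consistency, correct
wiring of every stage, parameter recovery under noise and low frame rates,
and the gate's behaviour — they do **not** establish accuracy on real faces,
where motion, illumination changes, skin-tone differences, makeup and facial
hair produce structured (non-Gaussian, non-stationary) artefacts that this
generator does not emulate. Amplitudes are free configuration knobs, not
calibrated to melanin or camera response.

## Known limitations

- JADE is validated on toy mixtures only; its numerical behaviour on large
  ill-conditioned channel sets is untested.
- The evaluation assumes the reference trace starts at the same instant as
  the recording; there is no cross-correlation lag search.
- The region-store CSV stores the distance trace on the first region's red
  rows; distance clocks that differ from the colour frames are nearest-matched
  on write (lossy round trip in that corner case).
- `per_channel` separation mode degenerates to scaling for single-channel
  ICA/PCA; it exists for parity of the method registry.
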