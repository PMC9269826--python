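"""Synthetic recording generator with the statistical structure the pipeline assumes.

The simulator emulates what a camera sees of a face: each pooled channel series
is a DC baseline plus a small cardiac sinusoid (skin flashing darker/lighter
with the pulse), an optional linear illumination trend, and white noise, sampled
at a configurable — possibly low and jittered — frame rate.  Oxygen saturation
is encoded in the DC ratio of the IR channel to the red channel: for every
second the IR level is derived by algebraically inverting the ratiometric SpO2
conversion at the configured distance, so that running the pipeline forward
recovers the configured SpO2 trajectory.

Defaults state a realistic home recording: 60 s at 30 fps, HR 72 BPM, SpO2 96 %,
0.6 m from the camera, pulsatile amplitude 1-2 % of the baseline intensity and
noise at 10 % of the amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .io import (
    ChannelSeries,
    GroundTruthTrace,
    RegionStore,
    REGIONS,
    TimeSeries,
    compute_grey,
)
from .spo2 import Spo2Params, load_extinction_table, ratio_for_spo2

#: relative cardiac-signal strength of each face region (forehead strongest).
REGION_GAIN = {
    "forehead": 1.0,
    "right_cheek": 0.9,
    "left_cheek": 0.9,
    "cheeks_nose": 0.95,
    "lips": 0.8,
}


@dataclass
class SimulationConfig:
    duration_s: int = 60
    fps_colour: float = 30.0
    fps_ir: float = 30.0
    fps_colour_per_second: list | None = None  # optional per-second overrides
    fps_ir_per_second: list | None = None
    jitter_ms: float = 2.0
    hr_trajectory: tuple = ("constant", 72.0)  # ("ramp", a, b) | ("walk", start, sd)
    spo2_trajectory: tuple = ("constant", 96.0)  # ("ramp", a, b)
    baseline: dict = field(
        default_factory=lambda: {"R": 120.0, "G": 90.0, "B": 70.0, "IR": 100.0}
    )
    amplitude: dict = field(
        default_factory=lambda: {"R": 1.5, "G": 2.0, "B": 1.0, "IR": 1.5}
    )
    noise_sd: float = 0.15
    trend_slope: float = 0.0  # intensity units per second
    distance: tuple = ("constant", 0.6)  # metres; ("ramp", a, b)
    participant_id: str = "SYN001"
    state: str = "resting1"
    seed: int = 0
    spo2_params: Spo2Params = field(default_factory=Spo2Params)

    def __post_init__(self):
        if self.duration_s < 1:
            raise ConfigurationError("duration must be at least 1 s")
        for fps in (self.fps_colour, self.fps_ir):
            if fps < 3:
                raise ConfigurationError("fps must be >= 3")
        if not any(a > 0 for a in self.amplitude.values()):
            raise ConfigurationError("at least one channel needs a positive amplitude")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")


def _trajectory(spec, n: int, rng, low: float, high: float) -> np.ndarray:
    kind = spec[0]
    if kind == "constant":
        vals = np.full(n, float(spec[1]))
    elif kind == "ramp":
        vals = np.linspace(float(spec[1]), float(spec[2]), n)
    elif kind == "walk":
        steps = rng.normal(0.0, float(spec[2]), size=n)
        steps[0] = 0.0
        vals = np.clip(float(spec[1]) + np.cumsum(steps), low, high)
    else:
        raise ConfigurationError(f"unknown trajectory kind {kind!r}")
    if np.any((vals < low) | (vals > high)):
        raise ConfigurationError(f"trajectory leaves the valid range [{low}, {high}]")
    return vals


def generate_ground_truth(config: SimulationConfig) -> GroundTruthTrace:
    """Per-second reference HR/SpO2 following the configured trajectories."""
    rng = np.random.default_rng(config.seed)
    n = config.duration_s
    hr = _trajectory(config.hr_trajectory, n, rng, 39.0, 200.0)
    spo2 = _trajectory(config.spo2_trajectory, n, rng, 70.0, 100.0)
    return GroundTruthTrace(seconds=np.arange(n), hr_bpm=hr, spo2_pct=spo2)


def _frame_times(duration_s: int, fps: float, per_second, jitter_ms: float, rng):
    """Timestamps in ms: ~fps frames per wall-clock second with jitter."""
    times = []
    for s in range(duration_s):
        n = int(round(per_second[s] if per_second is not None else fps))
        if n < 1:
            continue
        base = s * 1000.0 + (np.arange(n) + 0.5) * (1000.0 / n)
        if jitter_ms > 0:
            base = base + rng.uniform(-jitter_ms, jitter_ms, size=n)
        base = np.clip(base, s * 1000.0 + 1e-3, (s + 1) * 1000.0 - 1e-3)
        times.append(np.sort(base))
    t = np.concatenate(times)
    # enforce strict monotonicity in the (rare) event jitter creates ties
    t = np.maximum.accumulate(t + np.arange(len(t)) * 1e-9)
    return t


def _phase(t_ms: np.ndarray, hr_bpm: np.ndarray) -> np.ndarray:
    """Cumulative cardiac phase (in cycles) at each timestamp.

    The instantaneous frequency is piecewise constant per second: HR(s)/60 Hz.
    """
    freq = np.asarray(hr_bpm, dtype=float) / 60.0
    cum = np.concatenate([[0.0], np.cumsum(freq)])
    t_s = t_ms / 1000.0
    sec = np.clip(t_s.astype(int), 0, len(freq) - 1)
    return cum[sec] + freq[sec] * (t_s - sec)


def generate_region_store(truth: GroundTruthTrace, config: SimulationConfig) -> RegionStore:
    """Synthesize a full five-region, five-channel recording for a truth trace."""
    rng = np.random.default_rng(config.seed)
    table = load_extinction_table()
    n_sec = min(config.duration_s, len(truth))

    t_colour = _frame_times(
        n_sec, config.fps_colour, config.fps_colour_per_second, config.jitter_ms, rng
    )
    t_ir = _frame_times(
        n_sec, config.fps_ir, config.fps_ir_per_second, config.jitter_ms, rng
    )

    dist_per_sec = _trajectory(config.distance, n_sec, rng, 0.05, 9.99)

    # per-second IR/red DC ratio that makes the forward SpO2 conversion exact
    r_target = np.array(
        [ratio_for_spo2(s, table, config.spo2_params) for s in truth.spo2_pct[:n_sec]]
    )
    rho = (
        r_target
        * config.spo2_params.scaling
        * table.ir_oxy
        / (table.red_oxy * dist_per_sec)
    )

    phase_colour = _phase(t_colour, truth.hr_bpm[:n_sec])
    phase_ir = _phase(t_ir, truth.hr_bpm[:n_sec])
    pulse_colour = np.sin(2 * np.pi * phase_colour)
    pulse_ir = np.sin(2 * np.pi * phase_ir)
    sec_colour = np.clip((t_colour / 1000.0).astype(int), 0, n_sec - 1)
    sec_ir = np.clip((t_ir / 1000.0).astype(int), 0, n_sec - 1)

    regions = {}
    for region in REGIONS:
        gain = REGION_GAIN[region]
        channels = {}
        for name in ("R", "G", "B"):
            clean = (
                config.baseline[name]
                + gain * config.amplitude[name] * pulse_colour
                + config.trend_slope * t_colour / 1000.0
            )
            noise = rng.normal(0.0, config.noise_sd, size=len(t_colour))
            channels[name] = ChannelSeries(
                timestamps=t_colour.copy(), values=clean + noise, channel=name
            )
        channels["Gy"] = ChannelSeries(
            timestamps=t_colour.copy(),
            values=compute_grey(
                channels["R"].values, channels["G"].values, channels["B"].values
            ),
            channel="Gy",
        )
        # IR level is the red level scaled by the per-second SpO2/distance ratio,
        # so the pulsatile fraction matches and the DC ratio encodes SpO2 exactly
        red_clean = config.baseline["R"] + gain * config.amplitude["R"] * pulse_ir
        ir_clean = rho[sec_ir] * red_clean + config.trend_slope * t_ir / 1000.0
        ir_noise = rng.normal(0.0, config.noise_sd, size=len(t_ir))
        channels["IR"] = ChannelSeries(
            timestamps=t_ir.copy(), values=ir_clean + ir_noise, channel="IR"
        )
        regions[region] = channels

    distance = TimeSeries(timestamps=t_colour.copy(), values=dist_per_sec[sec_colour])
    store = RegionStore(
        participant_id=config.participant_id,
        state=config.state,
        regions=regions,
        distance=distance,
    )
    store.validate()
    return store
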