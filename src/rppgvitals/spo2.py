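"""Ratiometric SpO2 from red/IR intensities and haemoglobin extinction spectra.

Arterial oxygen saturation modulates how strongly blood absorbs red versus
near-infrared light: deoxygenated haemoglobin dominates absorption in the red
band (600-700 nm) while oxygenated haemoglobin absorbs more at 860 nm.  Per
detected pulse peak the pipeline forms a distance-compensated IR-to-red
intensity ratio

    r = (eps_red_oxy / eps_ir_oxy) * (IR * d / RED) / scaling

(scaling = 52, an empirical IR/R scaler) and converts it through the extinction
coefficients to a percentage

    SpO2 = 100 * (eps_red_deoxy - r * eps_ir_deoxy)
                / (eps_ir_oxy + eps_red_deoxy - eps_ir_deoxy - eps_red_oxy) - C

with a constant offset C (default 6 %).  The per-window value is the mean over
the pulse peaks of the band-filtered grey waveform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import ConfigurationError, NoPeakError, ValidationError
from .io import ChannelSeries, TimeSeries, _nearest_values
from .spectrum import BAND_HIGH, BAND_LOW

# Molar extinction coefficients of oxy-/deoxy-haemoglobin (cm^-1 / M), red band
# sampled at 10 nm over 600-700 nm, transcribed from the standard public
# compilation of haemoglobin optical absorption.
# Columns: wavelength_nm, oxy, deoxy.
RED_BAND_ROWS = (
    (600.0, 3200.0, 14677.2),
    (610.0, 1506.0, 9443.8),
    (620.0, 942.0, 6509.6),
    (630.0, 610.0, 5148.8),
    (640.0, 442.0, 4345.2),
    (650.0, 368.0, 3750.12),
    (660.0, 319.6, 3226.56),
    (670.0, 294.0, 2795.12),
    (680.0, 277.6, 2407.92),
    (690.0, 276.0, 2051.96),
    (700.0, 290.0, 1794.28),
)
#: 860 nm row (the IR illumination wavelength): (oxy, deoxy).
IR_ROW = (1058.0, 726.44)


@dataclass
class ExtinctionTable:
    """Extinction coefficients at the IR wavelength and the red-band mean."""

    ir_oxy: float
    ir_deoxy: float
    red_oxy: float
    red_deoxy: float
    source: str = "public haemoglobin extinction compilation"

    def __post_init__(self):
        if min(self.ir_oxy, self.ir_deoxy, self.red_oxy, self.red_deoxy) <= 0:
            raise ValidationError("extinction coefficients must be positive")
        if self.ir_oxy <= self.ir_deoxy:
            raise ValidationError("above ~800 nm oxy-Hb must absorb more than deoxy-Hb")
        if self.red_deoxy <= self.red_oxy:
            raise ValidationError("in the red band deoxy-Hb must absorb more than oxy-Hb")

    @property
    def denominator(self) -> float:
        return self.ir_oxy + self.red_deoxy - self.ir_deoxy - self.red_oxy


@dataclass
class Spo2Params:
    """Tunables of the ratiometric conversion."""

    scaling: float = 52.0  # empirical IR/R scaling factor
    offset_c: float = 6.0  # constant offset subtracted from the final percentage

    def __post_init__(self):
        if self.scaling <= 0:
            raise ValidationError("scaling must be positive")


def load_extinction_table() -> ExtinctionTable:
    """Embedded coefficients: 860 nm row plus the mean over the red-band rows."""
    rows = np.array(RED_BAND_ROWS)
    return ExtinctionTable(
        ir_oxy=IR_ROW[0],
        ir_deoxy=IR_ROW[1],
        red_oxy=float(rows[:, 1].mean()),
        red_deoxy=float(rows[:, 2].mean()),
    )


def ir_to_red_ratio(ir_value: float, red_value: float, dist: float,
                    table: ExtinctionTable, params: Spo2Params) -> float:
    """Distance-compensated, extinction-normalised IR/red intensity ratio."""
    if red_value <= 0:
        raise ValidationError("red intensity must be positive")
    if dist <= 0:
        raise ValidationError("distance must be positive")
    return (table.red_oxy / table.ir_oxy) * (ir_value * dist / red_value) / params.scaling


def spo2_from_ratio(r: float, table: ExtinctionTable, params: Spo2Params) -> float:
    """Convert a ratio to an oxygen-saturation percentage (clipped to [0, 100])."""
    denom = table.denominator
    if denom == 0:
        raise ConfigurationError("degenerate extinction table (zero denominator)")
    value = 100.0 * (table.red_deoxy - r * table.ir_deoxy) / denom - params.offset_c
    return float(np.clip(value, 0.0, 100.0))


def ratio_for_spo2(spo2: float, table: ExtinctionTable, params: Spo2Params) -> float:
    """Algebraic inverse of :func:`spo2_from_ratio` (used by the simulator)."""
    denom = table.denominator
    if denom == 0:
        raise ConfigurationError("degenerate extinction table (zero denominator)")
    r = (table.red_deoxy - (spo2 + params.offset_c) * denom / 100.0) / table.ir_deoxy
    if r <= 0:
        raise ConfigurationError(
            f"SpO2 target {spo2} is outside the invertible range for these coefficients"
        )
    return r


def spo2_window(grey_values, grey_timestamps_ms, raw_red: ChannelSeries,
                raw_ir: ChannelSeries, distance: TimeSeries,
                table: ExtinctionTable, params: Spo2Params,
                band=(BAND_LOW, BAND_HIGH)) -> float:
    """SpO2 for one window from the grey pulse waveform and raw red/IR series.

    The grey series (evenly sampled) is band-filtered in the frequency domain
    and inverse-transformed to a pulse waveform; at each pulse peak the
    nearest-timestamp raw red, raw IR and distance samples feed the ratiometric
    conversion, and the per-peak percentages are averaged.
    """
    grey = np.asarray(grey_values, dtype=float)
    t = np.asarray(grey_timestamps_ms, dtype=float)
    if len(grey) != len(t) or len(grey) < 4:
        raise ValidationError("grey series needs >= 4 samples with timestamps")
    fs = (len(t) - 1) / ((t[-1] - t[0]) / 1000.0)

    spec = np.fft.fft(grey)
    freqs = np.fft.fftfreq(len(grey), d=1.0 / fs)
    keep = (np.abs(freqs) >= band[0]) & (np.abs(freqs) <= band[1])
    pulse = np.fft.ifft(np.where(keep, spec, 0.0)).real

    peaks, _ = find_peaks(pulse)
    if peaks.size == 0:
        raise NoPeakError("no pulse peaks in the filtered grey waveform")

    peak_times = t[peaks]
    red_at = _nearest_values(raw_red.timestamps, raw_red.values, peak_times)
    ir_at = _nearest_values(raw_ir.timestamps, raw_ir.values, peak_times)
    dist_at = _nearest_values(distance.timestamps, distance.values, peak_times)

    values = [
        spo2_from_ratio(ir_to_red_ratio(ir, red, d, table, params), table, params)
        for ir, red, d in zip(ir_at, red_at, dist_at)
    ]
    return float(np.mean(values))
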