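"""Frequency-domain heart-rate machinery: FFT, bandpass, peak pick, SNR.

The cardiac passband is 0.66-3.33 Hz (39.6-199.8 BPM, printed as 39-200 BPM in
the usual truncated/rounded labels).  The quality score of a candidate is its
dominant in-band peak magnitude divided by the mean in-band magnitude — a
dimensionless spectral SNR.  The candidate with the best SNR across all regions
and channels/components wins the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import NoCandidateError, NoPeakError, ValidationError

#: cardiac passband in Hz
BAND_LOW = 0.66
BAND_HIGH = 3.33


@dataclass
class Spectrum:
    """One-sided magnitude spectrum (uniform frequency spacing fs / L)."""

    frequencies: np.ndarray
    magnitudes: np.ndarray


@dataclass
class VitalCandidate:
    """One (region, channel/component) heart-rate candidate for a window."""

    region: str
    provenance: str
    peak_frequency: float
    peak_magnitude: float
    snr: float

    @property
    def hr_bpm(self) -> float:
        return hr_bpm(self.peak_frequency)


def magnitude_spectrum(x, fs: float) -> Spectrum:
    """One-sided magnitude spectrum of a real series sampled at ``fs`` Hz."""
    x = np.asarray(x, dtype=float)
    if fs <= 0:
        raise ValidationError("sampling rate must be positive")
    if x.size < 4:
        raise ValidationError("need at least 4 samples for a spectrum")
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    mags = np.abs(np.fft.rfft(x))
    return Spectrum(frequencies=freqs, magnitudes=mags)


def bandpass(spec: Spectrum, low: float = BAND_LOW, high: float = BAND_HIGH) -> Spectrum:
    """Zero all magnitudes outside [low, high] Hz (frequencies unchanged)."""
    if low >= high:
        raise ValidationError("band lower edge must be below the upper edge")
    mask = (spec.frequencies >= low) & (spec.frequencies <= high)
    return Spectrum(spec.frequencies, np.where(mask, spec.magnitudes, 0.0))


def dominant_peak(spec: Spectrum):
    """The highest local spectral peak (ties broken toward lower frequency).

    Flat two-bin plateaus resolve to the lower-frequency bin.  Raises
    :class:`NoPeakError` when the (band-limited) spectrum has no positive peak.
    """
    mags = spec.magnitudes
    idx, _ = find_peaks(mags)
    idx = idx[mags[idx] > 0]
    if idx.size == 0:
        raise NoPeakError("no positive local maximum in spectrum")
    best = idx[np.argmax(mags[idx])]  # argmax takes the first (lowest-frequency) tie
    return float(spec.frequencies[best]), float(mags[best])


def snr(spec: Spectrum, peak_magnitude: float, low: float = BAND_LOW,
        high: float = BAND_HIGH) -> float:
    """Peak magnitude over the mean in-band magnitude (dimensionless)."""
    mask = (spec.frequencies >= low) & (spec.frequencies <= high)
    if not mask.any():
        raise ValidationError("no spectral bins inside the band")
    denom = float(spec.magnitudes[mask].mean())
    if denom == 0:
        return float("inf")
    return float(peak_magnitude) / denom


def hr_bpm(frequency: float) -> float:
    """Convert a cardiac frequency in Hz to beats per minute."""
    if frequency < 0:
        raise ValidationError("frequency must be non-negative")
    return 60.0 * frequency


def select_best(candidates) -> VitalCandidate:
    """Candidate with maximal SNR; ties keep the earliest-listed candidate."""
    candidates = list(candidates)
    if not candidates:
        raise NoCandidateError("no vital candidates to select from")
    best = candidates[0]
    for cand in candidates[1:]:
        if cand.snr > best.snr:
            best = cand
    return best
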