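"""Signal pre-processing primitives and the seven-technique registry.

Each raw pooled channel series can be conditioned before source separation by a
numbered combination of steps:

====  =======================================================
Type  Steps (applied left to right)
====  =======================================================
1     none (identity)
2     normalise
3     interpolate, hamming, smooth, median filter, normalise
4     detrend, interpolate, hamming, smooth, median filter, normalise
5     interpolate, hamming, normalise
6     detrend, interpolate, hamming, normalise
7     detrend, upsample x2, interpolate, hamming, normalise
====  =======================================================

Technique 7 exists for low-frame-rate streams: FFT upsampling doubles the sample
count so the downstream spectral estimate keeps a usable resolution.  The
``select_technique_auto`` rule picks 7 below 15 fps and 6 otherwise.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .errors import DegenerateSignalError, ValidationError

#: fps below which the upsampling technique is preferred.
FPS_SWITCH = 15.0


def l2_normalise(x) -> np.ndarray:
    """Scale a series to unit Euclidean norm."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise DegenerateSignalError("empty signal")
    norm = np.linalg.norm(x)
    if norm == 0:
        raise DegenerateSignalError("all-zero signal cannot be normalised")
    return x / norm


def interpolate_even(x, timestamps) -> np.ndarray:
    """Resample onto an evenly spaced grid spanning [first, last] timestamp.

    The grid has the same number of points as the input, so a stream with
    timestamp jitter becomes uniformly sampled without changing its length.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(timestamps, dtype=float)
    if len(x) != len(t) or len(x) < 2:
        raise ValidationError("need >= 2 samples with matching timestamps")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("timestamps must be strictly increasing (no duplicates)")
    even = np.linspace(t[0], t[-1], len(t))
    return np.interp(even, t, x)


def apply_hamming(x) -> np.ndarray:
    """Pointwise product with a Hamming window of the signal's length."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise DegenerateSignalError("Hamming window undefined for length < 2")
    return x * np.hamming(len(x))


def median_filter(x, kernel: int = 3) -> np.ndarray:
    """Sliding median with zero-padded edges; length preserved."""
    if kernel % 2 == 0 or kernel < 1:
        raise ValidationError("median kernel must be an odd positive integer")
    return sps.medfilt(np.asarray(x, dtype=float), kernel_size=kernel)


def detrend_linear(x) -> np.ndarray:
    """Remove the least-squares straight line from the series."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValidationError("detrend needs at least 2 samples")
    return sps.detrend(x, type="linear")


def upsample_fft(x, factor: int = 2) -> np.ndarray:
    """Fourier-domain resampling to ``len(x) * factor`` samples."""
    if factor < 1:
        raise ValidationError("upsampling factor must be >= 1")
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValidationError("upsampling needs at least 2 samples")
    return sps.resample(x, len(x) * factor)


def smooth(x, window: int = 5) -> np.ndarray:
    """Centred moving average with edge truncation; length preserved."""
    if window % 2 == 0 or window < 1:
        raise ValidationError("smoothing window must be an odd positive integer")
    x = np.asarray(x, dtype=float)
    half = window // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        out[i] = x[max(0, i - half) : i + half + 1].mean()
    return out


def select_technique_auto(fps: float) -> int:
    """fps-adaptive technique choice: 7 below 15 fps, else 6."""
    if fps <= 0:
        raise ValidationError("fps must be positive")
    return 7 if fps < FPS_SWITCH else 6


def apply_technique(x, timestamps, type_id: int, fps: float | None = None) -> np.ndarray:
    """Run the numbered step combination on one channel series.

    ``timestamps`` feed the interpolation step; after FFT upsampling (type 7)
    the time grid is rebuilt as an even grid over the same span.  The returned
    series may be longer than the input (type 7 doubles it).  ``fps`` is
    accepted for signature symmetry with the auto-selection rule but the steps
    themselves are rate-agnostic.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(timestamps, dtype=float)
    if type_id == 1:
        return x.copy()
    if type_id == 2:
        return l2_normalise(x)
    if type_id == 3:
        y = interpolate_even(x, t)
        return l2_normalise(median_filter(smooth(apply_hamming(y))))
    if type_id == 4:
        y = interpolate_even(detrend_linear(x), t)
        return l2_normalise(median_filter(smooth(apply_hamming(y))))
    if type_id == 5:
        return l2_normalise(apply_hamming(interpolate_even(x, t)))
    if type_id == 6:
        return l2_normalise(apply_hamming(interpolate_even(detrend_linear(x), t)))
    if type_id == 7:
        y = upsample_fft(detrend_linear(x), 2)
        t2 = np.linspace(t[0], t[-1], len(y))
        return l2_normalise(apply_hamming(interpolate_even(y, t2)))
    raise ValidationError(f"unknown pre-processing type {type_id!r}")
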