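"""Sliding-window orchestration of the whole vital-sign chain.

For every 15-s window (slid by 1 s) the pipeline aligns each region's channels
onto an even grid, conditions them with the fps-appropriate pre-processing
technique, extracts candidate components, scores every candidate's dominant
in-band spectral peak by SNR, and converts the best peak to BPM.  SpO2 comes
from the winning region's grey pulse waveform with the raw red/IR/distance
series.  A reliability gate holds the previous window's values whenever the new
estimate has SNR below threshold or jumps more than the deviation factor —
heart rate and oxygenation change gradually, so a one-second spike to double
the rate is noise, not physiology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import NoPeakError, ValidationError
from .io import RegionStore, estimate_fps
from .preprocess import apply_technique, select_technique_auto
from .separation import Candidate, SeparationSpec, align_channels, separate
from .spectrum import (
    BAND_HIGH,
    BAND_LOW,
    VitalCandidate,
    bandpass,
    dominant_peak,
    hr_bpm,
    magnitude_spectrum,
    select_best,
    snr,
)
from .spo2 import Spo2Params, load_extinction_table, spo2_window

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    window_s: int = 15
    step_s: int = 1
    band: tuple = (BAND_LOW, BAND_HIGH)
    snr_threshold: float = 5.0
    deviation_factor: float = 0.18
    preprocess: int | str = "auto"  # "auto" or a technique id 1-7
    separation: SeparationSpec = field(default_factory=SeparationSpec)
    spo2: Spo2Params = field(default_factory=Spo2Params)
    gt_alignment: str = "last"  # or "average"
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.step_s <= self.window_s):
            raise ValidationError("need 0 < step_s <= window_s")
        if self.band[0] >= self.band[1]:
            raise ValidationError("band lower edge must be below the upper edge")
        if self.snr_threshold <= 0:
            raise ValidationError("snr_threshold must be positive")
        if not (0 < self.deviation_factor < 1):
            raise ValidationError("deviation_factor must be in (0, 1)")
        if self.gt_alignment not in ("last", "average"):
            raise ValidationError("gt_alignment must be 'last' or 'average'")


def preset_config(state: str, **overrides) -> PipelineConfig:
    """Best-performing configuration per activity state.

    Resting recordings separate best with FastICA; active (post-exercise)
    recordings with PCA whitening followed by ICA.  Both use the fps-adaptive
    technique rule.
    """
    method = "pca_ica" if state == "active" else "fastica"
    overrides.setdefault("separation", SeparationSpec(method=method))
    return PipelineConfig(**overrides)


@dataclass
class VitalEstimate:
    """One window's vital estimate with provenance."""

    window_end_s: int
    hr_bpm: float
    spo2_pct: float
    snr: float
    region: str
    provenance: str
    accepted: bool


def slide(duration_s: int, window_s: int, step_s: int):
    """Window bounds [k*step, k*step + window] covering the recording."""
    if duration_s < window_s:
        raise ValidationError("recording shorter than one window")
    count = (duration_s - window_s) // step_s + 1
    return [(k * step_s, k * step_s + window_s) for k in range(count)]


def reliability_gate(new_hr, new_spo2, snr_value, previous: VitalEstimate | None,
                     cfg: PipelineConfig):
    """Accept the new values, or hold the previous estimate's.

    Returns (hr, spo2, accepted).  The first window (no previous) is accepted
    unconditionally.  Otherwise the new values are rejected when the SNR falls
    below threshold or either vital deviates from the previous value by more
    than the deviation factor.
    """
    if previous is None:
        return new_hr, new_spo2, new_hr is not None
    if new_hr is None or np.isnan(snr_value):
        return previous.hr_bpm, previous.spo2_pct, False
    if snr_value < cfg.snr_threshold:
        return previous.hr_bpm, previous.spo2_pct, False
    if previous.hr_bpm > 0 and abs(new_hr - previous.hr_bpm) / previous.hr_bpm > cfg.deviation_factor:
        return previous.hr_bpm, previous.spo2_pct, False
    if (
        new_spo2 is not None
        and previous.spo2_pct > 0
        and abs(new_spo2 - previous.spo2_pct) / previous.spo2_pct > cfg.deviation_factor
    ):
        return previous.hr_bpm, previous.spo2_pct, False
    return new_hr, new_spo2 if new_spo2 is not None else previous.spo2_pct, True


def _window_fps(fps_colour, fps_ir, start: int, end: int) -> float:
    """Conservative window frame rate: minimum per-second count across streams."""
    rates = []
    for trace in (fps_colour, fps_ir):
        chunk = trace[start:min(end, len(trace))]
        if len(chunk):
            rates.append(chunk.min())
    return float(min(rates)) if rates else 0.0


def _window_candidates(store, region, start, end, technique, cfg):
    """All scored candidates of one region for one window, plus the grey grid."""
    X, grid, labels = align_channels(store.regions[region], (start * 1000, end * 1000))
    fs = (len(grid) - 1) / ((grid[-1] - grid[0]) / 1000.0)

    rows = [apply_technique(x, grid, technique) for x in X]
    P = np.vstack(rows)
    fs_eff = fs * P.shape[1] / X.shape[1]  # technique 7 doubles the sample count

    raw_candidates = separate(P, cfg.separation, labels=labels)
    if not any(c.finite for c in raw_candidates):
        logger.warning("separation degenerate in %s [%d, %d); using raw rows", region, start, end)
        raw_candidates = [Candidate(r, f"none[fallback]:{l}") for r, l in zip(P, labels)]

    scored = []
    for cand in raw_candidates:
        if not cand.finite:
            continue
        spec = bandpass(magnitude_spectrum(cand.values, fs_eff), *cfg.band)
        try:
            freq, mag = dominant_peak(spec)
        except NoPeakError:
            continue
        scored.append(
            VitalCandidate(
                region=region,
                provenance=f"T{technique}/{cand.provenance}"
                + ("" if cand.converged else "/nonconverged"),
                peak_frequency=freq,
                peak_magnitude=mag,
                snr=snr(spec, mag, *cfg.band),
            )
        )
    grey_idx = labels.index("Gy") if "Gy" in labels else None
    grey_row = X[grey_idx] if grey_idx is not None else None
    return scored, grey_row, grid


def process_participant(store: RegionStore, cfg: PipelineConfig | None = None):
    """Run the full chain over a recording; one VitalEstimate per window."""
    cfg = cfg or PipelineConfig()
    store.validate()
    duration = store.duration_s()
    windows = slide(duration, cfg.window_s, cfg.step_s)

    first_region = store.region_order()[0]
    fps_colour = estimate_fps(store.regions[first_region]["R"].timestamps)
    ir_ts = store.regions[first_region].get("IR")
    fps_ir = estimate_fps(ir_ts.timestamps) if ir_ts is not None else fps_colour

    table = load_extinction_table()
    estimates: list[VitalEstimate] = []
    previous: VitalEstimate | None = None

    for start, end in windows:
        fps = _window_fps(fps_colour, fps_ir, start, end)
        if cfg.preprocess == "auto":
            technique = select_technique_auto(fps) if fps > 0 else 6
        else:
            technique = int(cfg.preprocess)

        candidates = []
        grey_by_region = {}
        for region in store.region_order():
            try:
                scored, grey_row, grid = _window_candidates(
                    store, region, start, end, technique, cfg
                )
            except ValidationError as exc:
                logger.info("skipping %s in [%d, %d): %s", region, start, end, exc)
                continue
            candidates.extend(scored)
            grey_by_region[region] = (grey_row, grid)

        if not candidates:
            hr_new, snr_value, region, provenance = None, 0.0, "", "no-candidate"
            spo2_new = None
        else:
            best = select_best(candidates)
            hr_new, snr_value = best.hr_bpm, best.snr
            region, provenance = best.region, best.provenance
            spo2_new = None
            grey_row, grid = grey_by_region.get(region, (None, None))
            if grey_row is not None and store.distance is not None:
                chans = store.regions[region]
                if "R" in chans and "IR" in chans:
                    try:
                        spo2_new = spo2_window(
                            grey_row, grid, chans["R"], chans["IR"],
                            store.distance, table, cfg.spo2, band=cfg.band,
                        )
                    except NoPeakError:
                        spo2_new = None

        hr_out, spo2_out, accepted = reliability_gate(hr_new, spo2_new, snr_value, previous, cfg)
        estimate = VitalEstimate(
            window_end_s=end,
            hr_bpm=float(hr_out) if hr_out is not None else float("nan"),
            spo2_pct=float(spo2_out) if spo2_out is not None else float("nan"),
            snr=float(snr_value),
            region=region,
            provenance=provenance,
            accepted=accepted,
        )
        estimates.append(estimate)
        previous = estimate
    return estimates
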