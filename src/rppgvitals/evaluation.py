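"""Ground-truth alignment and error metrics for per-window vital estimates.

Differences are taken as reference minus estimate.  The report carries the mean
difference, mean absolute difference, population standard deviation of the
differences (divisor N, not N-1), RMSE, and Pearson's r.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import GroundTruthTrace, RegionStore
from .pipeline import PipelineConfig, VitalEstimate, process_participant, slide


@dataclass
class MetricReport:
    mean_diff: float
    mean_abs_diff: float
    sd_error: float
    rmse: float
    pearson_r: float
    n: int
    vital: str = ""
    state: str = ""
    algorithm: str = ""
    technique: str = ""


def align_ground_truth(values, windows, method: str = "last") -> np.ndarray:
    """Per-window reference value from a per-second trace.

    ``last`` takes the value at the window's final second, ``average`` the mean
    over the window's seconds.
    """
    values = np.asarray(values, dtype=float)
    out = np.empty(len(windows))
    for i, (start, end) in enumerate(windows):
        if end > len(values):
            raise ValidationError("ground truth shorter than the recording")
        if method == "last":
            out[i] = values[end - 1]
        elif method == "average":
            out[i] = values[start:end].mean()
        else:
            raise ValidationError(f"unknown alignment method {method!r}")
    return out


def compute_metrics(reference, estimates, vital: str = "") -> MetricReport:
    """All error measures between per-window reference and estimated values."""
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimates, dtype=float)
    if ref.shape != est.shape or ref.size < 1:
        raise ValidationError("reference and estimates must have equal length >= 1")
    diff = ref - est
    mean_diff = float(diff.mean())
    mean_abs = float(np.abs(diff).mean())
    sd = float(np.sqrt(np.mean((diff - mean_diff) ** 2)))  # population divisor N
    rmse = float(np.sqrt(np.mean(diff**2)))
    if ref.size >= 2 and np.std(ref) > 0 and np.std(est) > 0:
        r = float(stats.pearsonr(ref, est).statistic)
    else:
        r = float("nan")  # undefined for constant input
    return MetricReport(
        mean_diff=mean_diff,
        mean_abs_diff=mean_abs,
        sd_error=sd,
        rmse=rmse,
        pearson_r=r,
        n=int(ref.size),
        vital=vital,
    )


def evaluate_estimates(estimates: list[VitalEstimate], gt: GroundTruthTrace,
                       window_s: int, step_s: int, method: str = "last"):
    """HR and SpO2 metric reports for a list of pipeline estimates."""
    windows = [(e.window_end_s - window_s, e.window_end_s) for e in estimates]
    hr_ref = align_ground_truth(gt.hr_bpm, windows, method)
    spo2_ref = align_ground_truth(gt.spo2_pct, windows, method)
    hr_est = np.array([e.hr_bpm for e in estimates])
    spo2_est = np.array([e.spo2_pct for e in estimates])
    ok_hr = np.isfinite(hr_est)
    ok_spo2 = np.isfinite(spo2_est)
    return (
        compute_metrics(hr_ref[ok_hr], hr_est[ok_hr], vital="HR"),
        compute_metrics(spo2_ref[ok_spo2], spo2_est[ok_spo2], vital="SpO2"),
    )


def grid_report(stores, grid, gt_traces, base_cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Sweep technique x separation configurations over one or more recordings.

    ``stores``/``gt_traces`` are parallel lists; ``grid`` is an iterable of
    (technique_id_or_auto, SeparationSpec).  Returns one row per
    (configuration, vital, state); failed cells are recorded with NaN metrics.
    """
    base_cfg = base_cfg or PipelineConfig()
    if isinstance(stores, RegionStore):
        stores, gt_traces = [stores], [gt_traces]
    rows = []
    for technique, sep in grid:
        cfg = replace(base_cfg, preprocess=technique, separation=sep)
        for store, gt in zip(stores, gt_traces):
            try:
                estimates = process_participant(store, cfg)
                reports = evaluate_estimates(
                    estimates, gt, cfg.window_s, cfg.step_s, cfg.gt_alignment
                )
            except Exception:  # noqa: BLE001 — a failed cell must not kill the sweep
                reports = [
                    MetricReport(*([float("nan")] * 5), n=0, vital=v)
                    for v in ("HR", "SpO2")
                ]
            for rep in reports:
                rep.state = store.state
                rep.algorithm = sep.method
                rep.technique = str(technique)
                rows.append(rep.__dict__ | {"participant": store.participant_id})
    return pd.DataFrame(rows)
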