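"""Source-extraction registry: candidate pulse signals from the channel matrix.

The pooled channel series of a region form an (N x T) observation matrix (rows
R, G, B, Gy, IR on a common even time grid).  Each registered method maps that
matrix to candidate component series from which the heart-rate peak is later
picked by spectral SNR:

- ``none``               the raw rows, untouched
- ``fastica``            FastICA independent components (optionally re-applied
                         up to three times: pass k+1 consumes pass k's output)
- ``pca``                principal-component score series, by explained variance
- ``pca_ica``            PCA whitening, then FastICA
- ``jade``               fourth-order-cumulant joint diagonalisation
- ``spectral_embedding`` nonlinear embedding coordinates of the sample graph

All methods return exactly N candidates in ``joint`` mode; ``per_channel`` mode
runs the method on each channel alone.  Non-convergence is flagged on the
candidate, never silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.manifold import SpectralEmbedding

from . import jade as jade_mod
from .errors import ValidationError
from .io import CHANNELS, ChannelSeries

METHODS = ("none", "fastica", "pca", "pca_ica", "jade", "spectral_embedding")

#: ICA re-application beyond three passes has no further effect; clamp there.
MAX_REPEATS = 3


@dataclass
class SeparationSpec:
    """Which extraction method to run and how."""

    method: str = "fastica"
    repeats: int = 1
    mode: str = "joint"  # or "per_channel"
    seed: int = 0
    max_iter: int = 500
    tol: float = 1e-4

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValidationError(f"unknown separation method {self.method!r}")
        if self.mode not in ("joint", "per_channel"):
            raise ValidationError(f"unknown separation mode {self.mode!r}")
        if self.repeats < 1:
            raise ValidationError("repeats must be >= 1")
        if self.repeats > MAX_REPEATS:
            warnings.warn(
                f"repeats={self.repeats} clamped to {MAX_REPEATS} "
                "(further ICA passes have no effect)",
                stacklevel=2,
            )
            self.repeats = MAX_REPEATS


@dataclass
class Candidate:
    """One candidate component series with provenance."""

    values: np.ndarray
    provenance: str
    converged: bool = True

    @property
    def finite(self) -> bool:
        return bool(np.all(np.isfinite(self.values)))


def _run_fastica(X: np.ndarray, spec: SeparationSpec):
    comps = X
    converged = True
    for _ in range(spec.repeats):
        ica = FastICA(
            n_components=comps.shape[0],
            whiten="unit-variance",
            max_iter=spec.max_iter,
            tol=spec.tol,
            random_state=spec.seed,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            comps = ica.fit_transform(comps.T).T
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
    return comps, converged


def _run_method(X: np.ndarray, spec: SeparationSpec):
    """Apply one method to an (N x T) matrix; returns (components, converged)."""
    n = X.shape[0]
    if spec.method == "none":
        return X.copy(), True
    if spec.method == "fastica":
        return _run_fastica(X, spec)
    if spec.method == "pca":
        pca = PCA(n_components=n, random_state=spec.seed)
        return pca.fit_transform(X.T).T, True
    if spec.method == "pca_ica":
        pca = PCA(n_components=n, whiten=True, random_state=spec.seed)
        whitened = pca.fit_transform(X.T).T
        return _run_fastica(whitened, spec)
    if spec.method == "jade":
        return jade_mod.jade(X), True
    if spec.method == "spectral_embedding":
        emb = SpectralEmbedding(
            n_components=min(n, X.shape[1] - 1),
            affinity="nearest_neighbors",
            random_state=spec.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords = emb.fit_transform(X.T).T
        return coords, True
    raise ValidationError(f"unknown separation method {spec.method!r}")


def separate(channels, spec: SeparationSpec, labels=None) -> list[Candidate]:
    """Produce candidate component series from an (N x T) channel matrix."""
    X = np.asarray(channels, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    n, t = X.shape
    if n < 1 or t <= n:
        raise ValidationError("need an (N x T) matrix with T > N")
    labels = list(labels) if labels is not None else [f"ch{i}" for i in range(n)]

    candidates: list[Candidate] = []
    if spec.mode == "joint":
        comps, converged = _run_method(X, spec)
        for i, row in enumerate(comps):
            tag = labels[i] if spec.method == "none" else f"comp{i}"
            candidates.append(
                Candidate(row, f"{spec.method}[joint]:{tag}", converged=converged)
            )
    else:
        for i, row in enumerate(X):
            comps, converged = _run_method(row[None, :], spec)
            candidates.append(
                Candidate(
                    comps[0],
                    f"{spec.method}[per_channel]:{labels[i]}",
                    converged=converged,
                )
            )
    return candidates


def align_channels(region: dict, window_ms, channels=CHANNELS):
    """Interpolate a region's channels onto the colour stream's even grid.

    ``window_ms`` bounds [start, end) select the colour frames; every channel
    (IR included, even when it runs on its own clock) is linearly interpolated
    onto an even grid spanning those frames.  Returns (matrix N x T, grid,
    channel labels).
    """
    start, end = window_ms
    present = [c for c in channels if c in region]
    if not present:
        raise ValidationError("region has no channels")
    ref = region["R"] if "R" in region else region[present[0]]
    mask = (ref.timestamps >= start) & (ref.timestamps < end)
    t_ref = ref.timestamps[mask]
    if len(t_ref) < 2:
        raise ValidationError("fewer than 2 colour samples in window")
    grid = np.linspace(t_ref[0], t_ref[-1], len(t_ref))

    rows = []
    for name in present:
        series: ChannelSeries = region[name]
        smask = (series.timestamps >= start) & (series.timestamps < end)
        if smask.sum() < 2:
            raise ValidationError(f"stream {name!r} has < 2 samples in window")
        rows.append(np.interp(grid, series.timestamps[smask], series.values[smask]))
    return np.vstack(rows), grid, present
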