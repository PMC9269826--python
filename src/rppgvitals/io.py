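"""Data model and CSV readers/writers for region stores and ground truth.

A *region store* holds, for one participant recording, the spatially pooled
pixel-intensity time series of five face regions (forehead, cheeks, cheeks+nose,
lips) in five channels (R, G, B, Gy, IR), together with per-frame timestamps and
the face-to-camera distance trace.  The colour channels (R, G, B and the derived
grey channel Gy) share one timestamp vector per region; the IR stream may run on
its own clock.

On-disk format (UTF-8 CSV, header row)::

    region,channel,timestamp_ms,value,distance_m

one row per (region, channel, frame).  ``distance_m`` is carried on the first
region's R rows and may be empty elsewhere.  Gy rows may be omitted on input;
the reader synthesises Gy from co-timestamped R, G, B.
Optional ``# key=value`` comment lines before the header carry participant
metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

REGIONS = ("forehead", "right_cheek", "left_cheek", "cheeks_nose", "lips")
COLOUR_CHANNELS = ("R", "G", "B", "Gy")
CHANNELS = COLOUR_CHANNELS + ("IR",)
STATES = ("resting1", "resting2", "active")

#: Native frame geometry of the colour and IR sensors of the acquisition camera.
COLOUR_DIMS = (1920, 1080)
IR_DIMS = (512, 424)


@dataclass
class TimeSeries:
    """A timestamped scalar series (timestamps in ms since acquisition start)."""

    timestamps: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    def validate(self, what: str = "series") -> None:
        if len(self.timestamps) != len(self.values):
            raise ValidationError(f"{what}: timestamps and values differ in length")
        if len(self.timestamps) and not np.all(np.diff(self.timestamps) > 0):
            raise ValidationError(f"{what}: timestamps not strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"{what}: non-finite values")


@dataclass
class ChannelSeries(TimeSeries):
    """Pooled intensity of one channel of one region over time."""

    channel: str = "R"

    def validate(self, what: str = "") -> None:  # noqa: D102
        if self.channel not in CHANNELS:
            raise ValidationError(f"unknown channel label {self.channel!r}")
        super().validate(what or f"channel {self.channel}")


@dataclass
class GroundTruthTrace:
    """Per-second reference HR (BPM) and SpO2 (%) from a contact oximeter."""

    seconds: np.ndarray
    hr_bpm: np.ndarray
    spo2_pct: np.ndarray

    def __post_init__(self):
        self.seconds = np.asarray(self.seconds, dtype=int)
        self.hr_bpm = np.asarray(self.hr_bpm, dtype=float)
        self.spo2_pct = np.asarray(self.spo2_pct, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.seconds)
        if len(self.hr_bpm) != n or len(self.spo2_pct) != n:
            raise ValidationError("ground truth columns differ in length")
        if n and (self.seconds[0] != 0 or not np.array_equal(self.seconds, np.arange(n))):
            raise ValidationError("ground-truth seconds must be contiguous from 0")
        if np.any((self.hr_bpm < 30) | (self.hr_bpm > 220)):
            raise ValidationError("hr_bpm outside [30, 220]")
        if np.any((self.spo2_pct < 50) | (self.spo2_pct > 100)):
            raise ValidationError("spo2_pct outside [50, 100]")

    def __len__(self) -> int:
        return len(self.seconds)


@dataclass
class FpsTrace:
    """Per-second frame counts for the colour and IR streams."""

    colour: np.ndarray
    ir: np.ndarray


@dataclass
class RegionStore:
    """All pooled region/channel series of one recording plus the distance trace."""

    participant_id: str = "unknown"
    state: str = "resting1"
    regions: dict = field(default_factory=dict)  # region -> {channel -> ChannelSeries}
    distance: TimeSeries | None = None

    def validate(self) -> None:
        if not self.regions:
            raise ValidationError("region store has no regions")
        if self.state not in STATES:
            raise ValidationError(f"unknown state label {self.state!r}")
        for region, channels in self.regions.items():
            if region not in REGIONS:
                raise ValidationError(f"unknown region label {region!r}")
            if not channels:
                raise ValidationError(f"region {region!r} has no channels")
            colour_ts = None
            for name, series in channels.items():
                if name != series.channel:
                    raise ValidationError(f"channel key {name!r} != label {series.channel!r}")
                series.validate(f"{region}/{name}")
                if name in COLOUR_CHANNELS:
                    if colour_ts is None:
                        colour_ts = series.timestamps
                    elif not np.array_equal(colour_ts, series.timestamps):
                        raise ValidationError(
                            f"colour channels of {region!r} do not share timestamps"
                        )
        if self.distance is not None:
            self.distance.validate("distance")
            if np.any((self.distance.values <= 0) | (self.distance.values >= 10)):
                raise ValidationError("distance values must be in (0, 10) metres")

    def region_order(self):
        """Regions present, in canonical order (drives candidate tie-breaking)."""
        return [r for r in REGIONS if r in self.regions]

    def duration_s(self) -> int:
        """Whole seconds spanned by the recording (ceiling of the last timestamp)."""
        last = max(
            s.timestamps[-1]
            for chans in self.regions.values()
            for s in chans.values()
            if len(s.timestamps)
        )
        return int(math.ceil(last / 1000.0))


# ---------------------------------------------------------------------------
# small acquisition-side utilities
# ---------------------------------------------------------------------------

def _nearest_values(ts, values, query_ts) -> np.ndarray:
    """Nearest-timestamp lookup of ``values`` (sampled at ``ts``) at ``query_ts``."""
    ts = np.asarray(ts, dtype=float)
    values = np.asarray(values, dtype=float)
    query_ts = np.atleast_1d(np.asarray(query_ts, dtype=float))
    idx = np.searchsorted(ts, query_ts)
    idx = np.clip(idx, 0, len(ts) - 1)
    left = np.clip(idx - 1, 0, len(ts) - 1)
    use_left = np.abs(ts[left] - query_ts) <= np.abs(ts[idx] - query_ts)
    return values[np.where(use_left, left, idx)]

def compute_grey(r, g, b):
    """Grey channel: arithmetic mean of the R, G, B intensities (64-bit float)."""
    return (np.asarray(r, dtype=float) + np.asarray(g, dtype=float) + np.asarray(b, dtype=float)) / 3.0


def spatial_pool(pixels) -> float:
    """Mean of all pixels of a region patch — one intensity per frame."""
    arr = np.asarray(pixels, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot pool an empty pixel array")
    return float(arr.mean())


def estimate_fps(timestamps) -> np.ndarray:
    """Per-second frame counts: fps[k] = #{t : k*1000 <= t < (k+1)*1000}."""
    t = np.asarray(timestamps, dtype=float)
    if t.size == 0:
        return np.zeros(0, dtype=int)
    if np.any(np.diff(t) < 0):
        raise ValidationError("timestamps must be monotonic")
    n_seconds = int(t[-1] // 1000) + 1
    counts = np.zeros(n_seconds, dtype=int)
    idx = (t // 1000).astype(int)
    np.add.at(counts, idx, 1)
    return counts


def map_colour_box_to_ir(box, colour_dims=COLOUR_DIMS, ir_dims=IR_DIMS):
    """Map a bounding box from colour-frame pixels into IR-frame pixels.

    Coordinates are divided by the width/height ratio between the two frames,
    floored to integer pixels, and clipped inside the IR frame.
    """
    x, y, w, h = box
    cw, ch = colour_dims
    iw, ih = ir_dims
    if x < 0 or y < 0 or w < 0 or h < 0 or x + w > cw or y + h > ch:
        raise ValidationError(f"box {box} outside the {cw}x{ch} colour frame")
    rw, rh = cw / iw, ch / ih
    ix = min(int(x / rw), iw)
    iy = min(int(y / rh), ih)
    iw_out = min(int(w / rw), iw - ix)
    ih_out = min(int(h / rh), ih - iy)
    return (ix, iy, iw_out, ih_out)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_STORE_COLUMNS = ["region", "channel", "timestamp_ms", "value", "distance_m"]


def write_region_store(store: RegionStore, path) -> None:
    """Write a region store to the long-format CSV dialect (lossless doubles)."""
    store.validate()
    first_region = store.region_order()[0]
    lines = [f"# participant_id={store.participant_id}", f"# state={store.state}"]
    lines.append(",".join(_STORE_COLUMNS))

    def fmt(v: float) -> str:
        return repr(float(v))

    for region in store.region_order():
        channels = store.regions[region]
        for channel in CHANNELS:
            if channel not in channels:
                continue
            series = channels[channel]
            carry_distance = (
                region == first_region and channel == "R" and store.distance is not None
            )
            if carry_distance:
                # distance rides on the first region's R rows; if its clock differs
                # from the colour frames it is nearest-matched onto them (lossy)
                dist_row = _nearest_values(
                    store.distance.timestamps, store.distance.values, series.timestamps
                )
            for i, (t, v) in enumerate(zip(series.timestamps, series.values)):
                d = fmt(dist_row[i]) if carry_distance else ""
                lines.append(f"{region},{channel},{fmt(t)},{fmt(v)},{d}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_region_store(path) -> RegionStore:
    """Read and validate a region store from the long-format CSV dialect."""
    meta = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, dtype={"region": str, "channel": str})
    for col in _STORE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"region-store file is missing required column {col!r}")

    regions: dict = {}
    distance = None
    for (region, channel), grp in df.groupby(["region", "channel"], sort=False):
        if channel not in CHANNELS:
            raise ValidationError(f"unknown channel label {channel!r}")
        ts = grp["timestamp_ms"].to_numpy(dtype=float)
        vals = grp["value"].to_numpy(dtype=float)
        if len(ts) > 1 and not np.all(np.diff(ts) > 0):
            raise ValidationError(
                f"timestamps not strictly increasing for {region}/{channel}"
            )
        regions.setdefault(region, {})[channel] = ChannelSeries(
            timestamps=ts, values=vals, channel=channel
        )
        dmask = grp["distance_m"].notna()
        if dmask.any() and distance is None:
            distance = TimeSeries(
                timestamps=grp.loc[dmask, "timestamp_ms"].to_numpy(dtype=float),
                values=grp.loc[dmask, "distance_m"].to_numpy(dtype=float),
            )

    # synthesise the grey channel where absent
    for region, channels in regions.items():
        if "Gy" not in channels and all(c in channels for c in ("R", "G", "B")):
            r, g, b = channels["R"], channels["G"], channels["B"]
            if np.array_equal(r.timestamps, g.timestamps) and np.array_equal(
                r.timestamps, b.timestamps
            ):
                channels["Gy"] = ChannelSeries(
                    timestamps=r.timestamps.copy(),
                    values=compute_grey(r.values, g.values, b.values),
                    channel="Gy",
                )

    store = RegionStore(
        participant_id=meta.get("participant_id", "unknown"),
        state=meta.get("state", "resting1"),
        regions=regions,
        distance=distance,
    )
    store.validate()
    return store


def write_ground_truth(gt: GroundTruthTrace, path) -> None:
    pd.DataFrame(
        {"second": gt.seconds, "hr_bpm": gt.hr_bpm, "spo2_pct": gt.spo2_pct}
    ).to_csv(path, index=False)


def read_ground_truth(path) -> GroundTruthTrace:
    """Read a per-second reference trace (columns: second, hr_bpm, spo2_pct)."""
    df = pd.read_csv(path)
    for col in ("second", "hr_bpm", "spo2_pct"):
        if col not in df.columns:
            raise FormatError(f"ground-truth file is missing required column {col!r}")
    return GroundTruthTrace(
        seconds=df["second"].to_numpy(),
        hr_bpm=df["hr_bpm"].to_numpy(),
        spo2_pct=df["spo2_pct"].to_numpy(),
    )
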