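"""Raw channel loading, 1-Hz synchronization, derived features, low-pass filtering.

Wearable channels (heart rate, minute ventilation, breathing frequency, hip
acceleration, cadence) and breath-by-breath oxygen uptake arrive on their own
time bases.  Everything is linearly interpolated onto a common integer-second
grid, a one-second lagged heart-rate difference is derived, and all model
channels are low-pass filtered at 0.01 Hz with a zero-phase Butterworth filter
before entering the regression-forest feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

#: Channels a recording may contain, in canonical file order.
CHANNEL_NAMES = ("HR", "VE", "BF", "Hacc", "CAD", "VO2")

#: Fixed feature-column order of the model matrix.
FEATURE_ORDER = ("HR", "dHR", "VE", "BF", "Hacc", "CAD")

#: Recognised segment labels.
SEGMENT_LABELS = ("PRTS1", "PRTS2", "ADL", "REST")


class PreprocessError(ValueError):
    """Raised on malformed channel data or contract violations."""


@dataclass(frozen=True)
class Segment:
    """Half-open labelled interval [start, end) in seconds from recording start."""

    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise PreprocessError(
                f"segment {self.label!r}: end ({self.end}) must exceed start ({self.start})"
            )


@dataclass
class RawChannel:
    """A single physiological channel on its native (possibly irregular) time base.

    Parameters
    ----------
    name
        One of :data:`CHANNEL_NAMES`.
    timestamps
        Seconds from recording start, strictly increasing.
    values
        Channel values in native units (bpm, L·min⁻¹, breaths·min⁻¹, g,
        steps·min⁻¹ or ml·min⁻¹·kg⁻¹).
    """

    name: str
    timestamps: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.name not in CHANNEL_NAMES:
            raise PreprocessError(f"unknown channel name {self.name!r}")
        if self.timestamps.ndim != 1 or self.timestamps.shape != self.values.shape:
            raise PreprocessError(f"channel {self.name}: timestamps/values shape mismatch")
        if len(self.timestamps) < 2:
            raise PreprocessError(f"channel {self.name}: needs at least 2 samples")
        if not np.all(np.diff(self.timestamps) > 0):
            raise PreprocessError(f"channel {self.name}: timestamps not strictly increasing")
        if not (np.all(np.isfinite(self.timestamps)) and np.all(np.isfinite(self.values))):
            raise PreprocessError(f"channel {self.name}: non-finite data")


@dataclass
class SensorFrame:
    """Uniform 1-Hz multichannel series for one participant with segment annotations."""

    time: np.ndarray
    channels: dict[str, np.ndarray]
    segments: list[Segment] = field(default_factory=list)
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time)
        if len(self.time) >= 2 and not np.all(np.diff(self.time) == 1):
            raise PreprocessError("SensorFrame time grid must have exact 1-s spacing")
        n = len(self.time)
        for name, vals in self.channels.items():
            if len(vals) != n:
                raise PreprocessError(f"channel {name}: length {len(vals)} != time length {n}")
        self._check_segments()

    def _check_segments(self) -> None:
        if not self.segments:
            return
        t0, t1 = self.time[0], self.time[-1] + 1
        ordered = sorted(self.segments, key=lambda s: s.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise PreprocessError(f"segments {a.label} and {b.label} overlap")
        for s in ordered:
            if s.start < t0 or s.end > t1:
                raise PreprocessError(f"segment {s.label} [{s.start},{s.end}) outside recording")

    @property
    def n_samples(self) -> int:
        return len(self.time)

    def segment_mask(self, *labels: str) -> np.ndarray:
        """Boolean mask of samples whose time falls in any segment with these labels."""
        mask = np.zeros(self.n_samples, dtype=bool)
        for seg in self.segments:
            if seg.label in labels:
                mask |= (self.time >= seg.start) & (self.time < seg.end)
        return mask

    def segment_values(self, channel: str, label: str) -> np.ndarray:
        """Values of `channel` restricted to the (unique) segment `label`."""
        segs = [s for s in self.segments if s.label == label]
        if not segs:
            raise PreprocessError(f"no segment labelled {label!r}")
        if len(segs) > 1:
            raise PreprocessError(f"multiple segments labelled {label!r}")
        seg = segs[0]
        mask = (self.time >= seg.start) & (self.time < seg.end)
        return np.asarray(self.channels[channel])[mask]


@dataclass
class FeatureMatrix:
    """Model design matrix: one row per 1-Hz sample, columns in :data:`FEATURE_ORDER`."""

    X: np.ndarray
    y: np.ndarray
    participant_ids: np.ndarray
    columns: tuple[str, ...] = FEATURE_ORDER

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.shape[0] != self.y.shape[0]:
            raise PreprocessError("feature rows and targets differ in length")
        if self.X.shape[1] != len(self.columns):
            raise PreprocessError("feature column count mismatch")


def load_participant(path, annotation_path=None):
    """Read a wide per-participant CSV (`time_s` + channel columns) and optional segments.

    Returns ``(channels, segments)`` where `channels` maps name -> RawChannel.
    Unknown channel columns raise; segment files use `label, start_s, end_s`
    with the half-open [start, end) convention.
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise PreprocessError("input CSV must have a 'time_s' column")
    unknown = [c for c in df.columns if c not in CHANNEL_NAMES and c != "time_s"]
    if unknown:
        raise PreprocessError(f"unknown channel columns: {unknown}")
    channels: dict[str, RawChannel] = {}
    for name in CHANNEL_NAMES:
        if name in df.columns:
            sub = df[["time_s", name]].dropna()
            channels[name] = RawChannel(name, sub["time_s"].to_numpy(), sub[name].to_numpy())
    if not channels:
        raise PreprocessError("no recognised channel columns found")
    segments: list[Segment] = []
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path)
        for col in ("label", "start_s", "end_s"):
            if col not in ann.columns:
                raise PreprocessError(f"annotation CSV missing column {col!r}")
        segments = [
            Segment(str(r.label), float(r.start_s), float(r.end_s)) for r in ann.itertuples()
        ]
    return channels, segments


def synchronize_resample(
    channels: dict[str, RawChannel],
    segments: list[Segment] | None = None,
    participant_id: str = "",
) -> SensorFrame:
    """Linearly interpolate all channels onto the integer-second grid of their
    common support.

    No extrapolation: the frame is trimmed to the intersection of channel time
    spans.  Raises if that overlap is shorter than 2 s.
    """
    if not channels:
        raise PreprocessError("no channels to synchronize")
    t0 = max(ch.timestamps[0] for ch in channels.values())
    t1 = min(ch.timestamps[-1] for ch in channels.values())
    if t1 - t0 < 2:
        raise PreprocessError(f"channel overlap window [{t0}, {t1}] shorter than 2 s")
    grid = np.arange(int(np.ceil(t0)), int(np.floor(t1)) + 1)
    out = {
        name: np.interp(grid, ch.timestamps, ch.values) for name, ch in channels.items()
    }
    segs = list(segments) if segments else []
    return SensorFrame(time=grid, channels=out, segments=segs, participant_id=participant_id)


def delta_hr(hr: np.ndarray) -> np.ndarray:
    """One-second lagged heart-rate difference: out[t] = hr[t] - hr[t-1], out[0] = 0."""
    hr = np.asarray(hr, dtype=float)
    if hr.size == 0:
        raise PreprocessError("delta_hr: empty input")
    return np.diff(hr, prepend=hr[:1])


def lowpass_001(
    series: np.ndarray, cutoff: float = 0.01, fs: float = 1.0, order: int = 4
) -> np.ndarray:
    """Zero-phase low-pass: forward-backward 4th-order Butterworth at `cutoff` Hz.

    Zero-phase filtering is essential here — a causal filter would delay the
    oxygen-uptake signal relative to its drivers and distort the temporal
    dynamics the gain analysis later measures.  Edges are handled by scipy's
    odd-reflection padding, 300 samples per end (capped for short series),
    which spans the ~100-s characteristic period of the cutoff.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 6 * order:
        raise PreprocessError(f"series of length {x.size} too short to filter (need {6 * order})")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    padlen = min(300, x.size - 1)
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def build_feature_matrix(
    frame: SensorFrame,
    restrict_to: tuple[str, ...] | None = None,
    filtered: bool = True,
) -> FeatureMatrix:
    """Assemble the model matrix from a SensorFrame.

    Columns follow :data:`FEATURE_ORDER` (HR, ΔHR, VE, BF, Hacc, CAD); the
    target is VO2.  With ``filtered=True`` every column and the target pass
    through the 0.01-Hz zero-phase low-pass (ΔHR is derived from unfiltered HR
    first).  ``restrict_to`` keeps only rows inside the named segments.
    """
    required = ("HR", "VE", "BF", "Hacc", "CAD", "VO2")
    missing = [c for c in required if c not in frame.channels]
    if missing:
        raise PreprocessError(f"missing channels: {missing}")
    cols = {
        "HR": np.asarray(frame.channels["HR"], dtype=float),
        "VE": np.asarray(frame.channels["VE"], dtype=float),
        "BF": np.asarray(frame.channels["BF"], dtype=float),
        "Hacc": np.asarray(frame.channels["Hacc"], dtype=float),
        "CAD": np.asarray(frame.channels["CAD"], dtype=float),
    }
    cols["dHR"] = delta_hr(cols["HR"])
    target = np.asarray(frame.channels["VO2"], dtype=float)
    if filtered:
        cols = {k: lowpass_001(v) for k, v in cols.items()}
        target = lowpass_001(target)
    X = np.column_stack([cols[name] for name in FEATURE_ORDER])
    bad = ~np.isfinite(X).all(axis=1) | ~np.isfinite(target)
    if bad.any():
        raise PreprocessError(f"non-finite value at row {int(np.flatnonzero(bad)[0])}")
    if restrict_to is not None:
        mask = frame.segment_mask(*restrict_to)
        X, target = X[mask], target[mask]
    pid = np.full(X.shape[0], frame.participant_id, dtype=object)
    return FeatureMatrix(X=X, y=target, participant_ids=pid)
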