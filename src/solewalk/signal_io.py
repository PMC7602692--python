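"""Reading, calibration, smoothing and windowing of plantar-pressure recordings.

A recording is one bout of one activity by one subject: 14 force time series
(7 sensor sites x left/right foot) sampled at 100 Hz. On disk a bout is a CSV
with columns ``t,L1..L7,R1..R7`` (``t`` optional) and a cohort is described by
a manifest CSV with columns ``subject_id,activity,file``.

Sensor site codes (both feet):

====  =====================
code  anatomical location
====  =====================
1     heel
2     lateral midfoot
3     center midfoot
4     lateral forefoot
5     center forefoot
6     medial forefoot
7     big toe
====  =====================
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sps

#: The nine activity classes, in canonical (lexicographic-stable) order.
ACTIVITIES: tuple[str, ...] = (
    "cycling",
    "office_work",
    "running",
    "sitting",
    "standing",
    "walking_downstairs",
    "walking_flat",
    "walking_slope",
    "walking_upstairs",
)

FEET: tuple[str, str] = ("left", "right")
SITES: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)

#: CSV column order for the 14 channels.
CHANNEL_COLUMNS: tuple[str, ...] = tuple(
    f"{foot[0].upper()}{site}" for foot in FEET for site in SITES
)

#: FSR sensing span in newtons.
SENSOR_RANGE_N: tuple[float, float] = (0.2, 20.0)

ADC_MAX = 4095  # 12-bit acquisition unit


def _column_key(col: str) -> tuple[str, int]:
    foot = "left" if col[0] == "L" else "right"
    return foot, int(col[1:])


@dataclass
class PressureRecording:
    """One labeled bout of 14-channel plantar-pressure data.

    ``channels`` maps ``(foot, site)`` -> force series in newtons; all series
    share the same length.
    """

    subject_id: str
    activity: str
    channels: dict[tuple[str, int], np.ndarray]
    sampling_rate: float = 100.0
    source: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise ValueError(
                f"unknown activity {self.activity!r}; expected one of {ACTIVITIES}"
            )
        lengths = {len(v) for v in self.channels.values()}
        if len(self.channels) != 14 or set(self.channels) != {
            (f, s) for f in FEET for s in SITES
        }:
            raise ValueError("a recording requires exactly the 14 (foot, site) channels")
        if len(lengths) != 1:
            raise ValueError(f"channel lengths differ: {sorted(lengths)}")
        if next(iter(lengths)) < 1:
            raise ValueError("channels must contain at least one sample")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, foot: str, site: int) -> np.ndarray:
        return self.channels[(foot, site)]

    def to_frame(self, include_time: bool = True) -> pd.DataFrame:
        """Channels as a DataFrame in the on-disk column dialect."""
        data: dict[str, np.ndarray] = {}
        if include_time:
            data["t"] = np.arange(self.n_samples) / self.sampling_rate
        for col in CHANNEL_COLUMNS:
            data[col] = self.channels[_column_key(col)]
        return pd.DataFrame(data)

    def smoothed(self) -> "PressureRecording":
        """Copy with every channel low-pass filtered (see :func:`lowpass_smooth`)."""
        return PressureRecording(
            subject_id=self.subject_id,
            activity=self.activity,
            channels={
                k: lowpass_smooth(v, self.sampling_rate) for k, v in self.channels.items()
            },
            sampling_rate=self.sampling_rate,
            source=self.source,
        )


@dataclass(frozen=True)
class Window:
    """A half-open sample slice ``[start_index, end_index)`` of one recording."""

    recording: PressureRecording
    start_index: int
    end_index: int

    @property
    def length_s(self) -> float:
        return (self.end_index - self.start_index) / self.recording.sampling_rate

    @property
    def start_s(self) -> float:
        return self.start_index / self.recording.sampling_rate

    def channel(self, foot: str, site: int) -> np.ndarray:
        return self.recording.channels[(foot, site)][self.start_index : self.end_index]


# ---------------------------------------------------------------------------
# calibration


class LinearCalibration:
    """ADC counts -> newtons via ``force = gain * raw + offset``, clipped at 0."""

    def __init__(self, gain: float, offset: float = 0.0):
        if gain < 0:
            raise ValueError("calibration gain must be non-negative")
        self.gain = float(gain)
        self.offset = float(offset)

    def __call__(self, raw: np.ndarray) -> np.ndarray:
        return self.gain * np.asarray(raw, dtype=float) + self.offset


class PiecewiseLinearCalibration:
    """Monotone lookup-table calibration interpolated between (raw, newton) knots."""

    def __init__(self, raw_points, newton_points):
        raw_points = np.asarray(raw_points, dtype=float)
        newton_points = np.asarray(newton_points, dtype=float)
        if raw_points.shape != newton_points.shape or raw_points.ndim != 1:
            raise ValueError("calibration knots must be two equal-length 1-D sequences")
        if np.any(np.diff(raw_points) <= 0):
            raise ValueError("raw calibration knots must be strictly increasing")
        if np.any(np.diff(newton_points) < 0):
            raise ValueError("calibration must be monotone non-decreasing")
        self.raw_points = raw_points
        self.newton_points = newton_points

    def __call__(self, raw: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(raw, dtype=float), self.raw_points, self.newton_points)


#: Default curve mapping the full 12-bit span onto the 0-20 N sensing span.
DEFAULT_CALIBRATION = LinearCalibration(gain=SENSOR_RANGE_N[1] / ADC_MAX)


def convert_to_newtons(raw, calibration=None) -> np.ndarray:
    """Convert a raw 12-bit ADC series to forces in newtons.

    The calibration curve must be monotone non-decreasing over [0, 4095]
    (checked by sampling); output is clipped below at 0 N.
    """
    if calibration is None:
        calibration = DEFAULT_CALIBRATION
    raw = np.asarray(raw, dtype=float)
    if raw.size and (raw.min() < 0 or raw.max() > ADC_MAX):
        raise ValueError(f"raw ADC values must lie in [0, {ADC_MAX}]")
    grid = calibration(np.linspace(0, ADC_MAX, 257))
    if np.any(np.diff(grid) < -1e-12):
        raise ValueError("calibration curve is not monotone non-decreasing")
    return np.clip(calibration(raw), 0.0, None)


# ---------------------------------------------------------------------------
# smoothing

_FILTER_ORDER = 2
_CUTOFF_HZ = 5.0


def lowpass_smooth(series, sampling_rate: float = 100.0) -> np.ndarray:
    """Zero-phase second-order Butterworth low-pass at 5 Hz.

    Applied forward-backward (``filtfilt``) so peak timing is not shifted;
    the effective magnitude response is the squared single-pass response.
    """
    series = np.asarray(series, dtype=float)
    if sampling_rate <= 2 * _CUTOFF_HZ:
        raise ValueError("sampling_rate must exceed twice the 5 Hz cutoff")
    b, a = _sps.butter(_FILTER_ORDER, _CUTOFF_HZ, btype="low", fs=sampling_rate)
    padlen = 3 * max(len(a), len(b))
    if len(series) <= padlen:
        raise ValueError(f"series too short to filter (need > {padlen} samples)")
    return _sps.filtfilt(b, a, series)


# ---------------------------------------------------------------------------
# windowing

#: Window lengths (seconds) of the standard sweep.
WINDOW_LENGTHS_S: tuple[int, ...] = (1, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55, 60)


def segment_windows(rec: PressureRecording, length_s: float) -> list[Window]:
    """Cut a recording into windows of ``length_s`` seconds with 50% overlap.

    Consecutive windows advance by exactly half a window; a trailing fragment
    shorter than the window is discarded. A recording shorter than one window
    yields an empty list.
    """
    n_win = length_s * rec.sampling_rate
    if abs(n_win - round(n_win)) > 1e-9:
        raise ValueError("length_s x sampling_rate must be an integer sample count")
    L = int(round(n_win))
    if L < 2 or L % 2:
        raise ValueError("window must span an even number >= 2 of samples")
    if rec.n_samples < L:
        return []
    stride = L // 2
    starts = range(0, rec.n_samples - L + 1, stride)
    return [Window(rec, s, s + L) for s in starts]


# ---------------------------------------------------------------------------
# disk I/O


def write_recording(rec: PressureRecording, path, include_time: bool = True) -> None:
    """Write one bout as CSV in the ``t,L1..L7,R1..R7`` dialect."""
    # %.17g round-trips float64 exactly
    rec.to_frame(include_time=include_time).to_csv(path, index=False, float_format="%.17g")


def _read_bout_csv(path, subject_id: str, activity: str) -> PressureRecording:
    try:
        # round_trip parsing keeps write->read exact to the last ulp
        frame = pd.read_csv(path, float_precision="round_trip")
    except ValueError as exc:  # non-numeric cells surface here on conversion below
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    cols = [c for c in frame.columns if c != "t"]
    if list(cols) != list(CHANNEL_COLUMNS):
        raise ValueError(
            f"schema error in {path}: expected channel columns {list(CHANNEL_COLUMNS)}, "
            f"found {cols}"
        )
    channels = {}
    for col in CHANNEL_COLUMNS:
        values = pd.to_numeric(frame[col], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(values))
        if bad.size:
            # +2: header line plus 1-based numbering
            raise ValueError(f"non-numeric value in {path}, column {col}, line {bad[0] + 2}")
        channels[_column_key(col)] = values
    return PressureRecording(subject_id=subject_id, activity=activity, channels=channels,
                             source=str(path))


def read_recordings(manifest_path, data_dir=None) -> list[PressureRecording]:
    """Read a cohort from a manifest CSV (columns ``subject_id,activity,file``).

    Each manifest row becomes one recording; bouts split across several files
    stay separate recordings (never concatenated across the gap).
    """
    manifest = pd.read_csv(manifest_path)
    required = {"subject_id", "activity", "file"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    if data_dir is None:
        data_dir = os.path.dirname(os.fspath(manifest_path))
    recordings = []
    for i, row in manifest.iterrows():
        path = os.path.join(data_dir, str(row["file"]))
        if not os.path.exists(path):
            raise FileNotFoundError(f"manifest row {i}: file not found: {path}")
        recordings.append(_read_bout_csv(path, str(row["subject_id"]), str(row["activity"])))
    return recordings
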