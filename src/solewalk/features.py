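"""Window features for activity recognition from plantar-pressure signals.

Five feature families are computed per analysis window:

- **general statistics** (4 per channel): mean, maximum, SD, median;
- **peak analysis** (7 per channel): peak count, inter-peak interval
  (mean, SD), peak magnitude (mean, SD), peak width at 30% of peak height
  (mean, SD);
- **gait phase** (2 per window): average difference between the
  foot-landing force peak (early stance) and the foot-lift force peak
  (late stance), and the average duration of the double-float phase when
  neither foot is in ground contact;
- **frequency domain** (5 per window): spectral features of the summed
  signal over the 0.05-50 Hz AC band;
- **pressure distribution** (up to 6 per window): anterior-posterior
  (forefoot envelope vs heel) and medial-lateral (medial vs lateral
  forefoot) force differences and Pearson correlations.

All SDs use the population convention (divide by n). Degenerate statistics
(no peaks, empty bands, zero-variance correlations) resolve to 0. The
per-foot *envelope* is the pointwise maximum over the selected channels of
that foot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sps
from scipy import stats as _stats

from solewalk.sensor_config import (
    SensorConfiguration,
    available_features,
)
from solewalk.signal_io import FEET, PressureRecording, Window, segment_windows


@dataclass
class FeatureParams:
    """Tunable thresholds of the gait-phase analysis.

    contact_rel
        Ground-contact threshold as a fraction of the foot-envelope maximum
        within the window.
    contact_floor_n
        Absolute floor on the contact threshold in newtons (twice the 0.2 N
        sensor sensing floor), so noise in unloaded windows never registers
        as contact.
    """

    contact_rel: float = 0.05
    contact_floor_n: float = 0.4


DEFAULT_PARAMS = FeatureParams()


@dataclass
class PeakSet:
    """Local maxima of one channel: positions, magnitudes, widths, intervals."""

    indices: np.ndarray        # sample positions, strictly increasing
    magnitudes: np.ndarray     # force at each peak (N)
    widths: np.ndarray         # seconds, chord at 30% of peak height
    intervals: np.ndarray      # seconds between consecutive peaks

    @property
    def n(self) -> int:
        return len(self.indices)


@dataclass
class FeatureVector:
    """Named feature values for one window under one sensor configuration."""

    values: dict[str, float]
    config: SensorConfiguration
    window: Window | None = field(default=None, compare=False)

    def as_array(self) -> np.ndarray:
        return np.fromiter(self.values.values(), dtype=float, count=len(self.values))


# ---------------------------------------------------------------------------
# general statistics


def general_statistics(series) -> tuple[float, float, float, float]:
    """(mean, max, population SD, median) of a force series."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("general_statistics requires a non-empty series")
    return float(x.mean()), float(x.max()), float(x.std()), float(np.median(x))


# ---------------------------------------------------------------------------
# peak analysis


def _width_bounds(x: np.ndarray, peak: int, h: float, x_min: float) -> tuple[float, float]:
    """Sub-sample endpoints of the maximal interval containing ``peak`` with x >= h."""
    n = len(x)
    if x_min >= h:  # whole window stays above the 30% chord
        return 0.0, float(n - 1)
    # scan left in blocks for the nearest sample below h
    left_pos = 0.0
    pos = peak
    while pos > 0:
        lo = max(0, pos - 256)
        below = np.flatnonzero(x[lo:pos] < h)
        if below.size:
            li = lo + below[-1]
            left_pos = li + (h - x[li]) / (x[li + 1] - x[li])
            break
        pos = lo
    right_pos = float(n - 1)
    pos = peak + 1
    while pos < n:
        hi = min(n, pos + 256)
        below = np.flatnonzero(x[pos:hi] < h)
        if below.size:
            ri = pos + below[0]
            right_pos = (ri - 1) + (x[ri - 1] - h) / (x[ri - 1] - x[ri])
            break
        pos = hi
    return left_pos, right_pos


def detect_peaks(series, sampling_rate: float = 100.0) -> PeakSet:
    """Local maxima with no height/prominence threshold; plateaus resolve to
    their midpoint. Peak width = duration of the maximal contiguous interval
    containing the peak where the series stays at or above 30% of the peak
    magnitude, with linear interpolation at the crossings."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("detect_peaks requires a non-empty series")
    indices, _ = _sps.find_peaks(x)
    if indices.size == 0:
        empty = np.empty(0)
        return PeakSet(indices, empty, empty, empty)
    magnitudes = x[indices]
    x_min = float(x.min())
    widths = np.empty(indices.size)
    for k, (p, m) in enumerate(zip(indices, magnitudes)):
        left, right = _width_bounds(x, int(p), 0.30 * m, x_min)
        widths[k] = (right - left) / sampling_rate
    intervals = np.diff(indices) / sampling_rate
    return PeakSet(indices, magnitudes, widths, intervals)


def peak_features(ps: PeakSet) -> tuple[float, ...]:
    """(count, interval mean, interval SD, magnitude mean, magnitude SD,
    width mean, width SD); statistics of empty sets are 0."""

    def _mean_sd(v: np.ndarray) -> tuple[float, float]:
        if v.size == 0:
            return 0.0, 0.0
        return float(v.mean()), float(v.std())

    im, isd = _mean_sd(ps.intervals)
    mm, msd = _mean_sd(ps.magnitudes)
    wm, wsd = _mean_sd(ps.widths)
    return float(ps.n), im, isd, mm, msd, wm, wsd


# ---------------------------------------------------------------------------
# gait phase


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def foot_envelope(window: Window, config: SensorConfiguration, foot: str) -> np.ndarray:
    """Pointwise maximum over the configuration's channels of one foot."""
    stack = np.stack([window.channel(foot, s) for s in config.sorted_sites])
    return stack.max(axis=0)


def contact_threshold(envelope: np.ndarray, params: FeatureParams = DEFAULT_PARAMS) -> float:
    return max(params.contact_rel * float(envelope.max()), params.contact_floor_n)


def _stance_landing_lift(env: np.ndarray, start: int, stop: int) -> float:
    """Early-stance peak minus late-stance peak for one full stance."""
    seg = env[start:stop]
    half = len(seg) // 2
    peaks, _ = _sps.find_peaks(seg)
    early = peaks[peaks < half]
    late = peaks[peaks >= half]
    early_val = seg[early[0]] if early.size else seg[:max(half, 1)].max()
    late_val = seg[late[-1]] if late.size else seg[half:].max() if half < len(seg) else seg.max()
    return float(early_val - late_val)


def gait_phase_features(
    window: Window,
    config: SensorConfiguration,
    params: FeatureParams = DEFAULT_PARAMS,
) -> tuple[float, float]:
    """(average landing-minus-lift force difference, mean double-float duration).

    Stance phases are contiguous super-threshold segments of a foot envelope
    lying entirely inside the window; segments touching the window border are
    discarded. The double float is an interior interval during which both
    feet are sub-threshold; windows without such intervals (static postures,
    walking) score 0.
    """
    n = window.end_index - window.start_index
    fs = window.recording.sampling_rate
    diffs: list[float] = []
    masks = {}
    for foot in FEET:
        env = foot_envelope(window, config, foot)
        thr = contact_threshold(env, params)
        mask = env >= thr
        masks[foot] = mask
        for start, stop in _runs(mask):
            if start == 0 or stop == n:  # not a full stance phase
                continue
            diffs.append(_stance_landing_lift(env, start, stop))
    landing_lift = float(np.mean(diffs)) if diffs else 0.0

    both_off = ~masks["left"] & ~masks["right"]
    floats = [
        (stop - start) / fs
        for start, stop in _runs(both_off)
        if start != 0 and stop != n
    ]
    double_float = float(np.mean(floats)) if floats else 0.0
    return landing_lift, double_float


# ---------------------------------------------------------------------------
# frequency domain

_BAND_AC = (0.05, 50.0)
_BAND_WEIGHTED = (1.67, 10.0)
_BAND_AC_STATS = (2.0, 10.0)
_EDGE_TOL = 1e-9


def frequency_features(summed, sampling_rate: float = 100.0) -> tuple[float, ...]:
    """Spectral features of the summed-channel signal.

    Discrete Fourier magnitudes (amplitude-normalized, DC excluded) over the
    0.05-50 Hz band give: (1) power density = mean squared magnitude over the
    band, (2) magnitude-weighted mean frequency over 1.67-10 Hz, (3) skewness
    of the magnitudes strictly below 10 Hz, (4) mean and (5) population SD of
    the magnitudes from 2 to 10 Hz. Band edges are inclusive; empty or
    zero-power bands score 0.
    """
    x = np.asarray(summed, dtype=float)
    n = x.size
    if n < sampling_rate:
        raise ValueError("frequency analysis needs a window of at least 1 s")
    amp = 2.0 / n * np.abs(np.fft.rfft(x))
    # FFT roundoff leaves ~1e-16-relative crumbs that would dominate ratio
    # features of spectrally empty bands; treat them as exact zeros
    amp[amp < 1e-12 * amp.max()] = 0.0
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)

    def band(lo, hi, include_hi=True):
        sel = (freqs >= lo - _EDGE_TOL) & (freqs > 0)
        sel &= freqs <= hi + _EDGE_TOL if include_hi else freqs < hi - _EDGE_TOL
        return amp[sel], freqs[sel]

    a_ac, _ = band(*_BAND_AC)
    power_density = float(np.mean(a_ac**2)) if a_ac.size else 0.0

    a_w, f_w = band(*_BAND_WEIGHTED)
    total = a_w.sum()
    weighted_mean = float((f_w * a_w).sum() / total) if total > 0 else 0.0

    a_skew, _ = band(_BAND_AC[0], 10.0, include_hi=False)
    if a_skew.size < 2 or np.ptp(a_skew) == 0:
        skewness = 0.0
    else:
        skewness = float(_stats.skew(a_skew))

    a_stats, _ = band(*_BAND_AC_STATS)
    if a_stats.size:
        ac_mean, ac_sd = float(a_stats.mean()), float(a_stats.std())
    else:
        ac_mean = ac_sd = 0.0
    return power_density, weighted_mean, skewness, ac_mean, ac_sd


# ---------------------------------------------------------------------------
# pressure distribution


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r; 0 when either series has zero variance."""
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def pressure_distribution_features(
    window: Window, config: SensorConfiguration
) -> dict[str, float]:
    """Anterior-posterior and medial-lateral distribution features.

    AP block (needs heel + any forefoot site): mean(forefoot envelope) -
    mean(heel) averaged over feet, plus Pearson r(forefoot envelope, heel)
    per foot. ML block (needs sites 4 and 6): mean(medial forefoot) -
    mean(lateral forefoot) averaged over feet, plus r(site 4, site 6) per
    foot. Requesting an unavailable block raises."""
    out: dict[str, float] = {}
    if config.has_ap_block:
        diffs = []
        for foot in FEET:
            heel = window.channel(foot, 1)
            ff = np.stack([window.channel(foot, s) for s in config.forefoot_sites]).max(axis=0)
            diffs.append(ff.mean() - heel.mean())
            out[f"pressure_distribution.ap_corr.{foot[0].upper()}"] = _pearson(ff, heel)
        out["pressure_distribution.ap_diff"] = float(np.mean(diffs))
    if config.has_ml_block:
        diffs = []
        for foot in FEET:
            lat = window.channel(foot, 4)
            med = window.channel(foot, 6)
            diffs.append(med.mean() - lat.mean())
            out[f"pressure_distribution.ml_corr.{foot[0].upper()}"] = _pearson(lat, med)
        out["pressure_distribution.ml_diff"] = float(np.mean(diffs))
    return out


# ---------------------------------------------------------------------------
# assembly


def extract(
    window: Window,
    config: SensorConfiguration,
    params: FeatureParams = DEFAULT_PARAMS,
) -> FeatureVector:
    """Compute every feature the configuration affords for one window.

    The key set of the result equals the configuration's feature catalog
    exactly, in catalog order; all values are finite.
    """
    fs = window.recording.sampling_rate
    values: dict[str, float] = {}
    summed = None
    for foot in FEET:
        tag = foot[0].upper()
        for site in config.sorted_sites:
            x = window.channel(foot, site)
            mean, mx, sd, med = general_statistics(x)
            values[f"general_statistics.mean.{tag}{site}"] = mean
            values[f"general_statistics.max.{tag}{site}"] = mx
            values[f"general_statistics.sd.{tag}{site}"] = sd
            values[f"general_statistics.median.{tag}{site}"] = med
            pf = peak_features(detect_peaks(x, fs))
            for stat, v in zip(
                ("n_peaks", "interval_mean", "interval_sd", "magnitude_mean",
                 "magnitude_sd", "width_mean", "width_sd"), pf):
                values[f"peak_analysis.{stat}.{tag}{site}"] = v
            summed = x.copy() if summed is None else summed + x
    landing_lift, double_float = gait_phase_features(window, config, params)
    values["gait_phase.landing_lift_diff"] = landing_lift
    values["gait_phase.double_float_s"] = double_float
    for name, v in zip(
        ("power_density", "weighted_mean_freq", "skewness_below_10hz",
         "ac_mean_2_10hz", "ac_sd_2_10hz"),
        frequency_features(summed, fs)):
        values[f"frequency_domain.{name}"] = v
    values.update(pressure_distribution_features(window, config))

    catalog = [e.feature_id for e in available_features(config)]
    ordered = {fid: values[fid] for fid in catalog}
    if len(ordered) != len(values):
        raise AssertionError("feature keys diverge from the configuration catalog")
    return FeatureVector(values=ordered, config=config, window=window)


def extract_matrix(
    recordings: list[PressureRecording],
    length_s: float,
    config: SensorConfiguration,
    params: FeatureParams = DEFAULT_PARAMS,
    smooth: bool = True,
) -> pd.DataFrame:
    """Feature matrix for a cohort: one row per window.

    Each recording is low-pass smoothed (unless ``smooth=False``), cut into
    50%-overlap windows of ``length_s`` seconds, and featurized under
    ``config``. Columns are the feature ids plus ``subject_id``, ``activity``
    and ``window_start_s``.
    """
    rows = []
    meta = []
    for rec in recordings:
        prepped = rec.smoothed() if smooth else rec
        for win in segment_windows(prepped, length_s):
            fv = extract(win, config, params)
            rows.append(fv.values)
            meta.append((rec.subject_id, rec.activity, win.start_s))
    columns = [e.feature_id for e in available_features(config)]
    frame = pd.DataFrame(rows, columns=columns)
    frame["subject_id"] = [m[0] for m in meta]
    frame["activity"] = [m[1] for m in meta]
    frame["window_start_s"] = [m[2] for m in meta]
    return frame
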