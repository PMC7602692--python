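"""Constructed-signal oracles for the five feature families."""

import numpy as np
import pytest

from solewalk import FULL_CONFIG, SensorConfiguration, extract
from solewalk.features import (
    detect_peaks,
    frequency_features,
    gait_phase_features,
    general_statistics,
    peak_features,
    pressure_distribution_features,
    PeakSet,
)
from solewalk.signal_io import FEET, SITES, PressureRecording, Window

FS = 100.0


def make_window(channel_map, n):
    """Window over a recording whose unspecified channels are zero."""
    channels = {
        (foot, site): np.zeros(n) for foot in FEET for site in SITES
    }
    for key, series in channel_map.items():
        channels[key] = np.asarray(series, dtype=float)
    rec = PressureRecording("S01", "standing", channels)
    return Window(rec, 0, n)


def raised_cosine_train(n, centers_s, width_s, height):
    t = np.arange(n) / FS
    x = np.zeros(n)
    for c in centers_s:
        z = (t - c) / width_s
        x += np.where(np.abs(z) <= 0.5, height * 0.5 * (1 + np.cos(2 * np.pi * z)), 0.0)
    return x


class TestGeneralStatistics:
    def test_constant_series(self):
        mean, mx, sd, med = general_statistics(np.full(10, 4.2))
        assert mean == pytest.approx(4.2) and med == pytest.approx(4.2)
        assert mx == 4.2 and sd == pytest.approx(0.0, abs=1e-12)

    def test_small_series_closed_form(self):
        mean, mx, sd, med = general_statistics([0, 1, 2, 3])
        assert (mean, mx, med) == (1.5, 3.0, 1.5)
        assert sd == pytest.approx(np.sqrt(1.25))  # population convention

    def test_negation_symmetry(self):
        x = np.array([0.5, 2.0, 1.0, 3.5])
        m1 = general_statistics(x)
        m2 = general_statistics(-x)
        assert m2[0] == -m1[0] and m2[2] == m1[2]
        assert m2[1] == -x.min() and m2[3] == -m1[3]

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            general_statistics([])


class TestPeakAnalysis:
    def test_monotone_series_has_no_peaks(self):
        ps = detect_peaks(np.linspace(0, 5, 200), FS)
        assert ps.n == 0
        assert peak_features(ps) == (0.0,) * 7

    def test_pulse_train_count_interval_magnitude(self):
        x = raised_cosine_train(2000, np.arange(1.0, 20.0, 2.0), 0.5, 7.0)
        ps = detect_peaks(x, FS)
        assert ps.n == 10
        assert ps.intervals.mean() == pytest.approx(2.0, abs=1 / FS)
        assert ps.intervals.std() == pytest.approx(0.0, abs=1 / FS)
        assert ps.magnitudes.mean() == pytest.approx(7.0, rel=1e-3)

    def test_triangle_width_is_70_percent_of_base(self):
        # chord at 30% of height of a triangle of base 1 s is 0.7 s
        t = np.arange(300) / FS
        x = 5.0 * np.clip(1 - np.abs(t - 1.5) / 0.5, 0, None)
        ps = detect_peaks(x, FS)
        assert ps.n == 1
        assert ps.widths[0] == pytest.approx(0.7, abs=1e-9)

    def test_plateau_resolves_to_midpoint(self):
        x = np.zeros(100)
        x[40:45] = 2.0
        ps = detect_peaks(x, FS)
        assert ps.n == 1 and ps.indices[0] == 42

    def test_single_peak_features(self):
        ps = detect_peaks(
            5.0 * np.clip(1 - np.abs(np.arange(100) / FS - 0.5) / 0.1, 0, None), FS
        )
        count, im, isd, mm, msd, wm, wsd = peak_features(ps)
        assert count == 1 and im == isd == 0.0
        assert mm == pytest.approx(5.0) and msd == 0.0
        assert wm > 0 and wsd == 0.0

    def test_degenerate_empty_peakset(self):
        empty = PeakSet(np.empty(0, int), np.empty(0), np.empty(0), np.empty(0))
        assert peak_features(empty) == (0.0,) * 7

    def test_width_spans_window_when_signal_never_drops(self):
        x = 10.0 + raised_cosine_train(500, [2.5], 0.5, 1.0)
        ps = detect_peaks(x, FS)
        assert ps.widths[0] == pytest.approx((len(x) - 1) / FS)


class TestGaitPhase:
    def test_static_standing_has_no_double_float(self):
        win = make_window(
            {(f, s): np.full(1000, 5.0) for f in FEET for s in (1, 5)}, 1000
        )
        landing_lift, double_float = gait_phase_features(win, FULL_CONFIG)
        assert double_float == 0.0 and landing_lift == 0.0

    def test_symmetric_stance_pulses_balance_landing_and_lift(self):
        n = 2000
        left = raised_cosine_train(n, np.arange(1.0, 20.0, 2.0), 0.8, 10.0)
        right = raised_cosine_train(n, np.arange(2.0, 20.0, 2.0), 0.8, 10.0)
        win = make_window({("left", 1): left, ("right", 1): right}, n)
        landing_lift, _ = gait_phase_features(win, FULL_CONFIG)
        assert landing_lift == pytest.approx(0.0, abs=0.05)

    def test_running_square_pulses_recover_flight_duration(self):
        # alternating 0.9 s contacts with 0.1 s of double float in between
        n = 2000
        left = np.zeros(n)
        right = np.zeros(n)
        for k in range(10):
            left[k * 200 : k * 200 + 90] = 10.0
            right[k * 200 + 100 : k * 200 + 190] = 10.0
        win = make_window({("left", 1): left, ("right", 1): right}, n)
        _, double_float = gait_phase_features(win, FULL_CONFIG)
        assert double_float == pytest.approx(0.10, abs=1 / FS)

    def test_asymmetric_stance_sign_convention(self):
        # landing peak 11 N, lift peak 7 N on a shared 1 N contact plateau
        # spanning the whole stance -> positive difference ~4 N
        n = 2000
        t = np.arange(n) / FS
        landing = raised_cosine_train(n, np.arange(0.8, 20.0, 2.0), 0.4, 10.0)
        lift = raised_cosine_train(n, np.arange(1.4, 20.0, 2.0), 0.4, 6.0)
        plateau = np.zeros(n)
        for k in np.arange(0.6, 19.0, 2.0):
            plateau[(t >= k) & (t <= k + 1.0)] = 1.0
        x = landing + lift + plateau
        win = make_window({("left", 1): x, ("right", 1): x}, n)
        landing_lift, _ = gait_phase_features(win, FULL_CONFIG)
        assert landing_lift == pytest.approx(4.0, abs=0.1)


class TestFrequencyDomain:
    def test_constant_signal_is_all_zero(self):
        feats = frequency_features(np.full(2000, 8.0), FS)
        assert feats == pytest.approx((0.0,) * 5, abs=1e-12)

    def test_single_line_weighted_mean_frequency(self):
        t = np.arange(2000) / FS
        feats = frequency_features(np.sin(2 * np.pi * 3.0 * t), FS)
        assert feats[1] == pytest.approx(3.0, abs=0.05)
        assert feats[0] > 0

    def test_two_equal_lines_average_to_midpoint(self):
        t = np.arange(2000) / FS
        x = np.sin(2 * np.pi * 3.0 * t) + np.sin(2 * np.pi * 7.0 * t)
        feats = frequency_features(x, FS)
        assert feats[1] == pytest.approx(5.0, abs=0.05)

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            frequency_features(np.ones(50), FS)


class TestPressureDistribution:
    def test_identical_forefoot_and_heel(self):
        t = np.arange(1000) / FS
        s = 5 + np.sin(2 * np.pi * t)
        win = make_window(
            {(f, site): s.copy() for f in FEET for site in (1, 4, 5, 6, 7)}, 1000
        )
        out = pressure_distribution_features(win, FULL_CONFIG)
        assert out["pressure_distribution.ap_diff"] == pytest.approx(0.0, abs=1e-12)
        assert out["pressure_distribution.ap_corr.L"] == pytest.approx(1.0)
        assert out["pressure_distribution.ml_diff"] == pytest.approx(0.0, abs=1e-12)
        assert out["pressure_distribution.ml_corr.R"] == pytest.approx(1.0)

    def test_loaded_heel_silent_forefoot_sign(self):
        win = make_window({(f, 1): np.full(500, 10.0) for f in FEET}, 500)
        out = pressure_distribution_features(win, FULL_CONFIG)
        assert out["pressure_distribution.ap_diff"] == pytest.approx(-10.0)
        # zero-variance series: correlation defined as 0
        assert out["pressure_distribution.ap_corr.L"] == 0.0

    def test_unavailable_block_is_omitted(self):
        win = make_window({}, 500)
        config = SensorConfiguration.from_sites(2, 3)
        assert pressure_distribution_features(win, config) == {}


class TestExtract:
    def test_full_config_yields_exact_catalog(self):
        rng = np.random.default_rng(1)
        win = make_window(
            {(f, s): np.abs(rng.normal(2, 1, 2000)) for f in FEET for s in SITES}, 2000
        )
        fv = extract(win, FULL_CONFIG)
        assert len(fv.values) == 167
        assert all(np.isfinite(v) for v in fv.values.values())

    def test_heel_only_config_yields_29(self):
        win = make_window({}, 2000)
        fv = extract(win, SensorConfiguration.from_sites(1))
        assert len(fv.values) == 29

    def test_all_zero_window_features_are_zero(self):
        fv = extract(make_window({}, 2000), FULL_CONFIG)
        assert all(v == 0.0 for v in fv.values.values())

    def test_scaling_covariance_and_invariance(self):
        rng = np.random.default_rng(7)
        base = {
            (f, s): raised_cosine_train(
                2000, np.arange(0.9 + 0.1 * s, 19.0, 2.0), 0.6, 5.0 + s
            ) + 0.2 * np.abs(rng.normal(size=2000))
            for f in FEET for s in SITES
        }
        k = 3.0
        fv1 = extract(make_window(base, 2000), FULL_CONFIG)
        fv2 = extract(make_window({key: k * v for key, v in base.items()}, 2000),
                      FULL_CONFIG)
        invariant = ("n_peaks", "interval_", "width_", "corr",
                     "weighted_mean_freq", "double_float", "skewness")
        power = ("power_density",)
        for fid, v1 in fv1.values.items():
            v2 = fv2.values[fid]
            if any(tag in fid for tag in invariant):
                assert v2 == pytest.approx(v1, rel=1e-6, abs=1e-9), fid
            elif any(tag in fid for tag in power):
                assert v2 == pytest.approx(k**2 * v1, rel=1e-6), fid
            else:  # magnitude-type features scale linearly
                assert v2 == pytest.approx(k * v1, rel=1e-6, abs=1e-9), fid

    def test_foot_swap_leaves_averaged_features_unchanged(self):
        rng = np.random.default_rng(3)
        base = {
            (f, s): np.abs(rng.normal(3, 1, 1500)) for f in FEET for s in SITES
        }
        swapped = {("left" if f == "right" else "right", s): v
                   for (f, s), v in base.items()}
        fv1 = extract(make_window(base, 1500), FULL_CONFIG).values
        fv2 = extract(make_window(swapped, 1500), FULL_CONFIG).values
        for fid in ("pressure_distribution.ap_diff", "pressure_distribution.ml_diff",
                    "gait_phase.landing_lift_diff", "gait_phase.double_float_s"):
            assert fv2[fid] == pytest.approx(fv1[fid], abs=1e-12)
        assert fv2["pressure_distribution.ap_corr.L"] == pytest.approx(
            fv1["pressure_distribution.ap_corr.R"])
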