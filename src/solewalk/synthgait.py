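"""Synthetic plantar-pressure cohorts with per-activity gait structure.

The generator emulates the statistical structure an insole-based activity
classifier exploits, not biomechanical ground truth:

- gait activities are trains of stance pulses alternating between feet:
  a heel-strike bump early in stance, forefoot/toe push-off bumps late in
  stance, riding on a plateau contact load so the foot envelope stays
  super-threshold for the whole stance;
- running uses a short stance (< half the cycle) so both feet are airborne
  between steps (double float);
- static activities (sitting, standing) are constant site loads plus a slow
  postural sway oscillation;
- office work is a mixture of standing and short walking bouts;
- subjects differ by a multiplicative weight scale and a cadence offset,
  which is what makes subject-wise hold-out meaningfully harder than
  window-wise splits.

All randomness flows from one master seed through spawned substreams, so a
cohort is bit-reproducible. Forces are in newtons, clipped at 0, sampled at
100 Hz on 14 channels (7 sites x both feet).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from solewalk.signal_io import (
    ACTIVITIES,
    FEET,
    SITES,
    PressureRecording,
    write_recording,
)

# timing of the two intra-stance bumps, in normalized stance time
_EARLY_CENTER, _EARLY_WIDTH = 0.30, 0.55
_LATE_CENTER, _LATE_WIDTH = 0.75, 0.50
_CONTACT_RAMP = 0.025       # Tukey ramp fraction of the stance plateau
_JITTER_SD = 0.05           # per-stance amplitude jitter, clipped to +-3 SD


@dataclass(frozen=True)
class SubjectEffect:
    """Per-subject generative offsets: heavier/lighter, faster/slower."""

    weight_scale: float = 1.0
    cadence_offset_hz: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.weight_scale <= 0:
            raise ValueError("weight_scale must be positive")


@dataclass(frozen=True)
class ActivityProfile:
    """Generative parameters for one activity's pressure signals.

    ``site_amplitudes`` maps site -> (heel-strike amplitude, push-off
    amplitude) in newtons; ``static_load`` maps site -> baseline force for
    static activities. ``flight_fraction`` is the fraction of the gait cycle
    with both feet airborne (running); consistency requires
    ``stance_fraction + flight_fraction <= 0.5`` when flight is present.
    """

    activity: str
    cadence_hz: float = 0.0
    stance_fraction: float = 0.6
    flight_fraction: float = 0.0
    site_amplitudes: dict[int, tuple[float, float]] = field(default_factory=dict)
    static_load: dict[int, float] = field(default_factory=dict)
    sway_amp: float = 0.0
    sway_hz: float = 0.3
    noise_sd: float = 0.15
    contact_floor_frac: float = 0.2
    bout_mixture: tuple[tuple["ActivityProfile", float], ...] | None = None

    def __post_init__(self):
        if not 0 <= self.stance_fraction <= 1:
            raise ValueError("stance_fraction must lie in [0, 1]")
        if self.flight_fraction > 0 and self.cadence_hz <= 0:
            raise ValueError("flight requires a positive cadence")
        if self.flight_fraction > 0 and self.stance_fraction + self.flight_fraction > 0.5 + 1e-9:
            raise ValueError("stance_fraction + flight_fraction must not exceed 0.5")
        if self.noise_sd < 0 or self.sway_amp < 0:
            raise ValueError("noise_sd and sway_amp must be non-negative")
        for site, (ae, al) in self.site_amplitudes.items():
            if ae < 0 or al < 0:
                raise ValueError(f"site {site}: amplitudes must be non-negative")

    def max_force_bound(self, weight_scale: float = 1.0) -> float:
        """Upper bound on any generated sample (before noise) times the
        subject's weight scale, plus a 6-sigma noise allowance."""
        peak = 0.0
        for ae, al in self.site_amplitudes.values():
            peak = max(peak, ae + al + self.contact_floor_frac * max(ae, al))
        static = max(self.static_load.values(), default=0.0) + self.sway_amp
        if self.bout_mixture:
            sub = max(p.max_force_bound(1.0) - 6 * p.noise_sd for p, _ in self.bout_mixture)
            peak = max(peak, sub)
        jitter_cap = 1 + 3 * _JITTER_SD
        return max(peak * jitter_cap, static) * weight_scale + 6 * self.noise_sd


def _raised_cosine(tau: np.ndarray, center: float, width: float) -> np.ndarray:
    z = (tau - center) / width
    out = np.where(np.abs(z) <= 0.5, 0.5 * (1 + np.cos(2 * np.pi * z)), 0.0)
    return out


def _contact_plateau(tau: np.ndarray, ramp: float = _CONTACT_RAMP) -> np.ndarray:
    """Tukey-like plateau on [0, 1]: cosine ramps of length ``ramp``, flat 1."""
    out = np.zeros_like(tau)
    inside = (tau >= 0) & (tau <= 1)
    x = tau[inside]
    edge = np.minimum(x, 1 - x)
    out[inside] = np.where(edge >= ramp, 1.0, 0.5 * (1 - np.cos(np.pi * edge / ramp)))
    return out


def _gait_channels(
    profile: ActivityProfile,
    effect: SubjectEffect,
    n: int,
    fs: float,
    rng: np.random.Generator,
) -> dict[tuple[str, int], np.ndarray]:
    t = np.arange(n) / fs
    cadence = max(profile.cadence_hz + effect.cadence_offset_hz, 0.2)
    T = 1.0 / cadence
    stance = profile.stance_fraction * T
    channels = {(f, s): np.zeros(n) for f in FEET for s in SITES}
    for foot, offset in zip(FEET, (0.0, T / 2)):
        shifted = t - offset
        cycle = np.floor(shifted / T).astype(int)
        tau = (shifted - cycle * T) / stance        # normalized stance time
        in_stance = (tau >= 0) & (tau <= 1)
        e_early = np.where(in_stance, _raised_cosine(tau, _EARLY_CENTER, _EARLY_WIDTH), 0.0)
        e_late = np.where(in_stance, _raised_cosine(tau, _LATE_CENTER, _LATE_WIDTH), 0.0)
        plateau = np.where(in_stance, _contact_plateau(tau), 0.0)
        # one amplitude jitter value per gait cycle
        n_cycles = cycle.max() - cycle.min() + 1
        jit_values = 1 + np.clip(rng.normal(0, _JITTER_SD, n_cycles), -3 * _JITTER_SD, 3 * _JITTER_SD)
        jitter = jit_values[cycle - cycle.min()]
        for site in SITES:
            ae, al = profile.site_amplitudes.get(site, (0.0, 0.0))
            if ae == 0 and al == 0:
                continue
            shape = ae * e_early + al * e_late
            shape = shape + profile.contact_floor_frac * max(ae, al) * plateau
            channels[(foot, site)] += effect.weight_scale * jitter * shape
    return channels


def _static_channels(
    profile: ActivityProfile,
    effect: SubjectEffect,
    n: int,
    fs: float,
    rng: np.random.Generator,
) -> dict[tuple[str, int], np.ndarray]:
    t = np.arange(n) / fs
    channels = {}
    for foot in FEET:
        for site in SITES:
            base = profile.static_load.get(site, 0.0) * effect.weight_scale
            phase = rng.uniform(0, 2 * np.pi)
            sway = profile.sway_amp * np.sin(2 * np.pi * profile.sway_hz * t + phase)
            channels[(foot, site)] = base + sway
    return channels


def _generate_channels(profile, effect, duration_s, fs, rng):
    n = int(round(duration_s * fs))
    if profile.bout_mixture:
        parts: list[dict] = []
        total = 0
        i = 0
        while total < n:
            sub_profile, sub_dur = profile.bout_mixture[i % len(profile.bout_mixture)]
            m = min(int(round(sub_dur * fs)), n - total)
            parts.append(_generate_channels(sub_profile, effect, m / fs, fs, rng))
            total += m
            i += 1
        return {
            key: np.concatenate([p[key] for p in parts])
            for key in parts[0]
        }
    if profile.cadence_hz > 0:
        channels = _gait_channels(profile, effect, n, fs, rng)
    else:
        channels = _static_channels(profile, effect, n, fs, rng)
    if profile.noise_sd > 0:
        for key in channels:
            channels[key] = channels[key] + rng.normal(0, profile.noise_sd, n)
    return {key: np.clip(v, 0.0, None) for key, v in channels.items()}


def simulate_recording(
    profile: ActivityProfile,
    effect: SubjectEffect = SubjectEffect(),
    duration_s: float = 240.0,
    sampling_rate: float = 100.0,
    subject_id: str = "S01",
    seed: int | None = None,
) -> PressureRecording:
    """One synthetic bout; deterministic given the profile, effect and seed
    (``effect.seed`` when ``seed`` is omitted)."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(effect.seed if seed is None else seed)
    channels = _generate_channels(profile, effect, duration_s, sampling_rate, rng)
    return PressureRecording(
        subject_id=subject_id,
        activity=profile.activity,
        channels=channels,
        sampling_rate=sampling_rate,
    )


# ---------------------------------------------------------------------------
# default activity profiles


def default_profiles() -> dict[str, ActivityProfile]:
    """The nine stock activity profiles.

    Amplitudes are in the insole's 0-20 N sensing span; cadences are gait-
    cycle rates (two steps per cycle). Walking variants share the overall
    pulse-train structure and differ in heel/forefoot amplitude balance and
    cadence: upstairs is forefoot-dominant, downstairs heel-dominant with a
    flatter forefoot profile, slope walking forefoot-shifted relative to
    flat walking. Running has a short stance and a true flight phase.
    """
    walking = ActivityProfile(
        activity="walking_flat",
        cadence_hz=0.9,
        stance_fraction=0.62,
        site_amplitudes={
            1: (15.0, 0.0), 2: (3.0, 1.0), 3: (2.0, 1.0),
            4: (2.0, 8.0), 5: (3.0, 10.0), 6: (2.0, 9.0), 7: (0.0, 12.0),
        },
    )
    standing = ActivityProfile(
        activity="standing",
        static_load={1: 8.0, 2: 2.0, 3: 1.5, 4: 3.0, 5: 4.0, 6: 3.0, 7: 1.0},
        sway_amp=0.5,
        sway_hz=0.3,
    )
    slow_walk = replace(
        walking,
        cadence_hz=0.75,
        site_amplitudes={s: (ae * 0.7, al * 0.7) for s, (ae, al) in walking.site_amplitudes.items()},
    )
    return {
        "sitting": ActivityProfile(
            activity="sitting",
            static_load={s: 0.05 for s in SITES},
            sway_amp=0.02,
            sway_hz=0.2,
            noise_sd=0.05,
        ),
        "standing": standing,
        "walking_flat": walking,
        "walking_upstairs": ActivityProfile(
            activity="walking_upstairs",
            cadence_hz=0.75,
            stance_fraction=0.65,
            site_amplitudes={
                1: (6.0, 0.0), 2: (2.0, 1.0), 3: (2.0, 1.0),
                4: (3.0, 10.0), 5: (4.0, 13.0), 6: (3.0, 12.0), 7: (1.0, 14.0),
            },
        ),
        "walking_downstairs": ActivityProfile(
            activity="walking_downstairs",
            cadence_hz=0.85,
            stance_fraction=0.58,
            site_amplitudes={
                1: (17.0, 0.0), 2: (4.0, 1.0), 3: (3.0, 1.0),
                4: (6.0, 6.0), 5: (7.0, 7.0), 6: (5.0, 6.0), 7: (1.0, 6.0),
            },
        ),
        "walking_slope": ActivityProfile(
            activity="walking_slope",
            cadence_hz=0.85,
            stance_fraction=0.63,
            site_amplitudes={
                1: (12.0, 0.0), 2: (2.5, 1.0), 3: (2.0, 1.0),
                4: (2.0, 9.0), 5: (3.0, 12.0), 6: (2.0, 10.0), 7: (0.0, 13.0),
            },
        ),
        "running": ActivityProfile(
            activity="running",
            cadence_hz=1.4,
            stance_fraction=0.4,
            flight_fraction=0.1,
            site_amplitudes={
                1: (20.0, 0.0), 2: (5.0, 2.0), 3: (4.0, 2.0),
                4: (4.0, 14.0), 5: (6.0, 18.0), 6: (4.0, 16.0), 7: (1.0, 16.0),
            },
        ),
        "cycling": ActivityProfile(
            activity="cycling",
            cadence_hz=1.5,
            stance_fraction=0.55,
            site_amplitudes={
                1: (0.5, 0.0), 2: (0.5, 0.3), 3: (0.5, 0.3),
                4: (2.0, 3.0), 5: (3.0, 4.0), 6: (2.0, 3.0), 7: (1.0, 2.0),
            },
            noise_sd=0.1,
        ),
        "office_work": ActivityProfile(
            activity="office_work",
            bout_mixture=(
                (replace(standing, activity="office_work"), 12.0),
                (replace(slow_walk, activity="office_work"), 4.0),
                (replace(standing, activity="office_work"), 8.0),
                (replace(slow_walk, activity="office_work"), 3.0),
            ),
        ),
    }


#: Bout durations in seconds (walking on a flat surface and running are
#: recorded twice as long as the other activities).
DEFAULT_DURATIONS_S: dict[str, float] = {
    a: 480.0 if a in ("walking_flat", "running") else 240.0 for a in ACTIVITIES
}


def simulate_cohort(
    n_subjects: int,
    profiles: dict[str, ActivityProfile] | None = None,
    durations: dict[str, float] | float | None = None,
    master_seed: int = 0,
    dropout: list[int] | None = None,
) -> tuple[list[PressureRecording], pd.DataFrame]:
    """Generate a cohort of subjects, each performing (up to) 9 activities.

    Subject effects are drawn per subject: weight scale lognormal(sd 0.12),
    cadence offset normal(sd 0.06 Hz). ``dropout`` optionally gives the
    number of activities each subject completes (e.g. ``[9]*11 + [8]*2 +
    [7]*2 + [6] + [5]`` mimics partial participation); dropped activities
    are chosen at random per subject. Returns the recordings and a manifest
    frame (``subject_id,activity,file``) in the on-disk dialect.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    if profiles is None:
        profiles = default_profiles()
    if durations is None:
        durations = DEFAULT_DURATIONS_S
    if np.isscalar(durations):
        durations = {a: float(durations) for a in profiles}
    if dropout is not None and len(dropout) != n_subjects:
        raise ValueError("dropout must list one activity count per subject")
    root = np.random.SeedSequence(master_seed)
    subject_seeds = root.spawn(n_subjects)
    recordings: list[PressureRecording] = []
    manifest_rows = []
    for i, sseq in enumerate(subject_seeds):
        subject_id = f"S{i + 1:02d}"
        rng = np.random.default_rng(sseq)
        effect = SubjectEffect(
            weight_scale=float(np.exp(rng.normal(0, 0.12))),
            cadence_offset_hz=float(rng.normal(0, 0.06)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        activities = sorted(profiles)
        if dropout is not None and dropout[i] < len(activities):
            keep = rng.choice(len(activities), size=dropout[i], replace=False)
            activities = [activities[j] for j in sorted(keep)]
        for activity in activities:
            bout_seed = int(rng.integers(0, 2**31 - 1))
            rec = simulate_recording(
                profiles[activity],
                effect,
                duration_s=durations[activity],
                subject_id=subject_id,
                seed=bout_seed,
            )
            recordings.append(rec)
            manifest_rows.append(
                {"subject_id": subject_id, "activity": activity,
                 "file": f"{subject_id}_{activity}.csv"}
            )
    return recordings, pd.DataFrame(manifest_rows)


def write_cohort(
    recordings: list[PressureRecording],
    manifest: pd.DataFrame,
    out_dir,
) -> str:
    """Write every bout CSV plus ``manifest.csv``; returns the manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    by_key = {(r.subject_id, r.activity): r for r in recordings}
    for _, row in manifest.iterrows():
        rec = by_key[(row["subject_id"], row["activity"])]
        write_recording(rec, os.path.join(out_dir, row["file"]))
    manifest_path = os.path.join(out_dir, "manifest.csv")
    manifest.to_csv(manifest_path, index=False)
    return manifest_path
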