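"""Sensor subsets and the feature-availability arithmetic they induce.

An insole carries up to 7 force sensors; a configuration is a non-empty
subset of sites applied symmetrically to both feet, so the configuration
space has 2^7 - 1 = 127 members. Most window features are computed per
channel, but the gait-phase, frequency-domain and pressure-distribution
families depend on which sites are present:

- per channel: 4 general statistics + 7 peak-analysis features;
- always: 2 gait-phase features (on the per-foot envelope of whatever sites
  are present) and 5 frequency-domain features (on the summed signal);
- anterior-posterior pressure-distribution block (3 features) only when the
  heel (site 1) and at least one forefoot site ({4,5,6,7}) are present;
- medial-lateral block (3 features) only when both the lateral (4) and
  medial (6) forefoot sensors are present.

Hence the closed form ``count = 22*|sites| + 7 + 3*[AP] + 3*[ML]``, which at
the full configuration gives 167 features.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from solewalk.signal_io import FEET, SITES

SITE_NAMES: dict[int, str] = {
    1: "heel",
    2: "lateral midfoot",
    3: "center midfoot",
    4: "lateral forefoot",
    5: "center forefoot",
    6: "medial forefoot",
    7: "big toe",
}

#: Forefoot sensor group used for the anterior-posterior envelope.
FOREFOOT_SITES: frozenset[int] = frozenset({4, 5, 6, 7})

GENERAL_STATS: tuple[str, ...] = ("mean", "max", "sd", "median")
PEAK_STATS: tuple[str, ...] = (
    "n_peaks",
    "interval_mean",
    "interval_sd",
    "magnitude_mean",
    "magnitude_sd",
    "width_mean",
    "width_sd",
)
GAIT_PHASE_FEATURES: tuple[str, ...] = ("landing_lift_diff", "double_float_s")
FREQUENCY_FEATURES: tuple[str, ...] = (
    "power_density",
    "weighted_mean_freq",
    "skewness_below_10hz",
    "ac_mean_2_10hz",
    "ac_sd_2_10hz",
)

CATEGORIES: tuple[str, ...] = (
    "general_statistics",
    "peak_analysis",
    "gait_phase",
    "frequency_domain",
    "pressure_distribution",
)


@dataclass(frozen=True)
class SensorConfiguration:
    """A non-empty subset of the 7 sensor sites, mirrored on both feet."""

    sites: frozenset[int]
    label: str = ""

    def __post_init__(self):
        sites = frozenset(int(s) for s in self.sites)
        object.__setattr__(self, "sites", sites)
        if not sites or not sites <= set(SITES):
            raise ValueError(f"sites must be a non-empty subset of {set(SITES)}")
        if not self.label:
            object.__setattr__(self, "label", "S" + "".join(map(str, sorted(sites))))

    @classmethod
    def from_sites(cls, *sites: int, label: str = "") -> "SensorConfiguration":
        return cls(frozenset(sites), label)

    @property
    def sorted_sites(self) -> tuple[int, ...]:
        return tuple(sorted(self.sites))

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def has_ap_block(self) -> bool:
        """Anterior-posterior distribution features available?"""
        return 1 in self.sites and bool(self.sites & FOREFOOT_SITES)

    @property
    def has_ml_block(self) -> bool:
        """Medial-lateral distribution features available?"""
        return {4, 6} <= self.sites

    @property
    def forefoot_sites(self) -> tuple[int, ...]:
        return tuple(sorted(self.sites & FOREFOOT_SITES))


#: The full 7-sensor configuration.
FULL_CONFIG = SensorConfiguration.from_sites(*SITES, label="full")


@dataclass(frozen=True)
class FeatureCatalogEntry:
    """One scalar feature a configuration affords for each analysis window."""

    feature_id: str
    category: str
    required_sites: frozenset[int]
    per_channel: bool


def enumerate_configurations(max_sites: int = 7) -> list[SensorConfiguration]:
    """All non-empty site subsets of size <= ``max_sites``, ordered by size
    then lexicographically. ``max_sites=7`` yields all 127."""
    if not 1 <= max_sites <= 7:
        raise ValueError("max_sites must be in 1..7")
    configs = []
    for k in range(1, max_sites + 1):
        for combo in combinations(SITES, k):
            configs.append(SensorConfiguration(frozenset(combo)))
    return configs


def available_features(config: SensorConfiguration) -> list[FeatureCatalogEntry]:
    """The exact feature catalog a configuration affords, in extraction order.

    Order: per-channel blocks (left foot sites ascending, then right), general
    statistics before peak analysis within a channel; then gait phase,
    frequency domain, and the pressure-distribution blocks.
    """
    entries: list[FeatureCatalogEntry] = []
    for foot in FEET:
        tag = foot[0].upper()
        for site in config.sorted_sites:
            req = frozenset({site})
            for stat in GENERAL_STATS:
                entries.append(FeatureCatalogEntry(
                    f"general_statistics.{stat}.{tag}{site}", "general_statistics",
                    req, True))
            for stat in PEAK_STATS:
                entries.append(FeatureCatalogEntry(
                    f"peak_analysis.{stat}.{tag}{site}", "peak_analysis", req, True))
    for name in GAIT_PHASE_FEATURES:
        entries.append(FeatureCatalogEntry(
            f"gait_phase.{name}", "gait_phase", frozenset(config.sites), False))
    for name in FREQUENCY_FEATURES:
        entries.append(FeatureCatalogEntry(
            f"frequency_domain.{name}", "frequency_domain", frozenset(config.sites), False))
    if config.has_ap_block:
        req = frozenset({1} | set(config.forefoot_sites))
        entries.append(FeatureCatalogEntry(
            "pressure_distribution.ap_diff", "pressure_distribution", req, False))
        for tag in ("L", "R"):
            entries.append(FeatureCatalogEntry(
                f"pressure_distribution.ap_corr.{tag}", "pressure_distribution", req, False))
    if config.has_ml_block:
        req = frozenset({4, 6})
        entries.append(FeatureCatalogEntry(
            "pressure_distribution.ml_diff", "pressure_distribution", req, False))
        for tag in ("L", "R"):
            entries.append(FeatureCatalogEntry(
                f"pressure_distribution.ml_corr.{tag}", "pressure_distribution", req, False))
    return entries


def count_features(config: SensorConfiguration) -> int:
    """Number of features the configuration affords.

    Closed form: ``(4 + 7) * 2 * |sites| + 7 + 3*[AP block] + 3*[ML block]``.
    """
    n = (len(GENERAL_STATS) + len(PEAK_STATS)) * 2 * config.n_sites
    n += len(GAIT_PHASE_FEATURES) + len(FREQUENCY_FEATURES)
    if config.has_ap_block:
        n += 3
    if config.has_ml_block:
        n += 3
    return n
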