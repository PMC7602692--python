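"""Feature-availability arithmetic of sensor configurations.

Every insole configuration is a subset of the 7 sensor sites, mirrored on
both feet. Each site contributes 11 per-channel features per foot; 7
whole-foot features are always computable; the anterior-posterior pressure
block (3 features) needs the heel plus a forefoot sensor, and the
medial-lateral block (3) needs both forefoot edge sensors. The script
prints the counts for the best k-sensor configurations — their sum is the
total number of (configuration, feature-count) combinations a full
elimination study has to cover.
"""

from solewalk import SensorConfiguration, count_features, enumerate_configurations

best = {
    1: (1,), 2: (1, 4), 3: (1, 2, 5), 4: (1, 2, 4, 5),
    5: (1, 2, 3, 4, 5), 6: (1, 2, 3, 4, 5, 7), 7: tuple(range(1, 8)),
}
print(f"configuration space: {len(enumerate_configurations(7))} site subsets")
total = 0
for k, sites in best.items():
    config = SensorConfiguration.from_sites(*sites)
    n = count_features(config)
    total += n
    print(f"best {k}-sensor {str(sites):24s} -> {n:3d} features")
print(f"sum of maxima over the best configurations: {total}")
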