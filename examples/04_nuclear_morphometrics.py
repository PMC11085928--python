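"""Nuclear morphometrics: areas, axis ratios, log-normal fits, group tests.

Emulates comparing nuclear areas between a flat culture plate (large,
spread nuclei) and a fibrous scaffold (smaller, rounder nuclei).
"""

import numpy as np

from infiltra import MorphSample, compare_groups, fit_lognormal

rng = np.random.default_rng(0)

# log-normal area distributions: plate nuclei larger than on-scaffold nuclei
plate = MorphSample("plate", rng.lognormal(np.log(180), 0.35, 15000))
mat_a = MorphSample("mat A", rng.lognormal(np.log(150), 0.35, 15000))
mat_b = MorphSample("mat B", rng.lognormal(np.log(148), 0.35, 15000))

for s in (plate, mat_a, mat_b):
    mu, sigma, ks = fit_lognormal(s.areas_um2)
    print(f"{s.group:7s} geometric mean area {np.exp(mu):6.1f} µm², "
          f"log-sd {sigma:.3f}, KS distance {ks:.4f}")

print("\nTukey HSD, all pairs (statistic = mean difference in µm²):")
table = compare_groups([plate, mat_a, mat_b])
print(table.to_string(index=False))

# With 15,000 nuclei per group even the 2 µm² gap between the two mats
# reaches the 0.05 level: at this sample size statistical significance is
# cheap, so the mean differences themselves (column `statistic`) are the
# quantity to interpret, not the flags alone.
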