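"""Calibrating measurement noise to a target limits-of-agreement width.

Under a multiplicative error model, two independent measurements of the
same nodule differ (relatively) with SD sqrt(2) * sigma, so 95% limits of
+/- H percent need a per-scan sigma of H / (1.96 * sqrt(2)) / 100.  This
script calibrates sigma for +/-15.5% limits, simulates cohorts of 100
nodules, and shows the recovered half-width.
"""

import numpy as np

from nodulevar import (
    SyntheticConfig,
    calibrate_noise,
    generate_cohort,
    interscan_agreement,
)

sigma = calibrate_noise(15.5)
print(f"per-scan relative sd for +/-15.5% limits: {sigma:.4f}")

halfwidths = []
for seed in range(200):
    cohort = generate_cohort(
        SyntheticConfig(n_nodules=100, per_scan_rel_sd=sigma,
                        n_oversize=0, n_undersize=0, n_poorseg=0, seed=seed)
    )
    _, rel = interscan_agreement(cohort)
    halfwidths.append(rel.loa_halfwidth)

print(f"mean recovered half-width over 200 cohorts of n=100: "
      f"{np.mean(halfwidths):.2f}% (sd across cohorts {np.std(halfwidths):.2f}%)")
print("The slight shortfall versus 15.5% is the small-sample bias of the "
      "sample SD (E[s] ~ 0.9975 sigma at n=100).")
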