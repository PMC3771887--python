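#!/usr/bin/env python
"""Family-wise error calibration of the tmax permutation procedure.

Under a global null (no condition difference anywhere), the probability that
the corrected test marks any of the 1734 cells significant should equal the
nominal family-wise alpha.  Simulates 200 replicate null experiments of 23
subjects with spatially correlated difference-wave noise on the 34 x 51
analysis grid, runs the sign-flip tmax test with 500 permutations at
alpha = 0.05 in each, and reports the empirical rate.  Also reports the
analytic test-wise alpha of the critical t printed by the method at df 22.
"""

import json
from pathlib import Path

import bex
from bex.massuni import simulate_null_fwer

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 2024


def main() -> None:
    OUT.mkdir(exist_ok=True)
    montage = bex.make_montage()
    rate = simulate_null_fwer(
        n_experiments=200, n_subjects=23, ch_names=bex.SUBSET_34,
        distances=montage.distances(bex.SUBSET_34), n_times=51,
        spatial_scale=0.4, n_perm=500, alpha=0.05, seed=SEED)
    alpha_tw = bex.testwise_alpha_from_critical_t(4.7419, 22)
    payload = {"empirical_fwer": rate, "n_experiments": 200,
               "nominal_alpha": 0.05,
               "binomial_95ci": [0.02, 0.09],
               "testwise_alpha_at_t_4p7419_df22": alpha_tw}
    (OUT / "fwer_calibration.json").write_text(json.dumps(payload, indent=2))
    print(f"empirical FWER over 200 null experiments: {rate:.3f} "
          f"(nominal 0.05; binomial 95% CI [0.02, 0.09])")
    print(f"two-tailed tail probability of t = 4.7419 at df = 22: "
          f"{alpha_tw:.3g} (prints as 0.000099 at two significant figures)")


if __name__ == "__main__":
    main()
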