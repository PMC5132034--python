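"""Why design-aware weights matter: the efficiency-versus-weights curve.

A stylized two-test setting (an efficient test "Best" and an inefficient
"Worst", slope correlation 0.8) in a 3-year trial with annual visits.  The
relative sample size N_composite/N_best is traced along the weight simplex
and evaluated at three named weightings: the design-optimal weights, the
unit-time-decline (UTD) weights optimized for a t=[0,1] design, and
inverse-baseline-SD weights.
"""

import numpy as np

from lmecomposite import (
    TrialDesign,
    bivariate_params,
    efficiency_curve,
    inverse_sd_weights,
    lme_weights,
    n_ratio,
    utd_weights,
)

truth = bivariate_params(0.8)
design = TrialDesign(np.array([0.0, 1.0, 2.0, 3.0]))

curve = efficiency_curve(truth, design, np.linspace(-1.0, 1.0, 401))
i = curve["n_ratio"].idxmin()
print(f"curve minimum: ratio {curve['n_ratio'].min():.3f} "
      f"at weight difference {curve['weight_diff'].iloc[i]:+.3f}")

for label, cw in [
    ("LME (design-aware)", lme_weights(truth, design)),
    ("UTD (t=[0,1])", utd_weights(truth)),
    ("inverse baseline SD", inverse_sd_weights([1.0, 1.0], truth.beta)),
]:
    r = n_ratio(truth, design, cw, 0)
    print(f"{label:22s} w = {np.round(cw.w, 3)}  N_composite/N_best = {r:.3f}")

print(
    "\nRatios below 1 mean the composite needs fewer subjects than the best\n"
    "single test.  With highly correlated slopes the optimal composite barely\n"
    "helps (0.992), while weights tuned for the wrong design (UTD) or to\n"
    "baseline SDs cost roughly 30-50% extra sample size in this design."
)
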