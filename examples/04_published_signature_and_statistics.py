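"""Score patients with the published DLR signature and run the
evaluation-statistics suite on synthetic scores.
"""

import numpy as np
import pandas as pd

from radsig.evalstats import (
    decision_curve,
    delong_test,
    roc_auc,
    two_by_two_tests,
    youden_cutoff,
)
from radsig.reference import dlr_score_model
from radsig.select_sig import score

# the published 15-feature deep-learning signature: on an all-zero feature
# vector the score is exactly the published intercept
model = dlr_score_model()
zero = pd.DataFrame({f: [0.0] for f in model.coefficients})
print(f"DLR-score at zero features: {float(score(model, zero)[0])!r}")

# cohort-comparability check on the published class distribution
res = two_by_two_tests([[32, 131], [29, 67]])
print(f"train/validation chi-square P = {res['chi2_p']:.3f}")

# ROC / Youden / DeLong on simulated paired scores
rng = np.random.default_rng(0)
y = rng.integers(0, 2, 200)
good = y + rng.normal(scale=0.7, size=200)
weak = y + rng.normal(scale=2.0, size=200)
r_good, r_weak = roc_auc(good, y), roc_auc(weak, y)
z, p = delong_test(good, weak, y)
cut = youden_cutoff(r_good)
nb = decision_curve(1 / (1 + np.exp(-good)), y, thresholds=[0.2])
print(f"AUC good {r_good.auc:.3f} vs weak {r_weak.auc:.3f}; DeLong p = {p:.2g}")
print(f"Youden cutoff {cut.cutoff:.3f} (J = {cut.youden_j:.3f})")
print(f"net benefit at pt=0.2: {nb.net_benefit[0]:.3f} "
      f"(treat-all {nb.treat_all[0]:.3f})")
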