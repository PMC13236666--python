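"""Build session TRIMP targets, intensity strata and the leakage audit.

TRIMP = sum_i D_i * dHR_i * exp(b * dHR_i) with the sex-specific b
(1.92 male / 1.67 female); sessions are stratified by TRIMP tertiles; the
audit bars the target and its derivatives from the predictor table.
"""

import numpy as np
import pandas as pd

from ecgload import compute_trimp, leakage_audit, stratify
from ecgload.hrv import FEATURE_COLUMNS

# one hour at half heart-rate reserve
male = compute_trimp([130.0], [60.0], "male", hr_rest=60.0, hr_max=200.0)
female = compute_trimp([130.0], [60.0], "female", hr_rest=60.0, hr_max=200.0)
print(f"TRIMP, 60 min at dHR=0.5: male {male.trimp:.3f} a.u., "
      f"female {female.trimp:.3f} a.u.")

rng = np.random.default_rng(0)
trimps = rng.gamma(4.0, 30.0, size=30)
labels = stratify(trimps)
print("tertile counts:", pd.Series(labels).value_counts().to_dict())

table = pd.DataFrame({c: rng.uniform(0, 1, 30) for c in FEATURE_COLUMNS})
table["acwr"] = rng.uniform(0.5, 1.5, 30)        # named derivative
table["shifted_load"] = 0.5 * trimps + 3.0       # affine alias
report = leakage_audit(table, trimps)
print("retained predictors:", report.retained)
print("dropped with reason:", report.dropped)
# The male value exceeds the female one (e^{1.92*0.5} > e^{1.67*0.5}); the
# audit keeps exactly the eight-feature roster and names why each column fell.
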