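"""Compare the classifier roster with the 0.632 bootstrap and pick a model.

Uses a small informative feature table (so it runs in seconds) to show
the training-table format — AUC / Sens / Spec with across-resample SDs
per model — and the simplicity-aware selection rule.
"""

import numpy as np
import pandas as pd

from rimmune import MODEL_ROSTER, bootstrap632_evaluate, select_final_model

rng = np.random.default_rng(0)
n, p = 60, 12
y = rng.integers(0, 2, size=n)
x = rng.normal(size=(n, p))
x[:, 0] += 1.5 * y  # two informative features
x[:, 1] -= 1.5 * y
table = pd.DataFrame(x, columns=[f"f{i}" for i in range(p)])

estimates = []
for spec in MODEL_ROSTER:
    est = bootstrap632_evaluate(spec, table, y, B=10, seed=1)
    estimates.append(est)
    print(f"{est.model:20s} AUC {est.auc:.3f} +- {est.auc_sd:.3f}   "
          f"Sens {est.sens:.3f}  Spec {est.spec:.3f}")

final = select_final_model(estimates)
best = max(estimates, key=lambda e: e.auc)
print(f"\nbest AUC: {best.model} ({best.auc:.3f} +- {best.auc_sd:.3f})")
print(f"selected final model: {final.name} (complexity rank {final.complexity_rank})")
print("Any model within one SD of the best is a candidate; the simplest wins.")
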