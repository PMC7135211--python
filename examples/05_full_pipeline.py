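"""Run the whole chain end-to-end on a small synthetic study.

Simulate -> extract -> score -> train -> evaluate, with 16 training and
12 test phantoms under strong image-immune coupling, then print the
selected model and its held-out performance.  (The package default is
60/40 with B=25; this small run finishes in well under a minute.)
"""

import tempfile
from pathlib import Path

from rimmune import make_report, run_all

config = {
    "seed": 42,
    "cohorts": {
        "train": {"n_samples": 16, "coupling_beta": 45.0},
        "test": {"n_samples": 12, "coupling_beta": 45.0},
    },
    "expression": {"n_genes": 800, "genes_per_set": 15},
    "modeling": {"B": 8},
}

out = Path(tempfile.mkdtemp(prefix="rimmune_demo_"))
manifest = run_all(config, out)
report = make_report(manifest)

info = manifest.selected_model["th2"]
print(f"selected model: {info['model']}")
print(f"0.632-bootstrap training AUC: {info['train_auc_632']:.3f}")
print(f"held-out test AUC: {info['test_auc']:.3f} (p = {info['test_p_value']:.4f})")
print(f"stage timings (s): {manifest.timings_s}")
print(f"tables and summary written under {out}")
print("With strong planted coupling the pipeline should recover the Th2 state")
print("almost perfectly; with coupling_beta = 0 the test AUC collapses to chance.")
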