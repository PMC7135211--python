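"""Generate a paired image/expression cohort with known ground truth.

Builds 6 tumor phantoms whose rim contrast is coupled to a latent Th2
activity, plus a matching expression matrix with planted immune-set
enrichment, and prints the latent states next to simple image summaries.
"""

import numpy as np

from rimmune import PhantomConfig, draw_latent_states, generate_phantom
from rimmune.expression import generate_expression, make_immune_gene_sets

config = PhantomConfig(n_samples=6, coupling_beta=45.0, seed=7)
states = draw_latent_states(config.n_samples, config.seed)
gene_sets = make_immune_gene_sets(n_genes=1000, genes_per_set=15, seed=7)
expr = generate_expression(states, gene_sets, seed=8, n_genes=1000)

print(f"{'sample':8s} {'th2 latent':>10s} {'rim-shell mean HU':>18s}")
for st in states:
    roi = generate_phantom(config, st)
    # crude rim summary: mean of the outermost 2 mm of the mask
    from rimmune.radiomics import decompose_regions

    rs = decompose_regions(roi, rim_depth_mm=2.0, seed=0)
    rim_mean = roi.intensities[rs.outer_mask].mean()
    print(f"{st.sample_id:8s} {st.th2_level:10.2f} {rim_mean:18.1f}")

print(f"\nexpression matrix: {expr.shape[0]} genes x {expr.shape[1]} samples, "
      f"{len(gene_sets)} immune gene sets")
print("Higher th2 latents should show brighter rims: the generator plants the")
print("image-immune coupling that the downstream pipeline is asked to recover.")
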