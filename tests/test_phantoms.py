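"""Generator contracts: determinism, coupling, and expression structure."""

import numpy as np
import pytest
from scipy import stats

from rimmune.expression import generate_expression, make_immune_gene_sets
from rimmune.phantoms import (
    LatentImmuneState,
    PhantomConfig,
    draw_latent_states,
    generate_cohort,
    generate_phantom,
)
from rimmune.radiomics import decompose_regions


def delta_th2_correlation(cfg: PhantomConfig, rim_depth_mm=2.0, seed=11) -> float:
    states, rois = generate_cohort(cfg)
    d = [decompose_regions(r, rim_depth_mm=rim_depth_mm, seed=seed).delta_values.mean() for r in rois]
    return float(np.corrcoef(d, [s.th2_level for s in states])[0, 1])


class TestPhantom:
    def test_zero_noise_determinism_and_core_level(self):
        cfg = PhantomConfig(seed=3, noise_sd_hu=0.0, coupling_beta=0.0, histogram_skew_param=0.0)
        st = LatentImmuneState("A", th2_level=1.7)
        a = generate_phantom(cfg, st)
        b = generate_phantom(cfg, st)
        assert np.array_equal(a.intensities, b.intensities)
        assert np.array_equal(a.mask, b.mask)
        # deep core voxels sit at the core mean exactly (no noise field)
        center = tuple(n // 2 for n in cfg.grid_shape)
        assert a.intensities[center] == pytest.approx(cfg.core_mean_hu, abs=1e-4)

    def test_null_coupling_makes_rim_contrast_independent_of_th2(self):
        cfg = PhantomConfig(seed=4, coupling_beta=0.0, n_samples=60)
        r = delta_th2_correlation(cfg)
        # 95% CI of a null Pearson correlation at n=60 covers 0
        assert abs(r) < 2.0 / np.sqrt(60)

    def test_strong_coupling_drives_delta_region_mean(self):
        cfg = PhantomConfig(seed=5, coupling_beta=45.0, n_samples=100)
        assert delta_th2_correlation(cfg) > 0.8

    def test_coupling_monotone_in_beta(self):
        corrs = [
            delta_th2_correlation(PhantomConfig(seed=6, coupling_beta=b, n_samples=40))
            for b in (0.0, 15.0, 45.0)
        ]
        assert corrs == sorted(corrs)

    def test_skew_param_shifts_histogram_asymmetry(self):
        st = LatentImmuneState("A")
        sym = generate_phantom(PhantomConfig(seed=7, histogram_skew_param=0.0), st)
        skw = generate_phantom(PhantomConfig(seed=7, histogram_skew_param=1.5), st)
        assert stats.skew(skw.roi_values) > stats.skew(sym.roi_values) + 0.3

    def test_tumor_must_fit_grid(self):
        with pytest.raises(ValueError, match="axis"):
            PhantomConfig(grid_shape=(16, 32, 32), tumor_radius_mm=8.0)

    def test_latent_states_reproducible(self):
        assert draw_latent_states(5, seed=9) == draw_latent_states(5, seed=9)


class TestExpression:
    def test_noiseless_ordering_puts_set_genes_on_top(self):
        sets = make_immune_gene_sets(n_genes=300, genes_per_set=10, seed=1)
        st = [LatentImmuneState("A", th2_level=30.0)]
        expr = generate_expression(st, sets, base_noise=0.0, seed=2, n_genes=300)
        col = expr["A"]
        th2_genes = set(sets["Th2_cells"])
        other = [g for g in expr.index if g not in {g for s in sets.values() for g in s}]
        assert col[list(th2_genes)].min() > col[other].max()

    def test_reproducible_and_nonnegative(self):
        sets = make_immune_gene_sets(n_genes=200, genes_per_set=8, seed=3)
        st = draw_latent_states(6, seed=4)
        a = generate_expression(st, sets, seed=5, n_genes=200)
        b = generate_expression(st, sets, seed=5, n_genes=200)
        assert a.equals(b)
        assert (a.values >= 0).all()

    def test_background_gene_means_equal_across_samples(self):
        sets = make_immune_gene_sets(n_genes=400, genes_per_set=10, seed=6)
        st = draw_latent_states(40, seed=7)
        expr = generate_expression(st, sets, base_noise=1.0, seed=8, n_genes=400)
        member = {g for s in sets.values() for g in s}
        bg = expr.loc[[g for g in expr.index if g not in member]]
        col_means = bg.mean(axis=0)
        # per-sample background mean fluctuates as noise/sqrt(n_bg)
        sem = 3.0 * 1.0 / np.sqrt(len(bg))
        assert (col_means - col_means.mean()).abs().max() < 3 * sem

    def test_missing_designated_set_raises(self):
        sets = {"A": ["G000001"], "B": ["G000002"], "C": ["G000003"]}
        with pytest.raises(KeyError):
            generate_expression([LatentImmuneState("S")], sets, seed=1, n_genes=10)
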