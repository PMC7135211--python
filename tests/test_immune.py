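"""ssGSEA scoring, signature PCA and mean-cutoff dichotomization."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from oracles import ssgsea_bruteforce
from rimmune.expression import generate_expression, make_immune_gene_sets
from rimmune.immune import dichotomize, pca_signatures, score_matrix, ssgsea_score
from rimmune.phantoms import draw_latent_states


class TestSsgsea:
    @pytest.mark.parametrize("n_genes", [5, 6, 7, 8])
    @pytest.mark.parametrize("alpha", [0.0, 0.25])
    def test_matches_bruteforce_on_all_small_sets(self, n_genes, alpha):
        rng = np.random.default_rng(n_genes)
        genes = [f"g{i}" for i in range(n_genes)]
        values = list(rng.choice([1.0, 2.0, 3.0, 4.0], size=n_genes))  # includes ties
        sample = pd.Series(values, index=genes)
        for k in range(1, n_genes):  # proper subsets only
            for sub in combinations(genes, k):
                got = ssgsea_score(sample, list(sub), alpha=alpha)
                ref = ssgsea_bruteforce(genes, values, set(sub), alpha)
                assert got == pytest.approx(ref, abs=1e-12)

    def test_sign_reflects_rank_position(self):
        sample = pd.Series([5.0, 4.0, 3.0, 2.0, 1.0], index=list("abcde"))
        assert ssgsea_score(sample, ["a", "b"], alpha=0.0) > 0
        assert ssgsea_score(sample, ["d", "e"], alpha=0.0) < 0

    def test_hand_enumerated_top2_of_5(self):
        # alpha=0, set = top-2: walk gives P_in (.5,1,1,1,1), P_out (0,0,1/3,2/3,1)
        sample = pd.Series([10.0, 9.0, 3.0, 2.0, 1.0], index=list("abcde"))
        expected = (0.5 - 0) + (1 - 0) + (1 - 1 / 3) + (1 - 2 / 3) + (1 - 1)
        assert ssgsea_score(sample, ["a", "b"], alpha=0.0) == pytest.approx(expected)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=30)
        sample = pd.Series(vals, index=[f"g{i}" for i in range(30)])
        warped = pd.Series(np.exp(0.5 * vals), index=sample.index)  # strictly monotone
        gene_set = [f"g{i}" for i in range(0, 30, 4)]
        for alpha in (0.0, 0.25):
            assert ssgsea_score(sample, gene_set, alpha=alpha) == pytest.approx(
                ssgsea_score(warped, gene_set, alpha=alpha), abs=1e-12
            )

    def test_single_sample_property(self):
        # a sample's raw score ignores all other samples entirely
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(20, 5)), index=[f"g{i}" for i in range(20)],
                            columns=list("ABCDE"))
        gene_set = ["g1", "g5", "g9"]
        full = ssgsea_score(expr["C"], gene_set)
        alone = ssgsea_score(expr[["C"]].iloc[:, 0], gene_set)
        assert full == alone

    def test_full_universe_set_rejected(self):
        sample = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="all measured genes"):
            ssgsea_score(sample, ["a", "b"])

    def test_disjoint_set_scores_missing(self):
        sample = pd.Series([1.0, 2.0], index=["a", "b"])
        assert np.isnan(ssgsea_score(sample, ["zz"]))


class TestScoreMatrix:
    def test_28_sets_give_28_columns_and_unit_range(self):
        sets = make_immune_gene_sets(n_genes=500, genes_per_set=10, seed=1)
        states = draw_latent_states(12, seed=2)
        expr = generate_expression(states, sets, seed=3, n_genes=500)
        scores = score_matrix(expr, sets, normalize=True)
        assert scores.shape == (12, 28)
        assert scores.values.max() - scores.values.min() == pytest.approx(1.0)

    def test_planted_enrichment_recovered(self):
        sets = make_immune_gene_sets(n_genes=5000, genes_per_set=20, seed=4)
        states = draw_latent_states(60, seed=5)
        expr = generate_expression(states, sets, base_noise=1.0, effect_size=2.0, seed=6)
        scores = score_matrix(expr, sets, alpha=0.25, normalize=True)
        from scipy.stats import spearmanr

        rho = spearmanr([s.th2_level for s in states], scores["Th2_cells"]).statistic
        assert rho > 0.7


class TestPca:
    def test_duplicated_signal_loads_entirely_on_pc1(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=30)
        m = pd.DataFrame({"s1": a, "s2": 2 * a + 1}, index=[f"x{i}" for i in range(30)])
        res = pca_signatures(m, k=2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_full_reconstruction(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(15, 4)), columns=list("abcd"))
        res = pca_signatures(m, k=4)
        recon = res.scores.values @ res.loadings.values.T
        centered = m.values - m.values.mean(axis=0)
        assert np.abs(recon - centered).max() < 1e-10
        # loadings orthonormal, variance fractions non-increasing and <= 1
        assert np.allclose(res.loadings.values.T @ res.loadings.values, np.eye(4), atol=1e-10)
        evr = res.explained_variance_ratio
        assert evr.sum() <= 1 + 1e-9 and all(np.diff(evr) <= 1e-12)

    def test_independent_latent_axes_separate_on_components(self):
        # planted th1 and th2 axes are independent, so their designated
        # signatures load on (nearly) orthogonal component directions
        sets = make_immune_gene_sets(n_genes=2000, genes_per_set=15, seed=7)
        states = draw_latent_states(80, seed=8)
        expr = generate_expression(states, sets, base_noise=0.5, effect_size=2.0, seed=9, n_genes=2000)
        scores = score_matrix(expr, sets)
        res = pca_signatures(scores, k=10)
        l_th1 = res.loadings.loc["Th1_cells"].values
        l_th2 = res.loadings.loc["Th2_cells"].values
        cos = abs(l_th1 @ l_th2) / (np.linalg.norm(l_th1) * np.linalg.norm(l_th2))
        assert cos < 0.3


class TestDichotomize:
    def test_mean_cutoff_labels(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        lab = dichotomize(s, cohort_id="train")
        assert lab.cutoff == pytest.approx(2.5)
        assert list(lab.labels) == ["low", "low", "high", "high"]
        assert (lab.binary == [0, 0, 1, 1]).all()

    def test_shift_equivariance(self):
        rng = np.random.default_rng(2)
        s = pd.Series(rng.normal(size=25))
        assert (dichotomize(s, "c").labels == dichotomize(s + 17.0, "c").labels).all()

    def test_label_counts_partition_cohort(self):
        rng = np.random.default_rng(3)
        s = pd.Series(rng.normal(size=41))
        lab = dichotomize(s, "c")
        assert (lab.labels == "high").sum() + (lab.labels == "low").sum() == 41

    def test_cohorts_apply_their_own_cutoff(self):
        rng = np.random.default_rng(4)
        train = pd.Series(rng.normal(size=50))
        test = pd.Series(rng.normal(size=50) + 1.5)  # shifted to the right
        lt = dichotomize(train, "train")
        le = dichotomize(test, "test")
        assert le.cutoff > lt.cutoff
        # pooled-cutoff labeling would call nearly everything high in the
        # shifted cohort, unlike the per-cohort rule
        pooled_cut = pd.concat([train, test]).mean()
        pooled_high = (test > pooled_cut).sum()
        own_high = (le.labels == "high").sum()
        assert pooled_high > own_high

    def test_degenerate_split_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            dichotomize(pd.Series([2.0, 2.0, 2.0]), "c")
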