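"""Tree handling, phylogenetic correlation, Gibbs sampler and summaries."""

import dendropy
import numpy as np
import pandas as pd
import pytest
import scipy.stats

from sensorydrive.phylo_pglmm import (
    MCMCSettings,
    ModelSpec,
    PhyloCorrelation,
    Priors,
    _rinvgamma,
    fit_pglmm,
    heritability,
    hpd_interval,
    p_mcmc,
    phylo_correlation,
    prune,
    read_newick,
    summarize,
)
from sensorydrive.synthetic_data import SimConfig, gen_species_table, gen_tree


def tree_from_newick(s: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)


class TestTrees:
    def test_read_newick_rejects_nonpositive_lengths(self, tmp_path):
        p = tmp_path / "bad.nwk"
        p.write_text("((A:1,B:0):1,C:2);\n")
        with pytest.raises(ValueError, match="length"):
            read_newick(p)

    def test_prune_preserves_path_lengths(self):
        t = gen_tree(8, seed=4)
        pdm = t.phylogenetic_distance_matrix()
        keep = ["sp001", "sp004", "sp007"]
        sub = prune(t, keep)
        assert sorted(lf.taxon.label for lf in sub.leaf_node_iter()) == keep
        pdm2 = sub.phylogenetic_distance_matrix()
        tax1 = {x.label: x for x in t.taxon_namespace}
        tax2 = {x.label: x for x in sub.taxon_namespace}
        for a in keep:
            for b in keep:
                if a < b:
                    d1 = pdm.patristic_distance(tax1[a], tax1[b])
                    d2 = pdm2.patristic_distance(tax2[a], tax2[b])
                    assert d2 == pytest.approx(d1, abs=1e-12)

    def test_prune_to_all_taxa_is_identity(self):
        t = gen_tree(6, seed=1)
        labels = sorted(lf.taxon.label for lf in t.leaf_node_iter())
        sub = prune(t, labels)
        assert sorted(lf.taxon.label for lf in sub.leaf_node_iter()) == labels

    def test_prune_missing_taxon_errors(self):
        t = gen_tree(5, seed=1)
        with pytest.raises(ValueError, match="absent"):
            prune(t, ["sp001", "nosuch"])

    def test_prune_leaves_input_tree_intact(self):
        t = gen_tree(6, seed=2)
        before = {x.label for x in t.taxon_namespace}
        prune(t, ["sp001", "sp002"])
        assert {x.label for x in t.taxon_namespace} == before


class TestPhyloCorrelation:
    def test_star_phylogeny_gives_identity(self):
        t = tree_from_newick("(A:1,B:1,C:1,D:1);")
        A = phylo_correlation(t)
        np.testing.assert_allclose(A.matrix, np.eye(4), atol=1e-12)

    def test_two_taxon_half_depth_split(self):
        # root edge of length 0.5 shared, then two branches of 0.5
        t = tree_from_newick("((A:0.5,B:0.5):0.5,C:1);")
        A = phylo_correlation(t)
        i, j = A.taxa.index("A"), A.taxa.index("B")
        assert A.matrix[i, j] == pytest.approx(0.5)
        k = A.taxa.index("C")
        assert A.matrix[i, k] == pytest.approx(0.0)

    def test_balanced_tree_matches_path_enumeration(self):
        t = tree_from_newick("((A:1,B:1):2,(C:2,D:2):1);")
        A = phylo_correlation(t)

        # brute-force oracle: shared root-to-MRCA path length per pair
        shared = {
            ("A", "B"): 2.0,
            ("C", "D"): 1.0,
            ("A", "C"): 0.0,
            ("A", "D"): 0.0,
            ("B", "C"): 0.0,
            ("B", "D"): 0.0,
        }
        depth = {"A": 3.0, "B": 3.0, "C": 3.0, "D": 3.0}
        for (x, y), c in shared.items():
            i, j = A.taxa.index(x), A.taxa.index(y)
            expected = c / np.sqrt(depth[x] * depth[y])
            assert A.matrix[i, j] == pytest.approx(expected, abs=1e-12)

    def test_nonultrametric_tree_still_unit_diagonal(self):
        t = tree_from_newick("((A:0.3,B:2):1,(C:0.5,D:4):0.2);")
        A = phylo_correlation(t)
        np.testing.assert_allclose(np.diag(A.matrix), 1.0, atol=1e-12)
        np.linalg.cholesky(A.matrix)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            PhyloCorrelation(("a", "b"), np.array([[1.0, 0.5], [0.2, 1.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            PhyloCorrelation(("a", "b"), np.array([[2.0, 0.5], [0.5, 2.0]]))


class TestSettings:
    def test_long_run_retains_1090_per_chain(self):
        assert MCMCSettings().retained_per_chain == 1090

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            MCMCSettings(n_iter=100, burn_in=200)
        with pytest.raises(ValueError):
            MCMCSettings(n_iter=100, burn_in=99, thin=10)


class TestGibbsSampler:
    def test_inverse_gamma_draws_match_scipy(self):
        rng = np.random.default_rng(0)
        draws = np.array([_rinvgamma(rng, 3.0, 2.0) for _ in range(4000)])
        ref = scipy.stats.invgamma(3.0, scale=2.0)
        assert scipy.stats.kstest(draws, ref.cdf).pvalue > 0.01

    def test_matches_conjugate_regression_with_identity_A(self):
        rng = np.random.default_rng(42)
        n = 50
        x = rng.standard_normal(n)
        y = 1.0 + 2.0 * x + rng.standard_normal(n)
        df = pd.DataFrame({"species": [f"s{i}" for i in range(n)], "x": x, "y": y})
        spec = ModelSpec(response="y", fixed_effects=("x",))
        ch = fit_pglmm(df, None, spec, settings=MCMCSettings.quick(seed=1, n_chains=2))

        X = np.column_stack([np.ones(n), x])
        bhat = np.linalg.solve(X.T @ X, X.T @ y)
        s = summarize(ch, "beta_x")
        mcse = np.std(ch.pooled("beta_x")) / np.sqrt(s.ess)
        assert abs(s.posterior_mean - bhat[1]) < 3 * mcse

    def test_recovers_simulated_effects(self):
        tree = gen_tree(120, seed=10)
        cfg = SimConfig(n_taxa=120, seed=10)
        df = gen_species_table(tree, cfg)
        spec = ModelSpec(response="response", fixed_effects=("habitat", "covariate"))
        ch = fit_pglmm(df, phylo_correlation(tree), spec, settings=MCMCSettings.quick(seed=2))
        lo, hi = hpd_interval(ch.pooled("beta_habitat"))
        assert lo < cfg.beta_habitat < hi or abs(
            summarize(ch, "beta_habitat").posterior_mean - cfg.beta_habitat
        ) < 1.0

    def test_response_shift_leaves_variances_unchanged(self):
        tree = gen_tree(60, seed=11)
        df = gen_species_table(tree, SimConfig(n_taxa=60, seed=11))
        A = phylo_correlation(tree)
        spec = ModelSpec(response="response", fixed_effects=("habitat",))
        ch1 = fit_pglmm(df, A, spec, settings=MCMCSettings.quick(seed=3))
        df2 = df.assign(response=df.response + 100.0)
        ch2 = fit_pglmm(df2, A, spec, settings=MCMCSettings.quick(seed=3))
        np.testing.assert_allclose(
            ch1.params["sigma2_a"], ch2.params["sigma2_a"], rtol=1e-8
        )
        np.testing.assert_allclose(
            ch1.params["sigma2_e"], ch2.params["sigma2_e"], rtol=1e-8
        )

    def test_extra_random_effect_sampled(self):
        tree = gen_tree(60, seed=12)
        df = gen_species_table(tree, SimConfig(n_taxa=60, seed=12, sigma2_u=2.0))
        A = phylo_correlation(tree)
        spec = ModelSpec(
            response="response", fixed_effects=("habitat",), extra_random="call_function"
        )
        ch = fit_pglmm(df, A, spec, settings=MCMCSettings.quick(seed=4))
        assert "sigma2_u" in ch.params
        assert np.all(ch.pooled("sigma2_u") > 0)

    def test_species_mismatch_errors(self):
        tree = gen_tree(10, seed=13)
        df = gen_species_table(tree, SimConfig(n_taxa=10, seed=13))
        A = phylo_correlation(tree)
        bad = df.assign(species=[f"x{i}" for i in range(len(df))])
        with pytest.raises(ValueError, match="mismatch"):
            fit_pglmm(bad, A, ModelSpec(response="response"), settings=MCMCSettings.quick())

    def test_singular_design_errors(self):
        tree = gen_tree(10, seed=14)
        df = gen_species_table(tree, SimConfig(n_taxa=10, seed=14))
        df["dup"] = 1.0  # collinear with intercept
        A = phylo_correlation(tree)
        with pytest.raises(ValueError, match="singular|constant"):
            fit_pglmm(
                df, A, ModelSpec(response="response", fixed_effects=("dup",)),
                settings=MCMCSettings.quick(),
            )

    def test_deterministic_given_seed(self):
        tree = gen_tree(20, seed=15)
        df = gen_species_table(tree, SimConfig(n_taxa=20, seed=15))
        A = phylo_correlation(tree)
        spec = ModelSpec(response="response", fixed_effects=("habitat",))
        ch1 = fit_pglmm(df, A, spec, settings=MCMCSettings.quick(seed=9))
        ch2 = fit_pglmm(df, A, spec, settings=MCMCSettings.quick(seed=9))
        for k in ch1.params:
            np.testing.assert_array_equal(ch1.params[k], ch2.params[k])


class TestSummaries:
    def _chains(self, arr):
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        return arr

    def test_posterior_mean_simple(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert float(x.mean()) == 2.5
        lo, hi = hpd_interval(x, prob=0.95)
        assert lo == 1.0 and hi == 4.0

    def test_hpd_contains_required_mass(self):
        rng = np.random.default_rng(21)
        x = rng.standard_normal(5000)
        lo, hi = hpd_interval(x, 0.95)
        frac = np.mean((x >= lo) & (x <= hi))
        assert frac >= 0.95
        # shortest interval for a normal sample is near the central one
        assert lo == pytest.approx(-1.96, abs=0.15)
        assert hi == pytest.approx(1.96, abs=0.15)

    def test_p_mcmc_all_positive_hits_floor(self):
        assert p_mcmc(np.ones(1000)) == pytest.approx(0.002)

    def test_p_mcmc_sign_balanced_is_one(self):
        x = np.concatenate([np.ones(500), -np.ones(500)])
        assert p_mcmc(x) == 1.0

    def test_p_mcmc_scale_invariant_and_floored(self):
        rng = np.random.default_rng(22)
        x = rng.standard_normal(400) + 1.0
        assert p_mcmc(x) == p_mcmc(x * 37.5)
        assert p_mcmc(x) >= 2.0 / 400

    def test_heritability_formula(self):
        from sensorydrive.phylo_pglmm import PGLMMChains

        ch = PGLMMChains(
            params={
                "sigma2_a": np.array([[1.0, 3.0]]),
                "sigma2_e": np.array([[1.0, 1.0]]),
            },
            fixed_names=(),
            variance_names=("sigma2_a", "sigma2_e"),
            settings=MCMCSettings.quick(),
            chain_seeds=(0,),
        )
        h2, _ = heritability(ch)
        np.testing.assert_allclose(h2, [[0.5, 0.75]])
        assert float(h2.mean()) == pytest.approx(0.625)

    def test_h2_bounded_in_unit_interval(self):
        tree = gen_tree(40, seed=16)
        df = gen_species_table(tree, SimConfig(n_taxa=40, seed=16))
        A = phylo_correlation(tree)
        ch = fit_pglmm(
            df, A, ModelSpec(response="response", fixed_effects=("habitat",)),
            settings=MCMCSettings.quick(seed=5),
        )
        h2, summ = heritability(ch)
        assert np.all((h2 > 0) & (h2 < 1))
        assert 0 < summ.posterior_mean < 1

    def test_unknown_parameter_errors(self):
        tree = gen_tree(10, seed=17)
        df = gen_species_table(tree, SimConfig(n_taxa=10, seed=17))
        ch = fit_pglmm(
            df, phylo_correlation(tree), ModelSpec(response="response"),
            settings=MCMCSettings.quick(seed=6),
        )
        with pytest.raises(KeyError):
            summarize(ch, "nope")
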