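"""Turnover forests, cumulative curves, landscape transforms, offsets."""

import numpy as np
import pandas as pd
import pytest

from duckmix import gea, synthio
from duckmix.gea import (combine_models, fit_turnover, genomic_offset,
                         map_rgb, null_comparison, site_allele_frequencies,
                         transform_environment)
from duckmix.genofilter import MISSING, GenotypeMatrix


@pytest.fixture(scope="module")
def fitted_model(env_dataset):
    matrix, env, _ = env_dataset
    freqs = site_allele_frequencies(matrix, min_polymorphic_sites=5)
    return fit_turnover(freqs, env, n_trees=60, seed=1), freqs, env


class TestSiteFrequencies:
    def test_polymorphism_census_matches_brute_force(self):
        rng = np.random.default_rng(2)
        n_sites, per_site, n_loci = 12, 8, 40
        geno = rng.integers(0, 3, (n_sites * per_site, n_loci)).astype(np.int8)
        geno[rng.random(geno.shape) < 0.05] = MISSING
        sites = [f"s{i // per_site:02d}" for i in range(n_sites * per_site)]
        m = GenotypeMatrix(geno, [f"i{i}" for i in range(len(sites))],
                           [f"l{j}" for j in range(n_loci)],
                           metadata=pd.DataFrame({"site_id": sites},
                                                 index=[f"i{i}" for i in
                                                        range(len(sites))]))
        table = site_allele_frequencies(m, min_polymorphic_sites=5)
        for j, locus in enumerate(m.locus_ids):
            poly = 0
            for s in sorted(set(sites)):
                rows = [i for i, x in enumerate(sites) if x == s]
                col = geno[rows, j]
                col = col[col != MISSING]
                if len(col) and 0 < col.sum() < 2 * len(col):
                    poly += 1
            assert (locus in table.columns) == (poly >= 5)

    def test_monomorphic_locus_removed(self):
        geno = np.zeros((20, 2), dtype=np.int8)
        geno[:, 1] = np.tile([0, 1], 10)
        ids = [f"i{i}" for i in range(20)]
        m = GenotypeMatrix(geno, ids, ["mono", "poly"],
                           metadata=pd.DataFrame(
                               {"site_id": [f"s{i % 10}" for i in range(20)]},
                               index=ids))
        table = site_allele_frequencies(m, min_polymorphic_sites=5)
        assert list(table.columns) == ["poly"]

    def test_frequencies_are_minor(self, env_dataset):
        matrix, _, _ = env_dataset
        table = site_allele_frequencies(matrix)
        assert float(table.mean().mean()) <= 0.5 + 1e-9


class TestFitTurnover:
    def test_curves_are_monotone_and_total_importance(self, fitted_model):
        model, _, _ = fitted_model
        for v in model.variables:
            thr, cum = model.curves[v]
            assert (np.diff(cum) >= -1e-12).all()
            assert model.variable_importance[v] == pytest.approx(
                cum[-1] if len(cum) else 0.0)
            assert model.variable_importance[v] >= 0

    def test_causal_variable_ranked_first(self, fitted_model):
        model, _, _ = fitted_model
        assert model.ranking()[0] == "env1"

    def test_constant_environment_column_gets_zero_importance(self,
                                                              env_dataset):
        matrix, env, _ = env_dataset
        env = env.copy()
        env["env2"] = 1.0
        freqs = site_allele_frequencies(matrix)
        model = fit_turnover(freqs, env, n_trees=30, seed=3)
        assert model.variable_importance["env2"] == 0.0

    def test_too_few_sites_rejected(self):
        freqs = pd.DataFrame(np.random.default_rng(0).random((3, 4)),
                             index=pd.Index([f"s{i}" for i in range(3)],
                                            name="site_id"))
        env = pd.DataFrame({"site_id": [f"s{i}" for i in range(3)],
                            "env1": [0, 1, 2], "env2": [1, 0, 1]})
        with pytest.raises(ValueError):
            fit_turnover(freqs, env)


class TestNullComparison:
    def test_zero_nulls_rejected(self, fitted_model):
        _, freqs, env = fitted_model
        with pytest.raises(ValueError):
            null_comparison(freqs, env, n_null=0)

    def test_planted_signal_beats_all_nulls(self, env_dataset):
        matrix, env, _ = env_dataset
        freqs = site_allele_frequencies(matrix).iloc[:, :25]
        res = null_comparison(freqs, env, n_null=12, seed=4, n_trees=40)
        assert res["exceedance"] == 1.0
        assert res["empirical_mean_r2"] > max(res["null_mean_r2"])


class TestTransformAndRgb:
    def test_identical_cells_identical_coordinates(self, fitted_model):
        model, _, env = fitted_model
        grid = pd.concat([env.iloc[:1], env.iloc[:1]], ignore_index=True)
        out = transform_environment(model, grid, top_k=3)
        cols = [c for c in out.columns if c.startswith("env")]
        assert out.loc[0, cols].tolist() == out.loc[1, cols].tolist()

    def test_out_of_range_values_clamp_to_endpoints(self, fitted_model):
        model, _, env = fitted_model
        top = model.top_variables(2)
        lo = env.copy()
        hi = env.copy()
        for v in top:
            lo[v] = env[v].min() - 100
            hi[v] = env[v].max() + 100
        tlo = transform_environment(model, lo, top_k=2)
        thi = transform_environment(model, hi, top_k=2)
        for v in top:
            assert (tlo[v] == 0.0).all()
            np.testing.assert_allclose(thi[v],
                                       model.variable_importance[v])

    def test_monotone_transect_gives_monotone_coordinates(self, fitted_model):
        model, _, env = fitted_model
        v = model.ranking()[0]
        transect = pd.DataFrame({u: np.full(50, env[u].median())
                                 for u in model.variables})
        transect[v] = np.linspace(env[v].min(), env[v].max(), 50)
        out = transform_environment(model, transect, top_k=3)
        assert (np.diff(out[v]) >= -1e-12).all()

    def test_missing_grid_variable_rejected(self, fitted_model):
        model, _, env = fitted_model
        with pytest.raises(ValueError, match="env"):
            transform_environment(model,
                                  env.drop(columns=[model.ranking()[0]]),
                                  top_k=3)

    def test_rgb_bounded_identical_and_rank_preserving(self, fitted_model):
        model, _, env = fitted_model
        t = transform_environment(model, env, top_k=3)
        rgb = map_rgb(t)
        for ch in ("R", "G", "B"):
            assert rgb[ch].between(0, 255).all()
        by_pc1 = rgb.sort_values("PC1")["R"].to_numpy()
        assert (np.diff(by_pc1) >= 0).all()
        dup = pd.concat([t.iloc[:1]] * 3 + [t.iloc[1:]], ignore_index=True)
        rgb2 = map_rgb(dup)
        assert rgb2.loc[0, ["R", "G", "B"]].tolist() \
            == rgb2.loc[1, ["R", "G", "B"]].tolist()


class TestCombine:
    def test_self_combination_is_idempotent(self, fitted_model):
        model, _, _ = fitted_model
        combined = combine_models([model, model])
        for v in model.variables:
            thr, cum = model.curves[v]
            cthr, ccum = combined.curves[v]
            np.testing.assert_allclose(cthr, thr)
            np.testing.assert_allclose(ccum, cum, atol=1e-12)

    def test_zero_importance_model_preserves_ranking(self, fitted_model,
                                                     env_dataset):
        model, freqs, env = fitted_model
        shuffled = env.copy()
        rng = np.random.default_rng(5)
        for v in model.variables:
            shuffled[v] = rng.permutation(shuffled[v].to_numpy())
        null_model = gea.fit_turnover(freqs.iloc[:, :10], shuffled,
                                      n_trees=20, seed=6)
        combined = combine_models([model, null_model])
        assert combined.ranking()[0] == model.ranking()[0]

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            combine_models([])


class TestGenomicOffset:
    def test_identical_grids_zero_offset(self, fitted_model):
        model, _, env = fitted_model
        out = genomic_offset(model, env, env.copy(), top_k=3)
        assert (out["offset"] == 0).all()

    def test_offset_nonnegative_and_symmetric(self, fitted_model):
        model, _, env = fitted_model
        future = env.copy()
        future["env1"] = future["env1"] + 0.5
        fwd = genomic_offset(model, env, future, top_k=3)
        rev = genomic_offset(model, future, env, top_k=3)
        assert (fwd["offset"] >= 0).all()
        np.testing.assert_allclose(fwd["offset"], rev["offset"])

    def test_zero_importance_variable_does_not_change_offset(self,
                                                             fitted_model):
        model, _, env = fitted_model
        future = env.copy()
        future["env1"] = future["env1"] + 0.5
        base = genomic_offset(model, env, future, top_k=3)
        least = model.ranking()[-1]
        env2, fut2 = env.copy(), future.copy()
        env2[least] = env2[least] + 999
        fut2[least] = fut2[least] - 999
        again = genomic_offset(model, env2, fut2, top_k=3)
        if model.variable_importance[least] == 0:
            np.testing.assert_allclose(base["offset"], again["offset"])

    def test_larger_uniform_shift_does_not_reduce_mean_offset(self,
                                                              fitted_model):
        model, _, env = fitted_model
        v = model.ranking()[0]
        f1, f2 = env.copy(), env.copy()
        span = env[v].max() - env[v].min()
        f1[v] = env[v] + 0.2 * span
        f2[v] = env[v] + 0.4 * span
        o1 = genomic_offset(model, env, f1, top_k=3)["offset"].mean()
        o2 = genomic_offset(model, env, f2, top_k=3)["offset"].mean()
        assert o2 >= o1 - 1e-12

    def test_cell_mismatch_rejected(self, fitted_model):
        model, _, env = fitted_model
        with pytest.raises(ValueError):
            genomic_offset(model, env, env.iloc[:-1], top_k=2)
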