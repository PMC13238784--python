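import numpy as np
import pandas as pd
import pytest

import forestdiv as fd
from forestdiv.simulate import _shared_depth_matrix


def small_config(**kw):
    base = dict(
        n_plots=8,
        n_species_pool=20,
        n_species_overstory=16,
        n_species_understory=14,
        mean_stems_overstory=25.0,
        mean_stems_understory=60.0,
        seed=5,
    )
    base.update(kw)
    return fd.SimulationConfig(**base)


class TestPhylogenySim:
    def test_two_tips_is_a_cherry(self):
        tree = fd.simulate_phylogeny(2, seed=0)
        assert tree.n_tips == 2
        pm = fd.patristic_matrix(tree)
        assert pm.data.shape == (2, 2)
        assert pm.data.iloc[0, 1] > 0

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            fd.simulate_phylogeny(1, seed=0)

    def test_same_seed_same_newick(self):
        a = fd.simulate_phylogeny(15, seed=11).as_newick()
        b = fd.simulate_phylogeny(15, seed=11).as_newick()
        assert a == b
        c = fd.simulate_phylogeny(15, seed=12).as_newick()
        assert a != c

    def test_yule_internode_intervals(self):
        """In a pure-birth tree stopped at n tips, the waiting time while k
        lineages exist is Exp(k*b): means 1/(k*b) within Monte-Carlo error.
        (Equivalent to exponential lineage growth E[N(t)] = e^(b t).)"""
        b, n, reps = 2.0, 10, 300
        sums = np.zeros(n - 2)
        for s in range(reps):
            tree = fd.simulate_phylogeny(n, birth_rate=b, seed=20_000 + s)
            tree.tree.calc_node_root_distances()
            splits = sorted(
                nd.root_distance for nd in tree.tree.preorder_node_iter()
                if not nd.is_leaf()
            )
            # splits[0] = root (2 lineages start); interval with k lineages
            # runs from splits[k-2] to splits[k-1]
            sums += np.diff(np.array(splits))
        means = sums / reps
        ks = np.arange(2, n - 1 + 1)[: len(means)]
        expected = 1.0 / (ks * b)
        # MC s.e. of an Exp(k b) mean over 300 reps is ~6% of the mean
        np.testing.assert_allclose(means, expected, rtol=0.25)


class TestTraitSim:
    def setup_method(self):
        self.tree = fd.simulate_phylogeny(12, seed=3)
        self.V, self.labels = _shared_depth_matrix(self.tree)

    def _latent(self, table):
        """Back out the latent z from the lognormal SLA column."""
        from forestdiv.simulate import TRAIT_LOG_MEAN, TRAIT_LOG_SD
        x = np.log(table.data["SLA"].to_numpy())
        return (x - TRAIT_LOG_MEAN["SLA"]) / TRAIT_LOG_SD["SLA"]

    def test_zero_rate_collapses_species(self):
        t = fd.simulate_traits(self.tree, sigma2=0.0, seed=1)
        assert t.data.nunique().max() == 1

    def test_strict_positivity(self):
        t = fd.simulate_traits(self.tree, sigma2=4.0, lambda_signal=0.3, seed=2)
        assert (t.data.to_numpy() > 0).all()

    def test_lambda_zero_uncorrelated_tips(self):
        reps = 200
        zs = np.array([
            self._latent(fd.simulate_traits(self.tree, 1.0, 0.0, seed=s))
            for s in range(reps)
        ])
        C = np.corrcoef(zs, rowvar=False)
        off = C[~np.eye(len(self.labels), dtype=bool)]
        assert np.abs(off).mean() < 0.08

    def test_lambda_one_brownian_covariance(self):
        reps = 400
        zs = np.array([
            self._latent(fd.simulate_traits(self.tree, 1.0, 1.0, seed=s))
            for s in range(reps)
        ])
        emp = np.cov(zs, rowvar=False)
        tbar = np.mean(np.diag(self.V))
        np.testing.assert_allclose(emp * tbar, self.V, atol=0.35 * tbar)

    def test_deterministic_under_seed(self):
        a = fd.simulate_traits(self.tree, seed=9).data
        b = fd.simulate_traits(self.tree, seed=9).data
        pd.testing.assert_frame_equal(a, b)


class TestCommunitySim:
    def test_inventory_satisfies_census_invariants(self):
        inv, env, truth = fd.simulate_community(small_config())
        df = inv.to_dataframe()
        assert (df["dbh"] >= 1.0).all()
        assert (df["dbh"] < 100.0).all()
        assert (df["height"] > 0).all()
        assert set(df["plot_id"]) == set(env.data.index)

    def test_full_determinism_under_seed(self):
        cfg = small_config()
        inv1, env1, t1 = fd.simulate_community(cfg)
        inv2, env2, t2 = fd.simulate_community(small_config())
        pd.testing.assert_frame_equal(inv1.to_dataframe(), inv2.to_dataframe())
        pd.testing.assert_frame_equal(env1.data, env2.data)
        pd.testing.assert_frame_equal(t1.plots, t2.plots)
        assert t1.phylogeny.as_newick() == t2.phylogeny.as_newick()

    def test_ground_truth_stem_sums_match_allometry_module(self):
        cfg = small_config()
        inv, _, truth = fd.simulate_community(cfg)
        model = cfg.allometric_model()
        tabs = fd.stratum_agb_tables(inv, model, cfg.stratum_threshold)
        for stratum in (fd.OVERSTORY, fd.UNDERSTORY):
            per_stem = truth.stems[truth.stems["stratum"] == stratum]
            sums = per_stem.groupby("plot_id")["agb_kg"].sum() / 1000 * 25
            got = tabs[stratum]["agb"]
            np.testing.assert_allclose(
                got.loc[sums.index].to_numpy(), sums.to_numpy(), rtol=1e-12
            )
            realized = truth.plots.query("stratum == @stratum").set_index("plot_id")
            np.testing.assert_allclose(
                got.loc[realized.index], realized["realized_agb"], rtol=1e-12
            )

    def test_stratum_species_subsets(self):
        inv, _, truth = fd.simulate_community(small_config())
        over = truth.stems.query("stratum == 'overstory'")["species"].nunique()
        under = truth.stems.query("stratum == 'understory'")["species"].nunique()
        assert over <= 16 and under <= 14

    def test_planted_effect_shapes_agb(self):
        cfg = small_config(
            n_plots=15,
            beta={"overstory": {"CWM_SLA": 1.0}, "understory": {}},
            noise_sd_fraction=0.01,
        )
        inv, env, truth = fd.simulate_community(cfg)
        realized = (
            truth.plots.query("stratum == 'overstory'")
            .set_index("plot_id")["realized_agb"]
        )
        driver = truth.predictors["overstory"]["CWM_SLA"]
        r = np.corrcoef(driver.loc[realized.index], realized)[0, 1]
        assert r > 0.8

    def test_low_noise_single_driver_r2_near_one(self):
        """Bivariate R^2 for the single planted driver approaches 1 as the
        noise s.d. goes to 0 (limit behaviour of the planted model)."""
        cfg = small_config(
            n_plots=20,
            beta={"overstory": {"MPD": 1.0}, "understory": {}},
            noise_sd_fraction=0.001,
        )
        _, _, truth = fd.simulate_community(cfg)
        realized = (
            truth.plots.query("stratum == 'overstory'")
            .set_index("plot_id")["realized_agb"]
        )
        fit = fd.bivariate_fit(
            truth.predictors["overstory"]["MPD"].loc[realized.index],
            np.log(realized),
        )
        assert fit.r2 > 0.95

    def test_unknown_planted_predictor_rejected(self):
        cfg = small_config(beta={"overstory": {"NOT_A_METRIC": 1.0}})
        with pytest.raises(fd.GenerationError, match="NOT_A_METRIC"):
            fd.simulate_community(cfg)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="lambda"):
            fd.SimulationConfig(lambda_signal=1.5)
        with pytest.raises(ValueError, match="pool"):
            fd.SimulationConfig(n_species_pool=40, n_species_overstory=48)

    def test_environment_within_study_ranges(self):
        _, env, _ = fd.simulate_community(small_config())
        e = env.data
        assert e["elevation"].between(2450, 2650).all()
        assert (e[list(fd.SOIL_VARS)] > 0).all().all()


def test_null_beta_leaves_independent_predictors_unimportant():
    """With no planted effects, environment axes (generated independently
    of the community) reach VIP > 1 only at roughly chance frequency.
    Composition-coupled metrics are excluded: stem counts tie them to AGB
    even under a null planting."""
    hits = 0
    reps = 25
    for s in range(reps):
        cfg = small_config(
            n_plots=15, seed=40_000 + s,
            beta={"overstory": {}, "understory": {}},
        )
        inv, env, truth = fd.simulate_community(cfg)
        over, _ = fd.split_strata(inv, cfg.stratum_threshold)
        ab = fd.abundance_matrix(over, stratum="overstory")
        div = fd.diversity_profile(ab, truth.traits, truth.phylogeny)
        es = fd.env_scores(env)
        X = pd.concat([div, es.scores.reindex(div.index)], axis=1)[
            fd.PREDICTOR_COLUMNS
        ]
        y = fd.plot_agb(over, cfg.allometric_model(),
                        plot_ids=list(X.index))["agb"].loc[X.index]
        v = fd.vip(fd.fit_pls(X, y, 2))
        hits += v["Topo_PC1"] > 1
    assert 0.02 <= hits / reps <= 0.75
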