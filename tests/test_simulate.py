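import numpy as np
import pytest

from forestbeta import simulate as sim
from forestbeta.io import ValidationError, cophenetic_distance


class TestSimulateTree:
    def test_two_tip_cherry_depth_one(self):
        phylo = sim.simulate_tree(2, seed=0)
        depths = [l.distance_from_root()
                  for l in phylo.tree.leaf_node_iter()]
        np.testing.assert_allclose(depths, 1.0)

    def test_binary_rooted_node_count(self):
        phylo = sim.simulate_tree(8, seed=1)
        assert len(phylo.tree.nodes()) == 2 * 8 - 1

    def test_ultrametric_unit_depth(self):
        phylo = sim.simulate_tree(12, seed=2)
        depths = np.array([l.distance_from_root()
                           for l in phylo.tree.leaf_node_iter()])
        np.testing.assert_allclose(depths, 1.0, atol=1e-9)

    def test_seed_determinism(self):
        a = sim.simulate_tree(10, seed=5).as_newick()
        b = sim.simulate_tree(10, seed=5).as_newick()
        assert a == b

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValidationError):
            sim.simulate_tree(1, seed=0)


class TestSimulateTraits:
    def test_standardized_columns(self):
        phylo = sim.simulate_tree(30, seed=0)
        traits = sim.simulate_traits(phylo, 4, w=0.7, seed=1)
        np.testing.assert_allclose(traits.table.mean(), 0.0, atol=1e-9)
        np.testing.assert_allclose(traits.table.std(ddof=1), 1.0, atol=1e-9)

    def test_w_zero_has_no_phylogenetic_signal(self):
        """With w=0, the correlation between trait distance and cophenetic
        distance should be indistinguishable from the tip-shuffled
        baseline (permutation oracle over replicates)."""
        phylo = sim.simulate_tree(25, seed=3)
        coph = cophenetic_distance(phylo)
        iu = np.triu_indices(25, 1)
        cvec = coph.values[iu]
        rng = np.random.default_rng(0)
        obs, null = [], []
        for rep in range(25):
            traits = sim.simulate_traits(phylo, 1, w=0.0, seed=100 + rep)
            t = traits.table.loc[coph.labels].to_numpy()[:, 0]
            tdist = np.abs(t[:, None] - t[None, :])[iu]
            obs.append(np.corrcoef(tdist, cvec)[0, 1])
            ts = rng.permutation(t)
            null.append(np.corrcoef(
                np.abs(ts[:, None] - ts[None, :])[iu], cvec)[0, 1])
        assert abs(np.mean(obs) - np.mean(null)) < 0.08

    def test_w_one_has_signal(self):
        phylo = sim.simulate_tree(25, seed=3)
        coph = cophenetic_distance(phylo)
        iu = np.triu_indices(25, 1)
        cvec = coph.values[iu]
        corrs = []
        for rep in range(10):
            traits = sim.simulate_traits(phylo, 1, w=1.0, seed=200 + rep)
            t = traits.table.loc[coph.labels].to_numpy()[:, 0]
            corrs.append(np.corrcoef(
                np.abs(t[:, None] - t[None, :])[iu], cvec)[0, 1])
        assert np.mean(corrs) > 0.15

    def test_invalid_args_rejected(self):
        phylo = sim.simulate_tree(4, seed=0)
        with pytest.raises(ValidationError):
            sim.simulate_traits(phylo, 0, w=0.5, seed=0)
        with pytest.raises(ValidationError):
            sim.simulate_traits(phylo, 2, w=1.5, seed=0)


class TestLandscape:
    def test_zero_sill_gives_constant_field(self):
        cfg = sim.ScenarioConfig.scaled("neutral", seed=0)
        for p in cfg.soil_params.values():
            p.sill = 0.0
            p.nugget = 0.0
        land = sim.simulate_landscape(cfg)
        for var, p in cfg.soil_params.items():
            np.testing.assert_allclose(land.fields[var], p.mean)

    def test_seed_determinism(self):
        cfg = sim.ScenarioConfig.scaled("neutral", seed=9)
        a = sim.simulate_landscape(cfg)
        b = sim.simulate_landscape(cfg)
        np.testing.assert_array_equal(a.elevation, b.elevation)
        np.testing.assert_array_equal(a.fields["pH"], b.fields["pH"])

    def test_relief_rescaling(self):
        cfg = sim.ScenarioConfig.scaled("neutral", seed=1)
        land = sim.simulate_landscape(cfg)
        assert land.elevation.min() == pytest.approx(708.2)
        assert land.elevation.max() == pytest.approx(869.1)

    def test_bad_resolution_rejected(self):
        cfg = sim.ScenarioConfig.scaled("neutral", seed=0, resolution=7.0)
        with pytest.raises(ValidationError, match="resolution"):
            sim.simulate_landscape(cfg)

    def test_variogram_self_consistency(self):
        """A simulated field, sampled and fitted by the soilenv machinery,
        recovers its generating correlation length within a factor two
        (median over seeds)."""
        from forestbeta import soilenv
        got = []
        for seed in range(5):
            cfg = sim.ScenarioConfig.scaled(
                "neutral", seed=seed, width=200.0, height=200.0,
                n_stems=10, n_species=5)
            land = sim.simulate_landscape(cfg)
            cfg2 = sim.ScenarioConfig.scaled(
                "neutral", seed=seed, width=200.0, height=200.0,
                soil_grid_spacing=15.0)
            samples = sim.simulate_soil_sampling(land, cfg2)
            emp = soilenv.empirical_variogram(samples, "extractable_P")
            got.append(soilenv.fit_variogram(emp).range_)
        true_range = 30.0
        assert true_range / 2 <= np.median(got) <= true_range * 2


class TestSimulateCensus:
    def _inputs(self, scenario, seed, **kw):
        cfg = sim.ScenarioConfig.scaled(scenario, seed=seed, **kw)
        phylo = sim.simulate_tree(cfg.n_species, cfg.seed)
        traits = sim.simulate_traits(phylo, cfg.n_traits,
                                     cfg.trait_signal_w, cfg.seed + 3)
        land = sim.simulate_landscape(cfg)
        return cfg, phylo, traits, land

    def test_exact_stem_count(self):
        cfg, phylo, traits, land = self._inputs("mixed", 4, n_stems=500)
        census = sim.simulate_census(phylo, traits, land, cfg)
        assert census.n_stems == 500

    def test_neutral_stems_ignore_optima(self):
        """Monte-Carlo oracle: under neutral assembly the correlation
        between a species' optimum and the field value at its stems is
        centred on zero across replicates."""
        corrs = []
        for seed in range(20):
            cfg, phylo, traits, land = self._inputs(
                "neutral", seed, n_stems=400, n_species=20)
            census = sim.simulate_census(phylo, traits, land, cfg)
            mu = sim.species_optima(traits, land, cfg.filter_variable)
            df = census.stems
            df = df.assign(e=land.value_at(cfg.filter_variable,
                                           df["x"].to_numpy(),
                                           df["y"].to_numpy()))
            mean_e = df.groupby("species")["e"].mean()
            common = mean_e.index
            if len(common) > 3:
                corrs.append(np.corrcoef(mu[common], mean_e[common])[0, 1])
        assert abs(np.mean(corrs)) < 0.15

    def test_strong_filtering_tracks_optima(self):
        """In the narrow-niche limit stems sit where the field is close
        to their species' optimum: the typical gap is within a few
        niche widths and far below the gap of unfiltered placement."""
        gaps = {}
        for scenario in ("filtered", "neutral"):
            cfg, phylo, traits, land = self._inputs(
                scenario, 2, n_stems=300, n_species=10, sigma_f=0.05)
            census = sim.simulate_census(phylo, traits, land, cfg)
            mu = sim.species_optima(traits, land, cfg.filter_variable)
            e = land.value_at(cfg.filter_variable,
                              census.stems["x"].to_numpy(),
                              census.stems["y"].to_numpy())
            gaps[scenario] = np.abs(
                e - census.stems["species"].map(mu).to_numpy())
        assert np.median(gaps["filtered"]) < 4 * 0.05
        assert np.mean(gaps["filtered"]) < np.mean(gaps["neutral"]) / 3


class TestSoilSampling:
    def test_design_geometry(self):
        cfg = sim.ScenarioConfig.scaled("neutral", seed=0)
        land = sim.simulate_landscape(cfg)
        table = sim.simulate_soil_sampling(land, cfg)
        # 10 m grid on [0, 100): 10 x 10 bases, 2 satellites each
        assert table.n_points == 100 * 3
        xy = table.coords()
        bases = xy[::3]
        np.testing.assert_allclose(bases % cfg.soil_grid_spacing, 0.0,
                                   atol=1e-9)
        allowed = {2.0, 5.0, 15.0}
        pairs = {(2.0, 5.0), (2.0, 15.0), (5.0, 15.0)}
        for b in range(100):
            base = xy[3 * b]
            radii = []
            for s in (1, 2):
                r = np.linalg.norm(xy[3 * b + s] - base)
                assert min(abs(r - a) for a in allowed) < 1e-9
                radii.append(round(r, 6))
            assert tuple(sorted(radii)) in pairs

    def test_zero_noise_reads_field_exactly(self):
        cfg = sim.ScenarioConfig.scaled("neutral", seed=1)
        land = sim.simulate_landscape(cfg)
        table = sim.simulate_soil_sampling(land, cfg)
        xy = table.coords()
        for var in ("pH", "total_C"):
            expected = land.value_at(var, xy[:, 0], xy[:, 1])
            np.testing.assert_allclose(
                table.samples[var].to_numpy(), expected)

    def test_spacing_larger_than_plot_rejected(self):
        cfg = sim.ScenarioConfig.scaled("neutral", seed=0)
        land = sim.simulate_landscape(cfg)
        cfg.soil_grid_spacing = 500.0
        with pytest.raises(ValidationError):
            sim.simulate_soil_sampling(land, cfg)


class TestScenarioConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValidationError):
            sim.ScenarioConfig(scenario="nope")
        with pytest.raises(ValidationError):
            sim.ScenarioConfig(trait_signal_w=2.0)
        with pytest.raises(ValidationError):
            sim.ScenarioConfig(n_species=0)

    def test_scaled_presets(self):
        cfg = sim.ScenarioConfig.scaled("filtered", seed=7)
        assert cfg.n_stems == 2000 and cfg.n_species == 50
        assert cfg.env_elevation_corr > 0
        neutral = sim.ScenarioConfig.scaled("neutral", seed=7)
        assert neutral.env_elevation_corr == 0.0
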