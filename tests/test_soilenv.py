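import numpy as np
import pandas as pd
import pytest

from forestbeta import soilenv
from forestbeta.grid import subdivide_plot
from forestbeta.io import SoilSampleTable, ValidationError


def _table(xy, values, name="v"):
    df = pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], name: values})
    return SoilSampleTable(df, [name])


def _exponential_field_samples(n, sill, range_, nugget, seed,
                               extent=200.0):
    """Direct multivariate-normal draw with exponential covariance —
    independent of the FFT generator in the simulate module."""
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0, extent, size=(n, 2))
    h = np.sqrt(((xy[:, None] - xy[None, :]) ** 2).sum(-1))
    cov = sill * np.exp(-h / range_) + nugget * np.eye(n)
    z = np.linalg.cholesky(cov + 1e-10 * np.eye(n)) @ rng.standard_normal(n)
    return xy, z


class TestEmpiricalVariogram:
    def test_constant_field_zero_semivariance(self, rng):
        xy = rng.uniform(0, 100, size=(50, 2))
        emp = soilenv.empirical_variogram(_table(xy, np.full(50, 3.0)), "v")
        ok = emp.counts > 0
        np.testing.assert_allclose(emp.semivariance[ok], 0.0, atol=1e-12)

    def test_white_noise_sill_everywhere(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 100, size=(500, 2))
        z = rng.normal(0, 2.0, 500)  # variance 4
        emp = soilenv.empirical_variogram(_table(xy, z), "v")
        ok = emp.counts > 30
        assert np.all(np.abs(emp.semivariance[ok] - 4.0) < 1.0)

    def test_missing_variable_rejected(self, rng):
        xy = rng.uniform(0, 100, size=(40, 2))
        with pytest.raises(ValidationError, match="absent"):
            soilenv.empirical_variogram(_table(xy, np.zeros(40)), "other")


class TestFitVariogram:
    def test_recovers_exponential_range_within_factor_two(self):
        """Single realizations at this extent/range ratio occasionally look
        longer-range than the generating model, so the recovery claim is
        on the median over replicates (plus a majority of single fits)."""
        ranges = []
        for seed in range(10):
            xy, z = _exponential_field_samples(
                500, sill=2.0, range_=60.0, nugget=0.01, seed=seed,
                extent=400.0)
            emp = soilenv.empirical_variogram(_table(xy, z), "v")
            ranges.append(soilenv.fit_variogram(emp).range_)
        assert 30.0 <= np.median(ranges) <= 120.0
        assert sum(30.0 <= r <= 120.0 for r in ranges) >= 6

    def test_pure_nugget_gives_small_partial_sill(self):
        rng = np.random.default_rng(2)
        xy = rng.uniform(0, 200, size=(500, 2))
        z = rng.normal(0, 1.0, 500)
        emp = soilenv.empirical_variogram(_table(xy, z), "v")
        model = soilenv.fit_variogram(emp)
        assert model.psill < 0.3 * (model.nugget + model.psill)

    def test_too_few_bins_rejected(self):
        emp = soilenv.EmpiricalVariogram(
            lags=np.array([1.0, 2, 3]),
            semivariance=np.array([1.0, 1, 1]),
            counts=np.array([5, 5, 5]))
        with pytest.raises(ValidationError, match="bins"):
            soilenv.fit_variogram(emp)


class TestBlockKrige:
    def test_constant_samples_predict_constant(self, rng):
        xy = rng.uniform(0, 40, size=(30, 2))
        table = _table(xy, np.full(30, 7.5))
        model = soilenv.VariogramModel("exponential", 0.1, 1.0, 20.0)
        grid = subdivide_plot(40.0, 40.0, 20.0)
        pred = soilenv.block_krige(table, model, grid, "v")
        np.testing.assert_allclose(pred.to_numpy(), 7.5, atol=1e-8)

    def test_weights_sum_to_one(self, rng):
        xy = rng.uniform(0, 40, size=(25, 2))
        table = _table(xy, rng.normal(size=25))
        model = soilenv.VariogramModel("exponential", 0.2, 1.0, 15.0)
        grid = subdivide_plot(40.0, 40.0, 10.0)
        _, weights = soilenv.block_krige(table, model, grid, "v",
                                         return_weights=True)
        np.testing.assert_allclose(weights.sum(axis=0), 1.0, atol=1e-8)

    def test_zero_nugget_exact_interpolation_at_sample(self, rng):
        # one 10x10 block, discretization 1 -> prediction point is the
        # block centre (5,5), where a sample sits
        xy = np.vstack([[5.0, 5.0], rng.uniform(0, 10, size=(10, 2))])
        vals = np.concatenate([[3.25], rng.normal(size=10)])
        table = _table(xy, vals)
        model = soilenv.VariogramModel("exponential", 0.0, 1.0, 8.0)
        grid = subdivide_plot(10.0, 10.0, 10.0)
        pred = soilenv.block_krige(table, model, grid, "v", discretization=1)
        assert pred.iloc[0] == pytest.approx(3.25, abs=1e-8)

    def test_duplicate_coordinates_deduplicated(self, rng):
        xy = rng.uniform(0, 40, size=(20, 2))
        xy = np.vstack([xy, xy[0]])
        table = _table(xy, np.concatenate([rng.normal(size=20),
                                           [5.0]]))
        model = soilenv.VariogramModel("exponential", 0.1, 1.0, 15.0)
        grid = subdivide_plot(40.0, 40.0, 20.0)
        pred = soilenv.block_krige(table, model, grid, "v")
        assert np.all(np.isfinite(pred))

    def test_beats_inverse_distance_weighting_on_exponential_fields(self):
        """Sanity: block kriging should track true subplot means better
        than IDW on fields it is the BLUP for.  Truth comes from a full
        gridded field; both predictors see the same 150 point samples."""
        from forestbeta.simulate import _gaussian_random_field
        wins = 0
        res, side, scale = 2.0, 100.0, 25.0
        grid = subdivide_plot(side, side, scale)
        n_nodes = int(side / res)
        k = int(scale / res)
        offs = (np.arange(4) + 0.5) / 4 * scale
        ox, oy = np.meshgrid(offs, offs)
        offsets = np.column_stack([ox.ravel(), oy.ravel()])
        for seed in range(20):
            rng = np.random.default_rng(seed)
            field = _gaussian_random_field(n_nodes, n_nodes, res,
                                           sill=1.0, range_=30.0,
                                           nugget=0.0, rng=rng)
            idx = rng.choice(n_nodes * n_nodes, size=150, replace=False)
            ii, jj = idx // n_nodes, idx % n_nodes
            xy = np.column_stack([(jj + 0.5) * res, (ii + 0.5) * res])
            z = field[ii, jj]
            table = _table(xy, z)
            emp = soilenv.empirical_variogram(table, "v")
            model = soilenv.fit_variogram(emp)
            kriged = soilenv.block_krige(table, model, grid, "v").to_numpy()
            truth = np.array([
                field[r * k:(r + 1) * k, c * k:(c + 1) * k].mean()
                for r in range(grid.n_rows) for c in range(grid.n_cols)])
            idw = []
            origins = grid.centers() - scale / 2
            for c in range(grid.n_cells):
                pts = origins[c][None, :] + offsets
                d = np.sqrt(((xy[:, None] - pts[None, :, :]) ** 2).sum(-1))
                w = 1.0 / (d + 1e-6) ** 2
                idw.append((w / w.sum(0) * z[:, None]).sum(0).mean())
            rmse_k = np.sqrt(((kriged - truth) ** 2).mean())
            rmse_i = np.sqrt(((np.array(idw) - truth) ** 2).mean())
            wins += rmse_k <= rmse_i
        assert wins >= 13


class TestEnvironmentDistance:
    def test_identical_profiles_zero_distance(self):
        env = pd.DataFrame({"a": [1.0, 1.0, 2.0], "b": [0.5, 0.5, 1.5]},
                           index=["p", "q", "r"])
        d, _ = soilenv.environment_distance(env, n_axes=2)
        assert d.loc("p", "q") == pytest.approx(0.0, abs=1e-12)

    def test_affine_rescaling_invariance(self, rng):
        env = pd.DataFrame(rng.normal(size=(10, 5)),
                           index=[f"s{i}" for i in range(10)])
        d1, _ = soilenv.environment_distance(env)
        env2 = env * 100.0 + 7.0
        d2, _ = soilenv.environment_distance(env2)
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-8)

    def test_matches_eigendecomposition_oracle(self, rng):
        env = pd.DataFrame(rng.normal(size=(12, 6)),
                           index=[f"s{i}" for i in range(12)])
        d, varexp = soilenv.environment_distance(env, n_axes=3)
        z = ((env - env.mean()) / env.std(ddof=1)).to_numpy()
        cov = z.T @ z / (len(z) - 1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        scores = z @ v[:, order[:3]]
        expected = np.sqrt(
            ((scores[:, None] - scores[None, :]) ** 2).sum(-1))
        np.testing.assert_allclose(d.values, expected, atol=1e-8)
        np.testing.assert_allclose(varexp, (w[order] / w.sum())[:3],
                                   atol=1e-10)

    def test_projection_contracts_full_distance(self, rng):
        env = pd.DataFrame(rng.normal(size=(10, 6)),
                           index=[f"s{i}" for i in range(10)])
        d3, _ = soilenv.environment_distance(env, n_axes=3)
        z = ((env - env.mean()) / env.std(ddof=1)).to_numpy()
        full = np.sqrt(((z[:, None] - z[None, :]) ** 2).sum(-1))
        assert np.all(d3.values <= full + 1e-9)
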