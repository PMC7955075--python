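"""Bioclim derivation, zonal statistics, PCA and displacement, checked
against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from pavuln import (
    GridSpec,
    MonthlyClimateCube,
    ProtectedArea,
    RasterLayer,
    climate_displacement,
    compute_bioclim,
    delta_mat,
    fit_climate_pca,
    monthly_climatology,
    simulate_monthly_climate,
    zonal_mean,
)
from pavuln.climate import Climatology


def bioclim_oracle(tmin, tmax, prec):
    """Exhaustive scan of the 12 wrap-around quarters for one cell.

    Independent scalar-loop reference for the vectorized derivation.
    """
    tmean = [(a + b) / 2.0 for a, b in zip(tmin, tmax)]
    mat = sum(tmean) / 12.0
    map_ = sum(prec)
    qt, qp = [], []
    for s in range(12):
        months = [s % 12, (s + 1) % 12, (s + 2) % 12]
        qt.append(sum(tmean[m] for m in months) / 3.0)
        qp.append(sum(prec[m] for m in months))
    return {
        "MAT": mat, "MTWQ": max(qt), "MTCQ": min(qt),
        "MAP": map_, "PWQ": max(qp), "PDQ": min(qp),
    }


def clim_from_cell(tmin, tmax, prec):
    g = GridSpec(1, 1)
    shape = (12, 1, 1)
    return Climatology(
        g,
        np.asarray(tmin, float).reshape(shape),
        np.asarray(tmax, float).reshape(shape),
        np.asarray(prec, float).reshape(shape),
    )


class TestClimatology:
    def test_mean_of_two_years(self, grid):
        cube = simulate_monthly_climate(grid, [2000], seed=1)
        tmin = np.stack([cube.tmin[0], cube.tmin[0] + 2.0])
        tmax = np.stack([cube.tmax[0], cube.tmax[0] + 2.0])
        prec = np.stack([cube.prec[0], cube.prec[0]])
        two = MonthlyClimateCube(grid, (2000, 2001), tmin, tmax, prec)
        clim = monthly_climatology(two)
        np.testing.assert_allclose(clim.tmin, cube.tmin[0] + 1.0)

    def test_epoch_subset_and_brute_force(self, grid):
        cube = simulate_monthly_climate(grid, range(2000, 2010), seed=2)
        clim = monthly_climatology(cube, range(2000, 2005))
        # independent cell-by-cell loop
        expected = np.zeros((12,) + grid.shape)
        for m in range(12):
            for r in range(grid.nrows):
                for c in range(grid.ncols):
                    expected[m, r, c] = np.mean(
                        [cube.tmax[i, m, r, c] for i in range(5)]
                    )
        np.testing.assert_allclose(clim.tmax, expected)

    def test_unknown_epoch_year_rejected(self, grid):
        cube = simulate_monthly_climate(grid, [2000, 2001], seed=0)
        with pytest.raises(ValueError):
            monthly_climatology(cube, [1999])


class TestComputeBioclim:
    def test_constant_climate_closed_form(self):
        clim = clim_from_cell([10.0] * 12, [20.0] * 12, [100.0] * 12)
        bio = compute_bioclim(clim)
        assert bio.MAT.values[0, 0] == pytest.approx(15.0)
        assert bio.MTWQ.values[0, 0] == pytest.approx(15.0)
        assert bio.MTCQ.values[0, 0] == pytest.approx(15.0)
        assert bio.MAP.values[0, 0] == pytest.approx(1200.0)
        assert bio.PWQ.values[0, 0] == pytest.approx(300.0)
        assert bio.PDQ.values[0, 0] == pytest.approx(300.0)

    def test_summer_peak_window(self):
        tmean = [0, 0, 0, 0, 0, 10, 10, 10, 0, 0, 0, 0]
        clim = clim_from_cell(tmean, tmean, [50.0] * 12)
        bio = compute_bioclim(clim)
        assert bio.MTWQ.values[0, 0] == pytest.approx(10.0)
        assert bio.MAT.values[0, 0] == pytest.approx(2.5)

    def test_wraparound_warm_quarter(self):
        # Warm Dec-Jan-Feb only: the best window crosses the year boundary.
        tmean = [12.0, 12.0] + [0.0] * 9 + [12.0]
        clim = clim_from_cell(tmean, tmean, [50.0] * 12)
        bio = compute_bioclim(clim)
        assert bio.MTWQ.values[0, 0] == pytest.approx(12.0)

    def test_matches_brute_force_oracle_on_random_climatologies(self, rng):
        n = 1000
        tmin = rng.normal(0, 10, size=(n, 12))
        tmax = tmin + rng.uniform(0, 15, size=(n, 12))
        prec = rng.gamma(2.0, 40.0, size=(n, 12))
        grid = GridSpec(n, 1)
        clim = Climatology(
            grid,
            tmin.T[:, :, None], tmax.T[:, :, None], prec.T[:, :, None],
        )
        bio = compute_bioclim(clim)
        for i in range(n):
            exp = bioclim_oracle(tmin[i], tmax[i], prec[i])
            for var, val in exp.items():
                assert getattr(bio, var).values[i, 0] == pytest.approx(val), (
                    f"cell {i}, {var}"
                )

    def test_ordering_invariants_on_random_input(self, rng):
        tmin = rng.normal(0, 10, size=(12, 15, 15))
        tmax = tmin + rng.uniform(0, 12, size=(12, 15, 15))
        prec = rng.gamma(2.0, 30.0, size=(12, 15, 15))
        bio = compute_bioclim(Climatology(GridSpec(15, 15), tmin, tmax, prec))
        assert np.all(bio.MTCQ.values <= bio.MAT.values + 1e-12)
        assert np.all(bio.MAT.values <= bio.MTWQ.values + 1e-12)
        assert np.all(bio.PDQ.values >= 0)
        assert np.all(bio.PDQ.values <= bio.PWQ.values + 1e-12)
        assert np.all(bio.PWQ.values <= bio.MAP.values + 1e-12)


class TestZonalMean:
    def test_uniform_raster(self, grid, one_cell_pa):
        layer = RasterLayer(grid, np.full(grid.shape, 7.0))
        assert zonal_mean(layer, one_cell_pa) == 7.0

    def test_two_cell_mean(self, grid):
        vals = np.zeros(grid.shape)
        vals[0, 0], vals[0, 1] = 1.0, 3.0
        pa = ProtectedArea("P", frozenset({(0, 0), (0, 1)}))
        assert zonal_mean(RasterLayer(grid, vals), pa) == 2.0

    def test_nodata_cells_excluded(self, grid):
        vals = np.zeros(grid.shape)
        vals[0, 0], vals[0, 1], vals[0, 2] = 2.0, 99.0, 4.0
        mask = np.zeros(grid.shape, bool)
        mask[0, 1] = True
        pa = ProtectedArea("P", frozenset({(0, 0), (0, 1), (0, 2)}))
        assert zonal_mean(RasterLayer(grid, vals, mask), pa) == 3.0

    def test_all_nodata_is_explicit_missing(self, grid, one_cell_pa):
        layer = RasterLayer(grid, np.zeros(grid.shape),
                            np.ones(grid.shape, bool))
        with pytest.warns(UserWarning, match="NODATA"):
            assert np.isnan(zonal_mean(layer, one_cell_pa))


class TestClimatePCA:
    def test_rank_one_data(self):
        t = np.linspace(0, 1, 30)
        X = pd.DataFrame(np.outer(t, np.arange(1, 7)),
                         columns=list("ABCDEF"))
        model = fit_climate_pca(X, variables=list("ABCDEF"))
        assert model.variance_explained[0] == pytest.approx(1.0)

    def test_variance_explained_monotone_and_bounded(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 6)), columns=list("ABCDEF"))
        model = fit_climate_pca(X, variables=list("ABCDEF"))
        ve = model.variance_explained
        assert ve[0] >= ve[1] and np.all(ve <= 1.0) and np.all(ve > 0)

    def test_loadings_match_eigendecomposition_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 6)) @ rng.normal(size=(6, 6)),
                         columns=list("ABCDEF"))
        model = fit_climate_pca(X, variables=list("ABCDEF"))
        Z = (X.values - X.values.mean(0)) / X.values.std(0, ddof=1)
        evals, evecs = np.linalg.eigh(np.cov(Z.T))
        order = np.argsort(evals)[::-1]
        expected = evecs[:, order[:2]]
        for j in range(2):  # sign-invariant comparison
            got = model.loadings[:, j]
            assert (np.allclose(got, expected[:, j], atol=1e-8)
                    or np.allclose(got, -expected[:, j], atol=1e-8))
        assert np.allclose(model.loadings.T @ model.loadings, np.eye(2),
                           atol=1e-10)

    def test_zero_variance_column_warns(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 6)), columns=list("ABCDEF"))
        X["F"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            fit_climate_pca(X, variables=list("ABCDEF"))

    def test_too_few_rows_rejected(self):
        X = pd.DataFrame(np.ones((2, 6)), columns=list("ABCDEF"))
        with pytest.raises(ValueError):
            fit_climate_pca(X, variables=list("ABCDEF"))


class TestDisplacement:
    @pytest.fixture
    def model(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 6)), columns=list("ABCDEF"))
        return fit_climate_pca(X, variables=list("ABCDEF"))

    def test_identical_epochs_zero(self, model, rng):
        past = pd.DataFrame(rng.normal(size=(5, 6)), columns=list("ABCDEF"),
                            index=[f"P{i}" for i in range(5)])
        disp = climate_displacement(model, past, past.copy())
        np.testing.assert_allclose(disp.displacement, 0.0, atol=1e-12)

    def test_three_four_five_triangle(self):
        # Identity-like model: loadings pick out two variables directly.
        model_vars = list("ABCDEF")
        center = np.zeros(6)
        scale = np.ones(6)
        loadings = np.zeros((6, 2))
        loadings[0, 0] = 1.0
        loadings[1, 1] = 1.0
        from pavuln.climate import PCAModel

        model = PCAModel(tuple(model_vars), center, scale, loadings,
                         np.array([0.6, 0.4]))
        past = pd.DataFrame([[0, 0, 0, 0, 0, 0]], columns=model_vars,
                            index=["P0"])
        present = pd.DataFrame([[3, 4, 0, 0, 0, 0]], columns=model_vars,
                               index=["P0"])
        disp = climate_displacement(model, past, present)
        assert disp.displacement["P0"] == pytest.approx(5.0)

    def test_mismatched_ids_listed(self, model, rng):
        past = pd.DataFrame(rng.normal(size=(3, 6)), columns=list("ABCDEF"),
                            index=["a", "b", "c"])
        present = past.copy()
        present.index = ["a", "b", "zzz"]
        with pytest.raises(ValueError, match="zzz"):
            climate_displacement(model, past, present)

    def test_row_order_invariance(self, model, rng):
        past = pd.DataFrame(rng.normal(size=(6, 6)), columns=list("ABCDEF"),
                            index=[f"P{i}" for i in range(6)])
        present = past + 0.5
        d1 = climate_displacement(model, past, present).table
        shuffled = past.sample(frac=1, random_state=0)
        d2 = climate_displacement(model, shuffled,
                                  present.loc[shuffled.index]).table
        pd.testing.assert_frame_equal(d1, d2.loc[d1.index])


class TestDeltaMat:
    def test_identical_epochs(self):
        mat = pd.Series([5.0, 6.0, 7.0], index=["a", "b", "c"])
        res = delta_mat(mat, mat.copy(), threshold=1.5)
        assert res.n_above == 0
        np.testing.assert_allclose(res.delta, 0.0)

    def test_uniform_warming_counts_all(self):
        mat = pd.Series([5.0, 6.0], index=["a", "b"])
        res = delta_mat(mat, mat + 2.0, threshold=1.5)
        assert res.n_above == 2

    def test_future_layers_averaged_then_subtracted(self):
        cur = pd.Series([0.0], index=["a"])
        futures = [pd.Series([v], index=["a"]) for v in (1.0, 2.0, 3.0)]
        res = delta_mat(cur, futures, threshold=1.5)
        assert res.delta["a"] == pytest.approx(2.0)
        assert res.n_above == 1

    def test_mismatched_ids_rejected(self):
        with pytest.raises(ValueError):
            delta_mat(pd.Series([1.0], index=["a"]),
                      pd.Series([1.0], index=["b"]))
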