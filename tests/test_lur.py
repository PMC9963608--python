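"""Buffers, stepwise selection, diagnostics, prediction, zonal means."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from airhealth.gridio import Grid, SurfaceStack, LANDCOVER_CLASSES
from airhealth.lur import (
    build_buffers,
    buffer_covariates_grid,
    diagnose,
    fit_terms,
    predict_surface,
    stepwise_fit,
    term_name,
    zonal_mean,
)
from airhealth.synthetic import RegionConfig, generate_region
from tests.conftest import constant_stack, lattice_units

FOREST = LANDCOVER_CLASSES.index("forest")
WATER = LANDCOVER_CLASSES.index("water")


def mid_station(stack: SurfaceStack) -> pd.DataFrame:
    tpl = stack.template
    x = tpl.origin[0] + tpl.ncols * tpl.cell_size / 2
    y = tpl.origin[1] + tpl.nrows * tpl.cell_size / 2
    return pd.DataFrame({"id": ["s0"], "x": [x], "y": [y], "pm25": [20.0]})


class TestBuildBuffers:
    def test_constant_field_gives_constant_mean(self):
        stack = constant_stack(7.5)
        X = build_buffers(mid_station(stack), stack, radii=[1000, 3000, 9000])
        assert np.allclose(X.to_numpy(), 7.5)

    def test_all_forest_proportion_one(self):
        lc = np.full((20, 20), FOREST)
        stack = constant_stack(1.0, landcover=lc)
        X = build_buffers(mid_station(stack), stack, radii=[2000, 5000])
        for r in (2000, 5000):
            assert X[term_name("lc_forest", r)].iloc[0] == pytest.approx(1.0)
            assert X[term_name("lc_built", r)].iloc[0] == 0.0

    def test_half_plane_forest_is_half_disc(self):
        """Station on the boundary of a half-plane of forest: the class
        proportion converges to the exact half-disc area fraction 0.5."""
        n = 200
        lc = np.full((n, n), WATER)
        lc[:, : n // 2] = FOREST
        stack = SurfaceStack({"landcover": Grid(lc, cell_size=10.0)})
        # station exactly on the forest/water boundary line x = n/2*10
        st = pd.DataFrame({"id": ["s0"], "x": [n / 2 * 10.0], "y": [n / 2 * 10.0], "pm25": [1.0]})
        X = build_buffers(st, stack, radii=[500.0], covariates=["lc_forest"])
        assert X.iloc[0, 0] == pytest.approx(0.5, abs=0.02)

    def test_buffer_mean_nonincreasing_for_point_source(self):
        """Covariate concentrated at the station: larger buffers dilute it."""
        data = np.zeros((41, 41))
        data[20, 20] = 100.0
        stack = SurfaceStack({"elevation": Grid(data, cell_size=100.0)})
        st = pd.DataFrame({"id": ["s0"], "x": [2050.0], "y": [2050.0], "pm25": [1.0]})
        radii = [100, 200, 400, 800, 1600]
        X = build_buffers(st, stack, radii=radii)
        means = [X[term_name("elevation", r)].iloc[0] for r in radii]
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_station_outside_grid_raises_with_names(self):
        stack = constant_stack(1.0)
        st = pd.DataFrame({"id": ["far"], "x": [1e9], "y": [1e9], "pm25": [1.0]})
        with pytest.raises(ValueError, match="far.*250"):
            build_buffers(st, stack, radii=[250.0])

    def test_radii_must_increase(self):
        stack = constant_stack(1.0)
        with pytest.raises(ValueError):
            build_buffers(mid_station(stack), stack, radii=[500, 500])

    def test_landcover_proportions_sum_to_one(self, small_region):
        _, stations, surfaces, _ = small_region
        X = build_buffers(stations, surfaces, radii=[1000, 4000],
                          covariates=[f"lc_{c}" for c in LANDCOVER_CLASSES])
        for r in (1000, 4000):
            total = sum(X[term_name(f"lc_{c}", r)] for c in LANDCOVER_CLASSES)
            assert np.allclose(total, 1.0, atol=1e-6)


class TestStepwise:
    def _noise_matrix(self, rng, n, k):
        return pd.DataFrame(
            {term_name(f"cov{j}", 1000): rng.standard_normal(n) for j in range(k)}
        )

    def test_single_true_predictor_recovered(self):
        rng = np.random.default_rng(0)
        X = self._noise_matrix(rng, 40, 6)
        y = 3.0 + 2.0 * X[term_name("cov2", 1000)].to_numpy()
        model = stepwise_fit(X, y)
        assert model.column_names == [term_name("cov2", 1000)]
        assert model.r2 == pytest.approx(1.0, abs=1e-8)
        assert model.coefficients[term_name("cov2", 1000)] == pytest.approx(2.0, abs=1e-8)

    def test_two_term_ground_truth_support_recovered(self):
        cfg = RegionConfig(n_rows=6, n_cols=12, n_stations=24, seed=13, noise_sd=0.0,
                           true_coefficients={"elevation": -0.002, "population": 1e-4})
        _, stations, surfaces, truth = generate_region(cfg)
        X = build_buffers(stations, surfaces)
        model = stepwise_fit(X, stations["pm25"].to_numpy())
        assert set(model.column_names) == {
            term_name("elevation", cfg.true_radius),
            term_name("population", cfg.true_radius),
        }
        for c in model.column_names:
            assert model.coefficients[c] == pytest.approx(
                truth.coefficients[c.split("@")[0]], abs=1e-6
            )

    def test_one_radius_per_covariate(self, small_region):
        _, stations, surfaces, _ = small_region
        X = build_buffers(stations, surfaces)
        model = stepwise_fit(X, stations["pm25"].to_numpy())
        covs = [c for c, _ in model.terms]
        assert len(covs) == len(set(covs))

    def test_r2_gate(self):
        rng = np.random.default_rng(1)
        X = self._noise_matrix(rng, 30, 4)
        signal = X[term_name("cov0", 1000)].to_numpy()
        good = 10 + 2 * signal + 0.01 * rng.standard_normal(30)
        bad = 10 + 0.3 * signal + rng.standard_normal(30)
        assert stepwise_fit(X, good).passes_gate(0.90)
        assert not stepwise_fit(X, bad).passes_gate(0.90)

    def test_zero_variance_y_rejected(self):
        X = self._noise_matrix(np.random.default_rng(2), 20, 3)
        with pytest.raises(ValueError, match="variance"):
            stepwise_fit(X, np.full(20, 5.0))

    def test_too_few_stations_rejected(self):
        X = self._noise_matrix(np.random.default_rng(2), 2, 3)
        with pytest.raises(ValueError, match="3 stations"):
            stepwise_fit(X, np.array([1.0, 2.0]))

    def test_r2_equals_independent_recomputation(self, small_region):
        _, stations, surfaces, _ = small_region
        X = build_buffers(stations, surfaces)
        y = stations["pm25"].to_numpy()
        model = stepwise_fit(X, y)
        design = np.column_stack(
            [np.ones(len(y))] + [X[c].to_numpy() for c in model.column_names]
        )
        beta = np.array([model.intercept] + [model.coefficients[c] for c in model.column_names])
        sse = float(((y - design @ beta) ** 2).sum())
        sst = float(((y - y.mean()) ** 2).sum())
        assert model.r2 == pytest.approx(1 - sse / sst, abs=1e-10)


class TestDiagnose:
    def test_duplicated_predictor_raises_vif_flag(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(30)
        X = pd.DataFrame(
            {
                term_name("a", 500): base,
                term_name("a_copy", 500): base,  # perfectly collinear
            }
        )
        y = 1 + base + 0.1 * rng.standard_normal(30)
        model = fit_terms(X, y, list(X.columns))
        diag = diagnose(model, X, y)
        assert diag["flag_vif"]
        assert max(diag["vif"].values()) > 10

    def test_dw_in_band_for_independent_residuals(self):
        """Under the null (independent Gaussian errors, n=200) the DW
        statistic should land in [1.5, 2.5] almost always."""
        rng = np.random.default_rng(4)
        n, hits, reps = 200, 0, 500
        x = rng.standard_normal(n)
        X = pd.DataFrame({term_name("x", 250): x})
        for _ in range(reps):
            y = 2 + x + rng.standard_normal(n)
            model = fit_terms(X, y, list(X.columns))
            d = diagnose(model, X, y)
            hits += 1.5 <= d["durbin_watson"] <= 2.5
        assert hits / reps >= 0.95

    def test_degenerate_residuals_report_no_normality_p(self):
        x = np.linspace(0, 1, 25)
        X = pd.DataFrame({term_name("x", 250): x})
        y = 5 + 3 * x  # exact fit, residuals ~ 0
        model = fit_terms(X, y, list(X.columns))
        diag = diagnose(model, X, y)
        assert diag["shapiro_p"] is None

    def test_saturated_model_rejected(self):
        X = pd.DataFrame({term_name("a", 250): [1.0, 2.0], term_name("b", 250): [0.0, 1.0]})
        y = np.array([1.0, 2.0])
        model = fit_terms(X, y, list(X.columns))
        with pytest.raises(ValueError, match="[Ss]aturated"):
            diagnose(model, X, y)


class TestPredictSurface:
    def test_intercept_only_constant_surface(self, small_region):
        from airhealth.lur import LURModel

        _, _, surfaces, _ = small_region
        model = LURModel(terms=[], intercept=12.5, coefficients={}, r2=0.0, n_obs=0)
        surf = predict_surface(model, surfaces)
        assert np.allclose(surf.data, 12.5)

    def test_noiseless_prediction_equals_true_surface(self, small_config):
        cfg = dataclasses.replace(small_config, noise_sd=0.0)
        _, stations, surfaces, truth = generate_region(cfg)
        X = build_buffers(stations, surfaces, radii=[cfg.true_radius])
        cols = [term_name(c, cfg.true_radius) for c in truth.coefficients]
        model = fit_terms(X, stations["pm25"].to_numpy(), cols)
        surf = predict_surface(model, surfaces)
        assert np.max(np.abs(surf.data - truth.true_surface.data)) <= 1e-6

    def test_doubling_coefficient_doubles_contribution(self, small_region):
        from airhealth.lur import LURModel

        _, _, surfaces, _ = small_region
        base = LURModel(terms=[("elevation", 1000.0)], intercept=0.0,
                        coefficients={term_name("elevation", 1000): 0.01},
                        r2=1.0, n_obs=0)
        double = LURModel(terms=[("elevation", 1000.0)], intercept=0.0,
                          coefficients={term_name("elevation", 1000): 0.02},
                          r2=1.0, n_obs=0)
        s1 = predict_surface(base, surfaces)
        s2 = predict_surface(double, surfaces)
        assert np.allclose(s2.data, 2 * s1.data, atol=1e-12)

    def test_missing_covariate_raises(self, small_region):
        from airhealth.lur import LURModel

        _, _, surfaces, _ = small_region
        model = LURModel(terms=[("nosuch", 1000.0)], intercept=0.0,
                         coefficients={term_name("nosuch", 1000): 1.0}, r2=1.0, n_obs=0)
        with pytest.raises(KeyError):
            predict_surface(model, surfaces)

    def test_negative_predictions_clipped(self, small_region):
        from airhealth.lur import LURModel

        _, _, surfaces, _ = small_region
        model = LURModel(terms=[("elevation", 1000.0)], intercept=-1e6,
                         coefficients={term_name("elevation", 1000): 0.0}, r2=0.0, n_obs=0)
        surf = predict_surface(model, surfaces)
        assert (surf.data == 0).all()


class TestZonalMean:
    def test_constant_surface(self):
        units = lattice_units(2, 3, size=3.0)
        surf = Grid(np.full((6, 9), 4.2), cell_size=1.0)
        zm = zonal_mean(surf, units)
        assert np.allclose(zm.to_numpy(), 4.2)
        assert list(zm.index) == list(units["unit_id"])

    def test_indicator_surface(self):
        units = lattice_units(2, 2, size=2.0)
        data = np.zeros((4, 4))
        data[0:2, 0:2] = 1.0  # exactly the first (south-west) unit
        zm = zonal_mean(Grid(data, cell_size=1.0), units)
        assert zm["u0_0"] == 1.0
        assert zm.drop("u0_0").eq(0.0).all()

    def test_matches_cell_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        data = rng.uniform(0, 30, size=(9, 9))
        units = lattice_units(3, 3, size=3.0)
        zm = zonal_mean(Grid(data, cell_size=1.0), units)
        for r in range(3):
            for c in range(3):
                oracle = data[3 * r : 3 * r + 3, 3 * c : 3 * c + 3].mean()
                assert zm[f"u{r}_{c}"] == pytest.approx(oracle, abs=1e-12)

    def test_relabeling_invariance(self, small_region):
        units, _, surfaces, truth = small_region
        zm1 = zonal_mean(truth.true_surface, units)
        shuffled = units.sample(frac=1.0, random_state=0).reset_index(drop=True)
        zm2 = zonal_mean(truth.true_surface, shuffled)
        assert zm1.sort_index().equals(zm2.sort_index())

    def test_too_small_unit_raises_with_name(self):
        units = lattice_units(1, 1, size=0.4)  # no cell centre inside
        surf = Grid(np.ones((4, 4)), cell_size=1.0)
        with pytest.raises(ValueError, match="u0_0"):
            zonal_mean(surf, units)


def test_coefficient_recovery_unbiased_over_seeds():
    """Mean bias of recovered coefficients tends to zero over noisy
    replicates (Monte-Carlo check of estimator unbiasedness)."""
    true = {"elevation": -0.002, "population": 1e-4}
    errs = {k: [] for k in true}
    for seed in range(100):
        cfg = RegionConfig(n_rows=4, n_cols=8, n_stations=24, seed=seed,
                           noise_sd=0.3, true_coefficients=dict(true),
                           surface_subdivision=3)
        _, stations, surfaces, _ = generate_region(cfg)
        X = build_buffers(stations, surfaces, radii=[cfg.true_radius])
        cols = [term_name(c, cfg.true_radius) for c in true]
        model = fit_terms(X, stations["pm25"].to_numpy(), cols)
        for c in cols:
            cov = c.split("@")[0]
            errs[cov].append(model.coefficients[c] - true[cov])
    for cov, e in errs.items():
        e = np.asarray(e)
        mc_se = e.std(ddof=1) / np.sqrt(len(e))
        assert abs(e.mean()) <= 4 * mc_se, cov
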