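"""Per-pixel regression: transforms, fitting (with an independent OLS oracle),
and bounded prediction."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from paleoemu.emulator import (ANNUAL, COEF_NAMES, fit_grid, fit_pixel,
                               inverse_transform, predict, transform_values)
from paleoemu.forcings import ForcingTable
from paleoemu.masks import LAND, LAND_ICE, OCEAN
from paleoemu.synthetic import make_snapshots, make_world


class TestTransforms:
    def test_anchor_points(self):
        assert transform_values([0.5], "logit")[0] == pytest.approx(0.0)
        assert transform_values([1.0], "log")[0] == pytest.approx(0.0)
        assert inverse_transform([0.0], "logit")[0] == pytest.approx(0.5)

    def test_round_trips(self, rng):
        p = rng.uniform(1e-6, 1 - 1e-6, 1000)
        assert np.allclose(inverse_transform(transform_values(p, "logit"), "logit"), p,
                           rtol=1e-10)
        q = rng.uniform(1e-3, 1e4, 1000)
        assert np.allclose(inverse_transform(transform_values(q, "log"), "log"), q,
                           rtol=1e-10)
        x = rng.normal(size=1000)
        assert np.array_equal(inverse_transform(transform_values(x, "identity"),
                                                "identity"), x)

    def test_inverse_bounded_for_extreme_inputs(self):
        # strictly inside (0, 1) wherever float64 can represent it; saturated
        # inputs land exactly on the bounds, never outside
        z = np.linspace(-36, 36, 101)
        cloud = inverse_transform(z, "logit")
        assert np.all((cloud > 0) & (cloud < 1))
        extreme = inverse_transform(np.array([-700.0, 700.0]), "logit")
        assert np.all((extreme >= 0) & (extreme <= 1))
        assert np.isfinite(extreme).all()
        prec = inverse_transform(np.array([-700.0, 0.0, 10.0]), "log")
        assert np.all(prec > 0)

    def test_out_of_domain_reported_with_context(self):
        with pytest.raises(ValueError, match="positive.*ocean prec"):
            transform_values([-1.0], "log", context="ocean prec")
        with pytest.raises(ValueError, match=r"\(0,1\)"):
            transform_values([1.5], "logit")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            transform_values([1.0], "sqrt")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-30, 30))
    def test_logistic_always_in_unit_interval(self, z):
        v = inverse_transform([z], "logit")[0]
        assert 0.0 < v < 1.0


def _make_design(rng, n=72, levels_pattern="mixed"):
    Z = rng.normal(size=(n, 4))
    if levels_pattern == "mixed":
        levels = rng.choice([OCEAN, LAND, LAND_ICE], size=n)
        # ensure all three occur
        levels[:3] = [OCEAN, LAND, LAND_ICE]
    elif levels_pattern == "ocean":
        levels = np.full(n, OCEAN)
    else:
        levels = np.full(n, LAND)
    return Z, levels


class TestFitPixel:
    def test_exact_recovery_without_noise(self, rng):
        Z, levels = _make_design(rng)
        beta = np.array([0.7, -0.3, 0.2, 1.1])
        off = {OCEAN: 0.0, LAND: 2.0, LAND_ICE: -4.0}
        y = 290.0 + Z @ beta + np.array([off[l] for l in levels])
        pm = fit_pixel(y, Z, levels)
        assert pm.ok
        assert np.allclose(pm.beta[:4], beta, atol=1e-10)
        assert pm.beta_surface(LAND) == pytest.approx(2.0, abs=1e-10)
        assert pm.beta_surface(LAND_ICE) == pytest.approx(-4.0, abs=1e-10)
        assert pm.beta_surface(OCEAN) == 0.0
        assert pm.r2 == pytest.approx(1.0)
        assert pm.rmse == pytest.approx(0.0, abs=1e-10)

    def test_matches_statsmodels_oracle(self, rng):
        # dual-route check: same design through an independent OLS implementation
        for _ in range(20):
            Z, levels = _make_design(rng, n=60)
            y = rng.normal(290, 3, 60) + Z @ rng.normal(size=4)
            pm = fit_pixel(y, Z, levels)

            X = np.column_stack([
                np.ones(60), Z,
                (levels == LAND).astype(float), (levels == LAND_ICE).astype(float),
            ])
            res = sm.OLS(y - y.mean(), X).fit()
            assert np.allclose(pm.beta[:4], res.params[1:5], atol=1e-8)
            assert pm.beta_surface(LAND) == pytest.approx(res.params[5], abs=1e-8)
            assert pm.beta_surface(LAND_ICE) == pytest.approx(res.params[6], abs=1e-8)
            assert np.allclose(pm.pvalues[:4], res.pvalues[1:5], atol=1e-8)
            assert np.allclose(pm.stderr[:4], res.bse[1:5], atol=1e-8)
            assert pm.rmse == pytest.approx(np.sqrt(np.mean(res.resid ** 2)), abs=1e-8)

    def test_constant_series_gives_null_fit(self, rng):
        Z, levels = _make_design(rng, levels_pattern="ocean")
        pm = fit_pixel(np.full(72, 280.0), Z, levels)
        assert np.allclose(pm.beta[:4], 0, atol=1e-10)
        assert pm.r2 == 0.0
        assert pm.rmse == pytest.approx(0.0, abs=1e-12)

    def test_single_level_pixel_leaves_dummies_unset(self, rng):
        Z, levels = _make_design(rng, levels_pattern="ocean")
        pm = fit_pixel(Z @ np.ones(4) + 5.0, Z, levels)
        assert pm.ok
        assert np.isnan(pm.beta[4]) and np.isnan(pm.beta[5])

    def test_log_scale_series_recovered(self, rng):
        # regression inputs live on the transformed scale: a multiplicative
        # natural-scale response is exactly linear after the log transform
        Z, levels = _make_design(rng, levels_pattern="ocean")
        beta = np.array([0.1, 0.05, -0.04, 0.2])
        y_natural = np.exp(6.0 + Z @ beta)
        pm = fit_pixel(transform_values(y_natural, "log"), Z, levels,
                       transform="log")
        assert np.allclose(pm.beta[:4], beta, atol=1e-10)
        assert pm.mean_term == pytest.approx(6.0, abs=1e-8)

    def test_rank_deficient_design_flagged_not_raised(self, rng):
        Z = np.zeros((20, 4))
        Z[:, 0] = rng.normal(size=20)
        Z[:, 1] = Z[:, 0]  # collinear
        pm = fit_pixel(rng.normal(size=20), Z, np.full(20, OCEAN))
        assert not pm.ok and pm.skip_reason


class TestFitGrid:
    def test_noiseless_world_recovered_exactly(self, world_clean, model_clean):
        for var, vm in model_clean.variables.items():
            tb = world_clean.true_beta[var]
            fit = vm.fitted
            assert fit.any()
            err = np.abs(vm.beta[..., :4] - tb[..., :4])
            assert np.nanmax(err[fit]) < 1e-8
            assert np.nanmax(np.abs(vm.r2[fit] - 1.0)) < 1e-10

    def test_grid_and_pixel_routes_agree(self, world_clean, snaps_clean, model_clean):
        # the batched grid fit must equal an individual pixel fit
        Z = world_clean.stats.apply(world_clean.forcings.block())
        i, j, m = 4, 6, ANNUAL
        levels = snaps_clean.masks.codes[:, i, j]
        y = snaps_clean.data["temperature"][:, m, i, j]
        pm = fit_pixel(y, Z, levels)
        vm = model_clean.variables["temperature"]
        assert vm.mean_term[m, i, j] == pytest.approx(pm.mean_term, abs=1e-10)
        got, want = vm.beta[m, i, j], pm.beta
        assert np.allclose(np.nan_to_num(got), np.nan_to_num(want), atol=1e-10)

    def test_pole_rows_never_fit(self):
        w = make_world(seed=1, nlon=12, nlat=9, noise_sd=0.0, include_poles=True)
        snaps = make_snapshots(w, noise=False)
        model = fit_grid(snaps, snaps.epochs, w.forcings, stats=w.stats)
        for vm in model.variables.values():
            assert not vm.fitted[:, 0, :].any()
            assert not vm.fitted[:, -1, :].any()
            assert vm.fitted[:, 1:-1, :].all()

    def test_missing_training_epoch_rejected(self, world_clean, snaps_clean):
        with pytest.raises((KeyError, ValueError)):
            fit_grid(snaps_clean, np.array([999]), world_clean.forcings)


class TestPredict:
    def test_reproduces_training_epochs_without_noise(self, world_clean, snaps_clean,
                                                      model_clean):
        for var in ("temperature", "precipitation", "cloud"):
            fld = predict(model_clean, world_clean.forcings,
                          snaps_clean.masks, var, month=ANNUAL)
            assert np.allclose(fld.values, snaps_clean.data[var][:, ANNUAL], atol=1e-8)

    def test_held_out_rmse_matches_noise_level(self, world_noisy, snaps_noisy):
        # fit on even epochs, test on odd: residual scatter ~ the injected sd
        idx = np.arange(snaps_noisy.epochs.size)
        train_e = snaps_noisy.epochs[idx % 2 == 0]
        test_i = idx[idx % 2 == 1]
        model = fit_grid(snaps_noisy, train_e, world_noisy.forcings,
                         stats=world_noisy.stats)
        fld = predict(model, world_noisy.forcings.subset(test_i),
                      snaps_noisy.masks.subset(test_i), "temperature", month=ANNUAL)
        err = fld.values - snaps_noisy.data["temperature"][test_i, ANNUAL]
        # held-out error includes fitted-parameter uncertainty on top of the
        # injected sd, so the scatter lands a little above 0.2
        rmse = np.sqrt(np.nanmean(err ** 2))
        assert 0.2 * 0.8 < rmse < 0.2 * 1.35

    def test_co2_sensitivity_sign(self, world_clean, model_clean):
        # raising only CO2 moves a pixel in the direction of its CO2 coefficient
        vm = model_clean.variables["temperature"]
        i, j = 5, 3
        b4 = vm.beta[ANNUAL, i, j, 3]
        assert np.isfinite(b4) and b4 != 0
        base = world_clean.forcings.block()[0]
        epochs = np.array([1, 0])
        t = ForcingTable(epochs=epochs,
                         obliquity=[base[0]] * 2, precession_i=[base[1]] * 2,
                         precession_ii=[base[2]] * 2, co2=[base[3], base[3] + 50])
        masks = world_clean.masks_at([1, 0])
        # hold the surface type fixed so only CO2 differs
        masks.codes[1] = masks.codes[0]
        fld = predict(model_clean, t, masks, "temperature", month=ANNUAL)
        diff = fld.values[1, i, j] - fld.values[0, i, j]
        assert np.sign(diff) == np.sign(b4)

    def test_bounded_variables_stay_bounded(self, world_clean, model_clean, rng):
        n = 50
        t = ForcingTable(
            epochs=np.arange(n, 0, -1),
            co2=rng.uniform(150, 400, n),
            obliquity=rng.uniform(21, 26, n),
            precession_i=rng.uniform(-0.1, 0.1, n),
            precession_ii=rng.uniform(-0.1, 0.1, n),
        )
        codes = rng.choice([OCEAN, LAND, LAND_ICE], size=(n,) + world_clean.grid.shape)
        from paleoemu.masks import SurfaceTypeGrid
        masks = SurfaceTypeGrid(grid=world_clean.grid, epochs=t.epochs, codes=codes)
        prec = predict(model_clean, t, masks, "precipitation", month=3)
        cloud = predict(model_clean, t, masks, "cloud", month=3)
        assert np.all(prec.values[np.isfinite(prec.values)] > 0)
        fin = cloud.values[np.isfinite(cloud.values)]
        assert np.all((fin > 0) & (fin < 1))

    def test_float32_output_dtype(self, world_clean, model_clean):
        fld = predict(model_clean, world_clean.forcings,
                      world_clean.masks_at(world_clean.forcings.epochs),
                      "temperature", month=ANNUAL, dtype=np.float32)
        assert fld.values.dtype == np.float32

    def test_unknown_variable_rejected(self, world_clean, model_clean):
        with pytest.raises((KeyError, ValueError)):
            predict(model_clean, world_clean.forcings,
                    world_clean.masks_at(world_clean.forcings.epochs),
                    "salinity", month=ANNUAL)
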