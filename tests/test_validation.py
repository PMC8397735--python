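"""Validation machinery: goodness maps, spatial covariance, proxy matching."""

import numpy as np
import pytest

from paleoemu.emulator import ANNUAL, fit_grid
from paleoemu.grid import ClimateField, Grid
from paleoemu.synthetic import make_proxies, make_snapshots, make_world, truth_field
from paleoemu.validation import (ProxyRecord, covariance_summary, goodness_maps,
                                 proxy_correlation, proxy_table, read_proxies,
                                 spatial_covariance)

G = Grid.global_regular(8, 6)


def _split(snaps):
    idx = np.arange(snaps.epochs.size)
    return idx[idx % 5 != 0], idx[idx % 5 == 0]


class TestGoodnessMaps:
    def test_noiseless_fit_is_perfect(self, world_clean, snaps_clean):
        tr, te = _split(snaps_clean)
        model = fit_grid(snaps_clean, snaps_clean.epochs[tr], world_clean.forcings,
                         stats=world_clean.stats)
        gm = goodness_maps(model, snaps_clean.subset(te), world_clean.forcings)
        for var in gm.r2:
            r2 = gm.r2[var][np.isfinite(gm.r2[var])]
            assert np.allclose(r2, 1.0, atol=1e-8)
            rmse = gm.rmse[var][np.isfinite(gm.rmse[var])]
            assert np.nanmax(rmse / np.maximum(1.0, rmse)) < 1e-6

    def test_held_out_rmse_tracks_noise_sd(self, world_noisy, snaps_noisy):
        tr, te = _split(snaps_noisy)
        model = fit_grid(snaps_noisy, snaps_noisy.epochs[tr], world_noisy.forcings,
                         stats=world_noisy.stats)
        gm = goodness_maps(model, snaps_noisy.subset(te), world_noisy.forcings)
        # temperature is fit on the identity scale, so natural-scale RMSE on
        # held-out epochs estimates the injected sd 0.2
        med = np.nanmedian(gm.rmse["temperature"])
        assert 0.2 * 0.7 < med < 0.2 * 1.4

    def test_overlapping_train_test_rejected(self, world_clean, snaps_clean,
                                             model_clean):
        with pytest.raises(ValueError, match="overlap"):
            goodness_maps(model_clean, snaps_clean, world_clean.forcings)


class TestSpatialCovariance:
    def test_matches_two_loop_oracle(self, rng):
        stack = rng.normal(size=(10, 1, 5))  # 10 epochs, 5 pixels
        got = spatial_covariance(stack)
        flat = stack.reshape(10, 5)
        for a in range(5):
            for b in range(5):
                xa, xb = flat[:, a], flat[:, b]
                want = np.sum((xa - xa.mean()) * (xb - xb.mean())) / 9.0
                assert got[a, b] == pytest.approx(want, abs=1e-12)

    def test_duplicated_pixels_share_rows(self, rng):
        series = rng.normal(size=10)
        stack = np.stack([np.tile(series[k], (1, 3)) for k in range(10)])
        c = spatial_covariance(stack)
        assert np.allclose(c, c[0, 0])

    def test_constant_series_give_zero_matrix(self):
        stack = np.full((6, 2, 2), 4.2)
        assert np.allclose(spatial_covariance(stack), 0.0)

    def test_dimension_equals_unmasked_pixel_count(self, rng):
        stack = rng.normal(size=(8, 4, 5))
        valid = rng.random((4, 5)) < 0.6
        c = spatial_covariance(stack, valid=valid)
        assert c.shape == (valid.sum(), valid.sum())

    def test_nan_pixels_dropped_automatically(self, rng):
        stack = rng.normal(size=(8, 3, 3))
        stack[:, 0, 0] = np.nan
        assert spatial_covariance(stack).shape == (8,) * 0 + (8, 8)

    def test_positive_semidefinite(self, rng):
        c = spatial_covariance(rng.normal(size=(30, 4, 4)))
        ev = np.linalg.eigvalsh(c)
        assert ev.min() > -1e-10

    def test_single_epoch_rejected(self, rng):
        with pytest.raises(ValueError, match="2 epochs"):
            spatial_covariance(rng.normal(size=(1, 3, 3)))


class TestCovarianceSummary:
    def test_emulated_structure_close_to_truth(self, world_clean, model_clean):
        from paleoemu.emulator import predict
        truth = truth_field(world_clean, "temperature", ANNUAL)
        emu = predict(model_clean, world_clean.forcings,
                      world_clean.masks_at(world_clean.forcings.epochs),
                      "temperature", month=ANNUAL)
        cs = covariance_summary(truth, emu)
        assert cs.diff_norm < 1e-6 * max(cs.truth_norm, 1.0)
        assert cs.truth.shape[0] == cs.pixel_index.size

    def test_grid_mismatch_rejected(self, rng):
        a = ClimateField(name="t", units="K", grid=G, times=[1, 0],
                         values=rng.normal(size=(2,) + G.shape))
        other = Grid.global_regular(4, 3)
        b = ClimateField(name="t", units="K", grid=other, times=[1, 0],
                         values=rng.normal(size=(2,) + other.shape))
        with pytest.raises(ValueError, match="grid"):
            covariance_summary(a, b)


def _series_field(series, i=2, j=3, times=None):
    times = np.arange(len(series), dtype=float)[::-1] if times is None else times
    vals = np.zeros((len(series),) + G.shape)
    vals[:, i, j] = series
    return ClimateField(name="temperature", units="K", grid=G,
                        times=times, values=vals)


class TestProxyCorrelation:
    def test_perfect_proxy_gives_unit_correlation(self, rng):
        series = rng.normal(280, 3, 50)
        fld = _series_field(series)
        p = ProxyRecord(name="A", lon=G.lon[3], lat=G.lat[2],
                        ages=fld.times, values=series)
        r, n = proxy_correlation(fld, p)
        assert r == pytest.approx(1.0)
        assert n == 50

    def test_sign_flip_gives_minus_one(self, rng):
        series = rng.normal(280, 3, 50)
        fld = _series_field(series)
        p = ProxyRecord(name="A", lon=G.lon[3], lat=G.lat[2],
                        ages=fld.times, values=-series)
        r, _ = proxy_correlation(fld, p)
        assert r == pytest.approx(-1.0)

    def test_affine_rescaling_leaves_correlation_unchanged(self, rng):
        series = rng.normal(280, 3, 40)
        fld = _series_field(series)
        noisy = series + rng.normal(0, 1, 40)
        p1 = ProxyRecord(name="A", lon=G.lon[3], lat=G.lat[2],
                         ages=fld.times, values=noisy)
        p2 = ProxyRecord(name="B", lon=G.lon[3], lat=G.lat[2],
                         ages=fld.times, values=3.7 * noisy - 100.0)
        assert proxy_correlation(fld, p1)[0] == pytest.approx(
            proxy_correlation(fld, p2)[0], abs=1e-12)

    def test_nearest_epoch_matching_within_half_ka(self, rng):
        series = rng.normal(280, 3, 30)
        fld = _series_field(series)
        # ages offset by 0.3 ka still match; one far-off age is dropped
        ages = fld.times[:10] + 0.3
        vals = series[:10]
        far_age = fld.times[0] + 0.8  # beyond the series span by > 0.5 ka
        p = ProxyRecord(name="A", lon=G.lon[3], lat=G.lat[2],
                        ages=np.append(ages, far_age),
                        values=np.append(vals, 999.0))
        r, n = proxy_correlation(fld, p)
        assert n == 10
        assert r == pytest.approx(1.0)

    def test_spearman_option_monotone_invariance(self, rng):
        series = rng.uniform(1, 10, 40)
        fld = _series_field(series)
        p = ProxyRecord(name="A", lon=G.lon[3], lat=G.lat[2],
                        ages=fld.times, values=np.exp(series))  # monotone map
        r, _ = proxy_correlation(fld, p, method="spearman")
        assert r == pytest.approx(1.0)

    def test_too_few_matches_rejected(self, rng):
        fld = _series_field(rng.normal(size=20))
        p = ProxyRecord(name="A", lon=G.lon[3], lat=G.lat[2],
                        ages=[0.0, 1.0], values=[1.0, 2.0])
        with pytest.raises(ValueError, match=">= 3"):
            proxy_correlation(fld, p)

    def test_masked_site_error_names_nearest_valid_cell(self, rng):
        vals = np.full((10,) + G.shape, np.nan)
        vals[:, 4, 4] = rng.normal(size=10)
        fld = ClimateField(name="temperature", units="K", grid=G,
                           times=np.arange(10.0)[::-1], values=vals)
        p = ProxyRecord(name="A", lon=G.lon[0], lat=G.lat[0],
                        ages=np.arange(5.0), values=np.arange(5.0))
        with pytest.raises(ValueError, match="masked cell.*nearest valid"):
            proxy_correlation(fld, p)

    def test_age_bounds_enforced(self):
        with pytest.raises(ValueError, match="0-800"):
            ProxyRecord(name="A", lon=0, lat=0, ages=[900.0], values=[1.0])

    def test_synthetic_proxies_at_finite_snr(self, world_clean):
        # snr=2 white noise bounds the attainable correlation near
        # 1/sqrt(1 + 1/snr^2) ~ 0.894
        from paleoemu.emulator import predict
        proxies = make_proxies(world_clean, n=25, snr=2.0, seed=0)
        truth = truth_field(world_clean, "temperature", ANNUAL,
                            epochs=world_clean.forcings_extended.epochs)
        rs = [proxy_correlation(truth, p)[0] for p in proxies]
        assert all(0.6 < r < 0.95 for r in rs)

    def test_proxy_table_shape_and_columns(self, world_clean):
        proxies = make_proxies(world_clean, n=5, snr=5.0, seed=1)
        truth = truth_field(world_clean, "temperature", ANNUAL,
                            epochs=world_clean.forcings_extended.epochs)
        tab = proxy_table(truth, proxies)
        assert list(tab.columns) == ["core", "lon", "lat", "corr_coeff",
                                     "n_matched", "type"]
        assert len(tab) == 5
        assert tab["corr_coeff"].min() > 0.9


class TestReadProxies:
    def test_round_trip_via_csv(self, tmp_path, world_clean):
        import pandas as pd
        proxies = make_proxies(world_clean, n=3, snr=3.0, seed=2)
        rows = [(p.name, p.lon, p.lat, a, v, p.kind)
                for p in proxies for a, v in zip(p.ages, p.values)]
        f = tmp_path / "proxies.csv"
        pd.DataFrame(rows, columns=["name", "lon", "lat", "age_ka", "value",
                                    "type"]).to_csv(f, index=False)
        back = read_proxies(f)
        assert [p.name for p in back] == [p.name for p in proxies]
        for a, b in zip(back, proxies):
            assert np.allclose(a.ages, b.ages)
            assert np.allclose(a.values, b.values)

    def test_missing_columns_reported(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("name,lon\nA,0\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_proxies(f)
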