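"""IVIM forward model, preprocessing, and the two voxelwise fitters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepamap import (BValueScheme, DWISeries, IVIMLeastSquares, IVIMBayesian,
                     McmcConfig, fit_ivim_bayes, fit_ivim_lsq,
                     global_liver_summary, ivim_signal,
                     median_filter_slicewise, resample_inplane, simulate_dwi)
from hepamap.ivim import (IVIMParams, TABLE_B_VALUES, TABLE_AVERAGES,
                          _forward, si_to_report, report_to_si)

B = np.array(TABLE_B_VALUES)


def _signals(n, rng, d_slow_rng=(0.4e-3, 2.5e-3), d_fast_rng=(30e-3, 250e-3),
             f_p_rng=(0.05, 0.5), s0=1000.0, noise=0.0, averages=None):
    d_slow = np.exp(rng.uniform(*np.log(d_slow_rng), n))
    d_fast = np.exp(rng.uniform(*np.log(d_fast_rng), n))
    f_p = rng.uniform(*f_p_rng, n)
    X = _forward(B, d_slow, d_fast, f_p, np.full(n, s0))
    if noise > 0:
        scale = noise if averages is None \
            else noise / np.sqrt(np.asarray(averages))
        X = X + scale * rng.standard_normal(X.shape)
    return X, (d_slow, d_fast, f_p)


class TestForwardModel:
    def test_normalized_at_b_zero(self):
        assert ivim_signal((1e-3, 50e-3, 0.3), 0.0) == 1.0

    def test_monoexponential_limit(self):
        np.testing.assert_allclose(ivim_signal((1.0e-3, 50e-3, 0.0), 1000.0),
                                   np.exp(-1.0), rtol=1e-12)

    def test_direct_evaluation(self):
        np.testing.assert_allclose(ivim_signal((1.0e-3, 50e-3, 0.3), 100.0),
                                   0.3 * np.exp(-5) + 0.7 * np.exp(-0.1),
                                   rtol=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ivim_signal((1e-3, 0.5e-3, 0.3), 10.0)  # d_fast < d_slow
        with pytest.raises(ValueError):
            ivim_signal((1e-3, 50e-3, 1.5), 10.0)
        with pytest.raises(ValueError):
            IVIMParams(-1e-3, 50e-3, 0.3)

    @settings(deadline=None, max_examples=50)
    @given(d_slow=st.floats(2e-4, 2.9e-3), ratio=st.floats(1.5, 100.0),
           f_p=st.floats(0.0, 1.0))
    def test_strictly_decreasing_in_b(self, d_slow, ratio, f_p):
        vals = ivim_signal((d_slow, d_slow * ratio, f_p), B)
        assert np.all(np.diff(vals) < 0)

    def test_unit_round_trip(self):
        for kind, v in (("d_slow", 1.02e-3), ("d_fast", 73.5e-3),
                        ("f_p", 0.292)):
            np.testing.assert_allclose(
                report_to_si(si_to_report(v, kind), kind), v, rtol=1e-15)


class TestMedianFilter:
    def _series(self, vol):
        scheme = BValueScheme(b_values=(0.0, 100.0), averages=(1, 1))
        sig = np.stack([vol, vol], axis=-1)
        return DWISeries(sig, scheme)

    def test_constant_unchanged(self):
        out = median_filter_slicewise(self._series(np.full((8, 8, 3), 7.0)))
        np.testing.assert_array_equal(out.signal, 7.0)

    def test_impulse_rejected(self):
        vol = np.zeros((8, 8, 3))
        vol[4, 4, 1] = 100.0
        out = median_filter_slicewise(self._series(vol))
        assert out.signal.max() == 0.0

    def test_matches_sliding_window_oracle(self, rng):
        vol = rng.random((8, 8, 1))
        out = median_filter_slicewise(self._series(vol)).signal[..., 0]
        sl = vol[:, :, 0]
        for i in range(1, 7):
            for j in range(1, 7):
                window = sl[i - 1:i + 2, j - 1:j + 2]
                assert out[i, j, 0] == np.median(window)


class TestResample:
    def test_constant_preserved(self):
        out = resample_inplane(np.full((340, 218), 3.5), (128, 128),
                               "down_for_fit")
        assert out.shape == (128, 128)
        np.testing.assert_allclose(out, 3.5, rtol=1e-7)

    def test_identity_when_same_shape(self, rng):
        x = rng.random((32, 32, 2))
        np.testing.assert_array_equal(
            resample_inplane(x, (32, 32), "up_for_maps"), x)

    def test_roundtrip_smooth_gradient(self):
        x, y = np.meshgrid(np.linspace(0, 1, 340), np.linspace(0, 1, 218),
                           indexing="ij")
        field = np.sin(2 * np.pi * x) + y
        down = resample_inplane(field, (128, 128), "down_for_fit")
        up = resample_inplane(down, (340, 218), "up_for_maps")
        rms = np.sqrt(np.mean((up - field) ** 2))
        assert rms < 0.02 * (field.max() - field.min())

    def test_too_small_target_rejected(self):
        with pytest.raises(ValueError):
            resample_inplane(np.zeros((16, 16)), (1, 8), "up_for_maps")


class TestLeastSquares:
    def test_noise_free_recovery_example(self):
        X = _forward(B, np.array([1.0e-3]), np.array([50e-3]),
                     np.array([0.25]), np.array([1000.0]))
        est = IVIMLeastSquares().fit(X)
        np.testing.assert_allclose(est.d_slow_[0], 1.0e-3, rtol=0.01)
        np.testing.assert_allclose(est.d_fast_[0], 50e-3, rtol=0.01)
        np.testing.assert_allclose(est.f_p_[0], 0.25, rtol=0.01)

    def test_monoexponential_input_gives_zero_f_p(self):
        X = 1000.0 * np.exp(-B * 1.0e-3)[None, :]
        est = IVIMLeastSquares().fit(X)
        assert est.f_p_[0] < 0.01

    def test_fast_component_noisier_than_slow(self, rng):
        # the well-known instability of the pseudo-diffusion estimate
        n = 500
        d_slow = np.full(n, 0.96e-3)
        d_fast = np.full(n, 36.4e-3)
        f_p = np.full(n, 0.216)
        X = _forward(B, d_slow, d_fast, f_p, np.full(n, 1000.0))
        X = X + (1000.0 / 30) * rng.standard_normal(X.shape)
        est = IVIMLeastSquares().fit(X)
        ok = np.isfinite(est.d_fast_)
        rel_rmse_fast = np.sqrt(np.mean(
            ((est.d_fast_[ok] - d_fast[ok]) / d_fast[ok]) ** 2))
        rel_rmse_slow = np.sqrt(np.mean(
            ((est.d_slow_[ok] - d_slow[ok]) / d_slow[ok]) ** 2))
        assert rel_rmse_fast > rel_rmse_slow

    def test_zero_voxel_flagged_nan(self):
        X = np.vstack([np.zeros(B.size),
                       _forward(B, np.array([1e-3]), np.array([50e-3]),
                                np.array([0.2]), np.array([1000.0]))[0]])
        est = IVIMLeastSquares().fit(X)
        assert np.isnan(est.d_slow_[0]) and est.n_failed_ == 1
        assert np.isfinite(est.d_slow_[1])

    def test_too_few_b_values_rejected(self):
        with pytest.raises(ValueError):
            IVIMLeastSquares(b_values=(0.0, 200.0, 400.0)).fit(
                np.ones((1, 3)))


class TestBayesian:
    def test_noise_free_recovery_within_2_percent(self, rng):
        X, (d_slow, d_fast, f_p) = _signals(30, rng)
        est = IVIMBayesian(n_iterations=3000, n_burn_in=1500, seed=1).fit(X)
        for name, tru in (("d_slow_", d_slow), ("d_fast_", d_fast),
                          ("f_p_", f_p)):
            rel = np.abs(getattr(est, name) - tru) / tru
            assert rel.max() < 0.02

    def test_seeded_determinism_bitwise(self, rng):
        X, _ = _signals(10, rng, noise=50.0)
        a = IVIMBayesian(n_iterations=500, n_burn_in=250, seed=9).fit(X)
        b = IVIMBayesian(n_iterations=500, n_burn_in=250, seed=9).fit(X)
        np.testing.assert_array_equal(a.d_fast_, b.d_fast_)
        np.testing.assert_array_equal(a.posterior_.ci_low["f_p"],
                                      b.posterior_.ci_low["f_p"])

    def test_prior_support_excluding_truth_pins_at_bound(self, rng):
        # truth d_slow = 2.0e-3 but prior support capped at 1.5e-3
        X, _ = _signals(5, rng, d_slow_rng=(2.0e-3, 2.0e-3),
                        d_fast_rng=(80e-3, 80e-3), f_p_rng=(0.3, 0.3))
        bounds = {"d_slow": (0.1e-3, 1.5e-3), "d_fast": (3e-3, 300e-3),
                  "f_p": (0.0, 0.6)}
        est = IVIMBayesian(n_iterations=1500, n_burn_in=750, seed=2,
                           bounds=bounds).fit(X)
        # posterior mass piles against the support bound, and the voxels
        # are flagged as pinned
        assert (est.d_slow_ <= 1.5e-3).all()
        assert (est.d_slow_ > 0.9 * 1.5e-3).all()
        assert est.at_bound_.all() and est.flagged_.all()

    def test_posterior_interval_orders(self, rng):
        X, _ = _signals(20, rng, noise=50.0)
        est = IVIMBayesian(n_iterations=1000, n_burn_in=500, seed=3).fit(X)
        post = est.posterior_
        for k in ("d_slow", "d_fast", "f_p"):
            assert (post.ci_low[k] <= post.median[k] + 1e-15).all()
            assert (post.median[k] <= post.ci_high[k] + 1e-15).all()
        assert ((post.acceptance_rate >= 0)
                & (post.acceptance_rate <= 1)).all()

    def test_shrinks_fast_map_noise_vs_lsq(self, rng):
        X, (d_slow, d_fast, f_p) = _signals(
            200, rng, d_slow_rng=(1.02e-3, 1.02e-3),
            d_fast_rng=(73.5e-3, 73.5e-3), f_p_rng=(0.292, 0.292),
            noise=50.0, averages=TABLE_AVERAGES)
        lsq = IVIMLeastSquares().fit(X)
        bay = IVIMBayesian(n_iterations=2000, n_burn_in=1000, seed=4).fit(X)
        assert np.nanstd(bay.d_fast_) < np.nanstd(lsq.d_fast_)


class TestMapLevel:
    def test_fit_maps_nan_outside_mask(self, healthy_truth):
        series = simulate_dwi(healthy_truth, noise_sd=0.0)
        maps = fit_ivim_lsq(series, healthy_truth.liver_mask)
        assert np.isnan(maps.d_slow[~healthy_truth.liver_mask]).all()
        assert np.isfinite(maps.d_slow[healthy_truth.liver_mask]).all()

    def test_bayes_map_wrapper_matches_estimator(self, healthy_truth):
        series = simulate_dwi(healthy_truth, noise_sd=10.0, seed=5)
        cfg = McmcConfig(n_iterations=400, n_burn_in=200, seed=6)
        maps, post = fit_ivim_bayes(series, healthy_truth.liver_mask, cfg)
        m = healthy_truth.liver_mask
        est = IVIMBayesian.from_config(series.scheme.b_values, cfg).fit(
            series.signal[m, :])
        np.testing.assert_array_equal(maps.d_fast[m], est.d_fast_)

    def test_empty_mask_rejected(self, healthy_truth):
        series = simulate_dwi(healthy_truth, noise_sd=0.0)
        with pytest.raises(ValueError):
            fit_ivim_lsq(series, np.zeros(healthy_truth.shape, bool))


class TestGlobalSummary:
    def _maps(self, values):
        from hepamap.ivim import IVIMMaps
        v = np.asarray(values, dtype=float).reshape(-1, 1, 1)
        mask = np.ones(v.shape, bool)
        return IVIMMaps(d_slow=v * 1e-3, d_fast=v * 1e-3, f_p=v / 100,
                        s0=v, mask=mask)

    def test_constant_map(self):
        s = global_liver_summary(self._maps([2.0, 2.0, 2.0]))
        assert s["d_slow"]["mean"] == s["d_slow"]["median"] == 2.0
        assert s["d_slow"]["sd"] == 0.0

    def test_two_voxel_hand_arithmetic(self):
        s = global_liver_summary(self._maps([1.0, 3.0]))
        assert s["d_slow"]["mean"] == 2.0
        assert s["d_slow"]["median"] == 2.0
        np.testing.assert_allclose(s["d_slow"]["sd"], np.sqrt(2.0))

    def test_nan_voxels_excluded_and_counted(self):
        maps = self._maps([1.0, 3.0, 5.0])
        maps.d_slow[2, 0, 0] = np.nan
        s = global_liver_summary(maps)
        assert s["d_slow"]["n_excluded"] == 1
        assert s["d_slow"]["mean"] == 2.0
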