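"""Tests for the spatio-temporal kernels and exact GP posterior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tvbopt import (
    GPHyperparams,
    SampleRecord,
    TimeVaryingGPRegressor,
    gp_posterior,
    half_life_to_epsilon,
    half_life_weight,
    spatial_kernel,
    spatiotemporal_kernel,
    temporal_kernel,
)

KINDS = ("static", "forgetting", "periodic", "forgetting_periodic")


def _random_hp(rng, kind=None):
    return GPHyperparams(
        l_x=rng.uniform(0.3, 3.0),
        T_x=2 * np.pi,
        epsilon=rng.uniform(0.0, 0.9),
        T_t=rng.uniform(3.0, 50.0),
        l_tp=rng.uniform(0.3, 3.0),
        sigma_n2=rng.uniform(1e-4, 0.1),
        kernel_kind=kind or KINDS[rng.integers(len(KINDS))],
        window=None,
    )


class TestKernels:
    def test_spatial_identity_and_value(self):
        hp = GPHyperparams(l_x=1.0)
        assert spatial_kernel(0.4, 0.4, hp) == pytest.approx(1.0)
        # half a period apart with unit lengthscale -> exp(-2)
        assert spatial_kernel(0.0, hp.T_x / 2, hp) == pytest.approx(np.exp(-2), abs=1e-6)
        assert spatial_kernel(0.0, hp.T_x / 2, hp) == pytest.approx(0.13534, abs=1e-5)

    @given(x=st.floats(-10, 10), x2=st.floats(-10, 10))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_spatial_periodicity_and_symmetry(self, x, x2):
        hp = GPHyperparams(l_x=0.7)
        assert spatial_kernel(x + hp.T_x, x2, hp) == pytest.approx(spatial_kernel(x, x2, hp))
        assert spatial_kernel(x, x2, hp) == pytest.approx(spatial_kernel(x2, x, hp))

    @pytest.mark.parametrize("kind", KINDS)
    def test_temporal_identity(self, kind):
        hp = GPHyperparams(kernel_kind=kind, epsilon=0.3)
        assert temporal_kernel(17, 17, hp) == pytest.approx(1.0)

    def test_forgetting_half_power(self):
        hp = GPHyperparams(kernel_kind="forgetting", epsilon=0.5)
        assert temporal_kernel(0, 2, hp) == pytest.approx(0.5)

    def test_periodic_full_period_recurrence(self):
        hp = GPHyperparams(kernel_kind="periodic", T_t=24.0)
        assert temporal_kernel(3, 3 + 24, hp) == pytest.approx(1.0)

    def test_forgetting_zero_reduces_to_static(self):
        hp0 = GPHyperparams(kernel_kind="forgetting", epsilon=0.0)
        lags = np.arange(40.0)
        assert np.allclose(temporal_kernel(0.0, lags, hp0), 1.0)

    def test_product_form_decomposes(self):
        # forgetting-periodic kernel equals the elementwise product of its parts
        from dataclasses import replace

        rng = np.random.default_rng(0)
        hp = _random_hp(rng, "forgetting_periodic")
        hp_f = replace(hp, kernel_kind="forgetting")
        hp_p = replace(hp, kernel_kind="periodic")
        t = rng.uniform(0, 200, size=(30, 1))
        combined = temporal_kernel(t, t.T, hp)
        assert np.allclose(
            combined, temporal_kernel(t, t.T, hp_f) * temporal_kernel(t, t.T, hp_p), atol=1e-12
        )

    def test_spatiotemporal_is_product(self):
        hp = GPHyperparams(kernel_kind="forgetting", epsilon=0.5, l_x=1.0)
        a = SampleRecord(x=0.0, t=0)
        b = SampleRecord(x=hp.T_x / 2, t=2)
        assert spatiotemporal_kernel(a, a, hp) == pytest.approx(1.0)
        assert spatiotemporal_kernel(a, b, hp) == pytest.approx(0.06767, abs=1e-5)

    def test_static_spatiotemporal_equals_spatial(self):
        hp = GPHyperparams(kernel_kind="static", l_x=0.8)
        a, b = SampleRecord(0.3, 0), SampleRecord(-1.2, 57)
        assert spatiotemporal_kernel(a, b, hp) == spatial_kernel(a.x, b.x, hp)

    @pytest.mark.parametrize("kind", KINDS)
    def test_gram_matrices_psd_and_bounded(self, kind):
        rng = np.random.default_rng(99)
        for _ in range(50):
            hp = _random_hp(rng, kind)
            n = rng.integers(2, 15)
            x = rng.uniform(-np.pi, np.pi, n)
            t = np.sort(rng.integers(0, 200, n)).astype(float)
            K = spatial_kernel(x[:, None], x[None, :], hp) * temporal_kernel(
                t[:, None], t[None, :], hp
            )
            assert np.allclose(K, K.T)
            assert np.all(K > 0.0) and np.all(K <= 1.0 + 1e-12)
            assert np.linalg.eigvalsh(K).min() >= -1e-10


class TestHalfLife:
    def test_mapping_and_weight(self):
        assert half_life_to_epsilon(100) == pytest.approx(np.log(2) / 100)
        assert half_life_to_epsilon(100) == pytest.approx(0.0069315, abs=1e-6)
        assert half_life_weight(100, 100) == 0.5
        assert half_life_weight(0, 100) == 1.0
        assert half_life_weight(200, 100) == pytest.approx(0.25)

    def test_large_half_life_limit(self):
        assert half_life_to_epsilon(1e9) < 1e-8

    def test_reported_operating_point(self):
        # eps = 0.22 corresponds to a half-life of ln2/0.22 = 3.15 samples
        assert np.log(2) / 0.22 == pytest.approx(3.15, abs=0.005)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            half_life_to_epsilon(0)
        with pytest.raises(ValueError):
            half_life_weight(-1, 10)


def _oracle_posterior(xs, ts, ys, qx, qt, hp):
    """Explicit-inverse posterior built term by term (independent oracle)."""
    n = len(xs)
    K = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = spatiotemporal_kernel((xs[i], ts[i]), (xs[j], ts[j]), hp)
    Kinv = np.linalg.inv(K + hp.sigma_n2 * np.eye(n))
    mu = np.empty(len(qx))
    var = np.empty(len(qx))
    for q in range(len(qx)):
        k_star = np.array(
            [spatiotemporal_kernel((qx[q], qt[q]), (xs[j], ts[j]), hp) for j in range(n)]
        )
        mu[q] = k_star @ Kinv @ ys
        var[q] = spatiotemporal_kernel((qx[q], qt[q]), (qx[q], qt[q]), hp) - k_star @ Kinv @ k_star
    return mu, var


class TestPosterior:
    def test_empty_history_recovers_prior(self):
        hp = GPHyperparams(kernel_kind="forgetting", epsilon=0.2)
        post = gp_posterior([], [(0.0, 0), (1.0, 5)], hp)
        assert np.allclose(post.mu, 0.0)
        assert np.allclose(post.var, 1.0)

    def test_noiseless_interpolation(self):
        hp = GPHyperparams(sigma_n2=0.0)
        post = gp_posterior([SampleRecord(0.5, 3, -0.7)], [(0.5, 3)], hp)
        assert post.mu[0] == pytest.approx(-0.7)
        assert post.var[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_explicit_inverse_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            hp = _random_hp(rng)
            n = rng.integers(1, 21)
            xs = rng.uniform(-np.pi, np.pi, n)
            ts = np.sort(rng.integers(0, 100, n)).astype(float)
            ys = rng.normal(0, 0.5, n)
            qx = rng.uniform(-np.pi, np.pi, 7)
            qt = rng.uniform(0, 100, 7)
            post = gp_posterior(list(zip(xs, ts, ys)), list(zip(qx, qt)), hp)
            mu, var = _oracle_posterior(xs, ts, ys, qx, qt, hp)
            assert np.allclose(post.mu, mu, atol=1e-8)
            assert np.allclose(post.var, var, atol=1e-8)

    def test_variance_bounded_by_prior_and_monotone(self):
        rng = np.random.default_rng(7)
        hp = GPHyperparams(kernel_kind="forgetting_periodic", epsilon=0.1, T_t=20)
        queries = [(q, 50.0) for q in np.linspace(-np.pi, np.pi, 9)]
        hist = []
        prev_var = np.full(9, np.inf)
        for i in range(15):
            hist.append(SampleRecord(rng.uniform(-np.pi, np.pi), i, rng.normal()))
            post = gp_posterior(hist, queries, hp)
            assert np.all(post.var <= 1.0 + 1e-10)
            assert np.all(post.var <= prev_var + 1e-8)  # information never lost
            prev_var = post.var

    def test_window_truncates_history(self):
        hp = GPHyperparams(window=5)
        hist = [SampleRecord(0.1 * i, i, float(i)) for i in range(20)]
        full = gp_posterior(hist, [(0.5, 20)], hp)
        tail = gp_posterior(hist[-5:], [(0.5, 20)], GPHyperparams(window=None))
        assert full.mu[0] == pytest.approx(tail.mu[0])

    def test_queries_required(self):
        with pytest.raises(ValueError):
            gp_posterior([], [], GPHyperparams())


class TestEstimator:
    def test_sklearn_contract(self):
        from sklearn.base import clone

        est = TimeVaryingGPRegressor(kernel_kind="forgetting", epsilon=0.2)
        params = est.get_params()
        assert params["epsilon"] == 0.2
        est2 = clone(est).set_params(epsilon=0.3)
        assert est2.get_params()["epsilon"] == 0.3
        with pytest.raises(AttributeError):
            est.predict(np.zeros((1, 2)))

    def test_matches_sklearn_gpr_static(self):
        # independent cross-check: sklearn's GP with the same periodic kernel
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import ExpSineSquared

        rng = np.random.default_rng(3)
        x = rng.uniform(-np.pi, np.pi, 12)
        y = np.sin(x) + rng.normal(0, 0.1, 12)
        q = np.linspace(-np.pi, np.pi, 25)
        ours = TimeVaryingGPRegressor(kernel_kind="static", l_x=1.3, sigma_n2=0.01)
        ours.fit(np.column_stack([x, np.zeros(12)]), y)
        mu, std = ours.predict(np.column_stack([q, np.zeros(25)]), return_std=True)
        ref = GaussianProcessRegressor(
            kernel=ExpSineSquared(length_scale=1.3, periodicity=2 * np.pi,
                                  length_scale_bounds="fixed", periodicity_bounds="fixed"),
            alpha=0.01, optimizer=None,
        ).fit(x[:, None], y)
        mu_ref, std_ref = ref.predict(q[:, None], return_std=True)
        assert np.allclose(mu, mu_ref, atol=1e-8)
        assert np.allclose(std, std_ref, atol=1e-6)

    def test_normalize_y_inverts_scaling(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([rng.uniform(-np.pi, np.pi, 10), np.arange(10.0)])
        y = 100.0 + 5.0 * rng.normal(size=10)
        est = TimeVaryingGPRegressor(normalize_y=True).fit(X, y)
        mu = est.predict(X)
        assert np.all(np.abs(mu - y) < 15.0)  # predictions on the raw scale

    def test_validates_hyperparameters(self):
        with pytest.raises(ValueError):
            TimeVaryingGPRegressor(epsilon=1.0).fit(np.zeros((2, 2)), np.zeros(2))
        with pytest.raises(ValueError):
            GPHyperparams(kernel_kind="nope")
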