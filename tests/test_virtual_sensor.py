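"""Virtual sensor: MCC weighting, basis expansion, TVARMA, Kalman, rebuild."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgfault import (
    BasisConfig,
    TvarmaModel,
    basis_f,
    basis_matrix,
    cross_corr_coeff,
    fit_tvarma,
    kalman_gain,
    make_tvk,
    mcc_input,
    mcc_matrix,
    predict_tvarma,
    tvk_estimate,
)
from emgfault.virtual_sensor import _tvarma_regressors


def _mixed_signals(n=4000, M=4, seed=2, bandlimited=False):
    """Channels sharing latent sources: informative correlations.

    With ``bandlimited=True`` the sources are filtered to the sEMG carrier
    band so samples are temporally correlated, which is what makes lagged
    prediction from the MCC input possible.
    """
    rng = np.random.default_rng(seed)
    s = rng.standard_normal((n, M))
    if bandlimited:
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, [20, 450], btype="band", fs=2000, output="sos")
        s = sosfiltfilt(sos, s, axis=0)
    mix = np.eye(M) + 0.5 * rng.uniform(0.2, 1.0, size=(M, M))
    return s @ mix


class TestCrossCorr:
    def test_self_correlation_is_one(self):
        x = np.random.default_rng(0).standard_normal(100)
        assert cross_corr_coeff(x, x) == pytest.approx(1.0)

    def test_anticorrelation_absolute_value(self):
        x = np.random.default_rng(0).standard_normal(100)
        assert cross_corr_coeff(x, -x) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(100000), rng.standard_normal(100000)
        assert cross_corr_coeff(x, y) <= 0.02

    def test_constant_input_defined_as_zero(self):
        x = np.random.default_rng(0).standard_normal(50)
        assert cross_corr_coeff(x, np.ones(50)) == 0.0


class TestMccMatrix:
    def test_two_channels_unit_weights(self):
        sig = _mixed_signals(M=2)
        m = mcc_matrix(sig)
        assert m.p[0, 1] == pytest.approx(1.0)
        assert m.p[1, 0] == pytest.approx(1.0)

    def test_three_equal_correlations_half_each(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(5000)
        sig = np.column_stack([base + 0.5 * rng.standard_normal(5000) for _ in range(3)])
        m = mcc_matrix(sig)
        assert np.allclose(m.p[m.p > 0], 0.5, atol=0.05)

    def test_matches_bruteforce_definition(self):
        """p_xy = c_xy / sum of available c, entry by entry."""
        sig = _mixed_signals(M=4)
        m = mcc_matrix(sig)
        M = 4
        c = np.zeros((M, M))
        for x in range(M):
            for y in range(M):
                if x != y:
                    c[x, y] = abs(np.corrcoef(sig[:, x], sig[:, y])[0, 1])
        for t in range(M):
            denom = sum(c[x, t] for x in range(M) if x != t)
            for x in range(M):
                expect = 0.0 if x == t else c[x, t] / denom
                assert m.p[x, t] == pytest.approx(expect, abs=1e-12)

    def test_normalization_diagonal_scale_invariance(self):
        sig = _mixed_signals(M=5)
        m = mcc_matrix(sig)
        assert np.allclose(np.diag(m.p), 0.0)
        assert np.allclose(m.p.sum(axis=0), 1.0, atol=1e-12)
        m2 = mcc_matrix(3.7 * sig)
        assert np.allclose(m.p, m2.p, atol=1e-12)

    def test_exclusion_redistributes_mass(self):
        sig = _mixed_signals(M=5)
        m = mcc_matrix(sig, excluded={1})
        assert np.all(m.p[1, :] == 0.0)
        assert np.allclose(m.p.sum(axis=0), 1.0, atol=1e-12)

    def test_too_few_channels_rejected(self):
        sig = _mixed_signals(M=3)
        with pytest.raises(ValueError):
            mcc_matrix(sig, excluded={0, 1})


class TestMccInput:
    def test_identical_sources_convexity(self):
        s = np.random.default_rng(4).standard_normal(1000)
        noise = 1e-6 * np.random.default_rng(5).standard_normal((1000, 3))
        sig = np.column_stack([s, s, s]) + noise
        m = mcc_matrix(sig)
        u = mcc_input(m, sig, target=0)
        assert np.allclose(u, s, atol=1e-4)

    def test_single_source_passthrough(self):
        sig = _mixed_signals(M=3)
        m = mcc_matrix(sig, excluded={1})
        u = mcc_input(m, sig, target=1)
        # channels 0 and 2 are the only sources; weights sum to 1
        w0, w2 = m.p[0, 1], m.p[2, 1]
        assert np.allclose(u, w0 * sig[:, 0] + w2 * sig[:, 2])

    def test_weighted_sum_matches_bruteforce(self):
        sig = _mixed_signals(M=4)
        m = mcc_matrix(sig)
        u = mcc_input(m, sig, target=2)
        brute = sum(m.p[x, 2] * sig[:, x] for x in range(4))
        assert np.allclose(u, brute)


class TestBasis:
    @pytest.mark.parametrize("family", ["legendre", "fourier", "time_power"])
    def test_constant_term(self, family):
        cfg = BasisConfig(N=100, V=3, family=family)
        assert all(basis_f(n, 0, cfg) == 1.0 for n in (0, 50, 99))

    def test_legendre_linear_vanishes_at_midpoint(self):
        cfg = BasisConfig(N=101, V=2)
        assert basis_f(50, 1, cfg) == pytest.approx(0.0, abs=1e-12)

    def test_fourier_closed_form(self):
        cfg = BasisConfig(N=64, V=2, family="fourier")
        t = 2 * 10 / 63 - 1
        assert basis_f(10, 2, cfg) == pytest.approx(np.cos(np.pi * t))

    def test_index_range_enforced(self):
        cfg = BasisConfig(N=10, V=1)
        with pytest.raises(ValueError):
            basis_f(0, 2, cfg)
        with pytest.raises(ValueError):
            basis_f(10, 0, cfg)


def _simulate_tvarma(alpha, beta, basis, u, noise_std, seed=0):
    """Direct recursion with known coefficients (independent of the fit)."""
    rng = np.random.default_rng(seed)
    F = basis_matrix(basis)
    P, Q = alpha.shape[0], beta.shape[0]
    N = basis.N
    a = F @ alpha.T
    b = F @ beta.T
    y = np.zeros(N)
    for n in range(max(P, Q), N):
        acc = sum(a[n, i - 1] * y[n - i] for i in range(1, P + 1))
        acc += sum(b[n, j - 1] * u[n - j] for j in range(1, Q + 1))
        y[n] = acc + noise_std * rng.standard_normal()
    return y


class TestTvarmaFit:
    def test_matches_normal_equations(self):
        """LS fit equals the brute-force normal-equations solution."""
        rng = np.random.default_rng(6)
        n = 400
        u = rng.standard_normal(n)
        y = rng.standard_normal(n)
        basis = BasisConfig(N=n, V=1)
        model = fit_tvarma(y, u, basis, P=2, Q=1, method="joint")
        F = basis_matrix(basis)
        X, target, _ = _tvarma_regressors(y, u, F, 2, 1)
        theta = np.linalg.solve(X.T @ X, X.T @ target)
        fitted = np.concatenate([model.alpha.ravel(), model.beta.ravel()])
        assert np.allclose(fitted, theta, atol=1e-8)

    def test_parameter_recovery_time_varying(self):
        """Coefficients of a known TVARMA recovered to < 0.05 at n = 1e4."""
        n = 10_000
        basis = BasisConfig(N=n, V=1)
        alpha = np.array([[0.5, 0.1], [-0.2, 0.05], [0.1, 0.0], [0.05, 0.0]])
        beta = np.array([[0.8, 0.2], [0.3, 0.0]])
        rng = np.random.default_rng(7)
        u = rng.standard_normal(n)
        y_clean = _simulate_tvarma(alpha, beta, basis, u, noise_std=0.0, seed=8)
        noise_std = np.sqrt(np.mean(y_clean**2) / 10 ** (30 / 10))  # 30 dB SNR
        y = _simulate_tvarma(alpha, beta, basis, u, noise_std=noise_std, seed=8)
        model = fit_tvarma(y, u, basis, P=4, Q=2, method="joint")
        assert np.max(np.abs(model.alpha - alpha)) < 0.05
        assert np.max(np.abs(model.beta - beta)) < 0.05

    def test_time_invariant_ar4_recovery(self):
        """V=0 reduces to classical AR(4); LS is consistent."""
        rng = np.random.default_rng(9)
        n = 20_000
        a_true = np.array([0.4, -0.3, 0.2, -0.1])
        y = np.zeros(n)
        for i in range(4, n):
            y[i] = sum(a_true[k] * y[i - 1 - k] for k in range(4)) + rng.standard_normal()
        model = fit_tvarma(y, None, BasisConfig(N=n, V=0), P=4, Q=0)
        # 2 standard errors ~ 2/sqrt(n)
        assert np.allclose(model.alpha.ravel(), a_true, atol=3 / np.sqrt(n) + 0.01)

    def test_history_too_short_rejected(self):
        with pytest.raises(ValueError):
            fit_tvarma(np.zeros(10), np.zeros(10), BasisConfig(N=10, V=2))


class TestTvarmaPredict:
    def test_zero_model_predicts_zero(self):
        model = TvarmaModel(
            alpha=np.zeros((4, 1)),
            beta=np.zeros((2, 1)),
            basis=BasisConfig(N=100, V=0),
            resid_var=0.0,
        )
        assert np.all(predict_tvarma(model, np.ones(50)) == 0.0)

    def test_random_walk_constant_continuation(self):
        model = TvarmaModel(
            alpha=np.array([[1.0], [0.0], [0.0], [0.0]]),
            beta=np.zeros((2, 1)),
            basis=BasisConfig(N=100, V=0),
            resid_var=0.0,
        )
        out = predict_tvarma(model, np.zeros(30), y_seed=np.array([0, 0, 0, 2.5]))
        assert np.allclose(out, 2.5)

    def test_reconstruction_beats_zero_predictor(self):
        """On correlated channels the model's normalized RMSE is < 1."""
        sig = _mixed_signals(n=12000, M=4, seed=10, bandlimited=True)
        m = mcc_matrix(sig)
        u = mcc_input(m, sig, target=0)
        n_fit = 6000
        model = fit_tvarma(sig[:n_fit, 0], u[:n_fit], BasisConfig(N=n_fit, V=2))
        pred = predict_tvarma(model, u[n_fit:], y_seed=sig[n_fit - 4 : n_fit, 0])
        truth = sig[n_fit:, 0]
        nrmse = np.sqrt(np.mean((pred - truth) ** 2) / np.mean(truth**2))
        assert nrmse < 1.0


class TestKalman:
    def test_no_process_noise_zero_gain(self):
        P, M = kalman_gain(1.0, 1.0, 1.0, 0.0, 1.0)
        assert P[0, 0] == pytest.approx(0.0, abs=1e-9)
        assert M[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_scalar_golden_ratio(self):
        P, M = kalman_gain(1.0, 1.0, 1.0, 1.0, 1.0)
        phi = (1 + np.sqrt(5)) / 2
        assert P[0, 0] == pytest.approx(phi, abs=1e-8)
        assert M[0, 0] == pytest.approx(phi - 1, abs=1e-8)

    def test_identity_2x2_decouples(self):
        I = np.eye(2)
        P, M = kalman_gain(I, I, I, I, I)
        phi = (1 + np.sqrt(5)) / 2
        assert np.allclose(P, phi * I, atol=1e-8)
        assert np.allclose(M, (phi - 1) * I, atol=1e-8)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(q=st.floats(0.01, 10), r=st.floats(0.01, 10), a=st.floats(0.3, 1.1))
    def test_riccati_fixed_point_residual(self, q, r, a):
        """The returned Pss satisfies the Riccati equation to < 1e-8."""
        P, _ = kalman_gain(a, 1.0, 1.0, q, r)
        p = P[0, 0]
        resid = abs(a * p * a - a * p * (p + r) ** -1 * p * a + q - p)
        assert resid < 1e-8

    def test_r_positive_definite_required(self):
        with pytest.raises(ValueError):
            kalman_gain(1.0, 1.0, 1.0, 1.0, 0.0)


class TestTvkEstimate:
    def test_perfect_measurement_limit(self):
        model = make_tvk(qw=1.0, r=1e-14)
        y = np.random.default_rng(11).standard_normal(200)
        est = tvk_estimate(model, np.zeros(200), y)
        assert np.allclose(est, y, atol=1e-5)

    def test_full_trust_prior_limit(self):
        model = make_tvk(qw=1e-14, r=1.0)
        y = np.random.default_rng(12).standard_normal(200)
        est = tvk_estimate(model, np.zeros(200), y, x0=0.0)
        assert np.max(np.abs(est)) < 1e-5

    def test_denoises_scalar_random_walk(self):
        """Error variance below the raw measurement and a naive smoother."""
        rng = np.random.default_rng(13)
        n = 5000
        q, r = 0.05, 1.0
        w = np.sqrt(q) * rng.standard_normal(n)
        x = np.cumsum(w)
        y = x + np.sqrt(r) * rng.standard_normal(n)
        model = make_tvk(qw=q, r=r)
        est = tvk_estimate(model, np.zeros(n), y, x0=0.0)
        err_kf = np.mean((est - x) ** 2)
        err_meas = np.mean((y - x) ** 2)
        alpha = 0.2  # exponential smoothing baseline
        smooth = np.empty(n)
        s = 0.0
        for i in range(n):
            s = (1 - alpha) * s + alpha * y[i]
            smooth[i] = s
        err_smooth = np.mean((smooth - x) ** 2)
        assert err_kf < err_meas
        assert err_kf < err_smooth

    def test_length_mismatch_rejected(self):
        model = make_tvk(qw=1.0, r=1.0)
        with pytest.raises(ValueError):
            tvk_estimate(model, np.zeros(10), np.zeros(11))
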