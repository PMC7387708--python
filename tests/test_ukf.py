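"""Unscented tracker: exact-Kalman equivalence, limits, EM recovery, PSD."""

import math

import numpy as np
import pytest

import skilltrack as st
from skilltrack.emission import BlockRecord, ParticipantSequence, TrialCounts
from skilltrack.ukf import (
    UKFEMConfig,
    UKFParams,
    UTConfig,
    _controls,
    sigma_points,
    ukf_em_fit,
    ukf_filter,
    ukf_predict_accuracy,
    ukf_smooth,
)

from conftest import make_tiny_sequence


def seq_from_y(y_frac_list, z_list, m=20, n_trials=40):
    """Sequence whose observed accuracies are y/m fractions (fp = 0)."""
    n_trials = max(n_trials, m)
    blocks = []
    for t, (y, z) in enumerate(zip(y_frac_list, z_list), start=1):
        tp = int(round(y * m))
        counts = TrialCounts(tp=tp, fn=m - tp, fp=0, n_trials=n_trials, n_targets=m)
        blocks.append(BlockRecord(t=t, session=1, z=z, counts=counts))
    return ParticipantSequence("UKF", blocks)


def exact_kalman(seq, params, H):
    """Closed-form Kalman recursion for a linear observation y = H x + w."""
    u = _controls(seq)
    m, P = params.x0.copy(), params.V0.copy()
    means, covs, ll = [], [], 0.0
    for t, blk in enumerate(seq.blocks):
        if t > 0:
            m = params.A @ m + params.B @ u[t]
            P = params.A @ P @ params.A.T + params.Q
        y = blk.y_frac
        if y is not None:
            S = float(H @ P @ H) + params.R
            K = P @ H / S
            innov = y - float(H @ m)
            m = m + K * innov
            P = P - np.outer(K, H @ P)
            ll += -0.5 * (math.log(2 * math.pi * S) + innov**2 / S)
        means.append(m.copy())
        covs.append(P.copy())
    return means, covs, ll


class TestObservation:
    def test_midpoint(self):
        assert st.ukf_observe(np.array([4.0, 1.6]), 4) == pytest.approx(0.5)

    def test_range_and_icc_agreement(self, irt_default):
        for skill in (-3.0, 2.5, 8.0, 20.0):
            v = st.ukf_observe(np.array([skill, 1.6]), 5)
            assert 0.0 < v < 1.0
            assert v == pytest.approx(st.icc(skill, 5, irt_default), rel=1e-12)

    def test_rho_clamped(self):
        # negative discrimination cannot flip the curve
        lo = st.ukf_observe(np.array([2.0, -3.0]), 5)
        hi = st.ukf_observe(np.array([8.0, -3.0]), 5)
        assert hi > lo


class TestFilter:
    def test_reduces_to_exact_kalman_with_linear_observation(self):
        rng = np.random.default_rng(0)
        H = np.array([0.12, 0.3])
        params = UKFParams(
            A=np.array([[0.95, 0.05], [0.0, 0.98]]),
            B=np.array([[0.01, 0.02, 0.1], [0.0, 0.0, 0.02]]),
            Q=np.diag([0.05, 0.01]),
            R=0.04,
            x0=np.array([2.0, 1.0]),
            V0=np.diag([0.5, 0.2]),
        )
        y = rng.uniform(0.2, 0.95, size=20).round(2)
        z = rng.integers(1, 6, size=20)
        seq = seq_from_y(y, z, m=100)
        lin = lambda state, zz: float(H @ state)
        beliefs, ll = ukf_filter(seq, params, obs_fn=lin)
        means, covs, ll_exact = exact_kalman(seq, params, H)
        assert ll == pytest.approx(ll_exact, abs=1e-8)
        for b, m, P in zip(beliefs, means, covs):
            assert np.allclose(b.mean, m, atol=1e-8)
            assert np.allclose(b.cov, P, atol=1e-8)

    def test_uninformative_observation_limit(self):
        # R -> inf: the posterior equals pure prior propagation
        params = UKFParams.default()
        big_r = UKFParams(
            params.A, params.B, params.Q, 1e12, params.x0, params.V0
        )
        seq = seq_from_y([0.3, 0.8, 0.5, 0.9], [2, 2, 3, 3])
        beliefs, _ = ukf_filter(seq, big_r)
        u = _controls(seq)
        m, P = big_r.x0.copy(), big_r.V0.copy()
        assert np.allclose(beliefs[0].mean, m, atol=1e-6)
        for t in range(1, 4):
            m = big_r.A @ m + big_r.B @ u[t]
            P = big_r.A @ P @ big_r.A.T + big_r.Q
            assert np.allclose(beliefs[t].mean, m, atol=1e-6)
            assert np.allclose(beliefs[t].cov, P, atol=1e-4)

    def test_covariances_stay_psd(self):
        seq = seq_from_y(
            [0.1, 0.95, 0.05, 0.9, 0.5, 0.99], [2, 5, 2, 6, 4, 8]
        )
        beliefs, _ = ukf_filter(seq, UKFParams.default())
        for b in beliefs:
            assert np.allclose(b.cov, b.cov.T)
            assert np.linalg.eigvalsh(b.cov).min() >= -1e-12

    def test_filtering_beats_prior_prediction_on_generative_data(self):
        # simulate from the tracker's own dynamics, then check the filtered
        # skill error is below the error of the prior (no-update) propagation
        params = UKFParams(
            A=np.array([[0.99, 0.0], [0.0, 1.0]]),
            B=np.array([[0.0, 0.05, 0.05], [0.0, 0.0, 0.0]]),
            Q=np.diag([0.05, 1e-6]),
            R=0.01,
            x0=np.array([3.0, 1.6]),
            V0=np.diag([1.0, 1e-6]),
        )
        rng = np.random.default_rng(1)
        err_filt, err_prior = [], []
        for _ in range(30):
            x = rng.multivariate_normal(params.x0, params.V0)
            u_prev_y = 0.5
            ys, zs, skills = [], [], []
            for t in range(60):
                z = int(np.clip(round(x[0] + rng.normal(0, 1)), 1, 10))
                u = np.array([z, u_prev_y, 1.0])
                if t > 0:
                    x = params.A @ x + params.B @ u + rng.multivariate_normal(
                        np.zeros(2), params.Q
                    )
                y = st.ukf_observe(x, z) + rng.normal(0, math.sqrt(params.R))
                y = float(np.clip(y, 0.0, 1.0))
                ys.append(round(y, 2))
                zs.append(z)
                skills.append(x[0])
                u_prev_y = y
            seq = seq_from_y(ys, zs, m=100)
            beliefs, _ = ukf_filter(seq, params)
            skills = np.array(skills)
            filt = np.array([b.mean[0] for b in beliefs])
            # prior propagation: filter with no updates
            prior, _ = ukf_filter(seq, UKFParams(
                params.A, params.B, params.Q, 1e12, params.x0, params.V0
            ))
            prior_m = np.array([b.mean[0] for b in prior])
            err_filt.append(np.sqrt(np.mean((filt - skills) ** 2)))
            err_prior.append(np.sqrt(np.mean((prior_m - skills) ** 2)))
        assert np.mean(err_filt) < np.mean(err_prior)


class TestSmootherAndEM:
    def test_smoother_last_matches_filter(self):
        seq = seq_from_y([0.4, 0.7, 0.6, 0.9, 0.8], [2, 2, 3, 3, 4])
        params = UKFParams.default()
        beliefs, _ = ukf_filter(seq, params)
        smoothed, cross, _ = ukf_smooth(seq, params)
        assert np.allclose(smoothed[-1].mean, beliefs[-1].mean, atol=1e-12)
        assert len(cross) == 4

    def test_em_recovers_dynamics_in_linear_special_case(self):
        # with a linear observation the model is an exact LDS and EM is
        # standard; the transition matrix should be recovered elementwise
        H = np.array([0.1, 0.25])
        true = UKFParams(
            A=np.array([[0.9, 0.05], [0.02, 0.95]]),
            B=np.array([[0.02, 0.0, 0.05], [0.0, 0.01, 0.02]]),
            Q=np.diag([0.02, 0.02]),
            R=0.0025,
            x0=np.array([2.0, 1.5]),
            V0=np.diag([0.3, 0.3]),
        )
        rng = np.random.default_rng(7)
        cohort = []
        for i in range(60):
            x = rng.multivariate_normal(true.x0, true.V0)
            ys, zs = [], []
            y_prev = 0.5
            for t in range(80):
                z = int(rng.integers(1, 6))
                u = np.array([z, y_prev, 1.0])
                if t > 0:
                    x = true.A @ x + true.B @ u + rng.multivariate_normal(
                        np.zeros(2), true.Q
                    )
                y = float(H @ x) + rng.normal(0, math.sqrt(true.R))
                y = float(np.clip(y, 0.01, 0.99))
                ys.append(round(y, 3))
                zs.append(z)
                y_prev = y
            cohort.append(seq_from_y(ys, zs, m=1000))
        lin = lambda state, zz: float(H @ state)
        fit = ukf_em_fit(
            cohort, init=true, config=UKFEMConfig(max_iter=25), obs_fn=lin
        )
        assert np.abs(fit.params.A - true.A).max() < 0.05

    def test_em_loglik_monotone_within_tolerance(self):
        cohort = st.simulate_cohort(
            8, plan=st.SessionPlan(n_sessions=3), seed=3
        )
        fit = ukf_em_fit(cohort, config=UKFEMConfig(max_iter=20))
        deltas = np.diff(fit.loglik_trace)
        assert (deltas > -1e-4 * np.maximum(1.0, np.abs(fit.loglik_trace[:-1]))).all()

    def test_em_noise_terms_stay_positive(self):
        cohort = st.simulate_cohort(
            6, plan=st.SessionPlan(n_sessions=3), seed=4
        )
        fit = ukf_em_fit(cohort, config=UKFEMConfig(max_iter=10))
        assert fit.params.R > 0
        assert np.linalg.eigvalsh(fit.params.Q).min() > 0
        assert np.linalg.eigvalsh(fit.params.V0).min() > 0


class TestPredict:
    def test_zero_noise_point_belief_midpoint(self):
        params = UKFParams(
            A=np.eye(2), B=np.zeros((2, 3)), Q=np.diag([1e-12, 1e-12]),
            R=0.01, x0=np.array([4.0, 1.6]), V0=np.diag([1e-12, 1e-12]),
        )
        bel = st.GaussianBelief(np.array([4.0, 1.6]), np.diag([1e-12, 1e-12]))
        pred = ukf_predict_accuracy(bel, np.array([4.0, 0.5, 1.0]), 4, params)
        assert pred == pytest.approx(0.5, abs=1e-4)

    def test_matches_monte_carlo_propagation(self):
        params = UKFParams(
            A=np.array([[0.95, 0.0], [0.0, 1.0]]),
            B=np.array([[0.02, 0.1, 0.05], [0.0, 0.0, 0.0]]),
            Q=np.diag([0.05, 0.001]),
            R=0.01,
            x0=np.array([3.0, 1.6]),
            V0=np.diag([0.4, 0.01]),
        )
        bel = st.GaussianBelief(np.array([4.0, 1.5]), np.diag([0.3, 0.02]))
        u = np.array([5.0, 0.7, 1.0])
        pred = ukf_predict_accuracy(bel, u, 5, params)
        rng = np.random.default_rng(9)
        xs = rng.multivariate_normal(bel.mean, bel.cov, size=100_000)
        xs = xs @ params.A.T + params.B @ u
        xs += rng.multivariate_normal(np.zeros(2), params.Q, size=100_000)
        mc = np.mean([st.ukf_observe(x, 5) for x in xs])
        assert pred == pytest.approx(mc, abs=0.01)

    def test_intermediate_skill_on_oscillating_levels(self):
        # alternating presented levels 8/9 with alternating performance:
        # the continuous tracker settles between the two integers
        ys, zs = [], []
        for t in range(60):
            if t % 2 == 0:
                zs.append(8); ys.append(0.85)
            else:
                zs.append(9); ys.append(0.35)
        seq = seq_from_y(ys, zs, m=20)
        params = UKFParams(
            A=np.eye(2), B=np.zeros((2, 3)), Q=np.diag([0.02, 1e-6]),
            R=0.02, x0=np.array([8.0, 1.6]), V0=np.diag([1.0, 1e-6]),
        )
        beliefs, _ = ukf_filter(seq, params)
        late = np.array([b.mean[0] for b in beliefs[30:]])
        frac_between = np.mean((late > 8.0) & (late < 9.0))
        assert frac_between >= 0.5
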