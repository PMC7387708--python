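"""Continuous-state skill tracker: unscented Kalman filter with 4PL observation.

The state is the 2-vector (skill, rho): the latent n-level ability on a
continuous scale, plus a per-participant, time-varying discrimination.  The
dynamics are linear-Gaussian with a control input,

    x_t = A x_{t-1} + B u_t + v_t,        v_t ~ N(0, Q),

where u_t = (z_t, y_{t-1}, 1): the current presented level, the previous
block accuracy, and a bias term.  The observation is the nonlinear 4PL curve
evaluated at the state's own discrimination (c = 0, d = 1),

    y_t = logistic(rho_t * (skill_t - z_t)) + w_t,   w_t ~ N(0, R),

so the update step uses the unscented transform (Merwe scaled sigma points).
The prediction step is linear and therefore exact, and because the dynamics
are linear the Rauch-Tung-Striebel smoother applies exactly to the filtered
moments; only the measurement update is approximate.  All of A, B, Q, R, x0
and V0 are estimated by (approximate) EM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .emission import ParticipantSequence

__all__ = [
    "UKFParams",
    "UTConfig",
    "GaussianBelief",
    "UKFFitResult",
    "ukf_observe",
    "sigma_points",
    "ukf_filter",
    "ukf_smooth",
    "ukf_em_fit",
    "ukf_predict_accuracy",
    "UKFPredictor",
]

_RHO_FLOOR = 0.05  # discrimination clamp inside the observation function
_COV_FLOOR = 1e-9


@dataclass
class UTConfig:
    """Merwe scaled sigma-point constants."""

    alpha: float = 0.5
    beta: float = 2.0
    kappa: float = 0.0


@dataclass
class GaussianBelief:
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)


@dataclass
class UKFParams:
    """Dynamics, noise and initial-state parameters of the tracker."""

    A: np.ndarray
    B: np.ndarray
    Q: np.ndarray
    R: float
    x0: np.ndarray
    V0: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float).reshape(2, 2)
        self.B = np.asarray(self.B, dtype=float).reshape(2, 3)
        self.Q = _repair_cov(np.asarray(self.Q, dtype=float).reshape(2, 2))
        self.R = float(self.R)
        self.x0 = np.asarray(self.x0, dtype=float).reshape(2)
        self.V0 = _repair_cov(np.asarray(self.V0, dtype=float).reshape(2, 2))
        if self.R <= 0:
            raise ValueError("observation variance R must be positive")

    @classmethod
    def default(cls) -> "UKFParams":
        """Near-identity dynamics around a mid-range starting skill."""
        return cls(
            A=np.eye(2),
            B=np.zeros((2, 3)),
            Q=np.diag([0.02, 1e-4]),
            R=0.02,
            x0=np.array([2.0, 1.6]),
            V0=np.diag([1.0, 0.25]),
        )

    def to_dict(self) -> dict:
        return {
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "Q": self.Q.tolist(),
            "R": self.R,
            "x0": self.x0.tolist(),
            "V0": self.V0.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UKFParams":
        return cls(
            np.array(d["A"]), np.array(d["B"]), np.array(d["Q"]),
            d["R"], np.array(d["x0"]), np.array(d["V0"]),
        )


@dataclass
class UKFFitResult:
    params: UKFParams
    loglik_trace: list[float]
    converged: bool
    n_iterations: int

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


def _repair_cov(P: np.ndarray) -> np.ndarray:
    """Symmetrise and floor eigenvalues so the covariance stays PSD."""
    P = 0.5 * (P + P.T)
    w, V = np.linalg.eigh(P)
    if w.min() < _COV_FLOOR:
        w = np.maximum(w, _COV_FLOOR)
        P = V @ np.diag(w) @ V.T
        P = 0.5 * (P + P.T)
    return P


def ukf_observe(state: np.ndarray, z: float) -> float:
    """Predicted block accuracy at a state point: 4PL with c=0, d=1.

    The discrimination component is clamped at 0.05 so sigma points cannot
    flip the sign of the curve.
    """
    skill, rho = float(state[0]), max(float(state[1]), _RHO_FLOOR)
    return 1.0 / (1.0 + math.exp(-rho * (skill - float(z))))


def sigma_points(
    mean: np.ndarray, cov: np.ndarray, ut: UTConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merwe scaled sigma points and their mean/covariance weights."""
    n = mean.size
    lam = ut.alpha**2 * (n + ut.kappa) - n
    c = n + lam
    try:
        L = np.linalg.cholesky(c * cov)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(c * _repair_cov(cov))
    pts = np.vstack([mean, mean + L.T, mean - L.T])
    wm = np.full(2 * n + 1, 1.0 / (2.0 * c))
    wc = wm.copy()
    wm[0] = lam / c
    wc[0] = lam / c + (1.0 - ut.alpha**2 + ut.beta)
    return pts, wm, wc


def _controls(seq: ParticipantSequence) -> np.ndarray:
    """Control vectors u_t = (z_t, y_{t-1}, 1); the pre-training accuracy is 0.5."""
    T = len(seq.blocks)
    u = np.ones((T, 3))
    y_prev = 0.5
    for t, blk in enumerate(seq.blocks):
        u[t, 0] = blk.z
        u[t, 1] = y_prev
        if blk.y_frac is not None:
            y_prev = blk.y_frac
    return u


def ukf_filter(
    seq: ParticipantSequence,
    params: UKFParams,
    ut: Optional[UTConfig] = None,
    obs_fn: Optional[Callable[[np.ndarray, float], float]] = None,
) -> tuple[list[GaussianBelief], float]:
    """Unscented filtering pass; returns per-block posteriors and the loglik.

    The prediction step is exact (linear dynamics); the measurement update
    pushes sigma points through the observation function.  Blocks without a
    defined accuracy skip the update.  ``obs_fn(state, z)`` defaults to the
    clamped 4PL; a linear function here reduces the filter to the exact
    Kalman filter (the unscented transform is exact for affine maps).
    """
    ut = ut or UTConfig()
    obs = obs_fn or ukf_observe
    u = _controls(seq)
    beliefs: list[GaussianBelief] = []
    loglik = 0.0
    m, P = params.x0.copy(), params.V0.copy()
    for t, blk in enumerate(seq.blocks):
        if t > 0:
            m = params.A @ m + params.B @ u[t]
            P = _repair_cov(params.A @ P @ params.A.T + params.Q)
        y = blk.y_frac
        if y is not None:
            pts, wm, wc = sigma_points(m, P, ut)
            yh = np.array([obs(p, blk.z) for p in pts])
            ybar = float(wm @ yh)
            dy = yh - ybar
            S = float(wc @ dy**2) + params.R
            S = max(S, 1e-12)
            C = (pts - m).T @ (wc * dy)
            K = C / S
            innov = y - ybar
            m = m + K * innov
            P = _repair_cov(P - np.outer(K, K) * S)
            loglik += -0.5 * (math.log(2.0 * math.pi * S) + innov**2 / S)
        beliefs.append(GaussianBelief(m.copy(), P.copy()))
    return beliefs, loglik


def ukf_smooth(
    seq: ParticipantSequence,
    params: UKFParams,
    ut: Optional[UTConfig] = None,
    obs_fn: Optional[Callable[[np.ndarray, float], float]] = None,
):
    """RTS smoothing on top of the unscented filter.

    Because the dynamics are linear, the smoother recursion is exact given
    the filtered moments.  Returns (smoothed beliefs, pairwise cross
    covariances Cov(x_t, x_{t+1} | y_1..T) for t = 0..T-2, loglik).
    """
    beliefs, loglik = ukf_filter(seq, params, ut, obs_fn)
    T = len(beliefs)
    u = _controls(seq)
    ms = [b.mean.copy() for b in beliefs]
    Ps = [b.cov.copy() for b in beliefs]
    cross = [None] * max(T - 1, 0)
    for t in range(T - 2, -1, -1):
        m_f, P_f = beliefs[t].mean, beliefs[t].cov
        m_pred = params.A @ m_f + params.B @ u[t + 1]
        P_pred = _repair_cov(params.A @ P_f @ params.A.T + params.Q)
        G = P_f @ params.A.T @ np.linalg.inv(P_pred)
        ms[t] = m_f + G @ (ms[t + 1] - m_pred)
        Ps[t] = _repair_cov(P_f + G @ (Ps[t + 1] - P_pred) @ G.T)
        cross[t] = G @ Ps[t + 1]
    smoothed = [GaussianBelief(m, P) for m, P in zip(ms, Ps)]
    return smoothed, cross, loglik


@dataclass
class UKFEMConfig:
    max_iter: int = 50
    tol: float = 1e-3
    ridge: float = 1e-8


def ukf_em_fit(
    cohort: Sequence[ParticipantSequence],
    init: Optional[UKFParams] = None,
    config: Optional[UKFEMConfig] = None,
    ut: Optional[UTConfig] = None,
    obs_fn: Optional[Callable[[np.ndarray, float], float]] = None,
) -> UKFFitResult:
    """Approximate EM for the tracker parameters A, B, Q, R, x0, V0.

    E-step: unscented RTS smoother per participant.  M-step: closed-form
    generalised-least-squares update for [A B] jointly, residual second
    moments for Q, smoothed initial moments for x0/V0, and sigma-point
    propagated observation residuals for R.  The E-step is approximate
    (unscented measurement updates), so the log-likelihood trace is
    monotone only approximately.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    params = init or UKFParams.default()
    config = config or UKFEMConfig()
    ut = ut or UTConfig()
    obs = obs_fn or ukf_observe

    trace: list[float] = []
    converged = False
    for _ in range(config.max_iter):
        total_ll = 0.0
        Sxphi = np.zeros((2, 5))
        Sphiphi = np.zeros((5, 5))
        Sxx = np.zeros((2, 2))
        n_steps = 0
        x0_acc = np.zeros(2)
        V0_acc = np.zeros((2, 2))
        r_acc, n_obs = 0.0, 0
        firsts: list[np.ndarray] = []

        for seq in cohort:
            smoothed, cross, ll = ukf_smooth(seq, params, ut, obs)
            total_ll += ll
            u = _controls(seq)
            firsts.append(smoothed[0].mean)
            V0_acc += smoothed[0].cov
            for t in range(1, len(smoothed)):
                m_prev, P_prev = smoothed[t - 1].mean, smoothed[t - 1].cov
                m_cur, P_cur = smoothed[t].mean, smoothed[t].cov
                C = cross[t - 1]  # Cov(x_{t-1}, x_t)
                phi_mean = np.concatenate([m_prev, u[t]])
                Exphi = np.zeros((2, 5))
                Exphi[:, :2] = C.T + np.outer(m_cur, m_prev)
                Exphi[:, 2:] = np.outer(m_cur, u[t])
                Ephiphi = np.zeros((5, 5))
                Ephiphi[:2, :2] = P_prev + np.outer(m_prev, m_prev)
                Ephiphi[:2, 2:] = np.outer(m_prev, u[t])
                Ephiphi[2:, :2] = Ephiphi[:2, 2:].T
                Ephiphi[2:, 2:] = np.outer(u[t], u[t])
                Sxphi += Exphi
                Sphiphi += Ephiphi
                Sxx += P_cur + np.outer(m_cur, m_cur)
                n_steps += 1
            for t, blk in enumerate(seq.blocks):
                if blk.y_frac is None:
                    continue
                pts, wm, wc = sigma_points(smoothed[t].mean, smoothed[t].cov, ut)
                yh = np.array([obs(p, blk.z) for p in pts])
                ybar = float(wm @ yh)
                r_acc += (blk.y_frac - ybar) ** 2 + float(wc @ (yh - ybar) ** 2)
                n_obs += 1

        trace.append(total_ll)
        if len(trace) > 1 and trace[-1] - trace[-2] < config.tol:
            converged = True
            break

        # ----- M-step
        W = np.linalg.solve(
            Sphiphi + config.ridge * np.eye(5), Sxphi.T
        ).T
        A_new, B_new = W[:, :2], W[:, 2:]
        Q_new = (Sxx - W @ Sxphi.T - Sxphi @ W.T + W @ Sphiphi @ W.T) / max(n_steps, 1)
        x0_new = np.mean(firsts, axis=0)
        V0_new = V0_acc / len(cohort) + np.mean(
            [np.outer(f - x0_new, f - x0_new) for f in firsts], axis=0
        )
        R_new = max(r_acc / max(n_obs, 1), 1e-6)
        params = UKFParams(
            A=A_new, B=B_new, Q=_repair_cov(Q_new), R=R_new,
            x0=x0_new, V0=_repair_cov(V0_new),
        )

    return UKFFitResult(
        params=params,
        loglik_trace=trace,
        converged=converged,
        n_iterations=len(trace),
    )


def ukf_predict_accuracy(
    belief_prev: GaussianBelief,
    u_next: np.ndarray,
    z_next: float,
    params: UKFParams,
    ut: Optional[UTConfig] = None,
    obs_fn: Optional[Callable[[np.ndarray, float], float]] = None,
) -> float:
    """Expected accuracy of the next block from the current posterior.

    Propagates the Gaussian belief through the linear dynamics and averages
    the observation function over the predicted sigma points.
    """
    ut = ut or UTConfig()
    obs = obs_fn or ukf_observe
    m = params.A @ belief_prev.mean + params.B @ np.asarray(u_next, dtype=float)
    P = _repair_cov(params.A @ belief_prev.cov @ params.A.T + params.Q)
    pts, wm, _ = sigma_points(m, P, ut)
    return float(wm @ np.array([obs(p, z_next) for p in pts]))


class UKFPredictor:
    """One-step-ahead accuracy predictions from a fitted UKF tracker."""

    def __init__(self, params: UKFParams, ut: Optional[UTConfig] = None):
        self.params = params
        self.ut = ut or UTConfig()

    def predict_sequence(self, seq: ParticipantSequence) -> np.ndarray:
        params, ut = self.params, self.ut
        u = _controls(seq)
        preds = np.empty(len(seq.blocks))
        m, P = params.x0.copy(), params.V0.copy()
        for t, blk in enumerate(seq.blocks):
            if t > 0:
                m = params.A @ m + params.B @ u[t]
                P = _repair_cov(params.A @ P @ params.A.T + params.Q)
            pts, wm, wc = sigma_points(m, P, ut)
            yh = np.array([ukf_observe(p, blk.z) for p in pts])
            preds[t] = float(wm @ yh)
            y = blk.y_frac
            if y is not None:
                ybar = preds[t]
                dy = yh - ybar
                S = max(float(wc @ dy**2) + params.R, 1e-12)
                K = (pts - m).T @ (wc * dy) / S
                m = m + K * (y - ybar)
                P = _repair_cov(P - np.outer(K, K) * S)
        return preds

    def describe(self) -> str:
        return "ukf"
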