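"""Input-output hidden Markov model for latent working-memory skill.

The latent state ``x_t`` is the participant's maximal n-level skill on a
discrete grid {1..N}.  The presented n-level ``z_t`` acts as a driving input:
it shifts the 4PL emission curve, and (in the history-driven variant) the
previous block's presented level and accuracy modulate the transition row.
Transitions are restricted to adjacent skill levels, which enforces smooth
skill progression.

Two tied transition architectures are provided:

* **model-1** -- three universal probabilities (down, stay, up), independent
  of history.
* **model-2** -- a 3 x 5 x 10 tensor of non-negative propensities indexed by
  (skill movement, z_prev - x_new in {-2..2}, decile bin of the previous
  accuracy).  Rows are formed by masking infeasible destinations and
  renormalising, so the tensor entries are propensities rather than
  probabilities.

Both are trained with a Baum-Welch EM adapted to tied parameters and
input-dependent rows: the E-step pools expected transition counts across all
participants into the tied cells, and the M-step maximises the expected
complete-data log-likelihood of the *normalised* rows numerically (masked
renormalisation makes raw count ratios inexact, including at the skill-grid
boundaries for model-1).  This keeps the generalised-EM monotonicity
guarantee that the test-suite asserts.  The IRT hyperparameters
(rho, c, d, alpha) enter the emissions only and are optimised in an outer
grid-search loop.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize

from .emission import (
    IRTParams,
    ParticipantSequence,
    bin_accuracy,
    emission_log_prob_states,
    icc,
)

__all__ = [
    "TransitionModel1",
    "TransitionModel2",
    "BeliefState",
    "EMConfig",
    "HMMFitResult",
    "transition_row",
    "build_transition_matrix",
    "forward_filter",
    "forward_backward",
    "em_fit",
    "grid_search_irt",
    "predict_accuracy",
    "skill_trajectory",
    "HMMPredictor",
]

logger = logging.getLogger(__name__)

_DX = (-1, 0, 1)  # movement of the latent skill: down, stay, up
_DZ_MAX = 2  # |z_prev - x_new| must not exceed this in model-2
_NEUTRAL_BIN = bin_accuracy(0.5)  # fallback bin when the previous accuracy is undefined


@dataclass
class TransitionModel1:
    """Universal adjacent-neighbour transitions with 3 tied probabilities."""

    q_down: float
    q_stay: float
    q_up: float
    pi: np.ndarray
    N: int = 10

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.N < 2:
            raise ValueError("need at least two skill states")
        q = np.array([self.q_down, self.q_stay, self.q_up])
        if (q < 0).any() or abs(q.sum() - 1.0) > 1e-12:
            raise ValueError("q_down + q_stay + q_up must be a distribution")
        if self.pi.shape != (self.N,) or abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must be a distribution over N states")

    @property
    def q(self) -> np.ndarray:
        return np.array([self.q_down, self.q_stay, self.q_up])

    @property
    def n_free_parameters(self) -> int:
        return 3

    def to_dict(self) -> dict:
        return {
            "kind": "model1",
            "N": self.N,
            "q_down": self.q_down,
            "q_stay": self.q_stay,
            "q_up": self.q_up,
            "pi": self.pi.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionModel1":
        return cls(d["q_down"], d["q_stay"], d["q_up"], np.array(d["pi"]), d["N"])


@dataclass
class TransitionModel2:
    """History-driven transitions: a 3 x 5 x 10 tensor of tied propensities.

    Axis 0 indexes the skill movement (down, stay, up), axis 1 the signed
    difference ``z_prev - x_new`` shifted to {0..4}, axis 2 the decile bin of
    the previous block accuracy.  Entries are non-negative propensities; each
    realised row is masked (adjacency and ``|z_prev - x_new| <= 2``) and then
    renormalised.  The overall scale of the tensor is not identified; it is
    fixed by setting the largest entry to 1.
    """

    q: np.ndarray
    pi: np.ndarray
    N: int = 10

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.q.shape != (3, 5, 10):
            raise ValueError("model-2 propensity tensor must be 3 x 5 x 10")
        if (self.q < 0).any():
            raise ValueError("propensities must be non-negative")
        if self.pi.shape != (self.N,) or abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must be a distribution over N states")

    @property
    def n_free_parameters(self) -> int:
        return int(np.prod(self.q.shape))

    def to_dict(self) -> dict:
        return {
            "kind": "model2",
            "N": self.N,
            "q": self.q.tolist(),
            "pi": self.pi.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionModel2":
        return cls(np.array(d["q"]), np.array(d["pi"]), d["N"])


TransitionModel = Union[TransitionModel1, TransitionModel2]


@dataclass
class BeliefState:
    """Filtered posterior over the latent skill grid {1..N}."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if (self.probs < -1e-12).any() or abs(self.probs.sum() - 1.0) > 1e-10:
            raise ValueError("belief must be a probability distribution")

    @property
    def map_skill(self) -> int:
        # np.argmax returns the first maximiser, i.e. ties break low
        return int(np.argmax(self.probs)) + 1


def transition_row(
    model: TransitionModel,
    x_prev: int,
    z_prev: Optional[int] = None,
    y_prev_frac: Optional[float] = None,
) -> np.ndarray:
    """Distribution of the next skill level given the previous block.

    Support is limited to {x_prev - 1, x_prev, x_prev + 1} intersected with
    the grid; model-2 additionally zeroes destinations with
    ``|z_prev - x_new| > 2``.  If the constraints zero every candidate the
    row degenerates to a self-transition (reset algorithms can present levels
    far from the skill estimate).
    """
    N = model.N
    if not 1 <= x_prev <= N:
        raise ValueError(f"skill state {x_prev} outside {{1..{N}}}")
    row = np.zeros(N)
    if isinstance(model, TransitionModel1):
        base = model.q
        for dx, w in zip(_DX, base):
            x_new = x_prev + dx
            if 1 <= x_new <= N:
                row[x_new - 1] = w
        s = row.sum()
        if s <= 0.0:
            row[:] = 0.0
            row[x_prev - 1] = 1.0
            return row
        row /= s
        return row
    if z_prev is None:
        raise ValueError("model-2 rows require the previous presented n-level")
    b = _NEUTRAL_BIN if y_prev_frac is None else bin_accuracy(y_prev_frac)
    return _masked_row(model, x_prev, z_prev, b)


def _masked_row(model: "TransitionModel2", x_prev: int, z_prev: int, b: int) -> np.ndarray:
    """Model-2 row for a (z, accuracy-bin) context; degenerates to self-transition."""
    N = model.N
    row = np.zeros(N)
    for i, dx in enumerate(_DX):
        x_new = x_prev + dx
        if not 1 <= x_new <= N:
            continue
        dz = z_prev - x_new
        if abs(dz) > _DZ_MAX:
            continue
        row[x_new - 1] = model.q[i, dz + _DZ_MAX, b - 1]
    s = row.sum()
    if s <= 0.0:
        row[:] = 0.0
        row[x_prev - 1] = 1.0
        return row
    return row / s


def build_transition_matrix(
    model: TransitionModel, z_prev: Optional[int], y_prev_frac: Optional[float]
) -> np.ndarray:
    """Row-stochastic N x N matrix for one step, driven by the previous block."""
    return np.vstack(
        [transition_row(model, x, z_prev, y_prev_frac) for x in range(1, model.N + 1)]
    )


# ---------------------------------------------------------------------------
# filtering and smoothing


def _emission_table(
    seq: ParticipantSequence, irt: IRTParams, N: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-block emission likelihoods over the skill grid.

    Returns ``(lik, has_obs)`` where ``lik[t]`` is the emission likelihood
    vector (scaled so its maximum is 1; the scaling constant cancels in all
    posteriors and is re-added to the log-likelihood) and ``has_obs[t]``
    flags blocks with a defined accuracy and at least one target.  Blocks
    without an observation contribute a flat likelihood.
    """
    T = len(seq.blocks)
    lik = np.ones((T, N))
    log_offset = np.zeros(T)
    has_obs = np.zeros(T, dtype=bool)
    for t, blk in enumerate(seq.blocks):
        if blk.y_succ is None or blk.counts.n_targets < 1:
            continue
        logp = emission_log_prob_states(
            blk.y_succ, blk.counts.n_targets, blk.z, irt, N
        )
        mx = logp.max()
        if not np.isfinite(mx):
            raise FloatingPointError(
                f"emission underflow for participant {seq.participant_id}, "
                f"block {blk.t}"
            )
        lik[t] = np.exp(logp - mx)
        log_offset[t] = mx
        has_obs[t] = True
    return lik, has_obs, log_offset


def _step_matrices(seq: ParticipantSequence, model: TransitionModel) -> list[np.ndarray]:
    """Transition matrix for each step t -> t+1, driven by block t."""
    if isinstance(model, TransitionModel1):
        M = build_transition_matrix(model, None, None)
        return [M] * (len(seq.blocks) - 1)
    return [
        build_transition_matrix(model, blk.z, blk.y_frac) for blk in seq.blocks[:-1]
    ]


def forward_filter(
    seq: ParticipantSequence, model: TransitionModel, irt: IRTParams
) -> tuple[list[BeliefState], float]:
    """Filtered beliefs p(x_t | y_1..t, z_1..t) and the data log-likelihood."""
    N = model.N
    lik, _, log_offset = _emission_table(seq, irt, N)
    mats = _step_matrices(seq, model)
    beliefs: list[BeliefState] = []
    loglik = 0.0
    alpha = model.pi * lik[0]
    for t in range(len(seq.blocks)):
        if t > 0:
            alpha = (mats[t - 1].T @ alpha) * lik[t]
        norm = alpha.sum()
        if norm <= 0.0 or not np.isfinite(norm):
            raise FloatingPointError(
                f"filter degenerated at block {seq.blocks[t].t} of participant "
                f"{seq.participant_id}"
            )
        alpha = alpha / norm
        loglik += math.log(norm) + log_offset[t]
        beliefs.append(BeliefState(alpha.copy()))
    return beliefs, loglik


def forward_backward(
    seq: ParticipantSequence, model: TransitionModel, irt: IRTParams
) -> tuple[np.ndarray, np.ndarray, float]:
    """Smoothed marginals and pairwise posteriors.

    Returns ``(gamma, xi, loglik)`` with ``gamma[t]`` = p(x_t | y_1..T) and
    ``xi[t]`` = p(x_t, x_{t+1} | y_1..T) for t = 0..T-2.
    """
    N = model.N
    T = len(seq.blocks)
    lik, _, log_offset = _emission_table(seq, irt, N)
    mats = _step_matrices(seq, model)

    alphas = np.empty((T, N))
    scales = np.empty(T)
    alpha = model.pi * lik[0]
    for t in range(T):
        if t > 0:
            alpha = (mats[t - 1].T @ alpha) * lik[t]
        scales[t] = alpha.sum()
        if scales[t] <= 0.0 or not np.isfinite(scales[t]):
            raise FloatingPointError(
                f"filter degenerated at block {seq.blocks[t].t} of participant "
                f"{seq.participant_id}"
            )
        alpha = alpha / scales[t]
        alphas[t] = alpha

    betas = np.empty((T, N))
    beta = np.ones(N)
    betas[-1] = beta
    for t in range(T - 2, -1, -1):
        beta = mats[t] @ (lik[t + 1] * beta) / scales[t + 1]
        betas[t] = beta

    gamma = alphas * betas
    gamma /= gamma.sum(axis=1, keepdims=True)

    xi = np.empty((T - 1, N, N)) if T > 1 else np.zeros((0, N, N))
    for t in range(T - 1):
        m = alphas[t][:, None] * mats[t] * (lik[t + 1] * betas[t + 1])[None, :]
        xi[t] = m / m.sum()

    loglik = float(np.sum(np.log(scales)) + log_offset.sum())
    return gamma, xi, loglik


# ---------------------------------------------------------------------------
# EM with tied parameters


@dataclass
class EMConfig:
    """Knobs of the adapted Baum-Welch loop.

    ``tol`` is the convergence threshold on the per-iteration increase of the
    total log-likelihood (the slope criterion); ``n_restarts`` draws extra
    random initialisations for model-2, which has a multimodal tied-parameter
    surface.
    """

    max_iter: int = 200
    tol: float = 1e-3
    seed: int = 0
    n_restarts: Optional[int] = None  # default: 1 for model-1, 5 for model-2
    mstep_maxiter: int = 300
    holdout_fraction: float = 0.0  # grid search scores training loglik when 0


@dataclass
class HMMFitResult:
    model: TransitionModel
    irt: IRTParams
    loglik_trace: list[float]
    converged: bool
    n_iterations: int

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


def _default_model(kind: str, N: int, rng: np.random.Generator, perturb: bool):
    pi = np.full(N, 1.0 / N)
    if kind == "model1":
        q = np.array([0.1, 0.8, 0.1])
        if perturb:
            q = rng.dirichlet([2.0, 10.0, 2.0])
        return TransitionModel1(q[0], q[1], q[2], pi, N)
    if kind == "model2":
        base = np.empty((3, 5, 10))
        base[0], base[1], base[2] = 0.1, 0.8, 0.1
        if perturb:
            base = base * np.exp(rng.normal(0.0, 0.5, size=base.shape))
        return TransitionModel2(base / base.max(), pi, N)
    raise ValueError(f"unknown model kind {kind!r}")


def _row_spec_model1(N: int):
    """Candidate tied-cell indices for every skill row of model-1."""
    rows = []
    for x in range(1, N + 1):
        cells, dests = [], []
        for i, dx in enumerate(_DX):
            if 1 <= x + dx <= N:
                cells.append(i)
                dests.append(x + dx - 1)
        rows.append((x - 1, np.array(cells), np.array(dests)))
    return rows


def _row_spec_model2(N: int, z: int, b: int):
    """Candidate tied-cell indices for every skill row of a (z, bin) context."""
    rows = []
    for x in range(1, N + 1):
        cells, dests = [], []
        for i, dx in enumerate(_DX):
            x_new = x + dx
            if not 1 <= x_new <= N:
                continue
            dz = z - x_new
            if abs(dz) > _DZ_MAX:
                continue
            cells.append(np.ravel_multi_index((i, dz + _DZ_MAX, b - 1), (3, 5, 10)))
            dests.append(x_new - 1)
        if cells:
            rows.append((x - 1, np.array(cells), np.array(dests)))
    return rows


def _maximise_tied(theta0: np.ndarray, row_cells: list, row_counts: list, maxiter: int):
    """Maximise sum_rows sum_j C_j log softmax_row(theta)_j over log-propensities.

    Each row is a masked subset of the tied cells; rows share cells, so the
    maximiser has no closed form.  L-BFGS with the analytic gradient.
    """
    n_cells = theta0.size
    flat_cells = np.concatenate(row_cells)
    flat_counts = np.concatenate(row_counts)
    row_id = np.repeat(np.arange(len(row_cells)), [len(c) for c in row_cells])
    n_rows = len(row_cells)
    row_tot = np.bincount(row_id, weights=flat_counts, minlength=n_rows)

    def neg(theta: np.ndarray):
        th = theta[flat_cells]
        mx = np.full(n_rows, -np.inf)
        np.maximum.at(mx, row_id, th)
        ex = np.exp(th - mx[row_id])
        denom = np.bincount(row_id, weights=ex, minlength=n_rows)
        logdenom = np.log(denom) + mx
        f = float(flat_counts @ th - row_tot @ logdenom)
        p = ex / denom[row_id]
        g = np.bincount(
            flat_cells, weights=flat_counts - row_tot[row_id] * p, minlength=n_cells
        )
        return -f, -g

    res = minimize(
        neg, theta0, jac=True, method="L-BFGS-B", options={"maxiter": maxiter}
    )
    return res.x


def em_fit(
    cohort: Sequence[ParticipantSequence],
    model_kind: str,
    irt: IRTParams,
    config: Optional[EMConfig] = None,
    init_model: Optional[TransitionModel] = None,
    N: int = 10,
) -> HMMFitResult:
    """Adapted Baum-Welch: tied transitions, IRT-fixed emissions.

    Expected transition counts are pooled across all participants into the
    tied cells; the tied parameters are then updated by numerically
    maximising the expected complete-data log-likelihood of the masked,
    renormalised rows (a generalised-EM M-step, so the log-likelihood trace
    is non-decreasing).  ``pi`` is updated from the pooled first-block
    smoothed marginals.  Iteration stops when the log-likelihood increase
    falls below ``config.tol`` (default 0.001).
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    if model_kind not in ("model1", "model2"):
        raise ValueError(f"unknown model kind {model_kind!r}")
    config = config or EMConfig()
    n_restarts = config.n_restarts
    if n_restarts is None:
        n_restarts = 5 if model_kind == "model2" else 1
    rng = np.random.default_rng(config.seed)

    # emissions do not depend on the transition parameters: compute once
    tables = [_emission_table(seq, irt, N) for seq in cohort]

    best: Optional[HMMFitResult] = None
    for restart in range(n_restarts):
        if init_model is not None and restart == 0:
            model = init_model
        else:
            model = _default_model(model_kind, N, rng, perturb=restart > 0)
        result = _em_single(cohort, tables, model, config, N)
        if best is None or result.loglik > best.loglik:
            best = result
    best.irt = irt
    return best


def _em_single(cohort, tables, model, config, N) -> HMMFitResult:
    trace: list[float] = []
    converged = False
    # per-sequence step contexts, fixed across iterations
    contexts = []
    for seq in cohort:
        ctx = []
        for blk in seq.blocks[:-1]:
            b = _NEUTRAL_BIN if blk.y_frac is None else bin_accuracy(blk.y_frac)
            ctx.append((blk.z, b))
        contexts.append(ctx)

    for it in range(config.max_iter):
        total_ll = 0.0
        pi_acc = np.zeros(N)
        if isinstance(model, TransitionModel1):
            counts = np.zeros((N, N))
        else:
            counts: dict[tuple[int, int], np.ndarray] = {}

        # transition matrices depend only on the (z, bin) context: cache them
        mat_cache: dict[Optional[tuple[int, int]], np.ndarray] = {}

        def _ctx_matrix(key):
            M = mat_cache.get(key)
            if M is None:
                if key is None:
                    M = build_transition_matrix(model, None, None)
                else:
                    z, b = key
                    M = np.vstack(
                        [
                            _masked_row(model, x, z, b)
                            for x in range(1, N + 1)
                        ]
                    )
                mat_cache[key] = M
            return M

        for seq, (lik, _, log_offset), ctx in zip(cohort, tables, contexts):
            if isinstance(model, TransitionModel1):
                mats = [_ctx_matrix(None)] * (len(seq.blocks) - 1)
            else:
                mats = [_ctx_matrix(key) for key in ctx]
            gamma, xi, ll = _fb_precomputed(seq, model, lik, log_offset, mats)
            if not np.isfinite(ll):
                raise FloatingPointError(
                    f"non-finite log-likelihood for participant {seq.participant_id}"
                )
            total_ll += ll
            pi_acc += gamma[0]
            if isinstance(model, TransitionModel1):
                counts += xi.sum(axis=0)
            else:
                for t, key in enumerate(ctx):
                    acc = counts.get(key)
                    if acc is None:
                        counts[key] = xi[t].copy()
                    else:
                        acc += xi[t]

        trace.append(total_ll)
        if len(trace) > 1 and trace[-1] - trace[-2] < config.tol:
            converged = trace[-1] - trace[-2] > -1e-6 * max(1.0, abs(trace[-1]))
            break

        # ----- M-step
        pi = pi_acc / pi_acc.sum()
        if isinstance(model, TransitionModel1):
            theta0 = np.log(np.maximum(model.q, 1e-12))
            row_cells, row_counts = [], []
            for x0, cells, dests in _row_spec_model1(N):
                c = counts[x0, dests]
                if c.sum() > 0:
                    row_cells.append(cells)
                    row_counts.append(c)
            theta = _maximise_tied(theta0, row_cells, row_counts, config.mstep_maxiter)
            q = np.exp(theta - theta.max())
            q /= q.sum()
            model = TransitionModel1(q[0], q[1], q[2], pi, N)
        else:
            theta0 = np.log(np.maximum(model.q.ravel(), 1e-12))
            row_cells, row_counts = [], []
            for (z, b), mat in counts.items():
                for x0, cells, dests in _row_spec_model2(N, z, b):
                    c = mat[x0, dests]
                    if c.sum() > 0:
                        row_cells.append(cells)
                        row_counts.append(c)
            theta = _maximise_tied(theta0, row_cells, row_counts, config.mstep_maxiter)
            q = np.exp(theta - theta.max()).reshape(3, 5, 10)
            model = TransitionModel2(q, pi, N)

    return HMMFitResult(
        model=model,
        irt=None,  # filled by em_fit
        loglik_trace=trace,
        converged=converged,
        n_iterations=len(trace),
    )


def _fb_precomputed(seq, model, lik, log_offset, mats=None):
    """forward_backward with precomputed emission table and step matrices."""
    N = model.N
    T = len(seq.blocks)
    if mats is None:
        mats = _step_matrices(seq, model)

    alphas = np.empty((T, N))
    scales = np.empty(T)
    alpha = model.pi * lik[0]
    for t in range(T):
        if t > 0:
            alpha = (mats[t - 1].T @ alpha) * lik[t]
        scales[t] = alpha.sum()
        alpha = alpha / scales[t]
        alphas[t] = alpha

    betas = np.empty((T, N))
    beta = np.ones(N)
    betas[-1] = beta
    for t in range(T - 2, -1, -1):
        beta = mats[t] @ (lik[t + 1] * beta) / scales[t + 1]
        betas[t] = beta

    gamma = alphas * betas
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi = np.empty((T - 1, N, N)) if T > 1 else np.zeros((0, N, N))
    for t in range(T - 1):
        m = alphas[t][:, None] * mats[t] * (lik[t + 1] * betas[t + 1])[None, :]
        xi[t] = m / m.sum()
    loglik = float(np.sum(np.log(scales)) + log_offset.sum())
    return gamma, xi, loglik


# ---------------------------------------------------------------------------
# IRT hyperparameter grid search


def default_irt_grid() -> list[IRTParams]:
    """Grid covering the plausible 4PL hyperparameter region.

    Includes rho 1.0..2.5 (step 0.1), c in {0, 0.05, 0.1}, d in
    {0.9, 0.95, 1.0} and alpha in {1, 3, 5, 8, 11.56, 20}.
    """
    rhos = np.round(np.arange(1.0, 2.51, 0.1), 10)
    cs = (0.0, 0.05, 0.1)
    ds = (0.9, 0.95, 1.0)
    alphas = (1.0, 3.0, 5.0, 8.0, 11.56, 20.0)
    return [
        IRTParams(rho=float(r), c=c, d=d, alpha=a)
        for r, c, d, a in itertools.product(rhos, cs, ds, alphas)
    ]


def grid_search_irt(
    cohort: Sequence[ParticipantSequence],
    model_kind: str,
    grid: Optional[Sequence[IRTParams]] = None,
    config: Optional[EMConfig] = None,
    N: int = 10,
) -> tuple[HMMFitResult, list[dict]]:
    """EM fit per IRT grid cell; returns the best fit and the score table.

    With ``config.holdout_fraction > 0`` a participant-level split is made
    and cells are scored on held-out log-likelihood; otherwise on training
    log-likelihood.
    """
    grid = list(grid) if grid is not None else default_irt_grid()
    if not grid:
        raise ValueError("IRT grid must be non-empty")
    config = config or EMConfig()

    train, heldout = list(cohort), []
    if config.holdout_fraction > 0.0:
        rng = np.random.default_rng(config.seed)
        order = rng.permutation(len(cohort))
        n_out = max(1, int(len(cohort) * config.holdout_fraction))
        heldout = [cohort[i] for i in order[:n_out]]
        train = [cohort[i] for i in order[n_out:]]

    table: list[dict] = []
    best_fit, best_score = None, -np.inf
    for params in grid:
        fit = em_fit(train, model_kind, params, config=config, N=N)
        if heldout:
            score = sum(
                forward_filter(seq, fit.model, params)[1] for seq in heldout
            )
        else:
            score = fit.loglik
        table.append(
            {
                "rho": params.rho,
                "c": params.c,
                "d": params.d,
                "alpha": params.alpha,
                "loglik": fit.loglik,
                "score": float(score),
            }
        )
        if score > best_score:
            best_fit, best_score = fit, score
    return best_fit, table


# ---------------------------------------------------------------------------
# prediction


def predict_accuracy(
    belief_prev: BeliefState,
    y_prev: Optional[float],
    z_prev: Optional[int],
    z_next: int,
    m_next: int,
    model: TransitionModel,
    irt: IRTParams,
) -> float:
    """One-step-ahead expected block accuracy.

    Propagates the belief through the transition rows driven by the previous
    block, then averages the ICC at the next presented level over the
    predicted belief.  ``m_next`` does not change the expectation of the
    accuracy fraction; it is accepted for interface symmetry.
    """
    bel = belief_prev.probs
    pred = np.zeros(model.N)
    for x in range(1, model.N + 1):
        if bel[x - 1] > 0.0:
            pred += bel[x - 1] * transition_row(model, x, z_prev, y_prev)
    grid = np.arange(1, model.N + 1)
    return float(pred @ icc(grid, z_next, irt))


def skill_trajectory(
    seq: ParticipantSequence, model: TransitionModel, irt: IRTParams
) -> np.ndarray:
    """Per-block point estimate of skill: argmax of the filtered belief.

    Ties break toward the lower skill level (conservative placement).
    """
    beliefs, _ = forward_filter(seq, model, irt)
    return np.array([b.map_skill for b in beliefs], dtype=int)


class HMMPredictor:
    """One-step-ahead accuracy predictions from a fitted IOHMM.

    The prediction for block t uses the belief after blocks 1..t-1 only;
    block 1 is predicted from the initial distribution pi.
    """

    def __init__(self, model: TransitionModel, irt: IRTParams):
        self.model = model
        self.irt = irt

    def predict_sequence(self, seq: ParticipantSequence) -> np.ndarray:
        N = self.model.N
        grid = np.arange(1, N + 1)
        lik, _, _ = _emission_table(seq, self.irt, N)
        preds = np.empty(len(seq.blocks))
        bel = self.model.pi.copy()
        for t, blk in enumerate(seq.blocks):
            preds[t] = float(bel @ icc(grid, blk.z, self.irt))
            # posterior update with the observation at t
            post = bel * lik[t]
            s = post.sum()
            if s <= 0:
                raise FloatingPointError(
                    f"belief degenerated at block {blk.t} of {seq.participant_id}"
                )
            post /= s
            if t < len(seq.blocks) - 1:
                M = build_transition_matrix(self.model, blk.z, blk.y_frac)
                bel = M.T @ post
        return preds

    def describe(self) -> str:
        kind = "model1" if isinstance(self.model, TransitionModel1) else "model2"
        return f"iohmm-{kind}"
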