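"""Observation model for block-level N-back performance.

A training *block* is a 2-3 minute stretch of continuous play at (nominally)
constant n-level.  Performance in a block is summarised by ``accBlock``,

    accBlock = TP / (TP + FN + FP),

hits over hits-plus-misses-plus-false-alarms (correct rejections are not
counted).  The probability that a participant with latent skill ``x`` answers
a single item correctly at presented n-level ``z`` follows a four-parameter
logistic item characteristic curve (4PL ICC)

    a(x, z) = c + (d - c) / (1 + exp(-rho * (x - z)))

with discrimination ``rho``, guessing floor ``c`` and carelessness ceiling
``d``.  Within a block the realised ability is a single beta-distributed draw
``a_hat ~ Beta(alpha * a, alpha * (1 - a))`` shared by all trials, which
couples responses within the block (attention / fatigue).  Marginalising the
binomial success count over ``a_hat`` yields a beta-binomial emission
distribution; ``alpha`` controls its concentration around the ICC value and
the binomial is recovered as ``alpha -> inf``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import betabinom

__all__ = [
    "TrialCounts",
    "BlockRecord",
    "ParticipantSequence",
    "IRTParams",
    "UndefinedAccuracyError",
    "acc_block",
    "icc",
    "emission_log_prob",
    "emission_log_prob_states",
    "bin_accuracy",
    "ICC_CLAMP_EPS",
]

#: mean of the realised-ability beta is clamped to [eps, 1-eps] so the beta
#: parameters stay strictly positive when c = 0 or d = 1.
ICC_CLAMP_EPS = 1e-6


class UndefinedAccuracyError(ValueError):
    """accBlock has a zero denominator: no targets and no false alarms."""


@dataclass(frozen=True)
class TrialCounts:
    """Outcome counts for one block: hits, misses, false alarms."""

    tp: int
    fn: int
    fp: int
    n_trials: int
    n_targets: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.n_trials, self.n_targets) < 0:
            raise ValueError("trial counts must be non-negative")
        if self.tp + self.fn != self.n_targets:
            raise ValueError("tp + fn must equal n_targets")
        if self.fp > self.n_trials - self.n_targets:
            raise ValueError("fp exceeds the number of non-target trials")
        if self.n_targets > self.n_trials:
            raise ValueError("n_targets exceeds n_trials")


@dataclass(frozen=True)
class BlockRecord:
    """One block of a training sequence.

    ``y_frac`` is the observed block accuracy (``accBlock``); ``y_succ`` is
    the effective success count ``round(y_frac * n_targets)`` used by the
    beta-binomial emission, which keeps the count on the binomial support
    {0..m} while preserving the false-alarm penalty of accBlock.  Blocks with
    an undefined accuracy carry ``y_frac = None``.
    """

    t: int
    session: int
    z: int
    counts: TrialCounts
    y_frac: Optional[float] = None
    y_succ: Optional[int] = None

    def __post_init__(self) -> None:
        if self.z < 1:
            raise ValueError("presented n-level must be >= 1")
        if self.t < 1:
            raise ValueError("block index is 1-based")
        denom = self.counts.tp + self.counts.fn + self.counts.fp
        if denom > 0:
            expected = acc_block(self.counts)
            y = self.y_frac if self.y_frac is not None else expected
            if abs(y - expected) > 1e-9:
                raise ValueError("y_frac inconsistent with counts")
            object.__setattr__(self, "y_frac", expected)
            object.__setattr__(
                self, "y_succ", int(round(expected * self.counts.n_targets))
            )
        else:
            object.__setattr__(self, "y_frac", None)
            object.__setattr__(self, "y_succ", None)

    @property
    def scorable(self) -> bool:
        return self.y_frac is not None


@dataclass
class ParticipantSequence:
    """Ordered blocks for one participant; ``true_skill`` only for simulated data."""

    participant_id: str
    blocks: list[BlockRecord]
    true_skill: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("a participant sequence must be non-empty")
        ts = [b.t for b in self.blocks]
        if any(b >= a for a, b in zip(ts[1:], ts[:-1])):
            raise ValueError("block indices must be strictly increasing")
        if self.true_skill is not None and len(self.true_skill) != len(self.blocks):
            raise ValueError("true_skill length must match blocks")

    def __len__(self) -> int:
        return len(self.blocks)


@dataclass(frozen=True)
class IRTParams:
    """Static item parameters of the 4PL ICC plus the beta concentration."""

    rho: float = 1.6
    c: float = 0.0
    d: float = 1.0
    alpha: float = 11.56

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise ValueError("discrimination rho must be positive")
        if not (0.0 <= self.c < 1.0):
            raise ValueError("guessing floor c must lie in [0, 1)")
        if not (self.c < self.d <= 1.0):
            raise ValueError("ceiling d must lie in (c, 1]")
        if not self.alpha > 0:
            raise ValueError("concentration alpha must be positive")


def acc_block(counts: TrialCounts) -> float:
    """Block accuracy TP / (TP + FN + FP).

    Raises :class:`UndefinedAccuracyError` when the denominator is zero
    (no targets presented and no false alarms); caller policy decides how to
    treat such blocks -- model fitting drops them.
    """
    denom = counts.tp + counts.fn + counts.fp
    if denom == 0:
        raise UndefinedAccuracyError(
            "accBlock undefined: no targets and no false alarms in block"
        )
    return counts.tp / denom


def icc(x, z, params: IRTParams):
    """4PL item characteristic curve c + (d-c) / (1 + exp(-rho (x - z))).

    Accepts scalars or arrays for ``x`` and ``z`` (broadcast).
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    out = params.c + (params.d - params.c) / (1.0 + np.exp(-params.rho * (x - z)))
    return out if out.ndim else float(out)


def _beta_params(a, alpha: float):
    a = np.clip(a, ICC_CLAMP_EPS, 1.0 - ICC_CLAMP_EPS)
    return alpha * a, alpha * (1.0 - a)


def emission_log_prob(y_succ: int, m: int, x, z, params: IRTParams):
    """Log beta-binomial probability of ``y_succ`` successes out of ``m`` targets.

    The success count is marginalised over the realised ability
    ``a_hat ~ Beta(alpha a, alpha (1-a))`` with ``a = icc(x, z)``; all
    arithmetic is done through log-gamma (scipy's betabinom).
    """
    if m < 1:
        raise ValueError("number of targets m must be >= 1")
    if not 0 <= y_succ <= m:
        raise ValueError("success count must lie in [0, m]")
    a, b = _beta_params(icc(x, z, params), params.alpha)
    out = betabinom.logpmf(y_succ, m, a, b)
    return out if np.ndim(out) else float(out)


def emission_log_prob_states(
    y_succ: int, m: int, z: int, params: IRTParams, n_states: int
) -> np.ndarray:
    """Emission log-likelihood over the latent skill grid {1..n_states}."""
    x = np.arange(1, n_states + 1)
    return np.asarray(emission_log_prob(y_succ, m, x, z, params))


def bin_accuracy(y_frac: float) -> int:
    """Index (1..10) of the evenly spaced accuracy bin containing ``y_frac``.

    Bins are half-open [(k-1)/10, k/10) except the top bin, which is closed
    so that y = 1 falls in bin 10.
    """
    if not 0.0 <= y_frac <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    return min(int(math.floor(y_frac * 10.0)) + 1, 10)
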