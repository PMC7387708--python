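"""Synthetic adaptive N-back training data with known ground-truth skill.

Simulated participants play blocks of an N-back task in which 30% of trials
are targets.  Per-block performance is generated from the same 4PL-ICC /
beta-binomial observation model the trackers assume: the realised per-block
ability is a beta draw around the ICC value, hits are binomial in the number
of targets, and false alarms arrive at a small constant rate on non-target
trials (the false-alarm process is deliberately outside the HMM emission, so
the accBlock / binomial-support reconciliation is exercised).

The presented n-level is driven by one of seven adaptive progression
algorithms: three trial-level staircases (level changes *within* a block on
runs of consecutive hits or errors), three mini-block rules (level changes
*between* 40-trial blocks on total error counts, one of which resets to
2-back at each session start), and a blockwise accuracy rule (up above 85%,
down below 70%).

Latent skill evolves between blocks according to a participant archetype:
a steady learner, a non-learner, an oscillator that plateaus and flips
between two adjacent levels, or an ``hmm_generative`` profile whose skill
follows a supplied tied transition model exactly (used for parameter-recovery
studies).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
from scipy.stats import beta as beta_dist

from .emission import (
    ICC_CLAMP_EPS,
    BlockRecord,
    IRTParams,
    ParticipantSequence,
    TrialCounts,
    acc_block,
    icc,
)
from .hmm import TransitionModel, TransitionModel1, TransitionModel2, transition_row

__all__ = [
    "AlgorithmSpec",
    "AlgorithmState",
    "BlockOutcome",
    "ParticipantProfile",
    "SessionPlan",
    "ALGORITHMS",
    "get_algorithm",
    "step_algorithm",
    "begin_session",
    "update_trial",
    "simulate_block",
    "simulate_cohort",
    "demo_history_model2",
]


@dataclass(frozen=True)
class AlgorithmSpec:
    """One adaptive progression rule.

    ``structure`` is ``within_block`` for trial-level staircases and
    ``between_block`` for mini-block / blockwise rules.  Threshold fields are
    used according to the rule family; unused ones stay ``None``.
    """

    name: str
    structure: str
    up_hits: Optional[int] = None  # staircase: consecutive hits to level up
    down_errors: Optional[int] = None  # staircase: consecutive errors to level down
    up_max_errors: Optional[int] = None  # mini-block: level up if errors < this
    down_min_errors: Optional[int] = None  # mini-block: level down if errors > this
    up_acc: Optional[float] = None  # blockwise: level up if accuracy > this
    down_acc: Optional[float] = None  # blockwise: level down if accuracy < this
    consecutive_blocks: int = 1  # blockwise: blocks in a row required
    reset_each_session: bool = False
    reset_level: int = 2


ALGORITHMS: dict[str, AlgorithmSpec] = {
    "staircase_classic": AlgorithmSpec(
        "staircase_classic", "within_block", up_hits=3, down_errors=2
    ),
    "staircase_moderate": AlgorithmSpec(
        "staircase_moderate", "within_block", up_hits=3, down_errors=3
    ),
    "staircase_difficult": AlgorithmSpec(
        "staircase_difficult", "within_block", up_hits=6, down_errors=2
    ),
    "miniblock_moderate": AlgorithmSpec(
        "miniblock_moderate", "between_block", up_max_errors=6, down_min_errors=8
    ),
    "miniblock_difficult": AlgorithmSpec(
        "miniblock_difficult", "between_block", up_max_errors=3, down_min_errors=6
    ),
    "miniblock_reset": AlgorithmSpec(
        "miniblock_reset",
        "between_block",
        up_max_errors=3,
        down_min_errors=6,
        reset_each_session=True,
    ),
    "blockwise_85_70": AlgorithmSpec(
        "blockwise_85_70", "between_block", up_acc=0.85, down_acc=0.70
    ),
}


def get_algorithm(name: Union[str, AlgorithmSpec]) -> AlgorithmSpec:
    if isinstance(name, AlgorithmSpec):
        return name
    try:
        return ALGORITHMS[name]
    except KeyError:
        raise ValueError(
            f"unknown algorithm {name!r}; known: {sorted(ALGORITHMS)}"
        ) from None


@dataclass
class AlgorithmState:
    """Mutable progression state: current level plus streak counters."""

    level: int = 2
    max_level: int = 10
    consec_hits: int = 0
    consec_errors: int = 0
    streak_above: int = 0
    streak_below: int = 0

    def _move(self, delta: int) -> None:
        self.level = min(max(self.level + delta, 1), self.max_level)
        self.consec_hits = 0
        self.consec_errors = 0
        self.streak_above = 0
        self.streak_below = 0


@dataclass(frozen=True)
class BlockOutcome:
    """Summary of one finished block, as the progression rules see it.

    ``errors`` counts misses plus false alarms; ``trial_results`` (staircase
    rules only) is the per-trial stream of 'hit' / 'error' / 'cr' events.
    """

    errors: int
    accuracy: Optional[float] = None
    trial_results: Optional[Sequence[str]] = None


def update_trial(alg: AlgorithmSpec, state: AlgorithmState, result: str) -> None:
    """Advance a within-block staircase by one trial.

    'hit' = collected target, 'error' = miss or false alarm, 'cr' = correct
    rejection (neutral: it breaks neither streak).  Streaks reset on the
    opposing event and on any level change.
    """
    if result == "hit":
        state.consec_hits += 1
        state.consec_errors = 0
        if state.consec_hits >= alg.up_hits:
            state._move(+1)
    elif result == "error":
        state.consec_errors += 1
        state.consec_hits = 0
        if state.consec_errors >= alg.down_errors:
            state._move(-1)
    elif result != "cr":
        raise ValueError(f"unknown trial result {result!r}")


def begin_session(alg: AlgorithmSpec, state: AlgorithmState) -> None:
    """Apply session-start behaviour (the reset rule starts sessions at 2-back)."""
    if alg.reset_each_session:
        state.level = min(alg.reset_level, state.max_level)
        state.consec_hits = state.consec_errors = 0
        state.streak_above = state.streak_below = 0


def step_algorithm(
    alg: Union[str, AlgorithmSpec],
    state: AlgorithmState,
    outcome: Optional[BlockOutcome] = None,
    session_start: bool = False,
) -> int:
    """Next presented n-level after a block outcome (or a session boundary)."""
    alg = get_algorithm(alg)
    if session_start:
        begin_session(alg, state)
        return state.level
    if outcome is None:
        raise ValueError("a block outcome is required unless session_start=True")

    if alg.structure == "within_block":
        for result in outcome.trial_results or ():
            update_trial(alg, state, result)
    elif alg.up_max_errors is not None:  # mini-block rules
        if outcome.errors < alg.up_max_errors:
            state._move(+1)
        elif outcome.errors > alg.down_min_errors:
            state._move(-1)
    else:  # blockwise accuracy rule
        acc = outcome.accuracy
        if acc is not None and acc > alg.up_acc:
            state.streak_above += 1
            state.streak_below = 0
        elif acc is not None and acc < alg.down_acc:
            state.streak_below += 1
            state.streak_above = 0
        else:
            state.streak_above = state.streak_below = 0
        if state.streak_above >= alg.consecutive_blocks:
            state._move(+1)
        elif state.streak_below >= alg.consecutive_blocks:
            state._move(-1)
    return state.level


# ---------------------------------------------------------------------------
# participant profiles and session plans


@dataclass(frozen=True)
class ParticipantProfile:
    """Latent-skill dynamics archetype plus the generative observation model.

    Archetypes: ``steady_learner`` climbs at ``learn_rate`` per block toward
    ``plateau`` with occasional lapses; ``non_learner`` has constant skill;
    ``oscillator`` climbs to ``plateau`` then flips between ``plateau`` and
    ``plateau + 1`` with probability ``osc_prob``; ``hmm_generative`` follows
    the supplied tied ``transition_model`` exactly.
    """

    archetype: str = "steady_learner"
    irt: IRTParams = field(default_factory=IRTParams)
    fp_rate: float = 0.05
    start_skill: int = 2
    learn_rate: float = 0.03
    lapse_prob: float = 0.005
    plateau: int = 7
    osc_prob: float = 0.2
    max_skill: int = 10
    transition_model: Optional[TransitionModel] = None

    def __post_init__(self) -> None:
        known = {"steady_learner", "non_learner", "oscillator", "hmm_generative"}
        if self.archetype not in known:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        for p in (self.fp_rate, self.learn_rate, self.lapse_prob, self.osc_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("profile probabilities must lie in [0, 1]")
        if self.archetype == "hmm_generative" and self.transition_model is None:
            raise ValueError("hmm_generative profiles need a transition_model")


@dataclass(frozen=True)
class SessionPlan:
    """Shape of a training course: 18 sessions of 40-trial blocks, 30% targets."""

    n_sessions: int = 18
    blocks_per_session: int = 8
    trials_per_block: int = 40
    target_rate: float = 0.30
    start_level: int = 2
    max_level: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.target_rate < 1.0:
            raise ValueError("target_rate must lie in (0, 1)")
        if self.trials_per_block < 1:
            raise ValueError("blocks must contain at least one trial")


def _update_skill(
    profile: ParticipantProfile,
    skill: int,
    y_prev: Optional[float],
    z_prev: int,
    rng: np.random.Generator,
) -> int:
    if profile.archetype == "non_learner":
        return skill
    if profile.archetype == "steady_learner":
        if skill < min(profile.plateau, profile.max_skill) and rng.random() < profile.learn_rate:
            return skill + 1
        if skill > 1 and rng.random() < profile.lapse_prob:
            return skill - 1
        return skill
    if profile.archetype == "oscillator":
        hi = min(profile.plateau + 1, profile.max_skill)
        if skill < profile.plateau and rng.random() < profile.learn_rate:
            return skill + 1
        if skill >= profile.plateau and rng.random() < profile.osc_prob:
            return hi if skill == profile.plateau else profile.plateau
        return skill
    # hmm_generative
    row = transition_row(profile.transition_model, skill, z_prev, y_prev)
    return int(rng.choice(len(row), p=row)) + 1


def _realized_ability(skill: int, z: int, irt: IRTParams, u: float) -> float:
    """Quantile-preserving realised ability: a shared uniform per block.

    At constant z this is exactly a Beta(alpha a, alpha (1-a)) draw; when a
    staircase changes the level mid-block, the same quantile is mapped
    through the beta at the new ICC mean, so the block keeps one coherent
    attention state.
    """
    a = float(np.clip(icc(skill, z, irt), ICC_CLAMP_EPS, 1.0 - ICC_CLAMP_EPS))
    return float(
        beta_dist.ppf(u, irt.alpha * a, irt.alpha * (1.0 - a))
    )


def simulate_block(
    skill: int,
    z: int,
    plan: SessionPlan,
    profile: ParticipantProfile,
    rng: np.random.Generator,
) -> tuple[TrialCounts, float]:
    """One constant-level block: beta-binomial hits plus constant-rate false alarms.

    Returns the trial counts and the realised ability that generated them.
    """
    n = plan.trials_per_block
    m = int(rng.binomial(n, plan.target_rate))
    a_hat = _realized_ability(skill, z, profile.irt, rng.uniform())
    tp = int(rng.binomial(m, a_hat)) if m > 0 else 0
    fp = int(rng.binomial(n - m, profile.fp_rate)) if n > m else 0
    counts = TrialCounts(tp=tp, fn=m - tp, fp=fp, n_trials=n, n_targets=m)
    return counts, a_hat


def _simulate_staircase_block(
    skill: int,
    alg: AlgorithmSpec,
    state: AlgorithmState,
    plan: SessionPlan,
    profile: ParticipantProfile,
    rng: np.random.Generator,
) -> tuple[TrialCounts, int, list[str]]:
    """One trial-level block under a within-block staircase.

    The presented level can change mid-block; the emitted record's z is the
    level at block start.  Returns (counts, z_start, trial results).
    """
    z_start = state.level
    u = rng.uniform()
    ability_cache: dict[int, float] = {}
    tp = fn = fp = m = 0
    results: list[str] = []
    for _ in range(plan.trials_per_block):
        z_cur = state.level
        if rng.random() < plan.target_rate:
            m += 1
            a_hat = ability_cache.get(z_cur)
            if a_hat is None:
                a_hat = _realized_ability(skill, z_cur, profile.irt, u)
                ability_cache[z_cur] = a_hat
            if rng.random() < a_hat:
                tp += 1
                results.append("hit")
            else:
                fn += 1
                results.append("error")
        else:
            if rng.random() < profile.fp_rate:
                fp += 1
                results.append("error")
            else:
                results.append("cr")
        update_trial(alg, state, results[-1])
    counts = TrialCounts(
        tp=tp, fn=fn, fp=fp, n_trials=plan.trials_per_block, n_targets=m
    )
    return counts, z_start, results


def simulate_cohort(
    n_participants: int,
    plan: Optional[SessionPlan] = None,
    profile: Union[ParticipantProfile, Sequence[ParticipantProfile], None] = None,
    algorithm: Union[str, AlgorithmSpec] = "blockwise_85_70",
    seed: int = 0,
    id_prefix: str = "SIM",
) -> list[ParticipantSequence]:
    """Simulate a cohort; deterministic in ``seed``; true skill recorded per block."""
    if n_participants < 1:
        raise ValueError("need at least one participant")
    plan = plan or SessionPlan()
    alg = get_algorithm(algorithm)
    if profile is None:
        profile = ParticipantProfile()
    profiles = (
        list(profile)
        if isinstance(profile, (list, tuple))
        else [profile] * n_participants
    )
    if len(profiles) != n_participants:
        raise ValueError("one profile per participant (or a single shared profile)")

    streams = np.random.SeedSequence(seed).spawn(n_participants)
    cohort: list[ParticipantSequence] = []
    for i, (prof, ss) in enumerate(zip(profiles, streams)):
        rng = np.random.default_rng(ss)
        state = AlgorithmState(level=plan.start_level, max_level=plan.max_level)
        skill = min(max(prof.start_skill, 1), prof.max_skill)
        blocks: list[BlockRecord] = []
        true_skill: list[int] = []
        t = 0
        for session in range(1, plan.n_sessions + 1):
            begin_session(alg, state)
            for _ in range(plan.blocks_per_session):
                t += 1
                if alg.structure == "within_block":
                    counts, z, results = _simulate_staircase_block(
                        skill, alg, state, plan, prof, rng
                    )
                    outcome = None  # staircase already stepped trial-by-trial
                else:
                    z = state.level
                    counts, _ = simulate_block(skill, z, plan, prof, rng)
                    try:
                        acc = acc_block(counts)
                    except ValueError:
                        acc = None
                    outcome = BlockOutcome(
                        errors=counts.fn + counts.fp, accuracy=acc
                    )
                blocks.append(BlockRecord(t=t, session=session, z=z, counts=counts))
                true_skill.append(skill)
                if outcome is not None:
                    step_algorithm(alg, state, outcome)
                skill = _update_skill(prof, skill, blocks[-1].y_frac, z, rng)
                skill = min(max(skill, 1), prof.max_skill)
        cohort.append(
            ParticipantSequence(
                participant_id=f"{id_prefix}{i:04d}",
                blocks=blocks,
                true_skill=true_skill,
            )
        )
    return cohort


def demo_history_model2(N: int = 10) -> TransitionModel2:
    """A strongly history-dependent tied transition tensor.

    The propensity to move up grows with the previous block's accuracy bin
    and is largest when the presented level sat above the destination skill
    (the participant was being stretched); the propensity to move down
    mirrors it.  Useful for generating data on which the history-driven
    model demonstrably out-predicts the universal one.
    """
    q = np.zeros((3, 5, 10))
    bins = (np.arange(10) + 0.5) / 10.0  # bin centres
    for j, dz in enumerate(range(-2, 3)):
        stretch = (dz + 2) / 4.0  # 0 when presented far below, 1 far above
        q[2, j, :] = 0.02 + 0.55 * bins * (0.4 + 0.6 * stretch)  # up
        q[0, j, :] = 0.02 + 0.45 * (1.0 - bins) * (1.0 - 0.5 * stretch)  # down
        q[1, j, :] = 0.8  # stay
    pi = np.full(N, 1.0 / N)
    return TransitionModel2(q / q.max(), pi, N)
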