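import numpy as np
import pytest

import skilltrack as st


@pytest.fixture
def irt_default() -> st.IRTParams:
    return st.IRTParams(rho=1.6, c=0.0, d=1.0, alpha=11.56)


@pytest.fixture
def model1_small() -> st.TransitionModel1:
    """Three-state universal transition model for enumeration oracles."""
    pi = np.array([0.5, 0.3, 0.2])
    return st.TransitionModel1(0.15, 0.7, 0.15, pi, N=3)


@pytest.fixture
def model2_small() -> st.TransitionModel2:
    """Three-state history-driven model with a structured, asymmetric tensor."""
    rng = np.random.default_rng(42)
    q = 0.05 + rng.uniform(size=(3, 5, 10))
    pi = np.array([0.4, 0.35, 0.25])
    return st.TransitionModel2(q / q.max(), pi, N=3)


def make_tiny_sequence(z_levels, y_succ, m=10, n_trials=30):
    """Hand-build a short ParticipantSequence with exact success counts."""
    blocks = []
    for t, (z, y) in enumerate(zip(z_levels, y_succ), start=1):
        counts = st.TrialCounts(tp=y, fn=m - y, fp=0, n_trials=n_trials, n_targets=m)
        blocks.append(st.BlockRecord(t=t, session=1, z=z, counts=counts))
    return st.ParticipantSequence(participant_id="TINY", blocks=blocks)


@pytest.fixture
def tiny_seq():
    return make_tiny_sequence(z_levels=[2, 2, 3, 2], y_succ=[7, 9, 4, 8])
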