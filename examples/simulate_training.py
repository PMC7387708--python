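"""Simulate adaptive N-back training and inspect the generated session log.

A cohort of steady learners plays the mini-block-reset progression rule:
the presented n-level restarts at 2-back every session, so the presented
level repeatedly diverges from the participant's true skill -- the situation
a skill tracker is supposed to see through.
"""

import numpy as np

from skilltrack import ParticipantProfile, SessionPlan, simulate_cohort

plan = SessionPlan(n_sessions=6)  # 6 sessions x 8 blocks x 40 trials
profile = ParticipantProfile(archetype="steady_learner", start_skill=2, learn_rate=0.05)
cohort = simulate_cohort(10, plan=plan, profile=profile,
                         algorithm="miniblock_reset", seed=7)

n_blocks = sum(len(seq) for seq in cohort)
targets = sum(b.counts.n_targets for seq in cohort for b in seq.blocks)
trials = sum(b.counts.n_trials for seq in cohort for b in seq.blocks)
print(f"{len(cohort)} participants, {n_blocks} blocks, {trials} trials")
print(f"target-trial fraction: {targets / trials:.3f} (generator draws at 0.30)")

seq = cohort[0]
print(f"\nparticipant {seq.participant_id}, first two sessions:")
print(" t  sess  z  true_skill  accuracy")
for blk, skill in list(zip(seq.blocks, seq.true_skill))[:16]:
    acc = "  --" if blk.y_frac is None else f"{blk.y_frac:.2f}"
    print(f"{blk.t:3d} {blk.session:4d} {blk.z:3d} {skill:8d}      {acc}")

final_skill = np.mean([seq.true_skill[-1] for seq in cohort])
print(f"\nmean true skill after training: {final_skill:.2f} "
      f"(started at {profile.start_skill}; presented level resets to 2 each session)")
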