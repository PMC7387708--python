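"""Evaluation harness: train/test splits, per-participant MSE, pooled RMSE.

A model handle is anything with ``predict_sequence(seq) -> array`` returning
one-step-ahead predicted block accuracies (NaN where no prediction exists)
and optionally ``describe()``.  The headline metric is the pooled test RMSE
in percent: 100 x sqrt(mean over all scored blocks of the squared error
between predicted and observed block accuracy).  The per-participant MSE
breakdown is always reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .emission import ParticipantSequence

__all__ = ["EvaluationReport", "split_cohort", "score_model", "compare_models"]


@dataclass
class EvaluationReport:
    per_participant_mse: dict[str, float]
    pooled_rmse_pct: float
    n_blocks_scored: int
    n_blocks_excluded: int
    model: str = ""
    split: str = ""

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "split": self.split,
            "pooled_rmse_pct": self.pooled_rmse_pct,
            "n_blocks_scored": self.n_blocks_scored,
            "n_blocks_excluded": self.n_blocks_excluded,
            "per_participant_mse": dict(self.per_participant_mse),
        }


def split_cohort(
    cohort: Sequence[ParticipantSequence],
    mode: str = "fraction_80_20",
    seed: int = 0,
    test_fraction: float = 0.2,
) -> tuple[list[ParticipantSequence], list[ParticipantSequence]]:
    """Participant-level train/test split (a participant is never divided).

    ``fraction_80_20`` assigns floor(test_fraction * n) participants to the
    test set with the remainder to train, under a seeded permutation.
    """
    if len(cohort) < 2:
        raise ValueError("need at least two participants to split")
    if mode != "fraction_80_20":
        raise ValueError(f"unknown split mode {mode!r}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cohort))
    n_test = max(1, int(len(cohort) * test_fraction))
    test_idx = set(order[:n_test].tolist())
    train = [cohort[i] for i in range(len(cohort)) if i not in test_idx]
    test = [cohort[i] for i in range(len(cohort)) if i in test_idx]
    return train, test


def score_model(
    model_handle,
    test_cohort: Sequence[ParticipantSequence],
    include_first_block: bool = True,
    split: str = "",
) -> EvaluationReport:
    """Pooled RMSE% and per-participant MSE of one-step-ahead predictions.

    Blocks with an undefined observed accuracy or without a prediction are
    excluded and counted.  ``include_first_block=False`` additionally drops
    each participant's first block (predicted from the prior alone).
    """
    if not test_cohort:
        raise ValueError("test cohort is empty")
    per_mse: dict[str, float] = {}
    sq_sum, n_scored, n_excluded = 0.0, 0, 0
    for seq in test_cohort:
        preds = np.asarray(model_handle.predict_sequence(seq), dtype=float)
        if preds.shape != (len(seq.blocks),):
            raise ValueError("predictor must return one value per block")
        errs = []
        for t, blk in enumerate(seq.blocks):
            if t == 0 and not include_first_block:
                n_excluded += 1
                continue
            if blk.y_frac is None or not np.isfinite(preds[t]):
                n_excluded += 1
                continue
            errs.append((preds[t] - blk.y_frac) ** 2)
        if errs:
            per_mse[seq.participant_id] = float(np.mean(errs))
            sq_sum += float(np.sum(errs))
            n_scored += len(errs)
    if n_scored == 0:
        raise ValueError("no scorable blocks in the test cohort")
    describe = getattr(model_handle, "describe", None)
    return EvaluationReport(
        per_participant_mse=per_mse,
        pooled_rmse_pct=100.0 * math.sqrt(sq_sum / n_scored),
        n_blocks_scored=n_scored,
        n_blocks_excluded=n_excluded,
        model=describe() if describe else type(model_handle).__name__,
        split=split,
    )


def compare_models(
    handles: Sequence, test_cohort: Sequence[ParticipantSequence], **kwargs
) -> list[EvaluationReport]:
    """Score several model handles on the same test cohort."""
    return [score_model(h, test_cohort, **kwargs) for h in handles]
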