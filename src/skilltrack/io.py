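"""Session-log CSV and model JSON serialisation.

The session-log dialect is one row per block with columns
``participant_id, session, block, n_level, n_trials, n_targets, tp, fn, fp``
(UTF-8, header row, comma-separated).  Ground-truth skill for simulated
cohorts travels in a sidecar CSV with columns
``participant_id, block, true_skill``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .emission import BlockRecord, IRTParams, ParticipantSequence, TrialCounts
from .hmm import HMMFitResult, TransitionModel1, TransitionModel2
from .ukf import UKFFitResult, UKFParams

__all__ = [
    "SESSION_COLUMNS",
    "read_sessions_csv",
    "write_sessions_csv",
    "read_truth_csv",
    "write_truth_csv",
    "save_model_json",
    "load_model_json",
]

logger = logging.getLogger(__name__)

SESSION_COLUMNS = [
    "participant_id",
    "session",
    "block",
    "n_level",
    "n_trials",
    "n_targets",
    "tp",
    "fn",
    "fp",
]


def write_sessions_csv(
    cohort: Sequence[ParticipantSequence], path: Union[str, Path]
) -> None:
    rows = []
    for seq in cohort:
        for blk in seq.blocks:
            rows.append(
                {
                    "participant_id": seq.participant_id,
                    "session": blk.session,
                    "block": blk.t,
                    "n_level": blk.z,
                    "n_trials": blk.counts.n_trials,
                    "n_targets": blk.counts.n_targets,
                    "tp": blk.counts.tp,
                    "fn": blk.counts.fn,
                    "fp": blk.counts.fp,
                }
            )
    pd.DataFrame(rows, columns=SESSION_COLUMNS).to_csv(path, index=False)


def read_sessions_csv(path: Union[str, Path]) -> list[ParticipantSequence]:
    """Read a session log; validates count invariants per block.

    Blocks whose accuracy denominator is zero are kept (they stay in the
    record for audit) but carry an undefined accuracy; model fitting skips
    them with a logged notice.
    """
    df = pd.read_csv(path)
    missing = set(SESSION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"session CSV missing columns: {sorted(missing)}")
    cohort = []
    for pid, grp in df.groupby("participant_id", sort=False):
        grp = grp.sort_values("block")
        blocks = []
        for row in grp.itertuples(index=False):
            counts = TrialCounts(
                tp=int(row.tp),
                fn=int(row.fn),
                fp=int(row.fp),
                n_trials=int(row.n_trials),
                n_targets=int(row.n_targets),
            )
            blocks.append(
                BlockRecord(
                    t=int(row.block),
                    session=int(row.session),
                    z=int(row.n_level),
                    counts=counts,
                )
            )
        n_undef = sum(1 for b in blocks if b.y_frac is None)
        if n_undef:
            logger.warning(
                "participant %s: %d block(s) with undefined accuracy "
                "(no targets, no false alarms); they are not used in fitting",
                pid, n_undef,
            )
        cohort.append(ParticipantSequence(participant_id=str(pid), blocks=blocks))
    return cohort


def write_truth_csv(
    cohort: Sequence[ParticipantSequence], path: Union[str, Path]
) -> None:
    rows = []
    for seq in cohort:
        if seq.true_skill is None:
            raise ValueError(f"participant {seq.participant_id} has no true skill")
        for blk, s in zip(seq.blocks, seq.true_skill):
            rows.append(
                {"participant_id": seq.participant_id, "block": blk.t, "true_skill": s}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_truth_csv(
    path: Union[str, Path], cohort: Sequence[ParticipantSequence]
) -> None:
    """Attach ground-truth skill from a sidecar CSV to an existing cohort."""
    df = pd.read_csv(path)
    by_pid = {pid: grp for pid, grp in df.groupby("participant_id", sort=False)}
    for seq in cohort:
        grp = by_pid.get(seq.participant_id)
        if grp is None:
            raise ValueError(f"no truth rows for participant {seq.participant_id}")
        grp = grp.sort_values("block")
        if list(grp["block"]) != [b.t for b in seq.blocks]:
            raise ValueError(
                f"truth blocks do not match sequence for {seq.participant_id}"
            )
        seq.true_skill = [int(s) for s in grp["true_skill"]]


# ---------------------------------------------------------------------------
# model JSON


def save_model_json(
    fit: Union[HMMFitResult, UKFFitResult], path: Union[str, Path], seed: Optional[int] = None
) -> None:
    if isinstance(fit, HMMFitResult):
        payload = {
            "family": "iohmm",
            "model": fit.model.to_dict(),
            "irt": {
                "rho": fit.irt.rho,
                "c": fit.irt.c,
                "d": fit.irt.d,
                "alpha": fit.irt.alpha,
            },
            "fit": {
                "loglik_trace": fit.loglik_trace,
                "converged": fit.converged,
                "n_iterations": fit.n_iterations,
                "seed": seed,
            },
        }
    elif isinstance(fit, UKFFitResult):
        payload = {
            "family": "ukf",
            "params": fit.params.to_dict(),
            "fit": {
                "loglik_trace": fit.loglik_trace,
                "converged": fit.converged,
                "n_iterations": fit.n_iterations,
                "seed": seed,
            },
        }
    else:
        raise TypeError(f"cannot serialise {type(fit).__name__}")
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model_json(path: Union[str, Path]):
    """Load a fitted model; returns an HMMFitResult or UKFFitResult."""
    d = json.loads(Path(path).read_text())
    fit_meta = d.get("fit", {})
    if d.get("family") == "iohmm":
        md = d["model"]
        model = (
            TransitionModel1.from_dict(md)
            if md["kind"] == "model1"
            else TransitionModel2.from_dict(md)
        )
        return HMMFitResult(
            model=model,
            irt=IRTParams(**d["irt"]),
            loglik_trace=fit_meta.get("loglik_trace", []),
            converged=fit_meta.get("converged", False),
            n_iterations=fit_meta.get("n_iterations", 0),
        )
    if d.get("family") == "ukf":
        return UKFFitResult(
            params=UKFParams.from_dict(d["params"]),
            loglik_trace=fit_meta.get("loglik_trace", []),
            converged=fit_meta.get("converged", False),
            n_iterations=fit_meta.get("n_iterations", 0),
        )
    raise ValueError(f"unrecognised model file {path}")
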