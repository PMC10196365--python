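"""Trial-level raw-behavior derivatives.

Prediction errors (delta_t = X_t - B_t), belief updates
(U_t = B_{t+1} - B_t), empirical learning rates (U_t / delta_t clipped to
[0, 1]), absolute performance error (|B_t - mu_t|, deviation from the
hidden mean rather than the noisy outcome), trials-after-change-point
(TAC), trial exclusion rules, PE-magnitude bins, and the learning-rate
implied belief-precision measure (effective sample size of the outcomes
integrated into the current belief).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .observer import ModelTrajectory
from .task import TaskRun

RT_LIMIT_S = 3.0            # attention cutoff: responses slower than 3 s are invalid
RUN_INVALID_FRACTION = 0.25  # a run losing more than this fraction of trials is dropped


@dataclass
class BehaviorSession:
    """One subject's responses over a session, flat across runs.

    ``predictions`` are the logged bucket placements B_t (NaN = no
    response); ``valid`` marks trials usable for analysis.  ``run_index``
    and ``condition`` mirror the task runs trial-for-trial.
    """

    subject_id: str
    predictions: np.ndarray
    rt: np.ndarray
    run_index: np.ndarray
    condition: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    excluded: bool = False

    def __post_init__(self) -> None:
        self.predictions = np.asarray(self.predictions, dtype=float)
        self.rt = np.asarray(self.rt, dtype=float)
        self.run_index = np.asarray(self.run_index, dtype=int)
        self.condition = np.asarray(self.condition, dtype=object)
        if self.valid is None:
            self.valid = np.isfinite(self.predictions)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.predictions)
        if not (len(self.rt) == len(self.run_index) == len(self.condition) == len(self.valid) == n):
            raise ValueError("session fields must be equally long")

    @property
    def n_trials(self) -> int:
        return len(self.predictions)


def session_from_runs(
    subject_id: str,
    runs: list[TaskRun],
    predictions: np.ndarray,
    rt: np.ndarray | None = None,
) -> BehaviorSession:
    """Assemble a BehaviorSession aligned with a list of task runs."""
    run_index = np.concatenate([np.full(r.n_trials, r.run_index) for r in runs])
    condition = np.concatenate([np.full(r.n_trials, r.condition, dtype=object) for r in runs])
    predictions = np.asarray(predictions, dtype=float)
    if rt is None:
        rt = np.full(len(predictions), 0.5)
    return BehaviorSession(subject_id, predictions, rt, run_index, condition)


def prediction_errors(outcomes: np.ndarray, predictions: np.ndarray,
                      valid: np.ndarray | None = None) -> np.ndarray:
    """delta_t = X_t - B_t; NaN on invalid trials."""
    outcomes = np.asarray(outcomes, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if outcomes.shape != predictions.shape:
        raise ValueError("outcomes and predictions misaligned")
    pe = outcomes - predictions
    if valid is not None:
        pe = np.where(np.asarray(valid, dtype=bool), pe, np.nan)
    return pe


def performance_errors(means: np.ndarray, predictions: np.ndarray,
                       valid: np.ndarray | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Deviation of the prediction from the hidden generative mean.

    Returns ``(absolute, signed)``; the absolute series is the one used in
    all trajectory analyses.
    """
    means = np.asarray(means, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if means.shape != predictions.shape:
        raise ValueError("means and predictions misaligned")
    signed = predictions - means
    if valid is not None:
        signed = np.where(np.asarray(valid, dtype=bool), signed, np.nan)
    return np.abs(signed), signed


def belief_updates(predictions: np.ndarray, run_index: np.ndarray,
                   valid: np.ndarray | None = None) -> np.ndarray:
    """U_t = B_{t+1} - B_t within each run; NaN on the last trial of a run
    and wherever either endpoint is invalid."""
    predictions = np.asarray(predictions, dtype=float)
    run_index = np.asarray(run_index)
    updates = np.full(len(predictions), np.nan)
    same_run = run_index[:-1] == run_index[1:]
    updates[:-1] = np.where(same_run, predictions[1:] - predictions[:-1], np.nan)
    if valid is not None:
        valid = np.asarray(valid, dtype=bool)
        ok = np.zeros(len(predictions), dtype=bool)
        ok[:-1] = valid[:-1] & valid[1:]
        updates = np.where(ok, updates, np.nan)
    return updates


def learning_rates(updates: np.ndarray, pes: np.ndarray) -> np.ndarray:
    """Empirical learning rate alpha_t = U_t / delta_t, clipped to [0, 1].

    Rates above 1 round to 1 and below 0 round to 0; delta_t = 0 or a
    missing endpoint yields NaN (no information about updating speed).
    """
    updates = np.asarray(updates, dtype=float)
    pes = np.asarray(pes, dtype=float)
    if updates.shape != pes.shape:
        raise ValueError("updates and pes misaligned")
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = updates / pes
    alpha = np.where(pes == 0, np.nan, alpha)
    return np.clip(alpha, 0.0, 1.0)


def trials_after_changepoint(changepoint_flags: np.ndarray) -> np.ndarray:
    """TAC: 1 on each flagged trial, counting up until the next flag.

    Run starts must be flagged upstream, so the counter resets at run
    boundaries by construction.
    """
    flags = np.asarray(changepoint_flags, dtype=int)
    if len(flags) == 0:
        raise ValueError("empty changepoint flags")
    if flags[0] != 1:
        raise ValueError("first trial must be flagged as a phase start")
    idx = np.arange(len(flags))
    last_cp = np.maximum.accumulate(np.where(flags == 1, idx, -1))
    return idx - last_cp + 1


def belief_precision(alpha: np.ndarray, run_index: np.ndarray,
                     offset_variant: bool = False) -> np.ndarray:
    """Effective-sample-size belief precision implied by learning rates.

    Within each run the belief is an exponentially-reweighted average of
    past outcomes plus the run's founding belief: each trial's outcome
    enters with weight alpha_t while all existing weights shrink by
    (1 - alpha_t).  Precision is ESS = 1 / sum(w^2) over those sum-to-one
    weights: after a full update (alpha = 1) it is exactly 1; after
    alpha = 0 it is unchanged; under a constant moderate alpha it converges
    to (2 - alpha) / alpha.  Missing alphas propagate weights unchanged
    (treated as alpha = 0) and yield NaN precision on that trial.

    ``offset_variant`` reports ESS - 1 instead (precision 0 after a full
    update).
    """
    alpha = np.asarray(alpha, dtype=float)
    finite = np.isfinite(alpha)
    if np.any((alpha[finite] < 0) | (alpha[finite] > 1)):
        raise ValueError("learning rates must lie in [0, 1]")
    run_index = np.asarray(run_index)
    precision = np.full(len(alpha), np.nan)
    for run in pd.unique(run_index):
        sel = np.flatnonzero(run_index == run)
        weights = [1.0]  # unit weight on the run-start belief
        for i in sel:
            a = alpha[i]
            if not np.isfinite(a):
                continue
            weights = [w * (1.0 - a) for w in weights]
            weights.append(a)
            ess = 1.0 / sum(w * w for w in weights)
            precision[i] = ess - 1.0 if offset_variant else ess
    return precision


def apply_exclusions(
    session: BehaviorSession,
    rt_limit: float = RT_LIMIT_S,
    run_invalid_fraction: float = RUN_INVALID_FRACTION,
    drop_subject_on_lost_run: bool = True,
) -> BehaviorSession:
    """Apply the trial- and run-level inclusion criteria.

    Trials with RT above ``rt_limit`` seconds or without a response are
    invalid; a run with more than ``run_invalid_fraction`` invalid trials is
    dropped entirely, and by default a subject losing any run is flagged
    excluded (matching the study's inclusion criterion).
    """
    valid = session.valid & np.isfinite(session.predictions)
    valid &= ~(np.isfinite(session.rt) & (session.rt > rt_limit))
    valid &= np.isfinite(session.rt)
    excluded = False
    for run in pd.unique(session.run_index):
        sel = session.run_index == run
        if (~valid[sel]).mean() > run_invalid_fraction:
            valid[sel] = False
            excluded = excluded or drop_subject_on_lost_run
    return BehaviorSession(
        session.subject_id, session.predictions, session.rt,
        session.run_index, session.condition, valid, excluded,
    )


def build_trial_table(
    session: BehaviorSession,
    runs: list[TaskRun],
    trajectory: ModelTrajectory | None = None,
) -> pd.DataFrame:
    """Merge task, behavior, and (optionally) observer columns per trial."""
    outcomes = np.concatenate([r.outcomes for r in runs])
    means = np.concatenate([r.means for r in runs])
    flags = np.concatenate([r.changepoint_flags for r in runs])
    sigma = np.concatenate([np.full(r.n_trials, r.sigma_n) for r in runs])
    trial_index = np.concatenate([np.arange(1, r.n_trials + 1) for r in runs])
    if len(outcomes) != session.n_trials:
        raise ValueError("session misaligned with task runs")

    pe = prediction_errors(outcomes, session.predictions, session.valid)
    perf_abs, perf_signed = performance_errors(means, session.predictions, session.valid)
    updates = belief_updates(session.predictions, session.run_index, session.valid)
    alpha = learning_rates(updates, pe)
    tac = trials_after_changepoint(flags)
    precision = belief_precision(alpha, session.run_index)

    table = pd.DataFrame({
        "subject_id": session.subject_id,
        "run_index": session.run_index,
        "trial_index": trial_index,
        "condition": session.condition,
        "mean": means,
        "outcome": outcomes,
        "changepoint": flags,
        "sigma_n": sigma,
        "prediction": session.predictions,
        "rt": session.rt,
        "valid": session.valid.astype(int),
        "pe": pe,
        "update": updates,
        "learning_rate": alpha,
        "perf_error": perf_abs,
        "perf_error_signed": perf_signed,
        "tac": tac,
        "precision": precision,
    })
    if trajectory is not None:
        table["cpp"] = trajectory.cpp
        table["ru"] = trajectory.ru
        table["alpha_model"] = trajectory.alpha_model
    return table


def mean_lr_by_pe_magnitude(
    trials: pd.DataFrame, hi_cut: float = 50.0, lo_cut: float = 5.0
) -> pd.DataFrame:
    """Per-subject mean learning rate in the large- and small-|PE| bins.

    Returns a frame indexed by subject_id with columns ``lr_hi`` (|PE| >
    hi_cut) and ``lr_lo`` (|PE| < lo_cut); NaN where a subject has no
    qualifying trials.
    """
    t = trials
    abs_pe = t["pe"].abs()
    hi = t.loc[abs_pe > hi_cut].groupby("subject_id")["learning_rate"].mean()
    lo = t.loc[abs_pe < lo_cut].groupby("subject_id")["learning_rate"].mean()
    out = pd.DataFrame({"lr_hi": hi, "lr_lo": lo})
    return out.reindex(pd.unique(t["subject_id"]))
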