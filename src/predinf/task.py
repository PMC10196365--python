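"""Helicopter-task stimulus generation.

The task is a change-point predictive-inference ("helicopter") paradigm: on
each trial an outcome (bag-drop location) is drawn from a Gaussian centered
on a hidden mean (the helicopter) on a 0-100 scale.  The mean is
piecewise-constant and resets to a fresh uniform draw with per-trial hazard
H = 0.125.  Outcome noise is manipulated between runs: low (SD 3.33) or
high (SD 8.33).  A session is 4 runs x 70 trials, two runs per noise
condition in randomized order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

LOW, HIGH = "low", "high"

#: columns of the trial CSV dialect shared across the package
TRIAL_COLUMNS = [
    "subject_id", "run_index", "trial_index", "condition",
    "mean", "outcome", "changepoint", "sigma_n",
]


@dataclass
class TaskConfig:
    """Generative configuration of the helicopter task.

    ``hazard`` is the per-trial change-point probability; ``mean_margin``
    restricts generative means to the central part of the scale (default
    [20, 80]) so that boundary truncation does not distort outcome SDs.
    ``constrained`` turns on rejection sampling of mean sequences until the
    number of stable phases per run falls inside ``phase_count_range``.
    """

    n_runs: int = 4
    trials_per_run: int = 70
    hazard: float = 0.125
    noise_sd_low: float = 3.33
    noise_sd_high: float = 8.33
    scale_min: float = 0.0
    scale_max: float = 100.0
    mean_margin: float = 0.2
    phase_count_range: tuple[int, int] = (4, 6)
    constrained: bool = False
    max_rejection_attempts: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        width = self.scale_max - self.scale_min
        if not 0.0 <= self.hazard <= 1.0:
            raise ValueError(f"hazard must lie in [0, 1], got {self.hazard}")
        if width <= 0:
            raise ValueError("scale_max must exceed scale_min")
        if not (0 < self.noise_sd_low < width and 0 < self.noise_sd_high < width):
            raise ValueError("noise SDs must be positive and smaller than the scale width")
        if self.trials_per_run < 2:
            raise ValueError("trials_per_run must be at least 2")
        if self.phase_count_range[0] < 1 or self.phase_count_range[0] > self.phase_count_range[1]:
            raise ValueError(f"invalid phase_count_range {self.phase_count_range}")
        if not 0.0 <= self.mean_margin < 0.5:
            raise ValueError("mean_margin must lie in [0, 0.5)")

    @property
    def scale_width(self) -> float:
        return self.scale_max - self.scale_min

    @property
    def mean_bounds(self) -> tuple[float, float]:
        pad = self.mean_margin * self.scale_width
        return self.scale_min + pad, self.scale_max - pad

    def sigma_for(self, condition: str) -> float:
        if condition == LOW:
            return self.noise_sd_low
        if condition == HIGH:
            return self.noise_sd_high
        raise ValueError(f"unknown condition {condition!r}")


@dataclass
class TaskRun:
    """One 70-trial run: generative means, outcomes, and change-point flags.

    ``changepoint_flags[t]`` is 1 on the first trial of every stable phase,
    including the first trial of the run.
    """

    run_index: int
    condition: str
    means: np.ndarray
    outcomes: np.ndarray
    changepoint_flags: np.ndarray
    sigma_n: float

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.outcomes = np.asarray(self.outcomes, dtype=float)
        self.changepoint_flags = np.asarray(self.changepoint_flags, dtype=int)
        if not (len(self.means) == len(self.outcomes) == len(self.changepoint_flags)):
            raise ValueError("means, outcomes and changepoint_flags must be equally long")

    @property
    def n_trials(self) -> int:
        return len(self.means)

    @property
    def n_phases(self) -> int:
        return int(self.changepoint_flags.sum())


class InfeasibleTaskConfig(RuntimeError):
    """Rejection sampling could not satisfy the phase-count constraint."""


def sample_mean_sequence(
    config: TaskConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a piecewise-constant mean sequence for one run.

    The first trial's mean is uniform on the allowed mean interval; on every
    later trial the mean resets, independently with probability ``hazard``,
    to a fresh uniform draw.  In constrained mode the whole sequence is
    rejection-sampled until the number of stable phases lies in
    ``phase_count_range``.

    Returns ``(means, changepoint_flags)``; the first trial is always
    flagged.
    """
    lo, hi = config.mean_bounds
    n = config.trials_per_run
    attempts = config.max_rejection_attempts if config.constrained else 1
    for _ in range(attempts):
        flags = np.zeros(n, dtype=int)
        flags[0] = 1
        flags[1:] = rng.random(n - 1) < config.hazard
        # one uniform mean per phase, held constant until the next reset
        phase_id = np.cumsum(flags) - 1
        phase_means = rng.uniform(lo, hi, size=phase_id[-1] + 1)
        means = phase_means[phase_id]
        n_phases = int(flags.sum())
        if not config.constrained:
            return means, flags
        if config.phase_count_range[0] <= n_phases <= config.phase_count_range[1]:
            return means, flags
    raise InfeasibleTaskConfig(
        f"no mean sequence with {config.phase_count_range} phases found in "
        f"{config.max_rejection_attempts} attempts (hazard={config.hazard}, "
        f"trials_per_run={config.trials_per_run})"
    )


def sample_outcomes(
    means: np.ndarray,
    sigma_n: float,
    config: TaskConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample outcomes X_t ~ Normal(mu_t, sigma_n^2), truncated to the scale.

    Truncation is by resampling (draws outside [scale_min, scale_max] are
    redrawn), never by clipping, so no point mass accumulates at the bounds.
    ``sigma_n = 0`` returns the means exactly.
    """
    means = np.asarray(means, dtype=float)
    if not np.all(np.isfinite(means)):
        raise ValueError("means must be finite")
    if sigma_n < 0 or not np.isfinite(sigma_n):
        raise ValueError(f"sigma_n must be finite and >= 0, got {sigma_n}")
    if sigma_n == 0:
        return means.copy()
    out = rng.normal(means, sigma_n)
    bad = (out < config.scale_min) | (out > config.scale_max)
    while bad.any():
        out[bad] = rng.normal(means[bad], sigma_n)
        bad = (out < config.scale_min) | (out > config.scale_max)
    return out


def generate_run(
    config: TaskConfig, run_index: int, condition: str, rng: np.random.Generator
) -> TaskRun:
    means, flags = sample_mean_sequence(config, rng)
    sigma = config.sigma_for(condition)
    outcomes = sample_outcomes(means, sigma, config, rng)
    return TaskRun(run_index, condition, means, outcomes, flags, sigma)


def generate_session(config: TaskConfig, rng: np.random.Generator) -> list[TaskRun]:
    """Generate one session: n_runs runs, half per noise condition, order shuffled."""
    if config.n_runs % 2:
        raise ValueError("n_runs must be even (equal split across noise conditions)")
    conditions = [LOW] * (config.n_runs // 2) + [HIGH] * (config.n_runs // 2)
    rng.shuffle(conditions)
    return [
        generate_run(config, i + 1, cond, rng) for i, cond in enumerate(conditions)
    ]


# ---------------------------------------------------------------------------
# serialization

def session_to_frame(runs: Iterable[TaskRun], subject_id: str = "") -> pd.DataFrame:
    """Flatten a session into the package's trial-table CSV dialect.

    ``run_index`` and ``trial_index`` are 1-based; ``subject_id`` is empty for
    pure stimulus streams.
    """
    rows = []
    for run in runs:
        rows.append(pd.DataFrame({
            "subject_id": subject_id,
            "run_index": run.run_index,
            "trial_index": np.arange(1, run.n_trials + 1),
            "condition": run.condition,
            "mean": run.means,
            "outcome": run.outcomes,
            "changepoint": run.changepoint_flags,
            "sigma_n": run.sigma_n,
        }))
    return pd.concat(rows, ignore_index=True)[TRIAL_COLUMNS]


def frame_to_session(frame: pd.DataFrame) -> list[TaskRun]:
    """Inverse of :func:`session_to_frame` (per subject)."""
    runs = []
    for run_index, grp in frame.groupby("run_index", sort=True):
        grp = grp.sort_values("trial_index")
        condition = grp["condition"].iloc[0]
        runs.append(TaskRun(
            run_index=int(run_index),
            condition=str(condition),
            means=grp["mean"].to_numpy(),
            outcomes=grp["outcome"].to_numpy(),
            changepoint_flags=grp["changepoint"].to_numpy(),
            sigma_n=float(grp["sigma_n"].iloc[0]),
        ))
    return runs


def write_session_csv(runs: Iterable[TaskRun], path, subject_id: str = "") -> None:
    # 17 significant digits so a write -> read round trip is bit-exact
    session_to_frame(runs, subject_id).to_csv(path, index=False, float_format="%.17g")


def read_session_csv(path) -> list[TaskRun]:
    return frame_to_session(pd.read_csv(path, keep_default_na=True,
                                        dtype={"subject_id": str},
                                        float_precision="round_trip"))


def task_config_to_dict(config: TaskConfig) -> dict:
    d = asdict(config)
    d["phase_count_range"] = list(config.phase_count_range)
    return d


def task_config_from_dict(d: dict) -> TaskConfig:
    d = dict(d)
    if "phase_count_range" in d:
        d["phase_count_range"] = tuple(d["phase_count_range"])
    return TaskConfig(**d)
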