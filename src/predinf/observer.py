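"""Reduced Bayesian observer for change-point predictive inference.

The observer tracks a single belief mean and two latent quantities:

* change-point probability (CPP, Omega): the posterior probability that the
  latest outcome was generated after a reset of the hidden mean, obtained by
  comparing a uniform "change" likelihood H/W against the Gaussian
  "no-change" predictive density of the prediction error;
* relative uncertainty (RU, tau): the share of predictive variance due to
  imprecision of the belief rather than outcome noise; tau decays as
  observations accumulate within a stable phase and rises after likely
  change points.

The normative learning rate combines both: a change point forces a full
update, and residual belief uncertainty scales up the update otherwise.
The observer can run generatively (ideal observer) or conditioned on a
subject's own predictions, in which case the subject's prediction is the
belief mean entering both the CPP computation and the tau update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .task import TaskRun

_SQRT_2PI = math.sqrt(2.0 * math.pi)

#: learning-rate compositions: "standard" is Omega + (1-Omega)*tau, bounded
#: in [0, 1]; "as_printed" is Omega + tau + Omega*tau clipped to [0, 1]
#: (kept for sensitivity analysis; it can exceed 1 before clipping).
LR_FORMS = ("standard", "as_printed")


@dataclass
class ObserverConfig:
    """Parameters of the reduced Bayesian observer.

    The hazard and noise SD are the true generative values of the task; the
    observer does not estimate them.  ``tau_init`` is the relative
    uncertainty at each run start (0.5 = a belief founded on effectively one
    observation).
    """

    hazard: float = 0.125
    scale_min: float = 0.0
    scale_max: float = 100.0
    tau_init: float = 0.5
    lr_form: str = "standard"

    def __post_init__(self) -> None:
        if not 0.0 <= self.hazard <= 1.0:
            raise ValueError(f"hazard must lie in [0, 1], got {self.hazard}")
        if not 0.0 <= self.tau_init < 1.0:
            raise ValueError(f"tau_init must lie in [0, 1), got {self.tau_init}")
        if self.scale_max <= self.scale_min:
            raise ValueError("scale_max must exceed scale_min")
        if self.lr_form not in LR_FORMS:
            raise ValueError(f"lr_form must be one of {LR_FORMS}")

    @property
    def scale_width(self) -> float:
        return self.scale_max - self.scale_min


@dataclass
class ModelTrajectory:
    """Trial-wise observer quantities aligned with a session's trials.

    ``ru[t]`` is the relative uncertainty holding *before* trial t's outcome
    is observed; ``cpp[t]`` and ``alpha_model[t]`` follow from that trial's
    prediction error.  Excluded trials carry NaN and propagate tau
    unchanged.
    """

    cpp: np.ndarray
    ru: np.ndarray
    alpha_model: np.ndarray
    predicted_update: np.ndarray


def change_point_probability(
    delta: float, tau: float, sigma_n: float, cfg: ObserverConfig
) -> float:
    """Posterior probability that prediction error ``delta`` follows a reset.

    Omega = H*(1/W) / (H*(1/W) + (1-H)*phi(delta; 0, sigma_pred^2)) with
    predictive variance sigma_pred^2 = sigma_n^2 / (1 - tau), which combines
    outcome noise with current belief uncertainty.
    """
    if not math.isfinite(delta):
        raise ValueError("delta must be finite")
    if not 0.0 <= tau < 1.0:
        raise ValueError(f"tau must lie in [0, 1), got {tau}")
    if sigma_n <= 0:
        raise ValueError("sigma_n must be positive")
    h = cfg.hazard
    if h == 0.0:
        return 0.0
    if h == 1.0:
        return 1.0
    sigma_pred = sigma_n / math.sqrt(1.0 - tau)
    z = delta / sigma_pred
    density = math.exp(-0.5 * z * z) / (sigma_pred * _SQRT_2PI)
    change = h / cfg.scale_width
    return change / (change + (1.0 - h) * density)


def update_relative_uncertainty(
    tau: float, omega: float, delta: float, sigma_n: float, cfg: ObserverConfig
) -> float:
    """Propagate relative uncertainty given this trial's CPP and error.

    The posterior belief variance N mixes the single-sample variance after a
    change (weight Omega), the decayed prior uncertainty absent a change
    (weight 1-Omega), and the variance contributed by uncertainty about
    whether a change occurred at all.  tau' = N / (N + sigma_n^2).
    """
    if not (math.isfinite(tau) and math.isfinite(omega) and math.isfinite(delta)):
        raise ValueError("tau, omega and delta must be finite")
    if not 0.0 <= tau < 1.0:
        raise ValueError(f"tau must lie in [0, 1), got {tau}")
    if not 0.0 <= omega <= 1.0:
        raise ValueError(f"omega must lie in [0, 1], got {omega}")
    var = sigma_n * sigma_n
    n = (
        omega * var
        + (1.0 - omega) * tau * var
        + omega * (1.0 - omega) * (delta * (1.0 - tau)) ** 2
    )
    return n / (n + var)


def normative_learning_rate(omega: float, tau: float, cfg: ObserverConfig) -> float:
    """Learning rate implied by CPP and RU under the configured composition."""
    if cfg.lr_form == "standard":
        return omega + (1.0 - omega) * tau
    return min(1.0, omega + tau + omega * tau)


def run_conditioned(
    predictions: np.ndarray,
    runs: list[TaskRun],
    cfg: ObserverConfig,
    valid: np.ndarray | None = None,
) -> ModelTrajectory:
    """Run the observer conditioned on a subject's own predictions.

    ``predictions`` is the flat per-trial series over the session's runs (the
    subject's belief mean B_t); ``valid`` flags usable trials.  tau resets to
    ``tau_init`` at each run start; on excluded trials tau is propagated
    unchanged and CPP/alpha are NaN.
    """
    predictions = np.asarray(predictions, dtype=float)
    n_total = sum(r.n_trials for r in runs)
    if len(predictions) != n_total:
        raise ValueError(
            f"predictions ({len(predictions)}) misaligned with task trials ({n_total})"
        )
    if valid is None:
        valid = np.isfinite(predictions)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(predictions)

    cpp = np.full(n_total, np.nan)
    ru = np.full(n_total, np.nan)
    alpha = np.full(n_total, np.nan)
    offset = 0
    for run in runs:
        tau = cfg.tau_init
        sigma = run.sigma_n
        for t in range(run.n_trials):
            i = offset + t
            ru[i] = tau
            if not valid[i]:
                continue
            delta = run.outcomes[t] - predictions[i]
            omega = change_point_probability(delta, tau, sigma, cfg)
            cpp[i] = omega
            alpha[i] = normative_learning_rate(omega, tau, cfg)
            tau = update_relative_uncertainty(tau, omega, delta, sigma, cfg)
        offset += run.n_trials
    deltas = np.concatenate([r.outcomes for r in runs]) - predictions
    return ModelTrajectory(cpp, ru, alpha, alpha * deltas)


def run_ideal_observer(runs: list[TaskRun], cfg: ObserverConfig) -> np.ndarray:
    """Generate noise-free ideal-observer predictions for a task session.

    The first prediction of each run is the scale midpoint; thereafter
    B_{t+1} = B_t + alpha_t * delta_t with the observer's own CPP/RU
    recursion, clipped to the scale bounds.  Returns the flat prediction
    series.
    """
    preds = []
    mid = 0.5 * (cfg.scale_min + cfg.scale_max)
    for run in runs:
        tau = cfg.tau_init
        b = mid
        sigma = run.sigma_n
        for t in range(run.n_trials):
            preds.append(b)
            delta = run.outcomes[t] - b
            omega = change_point_probability(delta, tau, sigma, cfg)
            a = normative_learning_rate(omega, tau, cfg)
            b = min(cfg.scale_max, max(cfg.scale_min, b + a * delta))
            tau = update_relative_uncertainty(tau, omega, delta, sigma, cfg)
    return np.array(preds)
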