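"""Synthetic participants for end-to-end parameter and effect recovery.

Agents are generative mirrors of the first-level analysis regression: their
update on each trial is a weighted sum of the prediction error delta, the
CPP-scaled error delta*Omega and the RU-scaled error delta*tau, plus
response noise, with a {alpha=0, alpha=1} lapse mixture reproducing the
bimodal learning-rate histogram seen empirically (perseveration vs. total
update).  A cohort ties agent weights and questionnaire scores (PDI, ASI,
CAPS, OCI-R, STAI-T, AES, AUDIT) to a latent trait z with configurable
loadings, so planted trait-behavior links can be recovered by the two-level
pipeline.

Default questionnaire intercepts/SDs and instrument ranges follow the
descriptive statistics of the study population the generator emulates
(e.g. PDI 7.43 +/- 5.65 on [0, 40]); default agent weights center on the
group-level regression coefficients (w_pe 0.77, w_cpp 0.08, w_ru 0.07).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import BehaviorSession, session_from_runs
from .observer import (
    ObserverConfig,
    change_point_probability,
    normative_learning_rate,
    update_relative_uncertainty,
)
from .task import TaskConfig, TaskRun, generate_session

QUESTIONNAIRES = ("pdi", "asi", "caps", "ocir", "stai_t", "aes", "audit")
PLE_COMPONENTS = ("pdi", "asi", "caps")

#: instrument (minimum, maximum, population mean, population SD)
INSTRUMENT_NORMS: dict[str, tuple[float, float, float, float]] = {
    "pdi": (0, 40, 7.43, 5.65),
    "asi": (0, 29, 11.60, 7.06),
    "caps": (0, 32, 4.35, 4.45),
    "ocir": (0, 72, 18.88, 11.72),
    "stai_t": (20, 80, 47.46, 11.54),
    "aes": (18, 72, 54.79, 7.95),
    "audit": (0, 40, 5.09, 5.00),
}


@dataclass
class AgentParams:
    """Generative behavioral parameters of one synthetic agent."""

    w_pe: float = 0.77
    w_cpp: float = 0.08
    w_ru: float = 0.07
    noise_sd: float = 5.0
    p_lapse0: float = 0.15
    p_lapse1: float = 0.15
    rt_mean: float = 0.8
    rt_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.p_lapse0 < 0 or self.p_lapse1 < 0 or self.p_lapse0 + self.p_lapse1 > 1:
            raise ValueError("lapse probabilities must be >= 0 and sum to <= 1")


@dataclass
class ParamLink:
    """Linear map z -> parameter: value = intercept + slope * z."""

    intercept: float
    slope: float = 0.0

    def __call__(self, z: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(z, dtype=float)


@dataclass
class CohortSpec:
    """Latent-trait cohort specification.

    ``param_links`` maps AgentParams fields to (intercept, slope) links on
    the latent trait z ~ N(0, 1); the default plants the study's headline
    associations (higher z -> lower w_pe and w_cpp).  ``loadings`` give each
    questionnaire's slope on z; residuals are drawn with correlation
    ``residual_corr`` among the three PLE components and independently
    elsewhere, then floored/ceiled at instrument bounds.
    """

    n_subjects: int = 300
    param_links: dict[str, ParamLink] = field(default_factory=lambda: {
        "w_pe": ParamLink(0.77, -0.05),
        "w_cpp": ParamLink(0.08, -0.04),
        "w_ru": ParamLink(0.07, 0.0),
        "noise_sd": ParamLink(5.0, 0.0),
        "p_lapse0": ParamLink(0.15, 0.0),
        "p_lapse1": ParamLink(0.15, 0.0),
    })
    loadings: dict[str, float] = field(default_factory=lambda: {
        "pdi": 0.6, "asi": 0.6, "caps": 0.6,
        "ocir": 0.2, "stai_t": 0.2, "aes": 0.0, "audit": 0.0,
    })
    residual_corr: float = 0.3

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not -1.0 / (len(PLE_COMPONENTS) - 1) < self.residual_corr < 1.0:
            raise ValueError("residual_corr yields a non-PSD correlation matrix")

    def agent_params(self, z: float) -> AgentParams:
        kwargs = {}
        for name, link in self.param_links.items():
            kwargs[name] = float(link(np.asarray(z)))
        # keep probabilities and noise in their legal ranges whatever z
        for p in ("p_lapse0", "p_lapse1"):
            if p in kwargs:
                kwargs[p] = float(np.clip(kwargs[p], 0.0, 1.0))
        if "noise_sd" in kwargs:
            kwargs["noise_sd"] = max(0.0, kwargs["noise_sd"])
        total = kwargs.get("p_lapse0", 0.0) + kwargs.get("p_lapse1", 0.0)
        if total > 1.0:
            kwargs["p_lapse0"] /= total
            kwargs["p_lapse1"] /= total
        return AgentParams(**kwargs)


def recovery_cohort_spec(n_subjects: int = 100) -> CohortSpec:
    """Benchmark cohort for first-level parameter recovery.

    Noise-only agents (no lapses, response noise SD 2 scale units) with wide
    independent-looking spreads of the generative weights, so that
    truth-correlations of the recovered coefficients are identifiable: the
    per-subject standard error of the PE*RU coefficient is sizable (delta*tau
    is collinear with delta within a run), so its truth spread is set widest.
    """
    return CohortSpec(
        n_subjects=n_subjects,
        param_links={
            "w_pe": ParamLink(0.70, -0.12),
            "w_cpp": ParamLink(0.25, 0.12),
            "w_ru": ParamLink(0.35, -0.30),
            "noise_sd": ParamLink(2.0, 0.0),
            "p_lapse0": ParamLink(0.0, 0.0),
            "p_lapse1": ParamLink(0.0, 0.0),
        },
    )


def simulate_agent(
    params: AgentParams,
    runs: list[TaskRun],
    cfg: ObserverConfig,
    rng: np.random.Generator,
    subject_id: str = "sim",
) -> BehaviorSession:
    """Simulate one agent's predictions on a task session.

    The conditioned observer tracks the agent's *own* predictions; on each
    trial the agent draws a lapse state (no update / total update) or
    otherwise updates by w_pe*delta + w_cpp*Omega*delta + w_ru*tau*delta
    plus Gaussian response noise, clipped to the scale.
    """
    preds = np.empty(sum(r.n_trials for r in runs))
    rts = np.abs(rng.normal(params.rt_mean, params.rt_sd, size=len(preds)))
    mid = 0.5 * (cfg.scale_min + cfg.scale_max)
    i = 0
    for run in runs:
        tau = cfg.tau_init
        b = mid
        sigma = run.sigma_n
        for t in range(run.n_trials):
            preds[i] = b
            delta = run.outcomes[t] - b
            omega = change_point_probability(delta, tau, sigma, cfg)
            u = rng.random()
            if u < params.p_lapse0:
                update = 0.0
            elif u < params.p_lapse0 + params.p_lapse1:
                update = delta
            else:
                update = (
                    params.w_pe * delta
                    + params.w_cpp * omega * delta
                    + params.w_ru * tau * delta
                )
                if params.noise_sd > 0:
                    update += rng.normal(0.0, params.noise_sd)
            b = min(cfg.scale_max, max(cfg.scale_min, b + update))
            tau = update_relative_uncertainty(tau, omega, delta, sigma, cfg)
            i += 1
    return session_from_runs(subject_id, runs, preds, rts)


def _questionnaire_scores(
    spec: CohortSpec, z: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Continuous scores per instrument, floored/ceiled at instrument bounds.

    score_j = mean_j + loading_j * z * sd_j + eps_j, with eps correlated at
    ``residual_corr`` among the PLE components so the composite's spread
    reflects overlapping constructs.
    """
    n = len(z)
    scores = {}
    # correlated residuals for the PLE trio
    k = len(PLE_COMPONENTS)
    corr = np.full((k, k), spec.residual_corr)
    np.fill_diagonal(corr, 1.0)
    ple_eps = rng.multivariate_normal(np.zeros(k), corr, size=n)
    for j, name in enumerate(QUESTIONNAIRES):
        lo, hi, mean, sd = INSTRUMENT_NORMS[name]
        lam = spec.loadings.get(name, 0.0)
        resid_sd = float(np.sqrt(max(1.0 - lam**2, 1e-6)))
        if name in PLE_COMPONENTS:
            eps = ple_eps[:, PLE_COMPONENTS.index(name)] * resid_sd
        else:
            eps = rng.normal(0.0, resid_sd, size=n)
        raw = mean + sd * (lam * z + eps)
        scores[name] = np.clip(raw, lo, hi)
    return pd.DataFrame(scores)


def ple_composite(panel: pd.DataFrame) -> pd.Series:
    """PLE sum score: z-scored PDI + ASI + CAPS across the analyzed sample."""
    if len(panel) < 2:
        raise ValueError("composite needs at least two subjects")
    parts = []
    for name in PLE_COMPONENTS:
        s = panel[name].astype(float)
        sd = s.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"degenerate sample: zero variance in {name}")
        parts.append((s - s.mean()) / sd)
    return sum(parts).rename("ple")


def simulate_cohort(
    spec: CohortSpec,
    task_cfg: TaskConfig,
    obs_cfg: ObserverConfig,
    rng: np.random.Generator,
) -> tuple[list[tuple[BehaviorSession, list[TaskRun]]], pd.DataFrame]:
    """Simulate a full cohort: sessions plus a subject-level panel.

    Each subject gets a fresh task session (condition order randomized per
    subject).  The returned panel carries questionnaire scores, the PLE
    composite, and the ground-truth latent trait and agent parameters for
    recovery tests.
    """
    z = rng.standard_normal(spec.n_subjects)
    panel = _questionnaire_scores(spec, z, rng)
    panel.insert(0, "subject_id", [f"s{i + 1:04d}" for i in range(spec.n_subjects)])
    panel["ple"] = ple_composite(panel).to_numpy()
    panel["true_z"] = z

    sessions = []
    truth_rows = []
    for i in range(spec.n_subjects):
        params = spec.agent_params(z[i])
        runs = generate_session(task_cfg, rng)
        session = simulate_agent(params, runs, obs_cfg, rng,
                                 subject_id=panel["subject_id"].iloc[i])
        sessions.append((session, runs))
        truth_rows.append({f"true_{k}": getattr(params, k)
                           for k in ("w_pe", "w_cpp", "w_ru", "noise_sd",
                                     "p_lapse0", "p_lapse1")})
    panel = pd.concat([panel, pd.DataFrame(truth_rows)], axis=1)
    return sessions, panel
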