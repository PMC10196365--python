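"""End-to-end drivers: configuration, serialization, and reproduction paths.

``run_pipeline`` chains cohort simulation -> exclusions -> conditioned
observer -> trial table -> first/second level and writes the subject table,
trial table, group table, second-level results and a recovery report.
``reproduce`` runs the identical analysis on externally supplied behavioral
data mapped to the package's CSV dialect through a documented adapter; it
never downloads anything.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import inference, metrics
from .cohort import CohortSpec, ParamLink, simulate_cohort
from .inference import (
    FirstLevelFit,
    correlate_r2_with_trait,
    fit_first_level,
    fit_second_level,
    fits_to_frame,
    group_tests,
    lr_trait_regression,
    regression_power,
    specificity_panel,
)
from .metrics import (
    BehaviorSession,
    apply_exclusions,
    build_trial_table,
    mean_lr_by_pe_magnitude,
)
from .observer import ObserverConfig, run_conditioned
from .task import (
    TaskConfig,
    TaskRun,
    frame_to_session,
    generate_session,
    session_to_frame,
    task_config_from_dict,
    task_config_to_dict,
)

log = logging.getLogger("predinf")

#: headline reference values of the study the reproduce path compares against
REFERENCE_VALUES = {
    "group_beta_pe": 0.77,
    "group_beta_pecpp": 0.08,
    "group_beta_peru": 0.07,
    "mean_r2": 0.78,
    "second_level_beta_pe": -1.00,
    "second_level_beta_pecpp": -0.84,
    "second_level_beta_peru": 0.02,
    "r2_ple_correlation": -0.17,
    "mean_perf_error": 8.64,
    "lr_hi_bin_beta": -0.03,
}


@dataclass
class PipelineConfig:
    """Nested configuration of the full synthetic pipeline."""

    task: TaskConfig = field(default_factory=lambda: TaskConfig(constrained=True))
    observer: ObserverConfig = field(default_factory=ObserverConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    hi_pe_cut: float = 50.0
    lo_pe_cut: float = 5.0
    min_trials_first_level: int = inference.MIN_TRIALS_FIRST_LEVEL
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "task": task_config_to_dict(self.task),
            "observer": vars(self.observer).copy(),
            "cohort": {
                "n_subjects": self.cohort.n_subjects,
                "param_links": {k: [v.intercept, v.slope]
                                for k, v in self.cohort.param_links.items()},
                "loadings": dict(self.cohort.loadings),
                "residual_corr": self.cohort.residual_corr,
            },
            "hi_pe_cut": self.hi_pe_cut,
            "lo_pe_cut": self.lo_pe_cut,
            "min_trials_first_level": self.min_trials_first_level,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cohort_d = dict(d.get("cohort", {}))
        if "param_links" in cohort_d:
            cohort_d["param_links"] = {
                k: ParamLink(*v) for k, v in cohort_d["param_links"].items()
            }
        return cls(
            task=task_config_from_dict(d.get("task", {})) if d.get("task") else TaskConfig(constrained=True),
            observer=ObserverConfig(**d.get("observer", {})),
            cohort=CohortSpec(**cohort_d),
            hi_pe_cut=d.get("hi_pe_cut", 50.0),
            lo_pe_cut=d.get("lo_pe_cut", 5.0),
            min_trials_first_level=d.get("min_trials_first_level",
                                         inference.MIN_TRIALS_FIRST_LEVEL),
            seed=d.get("seed", 0),
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# analysis core shared by the synthetic and external paths

def analyze_sessions(
    sessions: list[tuple[BehaviorSession, list[TaskRun]]],
    cfg: PipelineConfig,
) -> dict:
    """Exclusions -> observer -> trial table -> first level, per subject.

    Returns the concatenated trial table, first-level fits, and the list of
    excluded subject ids.
    """
    tables, fits, excluded = [], [], []
    for session, runs in sessions:
        session = apply_exclusions(session)
        if session.excluded:
            excluded.append(session.subject_id)
            continue
        trajectory = run_conditioned(session.predictions, runs, cfg.observer,
                                     valid=session.valid)
        table = build_trial_table(session, runs, trajectory)
        tables.append(table)
        fits.append(fit_first_level(table, session.subject_id,
                                    cfg.min_trials_first_level))
    if not tables:
        raise ValueError("all subjects excluded; nothing to analyze")
    trial_table = pd.concat(tables, ignore_index=True)
    return {"trial_table": trial_table, "fits": fits, "excluded": excluded}


def second_level_suite(
    trial_table: pd.DataFrame,
    fits: list[FirstLevelFit],
    panel: pd.DataFrame,
    cfg: PipelineConfig,
) -> dict:
    """Group tests, trait regressions, specificity panel, binned-LR links."""
    group = group_tests(fits)
    second = fit_second_level(panel, fits, outcome="ple")
    r, p = correlate_r2_with_trait(fits, panel, trait="ple")
    binned = mean_lr_by_pe_magnitude(trial_table, cfg.hi_pe_cut, cfg.lo_pe_cut)
    lr_links = {}
    for bin_name in ("lr_hi", "lr_lo"):
        try:
            lr_links[bin_name] = lr_trait_regression(binned, panel, bin_name)
        except ValueError as err:
            log.warning("binned-LR regression %s skipped: %s", bin_name, err)
    have_scores = [s for s in ("pdi", "asi", "caps", "ocir", "stai_t", "aes", "audit")
                   if s in panel.columns]
    spec_results = specificity_panel(panel, fits, tuple(have_scores)) if have_scores else []
    fit_frame = fits_to_frame(fits)
    return {
        "group": group,
        "second_level": second,
        "r2_trait_correlation": {"r": r, "p": p},
        "lr_links": lr_links,
        "specificity": spec_results,
        "mean_r2": float(fit_frame.loc[fit_frame["reliable"], "r2"].mean()),
        "mean_perf_error": float(
            trial_table.loc[trial_table["valid"] == 1, "perf_error"].mean()),
    }


def _results_to_json(results: dict, cfg: PipelineConfig) -> dict:
    second = results["second_level"]
    out = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_excluded": len(results.get("excluded", [])),
        "group_table": results["group"].to_dict(orient="index"),
        "second_level": {
            "outcome": second.outcome,
            "table": second.table.to_dict(orient="index"),
            "r2": second.r2, "f_p": second.f_p, "n": second.n,
        },
        "r2_trait_correlation": results["r2_trait_correlation"],
        "mean_r2": results["mean_r2"],
        "mean_perf_error": results["mean_perf_error"],
        "lr_links": {k: v.to_dict(orient="index")
                     for k, v in results["lr_links"].items()},
        "specificity": {
            r.outcome: r.table.to_dict(orient="index")
            for r in results["specificity"]
        },
        "power": {
            "n300_k3_f2_0.058": regression_power(300, 3, 0.058, 0.05),
        },
    }
    return out


# ---------------------------------------------------------------------------
# drivers

def simulate_task_csv(cfg: PipelineConfig, out_path) -> pd.DataFrame:
    """Generate one stimulus session and write the trial CSV."""
    rng = np.random.default_rng(cfg.seed)
    runs = generate_session(cfg.task, rng)
    frame = session_to_frame(runs)
    for run in runs:
        log.info("run %d (%s): %d phases", run.run_index, run.condition, run.n_phases)
    Path(out_path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out_path, index=False, float_format="%.8g")
    return frame


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Full synthetic pipeline; writes CSV/JSON artifacts and returns results."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    log.info("simulating cohort of %d subjects", cfg.cohort.n_subjects)
    sessions, panel = simulate_cohort(cfg.cohort, cfg.task, cfg.observer, rng)
    stage = analyze_sessions(sessions, cfg)
    results = second_level_suite(stage["trial_table"], stage["fits"], panel, cfg)
    results["excluded"] = stage["excluded"]

    # recovery report: planted links vs recovered estimates
    fit_frame = fits_to_frame(stage["fits"]).merge(panel, on="subject_id")
    recovery = {}
    for est, truth in (("beta_pe", "true_w_pe"), ("beta_pecpp", "true_w_cpp"),
                       ("beta_peru", "true_w_ru")):
        sub = fit_frame.dropna(subset=[est, truth])
        sd = sub[truth].std()
        recovery[est] = {
            "mean_estimate": float(sub[est].mean()),
            "mean_truth": float(sub[truth].mean()),
            "truth_correlation": float(np.corrcoef(sub[est], sub[truth])[0, 1])
            if sd > 0 else None,
        }
    payload = _results_to_json(results, cfg)
    payload["recovery"] = recovery

    subject_table = panel.merge(fits_to_frame(stage["fits"]), on="subject_id", how="left")
    subject_table.to_csv(out / "subjects.csv", index=False, float_format="%.8g")
    stage["trial_table"].to_csv(out / "trials.csv", index=False, float_format="%.8g")
    with open(out / "results.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
    save_config(cfg, out / "config.yaml")
    log.info("pipeline complete: %d subjects analyzed, %d excluded",
             len(stage["fits"]), len(stage["excluded"]))
    results["json"] = payload
    return results


# ---------------------------------------------------------------------------
# external-data adapter

#: mapping from adapter-expected columns to the package dialect; external
#: trial files must provide these per-trial fields (names configurable)
ADAPTER_TRIAL_COLUMNS = {
    "subject_id": "subject_id",
    "run_index": "run_index",
    "trial_index": "trial_index",
    "condition": "condition",
    "mean": "mean",
    "outcome": "outcome",
    "changepoint": "changepoint",
    "sigma_n": "sigma_n",
    "prediction": "prediction",
    "rt": "rt",
}


def adapt_external_trials(
    frame: pd.DataFrame, column_map: dict[str, str] | None = None
) -> list[tuple[BehaviorSession, list[TaskRun]]]:
    """Map an external per-trial table onto sessions + runs.

    ``column_map`` renames external columns to the package dialect
    (package name -> external name); schema problems are reported
    field-by-field.
    """
    column_map = {**ADAPTER_TRIAL_COLUMNS, **(column_map or {})}
    missing = [ext for ext in column_map.values() if ext not in frame.columns]
    if missing:
        raise ValueError(f"external table is missing columns: {missing}")
    renamed = frame.rename(columns={ext: pkg for pkg, ext in column_map.items()})
    sessions = []
    for sid, grp in renamed.groupby("subject_id", sort=True):
        grp = grp.sort_values(["run_index", "trial_index"])
        runs = frame_to_session(grp)
        session = BehaviorSession(
            subject_id=str(sid),
            predictions=grp["prediction"].to_numpy(float),
            rt=grp["rt"].to_numpy(float),
            run_index=grp["run_index"].to_numpy(int),
            condition=grp["condition"].to_numpy(object),
        )
        sessions.append((session, runs))
    return sessions


def reproduce(
    data_dir,
    cfg: PipelineConfig,
    out_dir=None,
    column_map: dict[str, str] | None = None,
) -> dict:
    """Run the full analysis on externally supplied data.

    Expects ``trials.csv`` (per-trial, adapter dialect) and ``subjects.csv``
    (questionnaire scores) in ``data_dir``; prints a side-by-side table
    against the study's headline numbers.  Never fetches data itself.
    """
    data = Path(data_dir)
    if not data.is_dir():
        raise FileNotFoundError(f"data directory {data} does not exist")
    trials = pd.read_csv(data / "trials.csv", dtype={"subject_id": str})
    panel = pd.read_csv(data / "subjects.csv", dtype={"subject_id": str})
    if "ple" not in panel.columns:
        from .cohort import ple_composite
        panel["ple"] = ple_composite(panel).to_numpy()
    sessions = adapt_external_trials(trials, column_map)
    stage = analyze_sessions(sessions, cfg)
    results = second_level_suite(stage["trial_table"], stage["fits"], panel, cfg)
    results["excluded"] = stage["excluded"]
    payload = _results_to_json(results, cfg)
    payload["comparison"] = comparison_table(results).to_dict(orient="index")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "results.json", "w") as fh:
            json.dump(payload, fh, indent=2, default=float)
    results["json"] = payload
    return results


def comparison_table(results: dict) -> pd.DataFrame:
    """Side-by-side of computed headline quantities vs the study's values."""
    second = results["second_level"].table
    computed = {
        "group_beta_pe": results["group"].loc["beta_pe", "mean"],
        "group_beta_pecpp": results["group"].loc["beta_pecpp", "mean"],
        "group_beta_peru": results["group"].loc["beta_peru", "mean"],
        "mean_r2": results["mean_r2"],
        "second_level_beta_pe": second.loc["beta_pe", "beta"],
        "second_level_beta_pecpp": second.loc["beta_pecpp", "beta"],
        "second_level_beta_peru": second.loc["beta_peru", "beta"],
        "r2_ple_correlation": results["r2_trait_correlation"]["r"],
        "mean_perf_error": results["mean_perf_error"],
    }
    if "lr_hi" in results["lr_links"]:
        computed["lr_hi_bin_beta"] = results["lr_links"]["lr_hi"].loc[
            "lr_on_trait", "slope"]
    rows = {k: {"computed": v, "reference": REFERENCE_VALUES.get(k)}
            for k, v in computed.items()}
    return pd.DataFrame(rows).T
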