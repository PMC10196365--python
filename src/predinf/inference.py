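"""Two-level statistical analysis of belief updating.

First level: per-subject OLS of trial-wise belief updates on the prediction
error and its interactions with the observer's change-point probability and
relative uncertainty (U_t ~ delta_t + delta_t*Omega_t + delta_t*tau_t, all
regressors mean-centered within subject).  The coefficients quantify how
much a participant updates per unit error and how strongly updating is
modulated at likely change points and under belief uncertainty.

Second level: group tests of the coefficients against zero; regressions of
trait scores (PLE composite and the specificity panel) on the per-subject
coefficients with Benjamini-Hochberg correction; the correlation of
first-level R^2 with a trait; PE-magnitude-binned learning-rate
regressions; linear mixed models of performance error / belief precision
over trials-after-change-point, noise condition, and trait; and the
noncentral-F power computation underlying the n = 300 design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

FIRST_LEVEL_PREDICTORS = ("beta_pe", "beta_pecpp", "beta_peru")
MIN_TRIALS_FIRST_LEVEL = 30


@dataclass
class FirstLevelFit:
    subject_id: str
    beta0: float
    beta_pe: float
    beta_pecpp: float
    beta_peru: float
    r2: float
    n_trials_used: int
    reliable: bool = True


@dataclass
class SecondLevelResult:
    """OLS of a (z-scored) trait on the three first-level coefficients."""

    outcome: str
    table: pd.DataFrame  # index: predictor; columns: beta, se, t, p [, p_bh]
    r2: float
    f_stat: float
    f_p: float
    n: int


@dataclass
class MixedFitResult:
    outcome: str
    fixed_effects: pd.DataFrame  # index: term; columns: beta, se, p
    random_structure: str
    converged: bool
    selection_log: list[str] = field(default_factory=list)
    fallback: bool = False


# ---------------------------------------------------------------------------
# first level

def build_first_level_design(
    trials: pd.DataFrame, min_trials: int = MIN_TRIALS_FIRST_LEVEL
) -> tuple[pd.Series, pd.DataFrame]:
    """Outcome and mean-centered design for one subject's trials.

    Uses only rows with a defined update and observer trajectory.  Raises
    ``ValueError`` on too few usable trials or a degenerate (constant)
    regressor.
    """
    needed = ["update", "pe", "cpp", "ru"]
    usable = trials.dropna(subset=needed)
    if "valid" in trials:
        usable = usable[usable["valid"].astype(bool)]
    if len(usable) < min_trials:
        raise ValueError(
            f"only {len(usable)} usable trials (< {min_trials}) for the first-level fit"
        )
    y = usable["update"].astype(float)
    X = pd.DataFrame({
        "pe": usable["pe"],
        "pe_cpp": usable["pe"] * usable["cpp"],
        "pe_ru": usable["pe"] * usable["ru"],
    })
    X = X - X.mean()
    if (X.std(ddof=0) < 1e-12).any():
        bad = X.columns[(X.std(ddof=0) < 1e-12)].tolist()
        raise ValueError(f"degenerate (constant) regressors after centering: {bad}")
    return y, sm.add_constant(X)


def fit_first_level(
    trials: pd.DataFrame,
    subject_id: str | None = None,
    min_trials: int = MIN_TRIALS_FIRST_LEVEL,
) -> FirstLevelFit:
    """OLS fit of one subject's updates on PE, PE*CPP, PE*RU."""
    if subject_id is None:
        subject_id = str(trials["subject_id"].iloc[0]) if "subject_id" in trials else ""
    try:
        y, X = build_first_level_design(trials, min_trials)
    except ValueError:
        return FirstLevelFit(subject_id, np.nan, np.nan, np.nan, np.nan,
                             np.nan, 0, reliable=False)
    res = sm.OLS(y, X).fit()
    params = res.params
    return FirstLevelFit(
        subject_id=subject_id,
        beta0=float(params["const"]),
        beta_pe=float(params["pe"]),
        beta_pecpp=float(params["pe_cpp"]),
        beta_peru=float(params["pe_ru"]),
        r2=float(res.rsquared),
        n_trials_used=int(res.nobs),
        reliable=res.nobs >= min_trials,
    )


def fits_to_frame(fits: list[FirstLevelFit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "subject_id": f.subject_id, "beta0": f.beta0, "beta_pe": f.beta_pe,
        "beta_pecpp": f.beta_pecpp, "beta_peru": f.beta_peru, "r2": f.r2,
        "n_trials_used": f.n_trials_used, "reliable": f.reliable,
    } for f in fits])


# ---------------------------------------------------------------------------
# group level

def group_tests(fits: list[FirstLevelFit] | pd.DataFrame,
                conf_level: float = 0.95) -> pd.DataFrame:
    """One-sample t-tests of each first-level coefficient against zero.

    Returns a frame indexed by coefficient with mean, CI bounds, t, p, and
    n; degenerate (zero-variance) coefficient sets are reported with NaN t.
    """
    frame = fits_to_frame(fits) if not isinstance(fits, pd.DataFrame) else fits
    frame = frame[frame["reliable"].astype(bool)] if "reliable" in frame else frame
    if len(frame) < 2:
        raise ValueError("group tests need at least two reliable fits")
    rows = {}
    for name in FIRST_LEVEL_PREDICTORS:
        x = frame[name].dropna().to_numpy()
        n = len(x)
        mean = x.mean()
        sd = x.std(ddof=1)
        if sd == 0:
            rows[name] = {"mean": mean, "ci_low": mean, "ci_high": mean,
                          "t": np.nan, "p": np.nan, "n": n}
            continue
        se = sd / np.sqrt(n)
        tcrit = scipy.stats.t.ppf(0.5 + conf_level / 2, df=n - 1)
        t_stat, p = scipy.stats.ttest_1samp(x, 0.0)
        rows[name] = {"mean": mean, "ci_low": mean - tcrit * se,
                      "ci_high": mean + tcrit * se, "t": float(t_stat),
                      "p": float(p), "n": n}
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# second level

def _zscore(s: pd.Series) -> pd.Series:
    sd = s.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero-variance outcome cannot be z-scored")
    return (s - s.mean()) / sd


def fit_second_level(
    panel: pd.DataFrame,
    fits: list[FirstLevelFit] | pd.DataFrame,
    outcome: str = "ple",
    zscore_outcome: bool = True,
    max_loss_fraction: float = 0.5,
) -> SecondLevelResult:
    """Regress a trait score on the three first-level coefficients.

    Predictors enter unstandardized (coefficients are on the raw first-level
    coefficient scale); the outcome is z-scored across the analyzed sample
    by default.
    """
    frame = fits_to_frame(fits) if not isinstance(fits, pd.DataFrame) else fits
    frame = frame[frame["reliable"].astype(bool)] if "reliable" in frame else frame
    merged = panel.merge(frame, on="subject_id", how="inner").dropna(
        subset=[outcome, *FIRST_LEVEL_PREDICTORS])
    if len(merged) < len(panel) * (1 - max_loss_fraction):
        raise ValueError(
            f"join lost {len(panel) - len(merged)} of {len(panel)} subjects"
        )
    y = merged[outcome].astype(float)
    if zscore_outcome:
        y = _zscore(y)
    X = sm.add_constant(merged[list(FIRST_LEVEL_PREDICTORS)].astype(float))
    res = sm.OLS(y, X).fit()
    table = pd.DataFrame({
        "beta": res.params, "se": res.bse, "t": res.tvalues, "p": res.pvalues,
    }).drop(index="const")
    return SecondLevelResult(
        outcome=outcome, table=table, r2=float(res.rsquared),
        f_stat=float(res.fvalue), f_p=float(res.f_pvalue), n=int(res.nobs),
    )


def correlate_r2_with_trait(
    fits: list[FirstLevelFit] | pd.DataFrame,
    panel: pd.DataFrame,
    trait: str = "ple",
) -> tuple[float, float]:
    """Pearson correlation of first-level R^2 with a trait score."""
    frame = fits_to_frame(fits) if not isinstance(fits, pd.DataFrame) else fits
    frame = frame[frame["reliable"].astype(bool)] if "reliable" in frame else frame
    merged = panel.merge(frame, on="subject_id").dropna(subset=[trait, "r2"])
    x, y = merged["r2"].to_numpy(), merged[trait].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in r2 or trait")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


def specificity_panel(
    panel: pd.DataFrame,
    fits: list[FirstLevelFit] | pd.DataFrame,
    scores: tuple[str, ...] = ("pdi", "asi", "caps", "ocir", "stai_t", "aes", "audit"),
    q: float = 0.05,
) -> list[SecondLevelResult]:
    """One second-level regression per questionnaire, BH-corrected.

    Benjamini-Hochberg is applied across the full family of predictor-by-
    score tests (3 predictors x 7 scores = 21); each result table gains a
    ``p_bh`` column.  Missing scores are skipped with a warning.
    """
    results = []
    for score in scores:
        if score not in panel.columns:
            warnings.warn(f"score {score!r} missing from panel; skipped")
            continue
        results.append(fit_second_level(panel, fits, outcome=score))
    raw = np.concatenate([r.table["p"].to_numpy() for r in results])
    _, adj, _, _ = multipletests(raw, alpha=q, method="fdr_bh")
    k = len(FIRST_LEVEL_PREDICTORS)
    for i, r in enumerate(results):
        r.table["p_bh"] = adj[i * k:(i + 1) * k]
    return results


def lr_trait_regression(
    binned: pd.DataFrame,
    panel: pd.DataFrame,
    bin_name: str = "lr_hi",
    trait: str = "ple",
) -> pd.DataFrame:
    """Association of binned mean learning rates with a trait score.

    Both regression directions are emitted (mean LR on trait and trait on
    mean LR); they share the same t and p.  Rows: direction; columns:
    slope, se, t, p, n.
    """
    merged = binned.reset_index(names="subject_id").merge(
        panel[["subject_id", trait]], on="subject_id").dropna(
        subset=[bin_name, trait])
    if len(merged) < 3:
        raise ValueError(f"too few subjects with data in bin {bin_name!r}")
    lr = merged[bin_name].astype(float)
    tr = merged[trait].astype(float)
    rows = {}
    for direction, (yv, xv) in {
        "lr_on_trait": (lr, tr), "trait_on_lr": (tr, lr),
    }.items():
        res = sm.OLS(yv, sm.add_constant(xv.rename("x"))).fit()
        rows[direction] = {
            "slope": float(res.params["x"]), "se": float(res.bse["x"]),
            "t": float(res.tvalues["x"]), "p": float(res.pvalues["x"]),
            "n": int(res.nobs),
        }
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# trajectory mixed models

#: random-effect structures, maximal first, in forced drop order
_RE_STRUCTURES = [
    ("intercept + tac + noise + tac:noise", "~tac * noise_high"),
    ("intercept + tac + noise", "~tac + noise_high"),
    ("intercept + tac", "~tac"),
    ("intercept", "~1"),
]


def trajectory_mixed_model(
    trials: pd.DataFrame,
    panel: pd.DataFrame,
    outcome: str = "perf_error",
    trait: str = "ple",
) -> MixedFitResult:
    """Mixed model of a trial outcome over TAC x noise x trait.

    Fits ``outcome ~ tac * noise_high * trait`` (noise_high = 1 for the
    high-noise condition) by REML with a subject random intercept and
    random slopes for TAC, noise, and their interaction.  On
    non-convergence or a singular random-effect covariance, random terms
    are dropped in the order tac:noise -> noise -> tac, logging a
    likelihood-ratio comparison at each step; if nothing converges the
    two-stage fallback (per-subject OLS slopes regressed on the trait) is
    reported.
    """
    data = trials.merge(panel[["subject_id", trait]], on="subject_id")
    data = data.dropna(subset=[outcome, "tac", trait])
    data = data[data["valid"].astype(bool)] if "valid" in data else data
    data = data.copy()
    data["noise_high"] = (data["condition"] == "high").astype(float)
    data = data.rename(columns={trait: "trait_score", outcome: "y"})
    formula = "y ~ tac * noise_high * trait_score"

    log: list[str] = []
    prev_llf = None
    for label, re_formula in _RE_STRUCTURES:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                model = smf.mixedlm(formula, data, groups=data["subject_id"],
                                    re_formula=re_formula)
                res = model.fit(reml=True, method="lbfgs", maxiter=200)
        except (np.linalg.LinAlgError, ValueError) as err:
            log.append(f"{label}: failed ({err})")
            continue
        singular = np.linalg.cond(np.asarray(res.cov_re)) > 1e8 if res.cov_re.size else False
        if prev_llf is not None:
            # LRT of the dropped random term(s); conservative chi2 reference
            lr = 2 * (prev_llf - res.llf)
            p = float(scipy.stats.chi2.sf(max(lr, 0.0), df=1))
            log.append(f"{label}: LRT vs previous structure p={p:.3g}")
        prev_llf = res.llf
        if res.converged and not singular:
            fe = pd.DataFrame({"beta": res.fe_params,
                               "se": res.bse_fe,
                               "p": res.pvalues[res.fe_params.index]})
            log.append(f"{label}: converged")
            return MixedFitResult(outcome, fe, label, True, log)
        log.append(f"{label}: {'singular' if singular else 'not converged'}, dropping")

    log.append("all structures failed; two-stage fallback")
    fe = _two_stage_fallback(data)
    return MixedFitResult(outcome, fe, "two-stage fallback", False, log, fallback=True)


def _two_stage_fallback(data: pd.DataFrame) -> pd.DataFrame:
    """Per-subject OLS of y ~ tac*noise; slopes regressed on the trait."""
    slopes = []
    for sid, grp in data.groupby("subject_id"):
        if grp["noise_high"].nunique() < 2 or len(grp) < 8:
            continue
        X = sm.add_constant(pd.DataFrame({
            "tac": grp["tac"], "noise_high": grp["noise_high"],
            "tac_noise": grp["tac"] * grp["noise_high"],
        }))
        res = sm.OLS(grp["y"], X).fit()
        slopes.append({"subject_id": sid, "trait_score": grp["trait_score"].iloc[0],
                       **res.params.to_dict()})
    sframe = pd.DataFrame(slopes)
    rows = {}
    for term in ("const", "tac", "noise_high", "tac_noise"):
        mean = sframe[term].mean()
        t, p = scipy.stats.ttest_1samp(sframe[term], 0.0)
        rows[term] = {"beta": mean, "se": sframe[term].std(ddof=1) / np.sqrt(len(sframe)),
                      "p": float(p)}
        res = sm.OLS(sframe[term], sm.add_constant(sframe["trait_score"])).fit()
        rows[f"{term}:trait_score"] = {
            "beta": float(res.params["trait_score"]),
            "se": float(res.bse["trait_score"]),
            "p": float(res.pvalues["trait_score"]),
        }
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# power

def regression_power(n: int, k_predictors: int, f2: float, alpha: float = 0.05) -> float:
    """Power of the fixed-model omnibus F-test of a multiple regression.

    Numerator df = k, denominator df = n - k - 1, noncentrality
    lambda = f^2 * n, evaluated on the noncentral-F distribution.
    """
    if k_predictors < 1 or n <= k_predictors + 1:
        raise ValueError("need n > k_predictors + 1 and k_predictors >= 1")
    if f2 < 0 or not 0 < alpha < 1:
        raise ValueError("f2 must be >= 0 and alpha in (0, 1)")
    df1, df2 = k_predictors, n - k_predictors - 1
    fcrit = scipy.stats.f.isf(alpha, df1, df2)
    if f2 == 0:
        return alpha
    return float(scipy.stats.ncf.sf(fcrit, df1, df2, f2 * n))
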