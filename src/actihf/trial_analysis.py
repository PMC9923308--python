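"""Trial-level statistics: baseline-adjusted intervention effects,
guideline-attainment logistic model, univariate screening and the
multivariable predictor models, with the usual regression diagnostics
(adjusted R^2, AIC, VIF, Cook's distance).

All models adjust for the baseline value of the outcome, treatment group
and the trial stratification variables (NT-proBNP stratum and centre).
Complete-case handling is applied per model and counts are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import EstimationError, SequencingError

log = logging.getLogger(__name__)

GROUP_LABELS = {"control": 0, "intervention": 1}
MODEL_IDS = (
    "m1_sociodemographic",
    "m2_exercise_health",
    "m3_combined",
    "univariate",
    "logistic_guideline",
)


@dataclass
class EffectEstimate:
    """A between-group effect: coefficient, 95% CI, p and per-arm n."""

    outcome: str
    beta: float
    ci_low: float
    ci_high: float
    p_value: float
    se: float
    n_per_arm: Dict[str, int]
    scale: str = "mean_difference"  # or "odds_ratio"
    stratum: str = ""
    bouting: str = ""
    visit: str = ""
    flagged: bool = False

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "beta": self.beta,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "se": self.se,
            "n_per_arm": self.n_per_arm,
            "scale": self.scale,
            "stratum": self.stratum,
            "bouting": self.bouting,
            "visit": self.visit,
            "flagged": self.flagged,
        }


@dataclass
class ModelFit:
    """A fitted regression with its diagnostics."""

    model_id: str
    coefficients: pd.DataFrame  # index term; beta, ci_low, ci_high, t, p
    adjusted_r2: float
    aic: float
    vif: Dict[str, float]
    cooks_distance: np.ndarray
    n: int
    flagged_observations: List = field(default_factory=list)


@dataclass
class ScreenResult:
    """One candidate from the univariate screen (adjusted regression)."""

    covariate: str
    beta: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    flagged: bool
    fit: Optional[ModelFit] = None


def change_score(baseline_mean, followup_mean):
    """Change from baseline: follow-up minus baseline (min/day)."""
    return followup_mean - baseline_mean


# ---------------------------------------------------------------------------
# design-matrix plumbing
# ---------------------------------------------------------------------------

def _group_codes(series: pd.Series) -> pd.Series:
    if series.dtype == object or str(series.dtype) == "category":
        unknown = set(series.unique()) - set(GROUP_LABELS)
        if unknown:
            raise EstimationError(f"unknown group labels {sorted(unknown)}")
        return series.map(GROUP_LABELS).astype(float)
    return series.astype(float)


def _centre_columns(series: pd.Series, coding: str) -> pd.DataFrame:
    levels = sorted(pd.unique(series.astype(str)))
    if coding == "ordinal":
        codes = pd.Series(pd.Categorical(series.astype(str), categories=levels).codes,
                          index=series.index, dtype=float)
        return pd.DataFrame({"centre": codes})
    if coding == "indicator":
        if len(levels) < 2:
            return pd.DataFrame(index=series.index)
        dummies = pd.get_dummies(series.astype(str), prefix="centre", dtype=float)
        return dummies.iloc[:, 1:]  # first level is the reference
    raise ValueError(f"unknown centre coding {coding!r}")


def _build_design(
    df: pd.DataFrame,
    terms: Sequence[str],
    centre_coding: str,
    protected: Sequence[str] = (),
) -> pd.DataFrame:
    """Assemble the design matrix; drop constant nuisance columns.

    ``terms`` are column names of ``df``; ``centre`` expands per
    ``centre_coding`` and ``group`` is coded intervention = 1.  Constant
    columns are dropped with a log note unless listed in ``protected``, in
    which case they raise an :class:`EstimationError` naming the term.
    """
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    for term in terms:
        if term == "centre":
            cols = _centre_columns(df["centre"], centre_coding)
            for c in cols.columns:
                X[c] = cols[c]
        elif term == "group":
            X["group"] = _group_codes(df["group"])
        else:
            X[term] = df[term].astype(float)
    X = X.astype(float)
    for col in list(X.columns):
        if col == "const":
            continue
        if X[col].nunique() <= 1:
            if col in protected:
                raise EstimationError(f"aliased term: {col} (no variation)")
            log.info("dropping constant design column %r", col)
            X = X.drop(columns=[col])
    _check_rank(X)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    vals = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(vals)
    if rank == X.shape[1]:
        return
    # identify the first column that fails to increase the rank
    r = 0
    for k in range(1, X.shape[1] + 1):
        rk = np.linalg.matrix_rank(vals[:, :k])
        if rk == r:
            raise EstimationError(f"aliased term: {X.columns[k - 1]}")
        r = rk
    raise EstimationError("rank-deficient design")


def _coef_table(res) -> pd.DataFrame:
    ci = res.conf_int(alpha=0.05)
    return pd.DataFrame(
        {
            "beta": res.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "t": res.tvalues,
            "p": res.pvalues,
        }
    )


def _complete_cases(df: pd.DataFrame, cols: Sequence[str], label: str) -> pd.DataFrame:
    sub = df.dropna(subset=list(cols))
    dropped = len(df) - len(sub)
    if dropped:
        log.info("%s: %d incomplete cases dropped (%d analysed)", label, dropped, len(sub))
    return sub


# ---------------------------------------------------------------------------
# intervention effects
# ---------------------------------------------------------------------------

def ancova_effect(
    data: pd.DataFrame,
    outcome: str = "followup",
    baseline: str = "baseline",
    centre_coding: str = "indicator",
    outcome_name: str = "",
    min_per_arm: int = 10,
    **labels,
) -> EffectEstimate:
    """Baseline-adjusted treatment effect via OLS (ANCOVA).

    Regresses the follow-up outcome on intercept, its baseline value, the
    group indicator (intervention = 1), the NT-proBNP stratum and centre.
    Returns the group coefficient with its normal-theory 95% CI and
    two-sided p value.
    """
    cols = [outcome, baseline, "group", "bnp2000", "centre"]
    sub = _complete_cases(data, cols, outcome_name or outcome)
    groups = _group_codes(sub["group"])
    n_per_arm = {
        "control": int((groups == 0).sum()),
        "intervention": int((groups == 1).sum()),
    }
    if min(n_per_arm.values()) == 0:
        raise EstimationError("aliased term: group (all subjects in one arm)")
    if min(n_per_arm.values()) < min_per_arm:
        log.warning("fewer than %d complete cases in one arm: %s", min_per_arm, n_per_arm)

    X = _build_design(
        sub.assign(**{baseline: sub[baseline]}),
        [baseline, "group", "bnp2000", "centre"],
        centre_coding,
        protected=("group", baseline),
    )
    y = pd.to_numeric(sub[outcome])
    res = sm.OLS(y, X).fit()
    ci = res.conf_int().loc["group"]
    return EffectEstimate(
        outcome=outcome_name or outcome,
        beta=float(res.params["group"]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(res.pvalues["group"]),
        se=float(res.bse["group"]),
        n_per_arm=n_per_arm,
        scale="mean_difference",
        **labels,
    )


def guideline_logistic(
    data: pd.DataFrame,
    outcome: str = "followup_meets",
    baseline: str = "baseline_meets",
    centre_coding: str = "indicator",
    outcome_name: str = "meets_guideline",
    **labels,
) -> EffectEstimate:
    """Group odds ratio for meeting the weekly PA guideline at follow-up.

    Logistic regression mirroring :func:`ancova_effect`'s covariates.  If
    separation is detected (fitted probabilities pinned at 0/1) the
    estimate is returned flagged with a warning rather than trusted.
    """
    cols = [outcome, baseline, "group", "bnp2000", "centre"]
    sub = _complete_cases(data, cols, outcome_name)
    y = pd.to_numeric(sub[outcome]).astype(float)
    if y.nunique() < 2:
        raise EstimationError("outcome constant: both guideline classes required")
    groups = _group_codes(sub["group"])
    n_per_arm = {
        "control": int((groups == 0).sum()),
        "intervention": int((groups == 1).sum()),
    }
    if min(n_per_arm.values()) == 0:
        raise EstimationError("aliased term: group (all subjects in one arm)")

    X = _build_design(sub, [baseline, "group", "bnp2000", "centre"],
                      centre_coding, protected=("group",))
    flagged = False
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        log.warning("perfect separation detected; refitting with BFGS and flagging")
        flagged = True
        res = sm.Logit(y, X).fit(method="bfgs", disp=0, maxiter=500)
    fitted = res.predict(X)
    if fitted.min() < 1e-8 or fitted.max() > 1 - 1e-8:
        if not flagged:
            log.warning("fitted probabilities pinned at 0/1; estimate flagged")
        flagged = True

    ci = res.conf_int().loc["group"]
    return EffectEstimate(
        outcome=outcome_name,
        beta=float(np.exp(res.params["group"])),
        ci_low=float(np.exp(ci[0])),
        ci_high=float(np.exp(ci[1])),
        p_value=float(res.pvalues["group"]),
        se=float(res.bse["group"]),  # SE on the log-odds scale
        n_per_arm=n_per_arm,
        scale="odds_ratio",
        flagged=flagged,
        **labels,
    )


# ---------------------------------------------------------------------------
# predictor models
# ---------------------------------------------------------------------------

_ADJUSTERS = ("baseline_mvpa", "group", "bnp2000", "centre")


def _fit_ols_model(
    model_id: str,
    data: pd.DataFrame,
    covariates: Sequence[str],
    outcome: str,
    centre_coding: str,
    cooks_flag: Optional[float],
) -> ModelFit:
    cols = [outcome, *covariates, *(c for c in _ADJUSTERS if c not in covariates)]
    sub = _complete_cases(data, cols, model_id)
    X = _build_design(
        sub, list(covariates) + [c for c in _ADJUSTERS if c not in covariates],
        centre_coding,
    )
    y = pd.to_numeric(sub[outcome])
    res = sm.OLS(y, X).fit()

    vif = {}
    vals = X.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        for i, col in enumerate(X.columns):
            if col == "const":
                continue
            vif[col] = float(variance_inflation_factor(vals, i))

    cooks = res.get_influence().cooks_distance[0]
    thresh = cooks_flag if cooks_flag is not None else 4.0 / len(sub)
    flagged = list(sub.index[np.asarray(cooks) > thresh])
    if flagged:
        log.info("%s: %d influential observations flagged (Cook's d > %.4g)",
                 model_id, len(flagged), thresh)
    return ModelFit(
        model_id=model_id,
        coefficients=_coef_table(res),
        adjusted_r2=float(res.rsquared_adj),
        aic=float(res.aic),
        vif=vif,
        cooks_distance=np.asarray(cooks),
        n=len(sub),
        flagged_observations=flagged,
    )


def univariate_screen(
    data: pd.DataFrame,
    candidates: Sequence[str],
    outcome: str = "delta_mvpa",
    alpha_entry: float = 0.15,
    centre_coding: str = "ordinal",
    min_cases: int = 20,
) -> List[ScreenResult]:
    """Adjusted univariate association of each candidate with MVPA change.

    One regression per candidate (outcome on candidate + the standard
    adjusters), complete-case per candidate; a candidate is flagged for
    model entry when its p value is below ``alpha_entry``.  Zero-variance
    candidates and candidates with fewer than ``min_cases`` complete cases
    are skipped with a warning.
    """
    results: List[ScreenResult] = []
    for cand in candidates:
        cols = [outcome, cand, *_ADJUSTERS]
        sub = _complete_cases(data, cols, f"screen:{cand}")
        if len(sub) < min_cases:
            log.warning("screen: %s skipped (%d complete cases < %d)",
                        cand, len(sub), min_cases)
            continue
        if pd.to_numeric(sub[cand]).nunique() <= 1:
            log.warning("screen: %s skipped (zero variance)", cand)
            continue
        X = _build_design(sub, [cand, *_ADJUSTERS], centre_coding)
        res = sm.OLS(pd.to_numeric(sub[outcome]), X).fit()
        ci = res.conf_int().loc[cand]
        p = float(res.pvalues[cand])
        results.append(
            ScreenResult(
                covariate=cand,
                beta=float(res.params[cand]),
                ci_low=float(ci[0]),
                ci_high=float(ci[1]),
                p_value=p,
                n=len(sub),
                flagged=p < alpha_entry,
            )
        )
    return results


def fit_multivariable(
    model_id: str,
    covariates: Sequence[str],
    data: pd.DataFrame,
    outcome: str = "delta_mvpa",
    centre_coding: str = "ordinal",
    cooks_flag: Optional[float] = None,
) -> ModelFit:
    """One multivariable predictor model with mutual adjustment.

    OLS of MVPA change on the selected covariates plus baseline MVPA,
    group, NT-proBNP stratum and centre; reports coefficients with CIs,
    adjusted R^2, AIC, per-predictor VIF and per-observation Cook's
    distances.  Influential observations are flagged, never removed.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}")
    return _fit_ols_model(model_id, data, covariates, outcome, centre_coding, cooks_flag)


class PredictorModels:
    """The screened model-1/2/3 workflow for baseline predictors of change.

    Model 1 draws on socio-demographic and medical-history candidates,
    model 2 on exercise-capacity and health-status candidates; model 3
    combines the significant (p < alpha_significant) predictors of models
    1 and 2 and therefore cannot be fitted before them.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        m1_candidates: Sequence[str],
        m2_candidates: Sequence[str],
        outcome: str = "delta_mvpa",
        alpha_entry: float = 0.15,
        alpha_significant: float = 0.05,
        centre_coding: str = "ordinal",
        cooks_flag: Optional[float] = None,
    ) -> None:
        self.data = data
        self.m1_candidates = list(m1_candidates)
        self.m2_candidates = list(m2_candidates)
        self.outcome = outcome
        self.alpha_entry = alpha_entry
        self.alpha_significant = alpha_significant
        self.centre_coding = centre_coding
        self.cooks_flag = cooks_flag
        self.screen_results: Optional[List[ScreenResult]] = None
        self.fits: Dict[str, ModelFit] = {}

    def screen(self) -> List[ScreenResult]:
        self.screen_results = univariate_screen(
            self.data,
            self.m1_candidates + self.m2_candidates,
            outcome=self.outcome,
            alpha_entry=self.alpha_entry,
            centre_coding=self.centre_coding,
        )
        return self.screen_results

    def _selected(self, pool: Sequence[str]) -> List[str]:
        if self.screen_results is None:
            self.screen()
        flagged = {r.covariate for r in self.screen_results if r.flagged}
        return [c for c in pool if c in flagged]

    def _fit(self, model_id: str, covariates: Sequence[str]) -> ModelFit:
        fit = fit_multivariable(
            model_id, covariates, self.data, outcome=self.outcome,
            centre_coding=self.centre_coding, cooks_flag=self.cooks_flag,
        )
        self.fits[model_id] = fit
        return fit

    def fit_m1(self) -> ModelFit:
        return self._fit("m1_sociodemographic", self._selected(self.m1_candidates))

    def fit_m2(self) -> ModelFit:
        return self._fit("m2_exercise_health", self._selected(self.m2_candidates))

    def fit_m3(self) -> ModelFit:
        if "m1_sociodemographic" not in self.fits or "m2_exercise_health" not in self.fits:
            raise SequencingError("model 3 requires models 1 and 2 to be fitted first")
        survivors: List[str] = []
        pools = {"m1_sociodemographic": self.m1_candidates,
                 "m2_exercise_health": self.m2_candidates}
        for mid, pool in pools.items():
            coefs = self.fits[mid].coefficients
            for term in pool:
                if term in coefs.index and coefs.loc[term, "p"] < self.alpha_significant:
                    survivors.append(term)
        return self._fit("m3_combined", survivors)

    def run(self) -> Dict[str, ModelFit]:
        self.screen()
        self.fit_m1()
        self.fit_m2()
        self.fit_m3()
        return self.fits


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

_TABLE_ROWS = [
    ("all_days", "mvpa"), ("all_days", "light"), ("all_days", "inactive"),
    ("weekend", "mvpa"), ("weekend", "light"), ("weekend", "inactive"),
    ("weekday", "mvpa"), ("weekday", "light"), ("weekday", "inactive"),
]


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def report_table2(
    visit_df: pd.DataFrame,
    covariates: pd.DataFrame,
    baseline_visit: str = "baseline",
    followup_visit: str = "final_followup",
    bouting: str = "bouted",
    centre_coding: str = "indicator",
):
    """Arm-level PA outcomes at baseline/follow-up with adjusted effects.

    ``visit_df`` is the per-visit PA table (one row per subject-visit, flat
    outcome columns); ``covariates`` carries subject_id, group, bnp2000 and
    centre.  Per outcome row: mean (SD) per arm at both visits, the arm
    means of per-subject change scores, and the baseline-adjusted
    between-group effect.  Unpaired subjects are excluded with a log entry.
    Returns ``(numeric_table, formatted_table, effects)``.
    """
    base = visit_df[visit_df["visit"] == baseline_visit].set_index("subject_id")
    follow = visit_df[visit_df["visit"] == followup_visit].set_index("subject_id")
    paired = base.index.intersection(follow.index)
    unpaired = len(base.index.union(follow.index)) - len(paired)
    if unpaired:
        log.info("outcome table: %d unpaired subject-visits excluded", unpaired)
    cov = covariates.set_index("subject_id").loc[paired]

    rows = []
    fmt_rows = []
    effects: List[EffectEstimate] = []
    for stratum, cat in _TABLE_ROWS:
        col = f"{stratum}_{cat}_{bouting}"
        b = base.loc[paired, col].astype(float)
        f = follow.loc[paired, col].astype(float)
        delta = change_score(b, f)
        data = pd.DataFrame(
            {
                "baseline": b,
                "followup": f,
                "group": cov["group"],
                "bnp2000": cov["bnp2000"],
                "centre": cov["centre"],
            }
        )
        eff = ancova_effect(
            data,
            centre_coding=centre_coding,
            outcome_name=f"{stratum}_{cat}",
            stratum=stratum,
            bouting=bouting,
            visit=followup_visit,
        )
        effects.append(eff)
        row = {"stratum": stratum, "category": cat}
        frow = {"stratum": stratum, "category": cat}
        for arm in ("intervention", "control"):
            sel = cov["group"] == arm
            row[f"{arm}_n"] = int(sel.sum())
            for label, series in (("baseline", b), ("followup", f), ("delta", delta)):
                m, s = float(series[sel].mean()), float(series[sel].std(ddof=1))
                row[f"{arm}_{label}_mean"] = m
                row[f"{arm}_{label}_sd"] = s
                frow[f"{arm}_{label}"] = f"{_fmt(m)} ({_fmt(s)})"
        row.update(effect=eff.beta, ci_low=eff.ci_low, ci_high=eff.ci_high, p=eff.p_value)
        frow["effect"] = (
            f"{_fmt(eff.beta)} ({_fmt(eff.ci_low)} to {_fmt(eff.ci_high)}) p={eff.p_value:.2f}"
        )
        rows.append(row)
        fmt_rows.append(frow)
    return pd.DataFrame(rows), pd.DataFrame(fmt_rows), effects
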