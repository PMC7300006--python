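"""Looking-time response models for the playback trials.

Three fixed-effects condition models (condition 1 vs 2-4; condition 3 vs
4; condition 5 vs 6, each with trial order and conflict intensity as
controls) and one mixed model of the dyadic social covariates with a
random subject intercept.  Every model is fitted by maximum likelihood
(not REML) so likelihood-ratio tests against the control-only null are
valid, and comes with collinearity (VIF) and residual-normality
diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "ModelFit",
    "LRTResult",
    "fit_condition_model",
    "fit_relationship_model",
    "vif",
    "residual_checks",
    "CONDITION_MODEL_SPECS",
]

# which conditions each condition model compares, and its reference level
CONDITION_MODEL_SPECS = {
    1: ((1, 2, 3, 4), 1),
    2: ((3, 4), 3),
    3: ((5, 6), 5),
}


@dataclass(frozen=True)
class LRTResult:
    chi2: float
    df: int
    p_value: float


@dataclass
class ModelFit:
    terms: pd.DataFrame          # index=term, columns: estimate, se, t, p
    log_likelihood: float
    n_obs: int
    random_effects: dict[str, float] | None  # variance components
    fitted: np.ndarray
    residuals: np.ndarray
    family: str                  # "ols" | "lmm"
    converged: bool = True
    singular: bool = False


def _lrt(ll_full: float, ll_null: float, df: int) -> LRTResult:
    chi2 = max(0.0, 2.0 * (ll_full - ll_null))
    return LRTResult(chi2=chi2, df=df, p_value=float(stats.chi2.sf(chi2, df)))


def _term_table(params, bse, tvals, pvals) -> pd.DataFrame:
    return pd.DataFrame({
        "estimate": params, "se": bse, "t": tvals, "p": pvals,
    })


def _clean_trials(trials: pd.DataFrame) -> pd.DataFrame:
    t = trials.copy()
    if "skipped" in t.columns:
        t = t[~t["skipped"].astype(bool)]
    return t.dropna(subset=["look_time"])


def fit_condition_model(trials: pd.DataFrame, which: int = 1
                        ) -> tuple[ModelFit, LRTResult]:
    """Fit one of the three condition models and test it against its null.

    The model regresses look time on condition (treatment contrasts with
    the first-listed condition as reference) plus trial order and
    conflict intensity; the null keeps only the controls.  The LRT
    chi-square has df = number of non-reference conditions.
    """
    if which not in CONDITION_MODEL_SPECS:
        raise ValueError("which must be 1, 2 or 3")
    conds, ref = CONDITION_MODEL_SPECS[which]
    t = _clean_trials(trials)
    t = t[t["condition"].isin(conds)].copy()
    counts = t["condition"].value_counts()
    thin = [c for c in conds if counts.get(c, 0) < 2]
    if thin:
        raise ValueError(f"conditions with fewer than 2 trials: {thin}")
    t["condition"] = pd.Categorical(t["condition"], categories=list(conds))

    formula = (f"look_time ~ C(condition, Treatment(reference={ref})) "
               "+ trial_order + conflict_intensity")
    full = smf.ols(formula, data=t).fit()
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        aliased = [n for n, b in zip(full.model.exog_names, np.isnan(full.params))
                   if b]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    null = smf.ols("look_time ~ trial_order + conflict_intensity", data=t).fit()
    lrt = _lrt(full.llf, null.llf, df=len(conds) - 1)

    terms = _term_table(full.params, full.bse, full.tvalues, full.pvalues)
    terms.index = [_pretty_term(n, ref) for n in terms.index]
    fit = ModelFit(terms=terms, log_likelihood=float(full.llf), n_obs=int(full.nobs),
                   random_effects=None, fitted=np.asarray(full.fittedvalues),
                   residuals=np.asarray(full.resid), family="ols")
    return fit, lrt


def _pretty_term(name: str, ref: int) -> str:
    if name.startswith("C(condition"):
        level = name.split("[T.")[-1].rstrip("]")
        return f"condition_{level}"
    return {"Intercept": f"condition_{ref} (reference)"}.get(name, name)


RELATIONSHIP_PREDICTORS = [
    "friendship_between_callers",
    "relatedness_between_callers",
    "elo_diff",
    "subject_centrality",
]


def fit_relationship_model(trials: pd.DataFrame) -> tuple[ModelFit, LRTResult]:
    """Mixed model of look time on the dyadic social covariates.

    Fixed effects: friendship between callers, relatedness between
    callers, |Elo difference| between callers, subject centrality, and
    the trial-order control; random intercept for subject.  Fitted by ML
    so the LRT against the control-only null (same random structure) is
    valid.  A singular random-intercept fit is flagged and refit as a
    fixed-effects model with a warning.
    """
    t = _clean_trials(trials)
    per_subj = t.groupby("subject_id").size()
    if (per_subj < 2).all():
        raise ValueError("random subject intercept needs subjects with >= 2 trials")
    fixed = " + ".join(RELATIONSHIP_PREDICTORS + ["trial_order"])
    formula = f"look_time ~ {fixed}"

    def _mixed(fml: str):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return smf.mixedlm(fml, data=t, groups=t["subject_id"]).fit(reml=False)

    full = _mixed(formula)
    null = _mixed("look_time ~ trial_order")
    singular = bool(full.cov_re.to_numpy().min() < 1e-8) or not full.converged
    if singular:
        warnings.warn("singular random-intercept fit; falling back to a "
                      "fixed-effects model", stacklevel=2)
        full_f = smf.ols(formula, data=t).fit()
        null_f = smf.ols("look_time ~ trial_order", data=t).fit()
        lrt = _lrt(full_f.llf, null_f.llf, df=len(RELATIONSHIP_PREDICTORS))
        terms = _term_table(full_f.params, full_f.bse, full_f.tvalues, full_f.pvalues)
        fit = ModelFit(terms=terms, log_likelihood=float(full_f.llf),
                       n_obs=int(full_f.nobs), random_effects={"subject": 0.0},
                       fitted=np.asarray(full_f.fittedvalues),
                       residuals=np.asarray(full_f.resid), family="ols",
                       singular=True)
        return fit, lrt

    lrt = _lrt(full.llf, null.llf, df=len(RELATIONSHIP_PREDICTORS))
    fe = full.fe_params.index
    terms = _term_table(full.fe_params, full.bse.loc[fe], full.tvalues.loc[fe],
                        full.pvalues.loc[fe])
    re_var = float(full.cov_re.iloc[0, 0])
    fitted = np.asarray(full.fittedvalues)
    fit = ModelFit(terms=terms, log_likelihood=float(full.llf), n_obs=int(full.nobs),
                   random_effects={"subject": re_var,
                                   "residual": float(full.scale)},
                   fitted=fitted,
                   residuals=t["look_time"].to_numpy() - fitted,
                   family="lmm", converged=bool(full.converged))
    return fit, lrt


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: 1 / (1 - R²_j) from
    regressing each column on all the others (plus an intercept).

    Perfectly collinear predictors report ``inf``.
    """
    x = design.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 predictors for a VIF")
    out = {}
    for j, name in enumerate(design.columns):
        y = x[:, j]
        others = sm.add_constant(np.delete(x, j, axis=1))
        r2 = sm.OLS(y, others).fit().rsquared
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def residual_checks(fit: ModelFit, plot_path=None) -> dict:
    """Residual-normality diagnostics: QQ data, skewness, kurtosis and a
    Shapiro-Wilk test.  Optionally writes a QQ plot."""
    r = np.asarray(fit.residuals, dtype=float)
    if r.std() == 0:
        return {"zero_variance": True, "skewness": 0.0, "kurtosis": 0.0,
                "shapiro_stat": np.nan, "shapiro_p": np.nan,
                "qq_theoretical": [], "qq_sample": []}
    (osm, osr), _ = stats.probplot(r, dist="norm", fit=True)
    sh = stats.shapiro(r)
    report = {
        "zero_variance": False,
        "skewness": float(stats.skew(r)),
        "kurtosis": float(stats.kurtosis(r)),
        "shapiro_stat": float(sh.statistic),
        "shapiro_p": float(sh.pvalue),
        "qq_theoretical": osm.tolist(),
        "qq_sample": osr.tolist(),
    }
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(osm, osr, s=8)
        lim = [min(osm.min(), osr.min()), max(osm.max(), osr.max())]
        ax.plot(lim, lim, color="grey", lw=1)
        ax.set_xlabel("theoretical quantiles")
        ax.set_ylabel("sample quantiles")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=100)
        plt.close(fig)
        report["plot"] = str(plot_path)
    return report
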