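"""Random-intercept linear mixed models linking memory, evidence and RT.

Three model families, all with a Gaussian random intercept per subject and
RT in milliseconds (restricted maximum likelihood):

* Model 1: RT ~ TargetMemoryScore x TrialType, all accurate trials;
  treatment coding with "other" as the reference trial type, memory score
  entered as the raw 0-4 count.
* Model 2: RT ~ probe-context evidence in the three trial periods, fit
  separately per trial type; a "nonprobe" variant substitutes the mean
  nonprobe-context delay evidence.
* Model 3: RT ~ delay evidence x overlap, lure trials only, overlap
  uncentered.

p-values use the Wald normal approximation by default; ``df="residual"``
switches to a t reference with n_obs - n_fixed - n_subjects degrees of
freedom (a conservative stand-in when subject counts are small).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

__all__ = [
    "FitResult",
    "fit_random_intercept_lm",
    "model1",
    "model2",
    "model3",
]

TRIAL_TYPE_ORDER = ["other", "target", "lure"]


@dataclass
class FitResult:
    params: pd.DataFrame  # index: term; columns beta, ci_low, ci_high, p
    group_var: float
    n_obs: int
    n_subjects: int
    converged: bool
    formula: str

    def beta(self, term: str) -> float:
        return float(self.params.loc[term, "beta"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.params.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])

    def p(self, term: str) -> float:
        return float(self.params.loc[term, "p"])


def _check_rank(model) -> None:
    X = model.exog
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design matrix is rank deficient")


def fit_random_intercept_lm(
    table: pd.DataFrame,
    formula: str,
    groups: str = "subject",
    df_method: str = "normal",
) -> FitResult:
    """REML fit of ``formula`` with a random intercept per ``groups`` level."""
    if table[groups].nunique() < 2:
        raise ValueError("need >= 2 subjects")
    model = smf.mixedlm(formula, data=table, groups=table[groups])
    _check_rank(model)
    # fit on unit-scaled endog/exog for numerical stability, then transform
    # the estimates back; the model itself is unchanged
    import statsmodels.api as sm
    import warnings

    y_sd = float(np.std(model.endog)) or 1.0
    x_sd = model.exog.std(axis=0)
    x_sd = np.where(x_sd == 0, 1.0, x_sd)
    ys, Xs = model.endog / y_sd, model.exog / x_sd
    scaled = sm.MixedLM(ys, Xs, groups=model.groups)
    # explicit start values: OLS fixed effects plus a moment estimate of the
    # intercept variance — without them the optimizer can report convergence
    # with corrupt fixed effects when the variance sits on the zero boundary
    from statsmodels.regression.mixed_linear_model import MixedLMParams

    fe0, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    resid = ys - Xs @ fe0
    groups_arr = np.asarray(model.groups)
    gmeans = pd.Series(resid).groupby(pd.Series(groups_arr)).mean()
    cov0 = max(float(gmeans.var(ddof=1)), 1e-3)
    start = MixedLMParams.from_components(fe_params=fe0, cov_re=np.array([[cov0]]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = scaled.fit(reml=True, method="lbfgs", start_params=start)
        except np.linalg.LinAlgError:
            fit = None
        if fit is None or not fit.converged or np.any(~np.isfinite(fit.bse_fe)):
            fit = scaled.fit(reml=True, start_params=start)
    back = y_sd / x_sd
    fe = pd.Series(np.asarray(fit.fe_params) * back, index=model.exog_names)
    se = pd.Series(np.asarray(fit.bse_fe) * back, index=model.exog_names)
    z = fe / se
    if df_method == "normal":
        crit = stats.norm.ppf(0.975)
        p = 2 * stats.norm.sf(np.abs(z))
    elif df_method == "residual":
        dof = max(len(table) - len(fe) - table[groups].nunique(), 1)
        crit = stats.t.ppf(0.975, dof)
        p = 2 * stats.t.sf(np.abs(z), dof)
    else:
        raise ValueError(f"unknown df_method {df_method!r}")
    params = pd.DataFrame(
        {"beta": fe, "se": se, "ci_low": fe - crit * se, "ci_high": fe + crit * se, "p": p}
    )
    return FitResult(
        params=params,
        group_var=float(np.asarray(fit.cov_re).ravel()[0]) * y_sd**2,
        n_obs=int(len(table)),
        n_subjects=int(table[groups].nunique()),
        converged=bool(fit.converged),
        formula=formula,
    )


def _rt_table(table: pd.DataFrame) -> pd.DataFrame:
    df = table.copy()
    bad = df["rt_ms"].isna() | (df["rt_ms"] <= 0)
    if "accurate" in df:
        bad |= ~df["accurate"].astype(bool)
    return df[~bad]


def model1(table: pd.DataFrame, df_method: str = "normal") -> FitResult:
    """RT ~ 1 + TargetMemoryScore * TrialType + (1 | subject)."""
    df = _rt_table(table)
    present = set(df["probe_type"].unique())
    if present != set(TRIAL_TYPE_ORDER):
        raise ValueError(f"all three trial types required; got {sorted(present)}")
    df["probe_type"] = pd.Categorical(df["probe_type"], categories=TRIAL_TYPE_ORDER)
    formula = "rt_ms ~ target_memory_score * probe_type"
    return fit_random_intercept_lm(df, formula, df_method=df_method)


def model2(
    table: pd.DataFrame,
    probe_type: str,
    evidence_source: str = "probe",
    df_method: str = "normal",
) -> FitResult:
    """RT ~ period evidences + (1 | subject), one probe type at a time.

    ``evidence_source="probe"`` uses probe-context evidence in the three
    trial periods (columns ev_target_presentation / ev_delay /
    ev_probe_presentation); ``"nonprobe"`` substitutes the mean
    nonprobe-context evidence (columns ev_nonprobe_*).
    """
    df = _rt_table(table)
    df = df[df["probe_type"] == probe_type]
    if df["subject"].nunique() < 2 or df.groupby("subject").size().min() < 2:
        raise ValueError("need >= 2 subjects with >= 2 trials of this type")
    prefix = "ev" if evidence_source == "probe" else "ev_nonprobe"
    cols = [f"{prefix}_target_presentation", f"{prefix}_delay", f"{prefix}_probe_presentation"]
    for c in cols:
        if df[c].std(ddof=0) == 0:
            raise ValueError(f"evidence column {c} is constant")
    formula = "rt_ms ~ " + " + ".join(cols)
    return fit_random_intercept_lm(df, formula, df_method=df_method)


def model3(table: pd.DataFrame, df_method: str = "normal") -> FitResult:
    """RT ~ delay evidence x overlap + (1 | subject), lure trials only."""
    df = _rt_table(table)
    df = df[df["probe_type"] == "lure"]
    if df["overlap"].std(ddof=0) == 0:
        raise ValueError("overlap has zero variance")
    formula = "rt_ms ~ ev_delay * overlap"
    return fit_random_intercept_lm(df, formula, df_method=df_method)
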