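"""Cohort-level inference: mixed models, logistic regressions, sample size.

The headline longitudinal comparison models a daily activity feature over
day 1..90 with a linear mixed model: fixed effects for disease group
(RA vs axSpA) and baseline covariates, a fixed linear day trend, and
per-participant random intercepts and slopes on day.  Residual
heteroscedasticity can be modelled with a power-of-the-mean variance
function, Var(e) = sigma^2 |mu|^(2*theta): for a given theta the model is
refitted exactly as a row-rescaled mixed model (dividing response, fixed
and random design rows by |mu|^theta yields homoscedastic errors), and
theta itself is estimated from the slope of log|residual| on log|fitted|,
iterated to stability.  It is engaged only when a residual-vs-fitted
slope test detects heteroscedasticity (the "when observed" convention).

Logistic models (guideline fulfilment; low-activity-cluster membership)
use maximum likelihood with Wald confidence intervals; age enters
dichotomised at 60 years and the BMI odds ratio is reported per 5-unit
increase.  The design-stage sample size uses the normal-approximation
two-means formula.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil, sqrt
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

DEFAULT_COVARIATES = ["sex", "age", "bmi", "disease_duration",
                      "biologic", "employed", "ptga"]


class CollinearityError(ValueError):
    """Raised when a model design matrix is rank deficient."""


@dataclass
class LmmResult:
    """Fixed effects and variance components of the longitudinal model."""

    fixed_effects: pd.DataFrame  # term, estimate, se, p
    group_term: str
    group_estimate: float
    group_p: float
    variance_components: dict
    variance_power: float | None
    converged: bool
    n_participants: int
    n_observations: int
    diagnostics: dict = field(default_factory=dict)


@dataclass
class LogisticResult:
    """Odds ratios with Wald 95% CIs for a binary cohort outcome."""

    table: pd.DataFrame  # term, estimate, se, or, ci_low, ci_high, p
    converged: bool
    separation_flag: bool
    n: int
    n_events: int

    def odds_ratio(self, term: str) -> pd.Series:
        row = self.table[self.table["term"] == term]
        if len(row) == 0:
            raise KeyError(f"no term {term!r} in logistic result")
        return row.iloc[0]


def _design_matrix(
    df: pd.DataFrame, covariates: Sequence[str], age_cut: float | None = None
) -> pd.DataFrame:
    """Numeric design columns for the requested covariates.

    Categorical two-level covariates become 0/1 indicators.  When
    ``age_cut`` is given, age is replaced by an ``age_ge_<cut>``
    indicator (the logistic-model convention).
    """
    X = pd.DataFrame(index=df.index)
    for c in covariates:
        v = df[c]
        if c == "age" and age_cut is not None:
            X[f"age_ge_{int(age_cut)}"] = (v >= age_cut).astype(float)
        elif v.dtype == bool:
            X[c] = v.astype(float)
        elif v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(v.dropna()))
            if len(levels) > 2:
                raise ValueError(f"covariate {c!r} has more than two levels: {levels}")
            X[f"{c}_{levels[-1]}"] = (v == levels[-1]).astype(float)
        else:
            X[c] = v.astype(float)
    return X


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise CollinearityError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} "
            f"columns {list(names)}); remove collinear covariates"
        )


def fit_group_lmm(
    data: pd.DataFrame,
    response: str = "steps_total",
    group_col: str = "group",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    participant_col: str = "participant_id",
    day_col: str = "day",
    variance_power: str | float | None = "auto",
    random_slope: bool = True,
    het_alpha: float = 0.05,
) -> LmmResult:
    """REML fit of the day-level group comparison.

    ``data`` holds one row per participant-day.  ``variance_power``:
    ``"auto"`` engages the power variance function only when a residual
    slope test is significant at ``het_alpha``; ``None``/``"none"``
    disables it; a float fixes theta.  Numerical optimisation of the
    homoscedastic (or rescaled) model is delegated to statsmodels'
    MixedLM; the variance-function estimation wrapping it is ours.
    """
    df = data[[participant_col, day_col, group_col, response, *covariates]].dropna()
    groups_present = df.groupby(group_col)[participant_col].nunique()
    if len(groups_present) < 2 or (groups_present < 2).any():
        raise ValueError(
            f"group comparison needs >=2 groups with >=2 participants each; "
            f"got {groups_present.to_dict()}"
        )
    levels = sorted(groups_present.index)
    gname = f"{group_col}_{levels[-1]}"

    y = df[response].to_numpy(dtype=float)
    scale = max(np.std(y), 1e-12)  # keep the optimizer well-scaled
    t = (df[day_col].to_numpy(dtype=float) - 45.5) / 90.0
    X = _design_matrix(df, covariates)
    X.insert(0, gname, (df[group_col] == levels[-1]).astype(float).to_numpy())
    X.insert(0, "const", 1.0)
    if np.ptp(t) > 0:  # a constant day column would alias the intercept
        X["day_c"] = t
    _check_rank(X.to_numpy(), X.columns)
    exog_re = np.column_stack([np.ones(len(df)), t]) if random_slope \
        else np.ones((len(df), 1))

    def _fit(w: np.ndarray):
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            m = sm.MixedLM(y / scale / w, X.to_numpy() / w[:, None],
                           groups=df[participant_col].to_numpy(),
                           exog_re=exog_re / w[:, None])
            try:
                r = m.fit(reml=True)
            except np.linalg.LinAlgError:
                r = m.fit(reml=True, method="powell")
        conv = r.converged and not any(
            "ConvergenceWarning" in str(x.category) for x in wlist)
        return r, conv

    w = np.ones(len(df))
    res, converged = _fit(w)
    # conditional fitted values (fixed + predicted random effects), the
    # same convention nlme's varPower weights by
    mu = np.asarray(res.fittedvalues) * scale * w
    het = _heteroscedasticity_test(mu, y - mu)
    theta: float | None = None
    want_power = (
        (variance_power == "auto" and het["p"] < het_alpha)
        or isinstance(variance_power, (int, float))
    )
    if want_power:
        theta = float(variance_power) if isinstance(variance_power, (int, float)) \
            else float(het["slope"])
        for _ in range(4):
            w = np.power(np.clip(np.abs(mu) / np.median(np.abs(mu)), 1e-6, None), theta)
            res, converged = _fit(w)
            mu = np.asarray(res.fittedvalues) * scale * w
            if isinstance(variance_power, (int, float)):
                break
            # remaining mean-variance slope of the rescaled residuals
            het_i = _heteroscedasticity_test(mu, (y - mu) / w)
            if abs(het_i["slope"]) < 0.01 or het_i["p"] >= het_alpha:
                break
            theta += float(het_i["slope"])

    k_fe = X.shape[1]
    params = np.asarray(res.fe_params) * scale
    se = np.asarray(res.bse[:k_fe]) * scale
    pvals = np.asarray(res.pvalues[:k_fe])
    fixed = pd.DataFrame({"term": list(X.columns), "estimate": params,
                          "se": se, "p": pvals})
    gi = list(X.columns).index(gname)
    vc = {"re_cov": (np.asarray(res.cov_re) * scale**2).tolist(),
          "residual_var": float(res.scale) * scale**2}
    return LmmResult(
        fixed_effects=fixed,
        group_term=gname,
        group_estimate=float(params[gi]),
        group_p=float(pvals[gi]),
        variance_components=vc,
        variance_power=theta,
        converged=bool(converged),
        n_participants=int(df[participant_col].nunique()),
        n_observations=len(df),
        diagnostics={"heteroscedasticity": het},
    )


def _heteroscedasticity_test(fitted: np.ndarray, resid: np.ndarray) -> dict:
    """Slope of log|residual| on log|fitted| with its p-value."""
    fitted = np.asarray(fitted, dtype=float)
    resid = np.asarray(resid, dtype=float)
    ok = (np.abs(fitted) > 1e-12) & (np.abs(resid) > 1e-12)
    if ok.sum() < 10:
        return {"slope": 0.0, "p": 1.0, "n": int(ok.sum())}
    lr = sps.linregress(np.log(np.abs(fitted[ok])), np.log(np.abs(resid[ok])))
    return {"slope": float(lr.slope), "p": float(lr.pvalue), "n": int(ok.sum())}


def _fit_logistic(
    y: np.ndarray, X: pd.DataFrame, or_rescale: dict[str, float] | None = None
) -> LogisticResult:
    if y.min() == y.max():
        raise ValueError("logistic outcome has a single class; cannot fit")
    _check_rank(X.to_numpy(), X.columns)
    separation = False
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        model = sm.Logit(y, X.to_numpy())
        try:
            res = model.fit(disp=False, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception as exc:  # PerfectSeparationError and kin
            raise ValueError(f"logistic fit failed ({exc}); check for separation")
        for x in wlist:
            if "separation" in str(x.message).lower():
                separation = True
    params = np.asarray(res.params)
    se = np.asarray(res.bse)
    if not np.all(np.isfinite(se)) or np.max(se) > 50:
        separation = True
    z = sps.norm.ppf(0.975)
    or_rescale = or_rescale or {}
    rows = []
    for i, term in enumerate(X.columns):
        c = or_rescale.get(term, 1.0)
        b, s = params[i] * c, se[i] * c
        rows.append({
            "term": term if c == 1.0 else f"{term} (per {c:g} units)",
            "estimate": params[i], "se": se[i],
            "or": float(np.exp(b)),
            "ci_low": float(np.exp(b - z * s)),
            "ci_high": float(np.exp(b + z * s)),
            "p": float(res.pvalues[i]),
        })
    return LogisticResult(
        table=pd.DataFrame(rows),
        converged=converged,
        separation_flag=separation,
        n=len(y),
        n_events=int(y.sum()),
    )


def fit_who_logistic(
    statuses: pd.DataFrame,
    covariates_table: pd.DataFrame,
    outcome: str = "who_met",
    group_col: str = "group",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    age_cut: float = 60.0,
) -> LogisticResult:
    """Adjusted odds of guideline fulfilment for the disease group.

    ``statuses`` is the who_status table; covariates come from the cohort
    table.  BMI's odds ratio is additionally reported per 5-unit
    increase.
    """
    cov = covariates_table.drop(columns=[outcome], errors="ignore")
    df = statuses[["participant_id", outcome]].merge(
        cov, on="participant_id", how="inner").dropna(
        subset=[outcome, group_col, *covariates])
    y = df[outcome].astype(float).to_numpy()
    levels = sorted(pd.unique(df[group_col]))
    X = _design_matrix(df, covariates, age_cut=age_cut)
    X.insert(0, f"{group_col}_{levels[-1]}",
             (df[group_col] == levels[-1]).astype(float))
    X.insert(0, "const", 1.0)
    return _fit_logistic(y, X, or_rescale={"bmi": 5.0})


def fit_low_cluster_logistic(
    model,
    covariates_table: pd.DataFrame,
    group_col: str = "group",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    age_cut: float = 60.0,
) -> LogisticResult:
    """Adjusted odds of belonging to the low-activity trajectory cluster.

    The low cluster is label 0 (lowest centroid grand mean).  BMI's odds
    ratio is reported per 5-unit increase and age enters dichotomised at
    ``age_cut`` years.
    """
    assignments = model.assignments if hasattr(model, "assignments") else model
    y_series = (assignments == 0).astype(float)
    if y_series.sum() == 0:
        raise ValueError("low-activity cluster is empty")
    df = covariates_table.set_index("participant_id").join(
        y_series.rename("low"), how="inner").dropna(
        subset=["low", group_col, *covariates])
    y = df["low"].to_numpy()
    levels = sorted(pd.unique(df[group_col]))
    X = _design_matrix(df, covariates, age_cut=age_cut)
    X.insert(0, f"{group_col}_{levels[-1]}",
             (df[group_col] == levels[-1]).astype(float))
    X.insert(0, "const", 1.0)
    return _fit_logistic(y, X, or_rescale={"bmi": 5.0})


def sample_size_two_means(
    delta: float,
    sd: float,
    power: float = 0.80,
    alpha: float = 0.05,
    method: str = "normal",
) -> int:
    """Participants per group to detect a mean difference ``delta``.

    Normal approximation (default): n = ceil(2 (z_{1-a/2} + z_{1-b})^2
    (sd/delta)^2), floored at 1.  ``method="t"`` solves the
    noncentral-t power equation instead (slightly larger n).
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if not 0.0 < power < 1.0:
        raise ValueError("power must be in (0, 1)")
    if method == "normal":
        z = sps.norm.ppf(1 - alpha / 2) + sps.norm.ppf(power)
        n = 2.0 * (z * sd / delta) ** 2
        return max(int(ceil(n - 1e-9)), 1)
    if method == "t":
        from statsmodels.stats.power import TTestIndPower
        n = TTestIndPower().solve_power(effect_size=delta / sd, power=power,
                                        alpha=alpha, alternative="two-sided")
        return max(int(ceil(n - 1e-9)), 1)
    raise ValueError(f"unknown method {method!r}")
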