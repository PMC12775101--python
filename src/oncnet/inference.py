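"""Balance diagnostics, propensity/IPTW, outcome models, and the
weighted paired t-test.

Standardized mean differences compare ever- vs never-connected
physicians at baseline: continuous covariates use the pooled-SD form
|m1-m2| / sqrt((v1+v2)/2), binary covariates the analogous
proportion-variance form, and K-category covariates the Mahalanobis
form on K-1 category proportions with the average multinomial
covariance. Propensity scores come from a logistic regression of
ever-connected status on all covariates with unweighted SMD >= 0.1, and
IPTW weights are the ATE form 1/p and 1/(1-p).

Outcome models are design-weighted linear mixed models of the one-year
outcome change on the connection count, with crossed random intercepts
for hospital referral region (geographic clustering) and physician
(repeated annual observations), fitted separately by practice rurality.
A Bonferroni correction over the five outcome families sets the
per-test significance threshold (0.05 / 5 = 0.01) and the matching 99%
confidence level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitFailureError, InvalidInputError
from .lmm import MixedFitResult, fit_crossed_lmm


# ---------------------------------------------------------------------------
# standardized mean differences


def smd(summary_1, summary_2, kind: str) -> float:
    """Standardized mean difference from group summaries.

    continuous: (mean, sd) per group; binary: proportion per group;
    multinomial: full K-vector of category proportions per group.
    """
    if kind == "continuous":
        (m1, s1), (m2, s2) = summary_1, summary_2
        denom = np.sqrt((s1**2 + s2**2) / 2)
        return 0.0 if denom == 0 and m1 == m2 else abs(m1 - m2) / denom
    if kind == "binary":
        p1, p2 = float(summary_1), float(summary_2)
        v1, v2 = p1 * (1 - p1), p2 * (1 - p2)
        denom = np.sqrt((v1 + v2) / 2)
        return 0.0 if denom == 0 and p1 == p2 else abs(p1 - p2) / denom
    if kind == "multinomial":
        p1 = np.asarray(summary_1, float)[:-1]
        p2 = np.asarray(summary_2, float)[:-1]
        T = p1 - p2
        S = (_multinomial_cov(p1) + _multinomial_cov(p2)) / 2
        try:
            sol = np.linalg.solve(S, T)
        except np.linalg.LinAlgError as exc:
            raise FitFailureError(f"singular multinomial covariance: {exc}") from exc
        return float(np.sqrt(T @ sol))
    raise InvalidInputError(f"unknown covariate kind {kind!r}")


def _multinomial_cov(p: np.ndarray) -> np.ndarray:
    return np.diag(p) - np.outer(p, p)


def _wmean(x, w):
    return float(np.sum(w * x) / np.sum(w))


def _wsd(x, w):
    m = _wmean(x, w)
    return float(np.sqrt(np.sum(w * (x - m) ** 2) / np.sum(w)))


def summarize(x: pd.Series, kind: str, weights=None, categories=None):
    """Group summary in the shape `smd` expects, optionally IPTW-weighted."""
    x = pd.Series(x)
    w = np.ones(len(x)) if weights is None else np.asarray(weights, float)
    ok = x.notna().to_numpy()
    x, w = x[ok], w[ok]
    if kind == "continuous":
        arr = x.to_numpy(float)
        return (_wmean(arr, w), _wsd(arr, w))
    if kind == "binary":
        return _wmean(x.to_numpy(float), w)
    if kind == "multinomial":
        cats = list(categories) if categories is not None else sorted(x.unique())
        tot = np.sum(w)
        return np.array([np.sum(w[(x == c).to_numpy()]) / tot for c in cats])
    raise InvalidInputError(f"unknown covariate kind {kind!r}")


#: baseline covariates entering the balance table: (column, kind)
BALANCE_COVARIATES = [
    ("male", "binary"),
    ("specialty", "multinomial"),
    ("rural", "binary"),
    ("panel_pct_hispanic", "continuous"),
    ("panel_pct_nh_black", "continuous"),
    ("panel_pct_nh_white", "continuous"),
    ("volume_category", "multinomial"),
    ("baseline_strength", "continuous"),
    ("baseline_transitivity", "continuous"),
    ("baseline_constraint", "continuous"),
    ("baseline_linchpin", "continuous"),
]

_CATEGORY_ORDER = {
    "specialty": ["medical oncology", "radiation oncology", "surgery"],
    "volume_category": ["low", "medium", "high"],
}


def balance_table(
    baseline: pd.DataFrame,
    connected: pd.Series,
    weights: pd.Series | None = None,
    covariates=None,
) -> pd.DataFrame:
    """Per-covariate unweighted and IPTW-weighted SMDs between ever- and
    never-connected physicians at baseline."""
    covariates = covariates or [
        (c, k) for c, k in BALANCE_COVARIATES if c in baseline.columns
    ]
    grp1 = connected.reindex(baseline.index).astype(bool)
    rows = []
    for col, kind in covariates:
        cats = _CATEGORY_ORDER.get(col)
        args = {"categories": cats} if kind == "multinomial" else {}
        s1 = summarize(baseline.loc[grp1, col], kind, **args)
        s2 = summarize(baseline.loc[~grp1, col], kind, **args)
        unw = smd(s1, s2, kind)
        wtd = np.nan
        if weights is not None:
            w = weights.reindex(baseline.index)
            keep = w.notna()  # physicians in the propensity sample
            g1, g2 = grp1 & keep, ~grp1 & keep
            s1w = summarize(
                baseline.loc[g1, col], kind, weights=w[g1].to_numpy(), **args
            )
            s2w = summarize(
                baseline.loc[g2, col], kind, weights=w[g2].to_numpy(), **args
            )
            wtd = smd(s1w, s2w, kind)
        rows.append((col, kind, unw, wtd))
    return pd.DataFrame(
        rows, columns=["covariate", "kind", "smd_unweighted", "smd_weighted"]
    )


# ---------------------------------------------------------------------------
# propensity / IPTW


@dataclass
class PropensityFit:
    covariates: list
    scores: pd.Series
    weights: pd.Series
    model: object


def _design(baseline: pd.DataFrame, covariates) -> pd.DataFrame:
    cols = {}
    for col, kind in covariates:
        if kind == "multinomial":
            cats = _CATEGORY_ORDER.get(col, sorted(baseline[col].dropna().unique()))
            for c in cats[1:]:
                cols[f"{col}[{c}]"] = (baseline[col] == c).astype(float)
        else:
            cols[col] = baseline[col].astype(float)
    return pd.DataFrame(cols, index=baseline.index)


def fit_propensity(
    baseline: pd.DataFrame,
    connected: pd.Series,
    smd_threshold: float = 0.1,
    truncation: tuple | None = None,
) -> PropensityFit:
    """Logistic propensity of ever being connected to a departing
    oncologist, using every covariate whose unweighted SMD meets the
    threshold; attaches ATE-form IPTW weights (optionally truncated at
    symmetric weight percentiles)."""
    import statsmodels.api as sm

    bal = balance_table(baseline, connected)
    selected = [
        (c, k)
        for (c, k), s in zip(
            [(r.covariate, r.kind) for r in bal.itertuples(index=False)],
            bal["smd_unweighted"],
        )
        if s >= smd_threshold
    ]
    if not selected:
        raise FitFailureError(
            f"no covariate reaches the SMD threshold {smd_threshold}"
        )
    X = _design(baseline, selected)
    ok = X.notna().all(axis=1)
    Xc = sm.add_constant(X[ok], has_constant="add")
    yv = connected.reindex(baseline.index)[ok].astype(float)
    try:
        model = sm.GLM(yv, Xc, family=sm.families.Binomial()).fit(maxiter=200)
    except Exception as exc:
        raise FitFailureError(f"propensity fit failed: {exc}") from exc
    if not getattr(model, "converged", True) or not np.all(
        np.isfinite(model.params)
    ):
        sep = X.columns[int(np.argmax(np.abs(model.params.values[1:])))]
        raise FitFailureError(f"propensity fit did not converge (suspect {sep!r})")
    p = model.predict(Xc).clip(1e-8, 1 - 1e-8)
    w = np.where(yv.astype(bool), 1.0 / p, 1.0 / (1.0 - p))
    w = pd.Series(w, index=p.index)
    if truncation is not None:
        lo, hi = np.percentile(w, truncation)
        w = w.clip(lo, hi)
    return PropensityFit(
        covariates=selected,
        scores=pd.Series(p, index=p.index),
        weights=w,
        model=model,
    )


# ---------------------------------------------------------------------------
# outcome models


@dataclass
class ModelResult:
    stratum: str
    outcome: str
    exposure: str
    k: int
    coef: float
    ci_low: float
    ci_high: float
    p_value: float
    significant: bool
    n_obs: int
    n_physicians: int
    fit: MixedFitResult


def fit_outcome_model(
    analysis: pd.DataFrame,
    outcome: str,
    exposure: str = "exposure_any",
    weights: pd.Series | None = None,
    stratum: str = "rural",
    k: int = 2,
    alpha: float = 0.01,
) -> ModelResult:
    """Design-weighted crossed random-intercept model of one outcome
    change on the per-year connection count within one rurality stratum.

    Returns the per-connection coefficient with its (1 - alpha) Wald CI
    and p-value; `significant` applies the Bonferroni-corrected
    threshold alpha.
    """
    if stratum not in ("rural", "urban"):
        raise InvalidInputError("stratum must be 'rural' or 'urban'")
    sub = analysis[analysis["rural"] == (stratum == "rural")]
    ycol = f"delta_{outcome}" if not outcome.startswith("delta_") else outcome
    sub = sub[sub[ycol].notna()]
    if weights is not None:
        w = sub["physician_id"].map(weights)
        sub = sub[w.notna()]
        w = w[w.notna()].to_numpy(float)
    else:
        w = None
    if len(sub) < 5:
        raise FitFailureError(f"too few rows ({len(sub)}) in stratum {stratum!r}")
    y = sub[ycol].to_numpy(float)
    X = np.column_stack([np.ones(len(sub)), sub[exposure].to_numpy(float)])
    fit = fit_crossed_lmm(
        y,
        X,
        groups={"hrr": sub["hrr_id"].to_numpy(), "physician": sub["physician_id"].to_numpy()},
        weights=w,
        exog_names=("intercept", exposure),
    )
    ci = fit.conf_int(alpha=alpha)
    pv = float(fit.pvalues()[1])
    return ModelResult(
        stratum=stratum,
        outcome=outcome,
        exposure=exposure,
        k=k,
        coef=float(fit.params[1]),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        p_value=pv,
        significant=pv < alpha,
        n_obs=len(sub),
        n_physicians=sub["physician_id"].nunique(),
        fit=fit,
    )


def bonferroni_threshold(alpha_family: float = 0.05, n_tests: int = 5) -> float:
    """Per-test significance threshold controlling the family-wise
    two-sided type-I error at `alpha_family` over `n_tests` models."""
    if n_tests < 1:
        raise InvalidInputError("n_tests must be >= 1")
    return alpha_family / n_tests


# ---------------------------------------------------------------------------
# weighted paired t-test


@dataclass
class PairedTestResult:
    stratum: str
    tie_subset: str
    mean_change: float
    sd_change: float
    n: int
    n_eff: float
    t_stat: float
    p_value: float


def weighted_paired_ttest(
    pre, post, weights, stratum: str = "", tie_subset: str = ""
) -> PairedTestResult:
    """Paired t-test of post - pre with IPTW weights.

    The standard error uses the Kish effective sample size
    n_eff = (sum w)^2 / sum w^2, inflating uncertainty to reflect the
    weighted sample's reduced information; the reference distribution is
    Student t with n_eff - 1 (possibly fractional) degrees of freedom.
    With equal weights this is exactly the classical paired t-test.
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    w = np.asarray(weights, float)
    if len(pre) != len(post) or len(pre) != len(w):
        raise InvalidInputError("pre, post and weights must align")
    if np.any(w <= 0):
        raise InvalidInputError("weights must be positive")
    d = post - pre
    n_eff = float(np.sum(w) ** 2 / np.sum(w**2))
    if n_eff <= 1:
        raise InvalidInputError(f"effective sample size {n_eff:.2f} <= 1")
    dbar = _wmean(d, w)
    s2 = np.sum(w * (d - dbar) ** 2) / np.sum(w) * n_eff / (n_eff - 1)
    se = np.sqrt(s2 / n_eff)
    t = dbar / se
    p = 2 * stats.t.sf(abs(t), df=n_eff - 1)
    return PairedTestResult(
        stratum=stratum,
        tie_subset=tie_subset,
        mean_change=dbar,
        sd_change=float(np.sqrt(s2)),
        n=len(d),
        n_eff=n_eff,
        t_stat=float(t),
        p_value=float(p),
    )
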