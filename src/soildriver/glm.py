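"""Gaussian log-link GLM fitting, scope-constrained stepwise AIC selection,
and model diagnostics.

Model fitting stands on :mod:`statsmodels`.  A "term" is one column of the
input frame; a categorical column (e.g. the ecosystem factor) is a single
term expanded to reference-coded dummy columns in the design.  AIC is
computed as ``-2*logLik + 2*(p + 1)`` with the Gaussian dispersion estimated
as RSS/n, so the dispersion parameter is counted alongside the ``p``
regression coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "FittedGLM",
    "build_design",
    "fit_glm",
    "stepwise_aic",
    "two_stage_selection",
    "vif_check",
    "residual_diagnostics",
]

_LINKS = {
    "log": sm.families.links.Log,
    "identity": sm.families.links.Identity,
}


def build_design(data: pd.DataFrame, terms: list[str]) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Design matrix (with intercept) and the term -> design-column map.

    Numeric columns enter as-is; categorical/object columns are expanded by
    reference-level dummy coding (first level dropped).
    """
    cols: dict[str, pd.Series] = {"const": pd.Series(1.0, index=data.index)}
    term_columns: dict[str, list[str]] = {}
    for term in terms:
        col = data[term]
        if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
            dummies = pd.get_dummies(col, prefix=term, drop_first=True, dtype=float)
            term_columns[term] = list(dummies.columns)
            for c in dummies.columns:
                cols[c] = dummies[c]
        else:
            term_columns[term] = [term]
            cols[term] = col.astype(float)
    return pd.DataFrame(cols, index=data.index), term_columns


@dataclass
class FittedGLM:
    """A fitted Gaussian GLM with selection metadata and diagnostics."""

    response: str
    terms: list[str]
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    llf: float
    aic: float
    fittedvalues: pd.Series
    resid: pd.Series
    term_columns: dict[str, list[str]]
    converged: bool
    link: str = "log"
    r2: float = np.nan
    mae: float = np.nan
    mse: float = np.nan
    rmse: float = np.nan
    groups: dict[str, str] = field(default_factory=dict)
    stage1: "FittedGLM | None" = None
    path: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def nobs(self) -> int:
        return len(self.fittedvalues)

    def summary(self) -> str:
        coef = pd.DataFrame(
            {"coef": self.params, "std err": self.bse, "t": self.tvalues}
        )
        lines = [
            f"Gaussian GLM ({self.link} link)  response: {self.response}",
            f"n = {self.nobs}   terms = {len(self.terms)}   converged = {self.converged}",
            f"AIC = {self.aic:.3f}   logLik = {self.llf:.3f}",
            f"r2 = {self.r2:.4f}   MAE = {self.mae:.4f}   "
            f"MSE = {self.mse:.4f}   RMSE = {self.rmse:.4f}",
            "",
            coef.to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        if self.groups:
            lines += ["", "driver groups: " + ", ".join(f"{t}={g}" for t, g in self.groups.items())]
        return "\n".join(lines)


def _r2_pred_obs(pred: np.ndarray, obs: np.ndarray) -> float:
    """Squared Pearson correlation of predicted vs observed (the study's
    GLM performance metric); 0 when either side is constant."""
    if np.std(pred) == 0 or np.std(obs) == 0:
        return 0.0
    return float(np.corrcoef(pred, obs)[0, 1] ** 2)


def fit_glm(
    data: pd.DataFrame,
    response: str,
    terms: list[str],
    link: str = "log",
    maxiter: int = 100,
    tol: float = 1e-8,
) -> FittedGLM:
    """Maximum-likelihood Gaussian-family fit with the given link.

    On IRLS failure with the default start, retries from OLS coefficients of
    ``log(max(y, eps))`` (log link only).  A fit that still fails is
    returned flagged ``converged=False`` with infinite AIC and NaN
    diagnostics so stepwise can skip it.
    """
    y = data[response].astype(float)
    x, term_columns = build_design(data, list(terms))
    n, k = x.shape
    if n <= k:
        raise ValueError(f"n={n} must exceed number of design columns k={k}")
    family = sm.families.Gaussian(_LINKS[link]())

    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, x, family=family).fit(maxiter=maxiter, tol=tol)
        except Exception:
            res = None
        if res is None and link == "log":
            try:
                z = np.log(np.maximum(y, max(y[y > 0].min() if (y > 0).any() else 1.0, 1e-8)))
                start = np.linalg.lstsq(x.to_numpy(), z, rcond=None)[0]
                res = sm.GLM(y, x, family=family).fit(
                    maxiter=maxiter, tol=tol, start_params=start
                )
            except Exception:
                res = None

    if res is None or not np.all(np.isfinite(res.params)):
        nan = pd.Series(np.nan, index=x.columns)
        return FittedGLM(
            response=response, terms=list(terms), params=nan, bse=nan, tvalues=nan,
            llf=-np.inf, aic=np.inf, fittedvalues=pd.Series(np.nan, index=y.index),
            resid=pd.Series(np.nan, index=y.index), term_columns=term_columns,
            converged=False, link=link,
        )

    mu = np.asarray(res.fittedvalues, dtype=float)
    resid = y.to_numpy() - mu
    rss = float(resid @ resid)
    if rss <= 0:
        llf, aic = np.inf, -np.inf  # degenerate perfect fit
    else:
        sigma2 = rss / n
        llf = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        aic = -2.0 * llf + 2.0 * (k + 1)  # +1 for the dispersion parameter

    return FittedGLM(
        response=response,
        terms=list(terms),
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        llf=llf,
        aic=aic,
        fittedvalues=pd.Series(mu, index=y.index),
        resid=pd.Series(resid, index=y.index),
        term_columns=term_columns,
        converged=bool(getattr(res, "converged", True)),
        link=link,
        r2=_r2_pred_obs(mu, y.to_numpy()),
        mae=float(np.mean(np.abs(resid))),
        mse=float(np.mean(resid**2)),
        rmse=float(np.sqrt(np.mean(resid**2))),
    )


def stepwise_aic(
    data: pd.DataFrame,
    response: str,
    start_terms: list[str],
    scope_lower: list[str],
    scope_upper: list[str],
    direction: str = "both",
    link: str = "log",
) -> FittedGLM:
    """Bidirectional AIC stepwise selection within a scope.

    From the start model, repeatedly evaluates single-term additions (from
    ``scope_upper``) and deletions (terms outside ``scope_lower``), accepting
    the move with the largest AIC decrease; terminates when no move lowers
    the AIC.  AIC ties among candidate moves are broken by preferring
    deletion over addition, then lexicographic term name.  Candidate fits
    that fail to converge are skipped with a warning.

    The accepted move path (``(move, term, aic)`` triples, starting with
    ``("start", "", aic)``) is recorded on the returned fit.
    """
    lower, upper = set(scope_lower), set(scope_upper)
    if not lower <= upper:
        raise ValueError("scope_lower must be a subset of scope_upper")
    if not set(start_terms) <= upper:
        raise ValueError("start model must be nested in scope_upper")
    if direction not in ("both", "forward", "backward"):
        raise ValueError(f"unknown direction {direction!r}")

    current = list(start_terms)
    fit = fit_glm(data, response, current, link=link)
    path = [("start", "", fit.aic)]

    while True:
        candidates: list[tuple[float, int, str, str]] = []  # (aic, move_rank, term, move)
        if direction in ("both", "backward"):
            for t in current:
                if t in lower:
                    continue
                trial = [u for u in current if u != t]
                f = fit_glm(data, response, trial, link=link)
                if not f.converged:
                    warnings.warn(f"candidate drop {t!r} did not converge; skipped")
                    continue
                candidates.append((f.aic, 0, t, "drop"))
        if direction in ("both", "forward"):
            for t in sorted(upper - set(current)):
                trial = current + [t]
                f = fit_glm(data, response, trial, link=link)
                if not f.converged:
                    warnings.warn(f"candidate add {t!r} did not converge; skipped")
                    continue
                candidates.append((f.aic, 1, t, "add"))
        if not candidates:
            break
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        best_aic, _, term, move = candidates[0]
        if not best_aic < fit.aic - 1e-10:
            break
        current = [u for u in current if u != term] if move == "drop" else current + [term]
        fit = fit_glm(data, response, current, link=link)
        path.append((move, term, fit.aic))

    fit.path = path
    return fit


def two_stage_selection(
    data: pd.DataFrame,
    response: str,
    soil_terms: list[str],
    climate_terms: list[str],
    pesticide_terms: list[str],
    ecosystem_term: str | None = "ecosystem",
    start: str = "intercept",
    link: str = "log",
) -> FittedGLM:
    """The two-stage scope-constrained selection.

    Stage 1 selects among soil, climate and ecosystem terms (preventing
    biased selection of pesticides that merely track environment).  Stage 2
    re-runs stepwise with the stage-1 retained terms locked in
    (``scope_lower``) and pesticide terms allowed to enter only if they
    lower the AIC.  The returned stage-2 fit carries per-term driver-group
    labels and the stage-1 fit.
    """
    env_terms = list(soil_terms) + list(climate_terms)
    if ecosystem_term is not None and ecosystem_term in data.columns:
        env_terms.append(ecosystem_term)
    start_terms = env_terms if start == "full" else []
    stage1 = stepwise_aic(data, response, start_terms, [], env_terms, link=link)

    upper = stage1.terms + [t for t in pesticide_terms if t not in stage1.terms]
    final = stepwise_aic(data, response, stage1.terms, stage1.terms, upper, link=link)

    group_of = {t: "soil" for t in soil_terms}
    group_of.update({t: "climate" for t in climate_terms})
    group_of.update({t: "pesticides" for t in pesticide_terms})
    if ecosystem_term is not None:
        group_of[ecosystem_term] = "ecosystem"
    final.groups = {t: group_of.get(t, "other") for t in final.terms}
    final.stage1 = stage1
    return final


def vif_check(model: FittedGLM, data: pd.DataFrame, threshold: float = 10.0) -> pd.DataFrame:
    """Generalized variance inflation factors per term.

    Single-column terms get the classical ``VIF = 1/(1 - R^2_j)``; a
    multi-column factor term gets the generalized VIF
    ``det(R_11) det(R_22) / det(R)`` reported (additionally) as
    ``GVIF^(1/(2 df))``.  Exact collinearity yields an infinite VIF and a
    flag.
    """
    x, term_columns = build_design(data, model.terms)
    x = x.drop(columns="const")
    if sum(len(v) for v in term_columns.values()) < 2:
        raise ValueError("VIF needs >= 2 non-intercept design columns")
    corr = np.corrcoef(x.to_numpy(float), rowvar=False)
    names = list(x.columns)
    det_all = np.linalg.det(corr)
    rows = []
    for term, cols in term_columns.items():
        idx = [names.index(c) for c in cols]
        rest = [i for i in range(len(names)) if i not in idx]
        if not rest:
            continue
        d1 = np.linalg.det(corr[np.ix_(idx, idx)])
        d2 = np.linalg.det(corr[np.ix_(rest, rest)])
        if det_all <= 1e-12:
            gvif = np.inf
        else:
            gvif = d1 * d2 / det_all
        df = len(cols)
        adj = gvif ** (1.0 / (2 * df)) if np.isfinite(gvif) else np.inf
        rows.append(
            {
                "term": term,
                "df": df,
                "gvif": gvif,
                "gvif_adj": adj,
                "flagged": (not np.isfinite(gvif)) or (adj**2 > threshold if df == 1 else
                                                       adj > np.sqrt(threshold)),
            }
        )
    return pd.DataFrame(rows).set_index("term")


def residual_diagnostics(model: FittedGLM) -> dict:
    """Normality summary of the response residuals.

    Returns the residuals, their normal-QQ correlation coefficient, and the
    Shapiro-Wilk statistic and p-value.  Zero residuals are reported as a
    perfect fit.
    """
    from scipy import stats

    resid = model.resid.to_numpy(float)
    if np.allclose(resid, 0):
        return {"residuals": model.resid, "qq_corr": 1.0, "shapiro_w": 1.0,
                "shapiro_p": 1.0, "perfect_fit": True}
    (osm, osr), (slope, intercept, r) = stats.probplot(resid, dist="norm")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w, p = stats.shapiro(resid) if len(resid) <= 5000 else stats.shapiro(resid[:5000])
    return {"residuals": model.resid, "qq_corr": float(r), "shapiro_w": float(w),
            "shapiro_p": float(p), "perfect_fit": False}
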