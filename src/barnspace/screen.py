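"""Exhaustive AICc screening of linear models for each space-use measure.

For each response S_i, every marginality-respecting combination of the
predictors L (lameness), P (parity), D (days in milk) and their interaction
terms is fitted by OLS and ranked by small-sample-corrected AIC. The best
model is then put through a diagnostic battery (Shapiro-Wilk normality of
residuals, Cook-Weisberg non-constant-variance score test, variance
inflation factors) and an automated outlier-removal protocol.

AICc here counts the error variance as a parameter:
    k* = #slopes + intercept + 1,  AICc = -2 ll + 2 k* + 2 k*(k*+1)/(n-k*-1).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

PREDICTORS = ("L", "P", "D")
ALPHA = 0.05
VIF_THRESHOLD = 10.0


class SingularityError(ValueError):
    """Design matrix is rank deficient."""


def _term_name(components: tuple[str, ...]) -> str:
    return ":".join(components)


def enumerate_models(predictors=PREDICTORS) -> list[tuple[str, ...]]:
    """All marginality-respecting term sets over the predictors.

    A term set may contain an interaction only if all its constituent main
    effects are present. The intercept-only (empty) set is included. Order
    is deterministic: by term-set size, then lexicographic.
    """
    predictors = tuple(predictors)
    if not predictors:
        raise ValueError("need at least one predictor")
    models: list[tuple[str, ...]] = []
    for r in range(len(predictors) + 1):
        for mains in itertools.combinations(predictors, r):
            inters = [
                _term_name(c)
                for k in range(2, len(mains) + 1)
                for c in itertools.combinations(mains, k)
            ]
            for s in range(len(inters) + 1):
                for chosen in itertools.combinations(inters, s):
                    models.append(tuple(mains) + chosen)
    models.sort(key=lambda terms: (len(terms), terms))
    return models


def respects_marginality(terms) -> bool:
    present = set(terms)
    for t in terms:
        parts = t.split(":")
        if len(parts) > 1 and not all(p in present for p in parts):
            return False
    return True


def design_matrix(data: pd.DataFrame, terms) -> pd.DataFrame:
    """Column per term; interaction columns are products of main columns."""
    cols = {}
    for t in terms:
        parts = t.split(":")
        col = data[parts[0]].astype(float).copy()
        for p in parts[1:]:
            col = col * data[p].astype(float)
        cols[t] = col
    X = pd.DataFrame(cols, index=data.index)
    return sm.add_constant(X, has_constant="add")


@dataclass
class LinearModelFit:
    """One fitted OLS model for one response."""

    response: str
    terms: tuple[str, ...]
    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    aicc: float
    fvalue: float
    f_pvalue: float
    n: int
    llf: float
    shapiro_p: float = math.nan
    ncv_p: float = math.nan
    vif: dict[str, float] = field(default_factory=dict)
    removed_ids: tuple[str, ...] = ()
    normality_ok: bool | None = None
    homoscedastic: bool | None = None
    error: str | None = None
    _res: object = field(default=None, repr=False, compare=False)

    @property
    def significant_terms(self) -> tuple[str, ...]:
        return tuple(
            t for t in self.terms if self.pvalues.get(t, 1.0) < ALPHA
        )

    @property
    def intercept_only(self) -> bool:
        return not self.terms


def aicc_gaussian(llf: float, n: int, n_coef: int) -> float:
    """AICc for a Gaussian model; parameter count includes the variance."""
    k = n_coef + 1
    if n - k - 1 <= 0:
        return math.nan
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_linear(
    data: pd.DataFrame, response: str, terms, *, check_rank: bool = True
) -> LinearModelFit:
    """OLS fit of one term set; raises SingularityError on collinear terms."""
    terms = tuple(terms)
    if not respects_marginality(terms):
        raise ValueError(f"term set {terms} violates marginality")
    sub = data.dropna(subset=[response, *{p for t in terms for p in t.split(":")}])
    y = sub[response].astype(float)
    X = design_matrix(sub, terms)
    n = len(sub)
    if n < X.shape[1] + 1:
        raise ValueError(f"too few rows (n={n}) for {X.shape[1]} coefficients")
    if check_rank and np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise SingularityError(f"collinear design for terms {terms}")
    res = sm.OLS(y, X).fit()
    aicc = aicc_gaussian(res.llf, n, len(res.params))
    return LinearModelFit(
        response=response,
        terms=terms,
        params={k: float(v) for k, v in res.params.items()},
        bse={k: float(v) for k, v in res.bse.items()},
        pvalues={k: float(v) for k, v in res.pvalues.items()},
        aicc=float(aicc),
        fvalue=float(res.fvalue) if terms else math.nan,
        f_pvalue=float(res.f_pvalue) if terms else math.nan,
        n=n,
        llf=float(res.llf),
        _res=res,
    )


def ncv_test(res) -> float:
    """Cook-Weisberg score test of residual variance against fitted values.

    Returns the chi-square (1 df) p-value; NaN for degenerate residuals.
    """
    e = np.asarray(res.resid, dtype=float)
    n = e.size
    if n < 3 or np.allclose(e, e[0]):
        return math.nan
    sigma2 = float(e @ e) / n
    u = e**2 / sigma2
    z = sm.add_constant(np.asarray(res.fittedvalues, dtype=float))
    aux = sm.OLS(u, z).fit()
    ss_reg = float(((aux.fittedvalues - u.mean()) ** 2).sum())
    stat = ss_reg / 2.0
    return float(st.chi2.sf(stat, df=1))


def vif_scores(data: pd.DataFrame, predictors=PREDICTORS) -> dict[str, float]:
    """VIF_j = 1/(1 - R^2_j) from regressing predictor j on the others."""
    out = {}
    cols = [p for p in predictors if p in data.columns]
    for p in cols:
        others = [q for q in cols if q != p]
        if not others:
            out[p] = 1.0
            continue
        X = sm.add_constant(data[others].astype(float))
        r2 = sm.OLS(data[p].astype(float), X).fit().rsquared
        out[p] = float("inf") if r2 >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2))
    return out


def diagnostics(fit: LinearModelFit) -> LinearModelFit:
    """Attach Shapiro-Wilk, NCV and VIF results to a fitted model."""
    res = fit._res
    if res is None:
        raise ValueError("fit carries no underlying regression result")
    e = np.asarray(res.resid, dtype=float)
    if e.size >= 3 and not np.allclose(e, e[0]):
        fit.shapiro_p = float(st.shapiro(e).pvalue)
    fit.ncv_p = ncv_test(res)
    mains = sorted({p for t in fit.terms for p in t.split(":")})
    if mains:
        exog = pd.DataFrame(res.model.exog, columns=res.model.exog_names)
        fit.vif = vif_scores(exog, predictors=[m for m in mains if m in exog])
    fit.normality_ok = bool(fit.shapiro_p >= ALPHA) if not math.isnan(fit.shapiro_p) else None
    fit.homoscedastic = bool(fit.ncv_p >= ALPHA) if not math.isnan(fit.ncv_p) else None
    return fit


def outlier_protocol(
    data: pd.DataFrame,
    response: str,
    terms,
    *,
    id_col: str = "cow_id",
    max_removals: int = 2,
    alpha: float = ALPHA,
    forced_ids: tuple[str, ...] = (),
) -> LinearModelFit:
    """Greedy studentized-residual removal until residuals pass normality.

    While the Shapiro-Wilk test rejects at ``alpha`` and fewer than
    ``max_removals`` observations have been dropped, the observation with
    the largest absolute (externally) studentized residual is removed and
    the model refitted. ``forced_ids`` are removed up front, which allows
    replicating a published named-id protocol exactly.
    """
    work = data[~data[id_col].astype(str).isin([str(i) for i in forced_ids])].copy()
    removed = [str(i) for i in forced_ids if str(i) in set(data[id_col].astype(str))]
    fit = diagnostics(fit_linear(work, response, terms))
    while (
        not math.isnan(fit.shapiro_p)
        and fit.shapiro_p < alpha
        and len(removed) < max_removals
    ):
        infl = fit._res.get_influence()
        stud = np.abs(infl.resid_studentized_external)
        worst = int(np.argmax(stud))
        worst_id = str(work[id_col].iloc[worst])
        work = work.drop(work.index[worst])
        removed.append(worst_id)
        try:
            fit = diagnostics(fit_linear(work, response, terms))
        except ValueError:
            fit.removed_ids = tuple(removed[:-1])
            return fit
    fit.removed_ids = tuple(removed)
    return fit


@dataclass
class ScreenReport:
    """Per-response best models plus global collinearity diagnostics."""

    fits: list[LinearModelFit]
    vif: dict[str, float]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for f in self.fits:
            rows.append(
                {
                    "response": f.response,
                    "terms": "+".join(f.terms) if f.terms else "(intercept)",
                    "aicc": f.aicc,
                    "f_stat": f.fvalue,
                    "f_pvalue": f.f_pvalue,
                    "coefficients": ";".join(
                        f"{k}={v:.6g}" for k, v in f.params.items()
                    ),
                    "pvalues": ";".join(
                        f"{k}={v:.4g}" for k, v in f.pvalues.items()
                    ),
                    "shapiro_p": f.shapiro_p,
                    "ncv_p": f.ncv_p,
                    "removed_ids": ",".join(f.removed_ids),
                    "n": f.n,
                    "significant_terms": "+".join(f.significant_terms),
                    "error": f.error or "",
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        def clean(v):
            return None if isinstance(v, float) and math.isnan(v) else v

        payload = {
            "vif": {k: clean(v) for k, v in self.vif.items()},
            "responses": [
                {
                    "response": f.response,
                    "terms": list(f.terms),
                    "params": {k: clean(v) for k, v in f.params.items()},
                    "pvalues": {k: clean(v) for k, v in f.pvalues.items()},
                    "aicc": clean(f.aicc),
                    "f_stat": clean(f.fvalue),
                    "f_pvalue": clean(f.f_pvalue),
                    "shapiro_p": clean(f.shapiro_p),
                    "ncv_p": clean(f.ncv_p),
                    "removed_ids": list(f.removed_ids),
                    "n": f.n,
                }
                for f in self.fits
            ],
        }
        return json.dumps(payload, indent=2)


def select_best(
    data: pd.DataFrame, response: str, predictors=PREDICTORS
) -> LinearModelFit:
    """Fit every enumerated model and return the minimum-AICc fit.

    Candidate AICc values come from a direct least-squares pass (identical
    to the OLS fit but without the inference overhead); the winning term
    set is then refitted through :func:`fit_linear`.
    """
    sub = data.dropna(subset=[response, *predictors])
    y = sub[response].astype(float).to_numpy()
    n = len(y)
    cols = {p: sub[p].astype(float).to_numpy() for p in predictors}
    best_terms, best_aicc = None, math.inf
    for terms in enumerate_models(predictors):
        k_coef = len(terms) + 1
        if n - (k_coef + 1) - 1 <= 0:
            continue
        X = np.ones((n, k_coef))
        for j, t in enumerate(terms, start=1):
            col = np.ones(n)
            for p in t.split(":"):
                col = col * cols[p]
            X[:, j] = col
        if np.linalg.matrix_rank(X) < k_coef:
            continue
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        sigma2 = float(resid @ resid) / n
        if sigma2 <= 0:
            sigma2 = 1e-300
        llf = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1)
        aicc = aicc_gaussian(llf, n, k_coef)
        if aicc < best_aicc - 1e-12:
            best_terms, best_aicc = terms, aicc
    if best_terms is None:
        raise ValueError(f"no fittable model for response {response}")
    return fit_linear(data, response, best_terms)


def screen_all(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    *,
    responses=None,
    predictors=PREDICTORS,
    max_removals: int = 2,
    forced_removals: dict[str, tuple[str, ...]] | None = None,
) -> ScreenReport:
    """Run the full selection + diagnostics + outlier protocol battery.

    ``features`` holds cow_id and the S measures; ``metadata`` holds
    cow_id, lame, parity, dim. Responses defaulting to every S column
    present. Returns one final fit per response.
    """
    from .metrics import MEASURES

    data = features.merge(
        metadata.rename(
            columns={"lame": "L", "parity": "P", "dim": "D", "yield": "Y"}
        ),
        on="cow_id",
        how="inner",
    )
    if responses is None:
        responses = [m for m in MEASURES if m in data.columns]
    forced_removals = forced_removals or {}
    fits = []
    for resp in responses:
        try:
            usable = data.dropna(subset=[resp])
            best = select_best(usable, resp, predictors)
            final = outlier_protocol(
                usable,
                resp,
                best.terms,
                max_removals=max_removals,
                forced_ids=forced_removals.get(resp, ()),
            )
        except (ValueError, SingularityError) as e:
            final = LinearModelFit(
                response=resp,
                terms=(),
                params={},
                bse={},
                pvalues={},
                aicc=math.nan,
                fvalue=math.nan,
                f_pvalue=math.nan,
                n=0,
                llf=math.nan,
                error=str(e),
            )
        fits.append(final)
    return ScreenReport(fits=fits, vif=vif_scores(data, predictors))
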