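"""Logistic prediction of lameness status from space-use measures.

Candidate features are the measures whose screened linear model carried at
least one significant predictor. Every feature subset up to ``max_size`` is
fitted by maximum-likelihood logistic regression and ranked by AICc
(binomial likelihood, k = number of coefficients). Cows are classified as
lame when the fitted probability is >= 0.5 (ties go to lame).

Complete or quasi-separation at n = 20 is common; such fits are flagged and
their plain-ML coefficient table is withheld, but a ridge-stabilised refit
still provides a usable decision boundary and the fit keeps its place in
the AICc ranking (mirroring how an unpenalised IRLS fit would rank).
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

ALPHA = 0.05
_SEP_COEF_LIMIT = 100.0


def _measure_order(name: str) -> tuple:
    m = re.fullmatch(r"S(\d+)", name)
    return (0, int(m.group(1))) if m else (1, name)


def candidate_features(screen_report) -> list[str]:
    """Measures whose selected linear model has a significant predictor."""
    pool = [
        f.response
        for f in screen_report.fits
        if f.terms and any(p < ALPHA for t, p in f.pvalues.items() if t != "const")
    ]
    return sorted(pool, key=_measure_order)


@dataclass
class LogisticModelFit:
    """One candidate logistic model over a feature subset."""

    features: tuple[str, ...]
    params: dict[str, float] | None  # None when separation makes ML unstable
    aicc: float
    llf: float
    n: int
    probabilities: np.ndarray = field(repr=False, default=None)
    classes: np.ndarray = field(repr=False, default=None)
    correct: int = 0
    misclassified_ids: tuple[str, ...] = ()
    separated: bool = False
    converged: bool = True
    stabilized_params: dict[str, float] | None = None
    exclusion_reason: str | None = None

    @property
    def usable(self) -> bool:
        return self.exclusion_reason is None


def aicc_binomial(llf: float, n: int, n_coef: int) -> float:
    if n - n_coef - 1 <= 0:
        return math.nan
    return -2.0 * llf + 2.0 * n_coef + 2.0 * n_coef * (n_coef + 1) / (n - n_coef - 1)


def _ridge_logit(X: np.ndarray, y: np.ndarray, alpha: float = 0.1) -> np.ndarray:
    """Newton-iterated L2-penalised logistic fit (intercept unpenalised).

    Columns after the intercept are standardised internally so the penalty
    is scale-invariant; returned coefficients are on the original scale.
    """
    n, p = X.shape
    loc = X.mean(axis=0)
    scale = X.std(axis=0)
    loc[0], scale[0] = 0.0, 1.0  # intercept column untouched
    scale[scale <= 0] = 1.0
    Z = (X - loc) / scale
    beta = np.zeros(p)
    pen = alpha * np.eye(p)
    pen[0, 0] = 0.0
    for _ in range(200):
        mu = expit(Z @ beta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = Z.T @ (y - mu) - pen @ beta
        hess = Z.T @ (Z * w[:, None]) + pen
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            break
    out = beta / scale
    out[0] = beta[0] - float((beta[1:] * loc[1:] / scale[1:]).sum())
    return out


def _ml_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 100):
    """Plain maximum-likelihood logistic fit by damped Newton iteration.

    Works on an internally standardised design for numerical stability.
    Returns (beta, llf, converged, separated); ``separated`` is raised when
    coefficients diverge or the fit predicts the labels perfectly.
    """
    n, p = X.shape
    loc = X.mean(axis=0)
    scale = X.std(axis=0)
    loc[0], scale[0] = 0.0, 1.0
    scale[scale <= 0] = 1.0
    Z = (X - loc) / scale

    def loglik(b):
        eta = Z @ b
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    beta = np.zeros(p)
    ll = loglik(beta)
    converged = separated = False
    for _ in range(max_iter):
        mu = expit(Z @ beta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        grad = Z.T @ (y - mu)
        hess = Z.T @ (Z * w[:, None]) + 1e-12 * np.eye(p)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        # damped update: halve until the likelihood does not decrease
        lam, new_ll = 1.0, -np.inf
        for _half in range(30):
            cand = beta + lam * step
            new_ll = loglik(cand)
            if new_ll >= ll - 1e-12:
                break
            lam *= 0.5
        beta, improved, ll = cand, new_ll - ll, new_ll
        if np.abs(beta).max() > 30.0:  # standardised scale: clear divergence
            separated = True
            break
        if improved < 1e-10 and np.abs(grad).max() < 1e-6:
            converged = True
            break
    mu = expit(Z @ beta)
    if np.all(np.abs(mu - y) < 1e-8):
        separated = True
    out = beta / scale
    out[0] = beta[0] - float((beta[1:] * loc[1:] / scale[1:]).sum())
    return out, ll, converged, separated


def _fit_one(
    X: pd.DataFrame, y: np.ndarray, ids: np.ndarray, features: tuple[str, ...]
) -> LogisticModelFit:
    Xc = sm.add_constant(X[list(features)].astype(float), has_constant="add")
    n = len(y)
    arr = Xc.to_numpy(float)
    try:
        params, llf, converged, separated = _ml_logit(arr, y)
    except Exception:
        return LogisticModelFit(
            features, None, math.nan, math.nan, n, exclusion_reason="non-convergence"
        )
    if not converged and not separated:
        return LogisticModelFit(
            features, None, math.nan, llf, n, exclusion_reason="non-convergence"
        )
    probs = expit(arr @ params)
    if np.abs(params).max() > _SEP_COEF_LIMIT:
        separated = True

    stabilized = None
    if separated:
        # a separated ML fit has llf -> 0, which would collapse AICc to ~2k
        # and let any separating subset outrank every stable fit on noise;
        # rank it instead by the unpenalised likelihood at ridge-stabilised
        # coefficients, which scores the subset's genuine signal
        beta = _ridge_logit(arr, y)
        stabilized = dict(zip(Xc.columns, beta.tolist()))
        probs = expit(arr @ beta)
        pc = np.clip(probs, 1e-12, 1 - 1e-12)
        llf = float(np.sum(y * np.log(pc) + (1 - y) * np.log(1 - pc)))
    aicc = aicc_binomial(llf, n, len(params))
    if not np.isfinite(aicc) or not np.isfinite(llf):
        return LogisticModelFit(
            features, None, math.nan, llf, n, exclusion_reason="undefined AICc"
        )
    classes = (probs >= 0.5).astype(int)
    correct = int((classes == y).sum())
    wrong = tuple(str(i) for i in ids[classes != y])
    return LogisticModelFit(
        features=features,
        params=None if separated else dict(zip(Xc.columns, params.tolist())),
        aicc=float(aicc),
        llf=llf,
        n=n,
        probabilities=probs,
        classes=classes,
        correct=correct,
        misclassified_ids=wrong,
        separated=separated,
        converged=converged,
        stabilized_params=stabilized,
    )


def select_logistic(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    pool: list[str],
    *,
    max_size: int = 3,
    label_col: str = "lame",
) -> list[LogisticModelFit]:
    """Fit every subset of the pool up to ``max_size``; rank by AICc.

    Returns usable fits sorted ascending by AICc (separation-flagged fits
    keep their AICc rank), followed by excluded fits. The ranking is
    invariant to the order the pool is supplied in.
    """
    if not pool:
        raise ValueError("empty candidate-feature pool; classifier skipped")
    pool = sorted(set(pool), key=_measure_order)
    data = features.merge(metadata[["cow_id", label_col]], on="cow_id", how="inner")
    data = data.dropna(subset=pool + [label_col])
    y = data[label_col].astype(int).to_numpy()
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    ids = data["cow_id"].astype(str).to_numpy()
    fits = []
    for size in range(1, max_size + 1):
        for subset in itertools.combinations(pool, size):
            fits.append(_fit_one(data, y, ids, subset))
    # separated fits carry a ridge-stabilised likelihood (see _fit_one), so
    # a single AICc ordering applies to stable and flagged fits alike
    ranked = sorted(
        [f for f in fits if f.usable], key=lambda f: (f.aicc, len(f.features), f.features)
    )
    return ranked + [f for f in fits if not f.usable]


def predict(fit: LogisticModelFit, features: pd.DataFrame) -> pd.DataFrame:
    """Probabilities and classes for new cows; p >= 0.5 classifies as lame."""
    coef = fit.params if fit.params is not None else fit.stabilized_params
    if coef is None:
        raise ValueError("fit has no usable coefficients")
    missing_cols = [f for f in fit.features if f not in features.columns]
    if missing_cols:
        raise ValueError(f"missing feature column(s): {missing_cols}")
    X = sm.add_constant(
        features[list(fit.features)].astype(float), has_constant="add"
    )
    beta = np.array([coef[c] for c in X.columns])
    vals = X.to_numpy(float)
    ok = np.isfinite(vals).all(axis=1)
    p = np.full(len(X), math.nan)
    p[ok] = expit(vals[ok] @ beta)
    out = pd.DataFrame(
        {
            "probability": p,
            "predicted_lame": np.where(
                np.isnan(p), -1, (p >= 0.5).astype(int)
            ),
            "flagged": ~ok,
        },
        index=features.index,
    )
    if "cow_id" in features.columns:
        out.insert(0, "cow_id", features["cow_id"].astype(str))
    return out


def ranking_table(fits: list[LogisticModelFit]) -> pd.DataFrame:
    """Delimited-text-friendly view of a ranked fit list."""
    rows = []
    for f in fits:
        coef = f.params if f.params is not None else f.stabilized_params
        rows.append(
            {
                "subset": "+".join(f.features),
                "aicc": f.aicc,
                "coefficients": ";".join(f"{k}={v:.6g}" for k, v in coef.items())
                if coef
                else "",
                "correct": f.correct,
                "n": f.n,
                "misclassified_ids": ",".join(f.misclassified_ids),
                "separated": f.separated,
                "excluded": f.exclusion_reason or "",
            }
        )
    return pd.DataFrame(rows)
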