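"""Beta regression of the introgression index on environmental covariates.

Covers the whole modelling chain: Pearson pre-filter of correlated
covariates, scaling/centring, the VIF collinearity loop, maximum-likelihood
beta regression with a logit mean link (statsmodels BetaModel under the
hood), both-direction stepwise AIC selection and Cox-Snell generalized R^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.othermod.betareg import BetaModel

__all__ = [
    "FitResult",
    "correlation_filter",
    "standardize",
    "squeeze_unit_interval",
    "fit_beta",
    "stepwise_aic",
    "vif_loop",
    "generalized_r2",
    "run_env_model",
]


@dataclass
class FitResult:
    terms: list[str]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    loglik: float
    aic: float
    nobs: int
    converged: bool
    model: object = field(repr=False, default=None)


def correlation_filter(
    env: pd.DataFrame,
    covariates: list[str],
    r_max: float = 0.7,
    primary_set: list[str] | None = None,
    preferences: list[str] | None = None,
) -> list[str]:
    """Drop covariates that are Pearson-correlated at |r| >= r_max.

    Derived variables (those not in ``primary_set``) are dropped whenever
    they correlate with any primary variable. Among correlated primary
    pairs the one appearing earlier in ``preferences`` (falling back to
    input order) is kept. Deterministic: candidates are scanned in input
    order.
    """
    primary = set(primary_set) if primary_set is not None else set(covariates)
    prefs = list(preferences or [])

    def rank(name: str) -> tuple[int, int]:
        in_pref = prefs.index(name) if name in prefs else len(prefs)
        return (in_pref, covariates.index(name))

    corr = env[covariates].corr().abs()
    retained = [c for c in covariates if c in primary]
    # derived vs primary screen
    for c in covariates:
        if c in primary:
            continue
        if not any(corr.loc[c, p] >= r_max for p in retained):
            retained.append(c)
    # primary vs primary screen, preferred one wins
    retained_sorted = sorted(retained, key=rank)
    kept: list[str] = []
    for c in retained_sorted:
        if all(corr.loc[c, k] < r_max for k in kept):
            kept.append(c)
    return [c for c in covariates if c in kept]


def standardize(env: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Centre to mean 0 and scale to sd 1 (ddof=0); constant columns error."""
    out = env.copy()
    for c in covariates:
        x = out[c].to_numpy(float)
        sd = x.std()
        if sd == 0:
            raise ValueError(f"covariate {c!r} is constant")
        out[c] = (x - x.mean()) / sd
    return out


def squeeze_unit_interval(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """(y * (n - 1) + 0.5) / n, moving exact 0/1 responses into (0, 1)."""
    y = np.asarray(y, float)
    if n is None:
        n = y.size
    return (y * (n - 1) + 0.5) / n


def fit_beta(y, X: pd.DataFrame, squeeze: bool = False) -> FitResult:
    """ML beta regression with logit mean link and a free scalar precision.

    ``X`` must not contain a constant column (one is added). Boundary
    responses raise unless ``squeeze`` is set. The precision is modelled
    with an intercept only; the parameter count entering the AIC includes it.
    """
    y = np.asarray(y, float)
    if np.any((y <= 0) | (y >= 1)):
        if not squeeze:
            raise ValueError("response contains values outside (0, 1); enable squeeze")
        y = squeeze_unit_interval(y)
    if y.std() == 0:
        raise ValueError("constant response cannot be fit")
    exog = pd.DataFrame(X).copy()
    terms = list(exog.columns)
    exog.insert(0, "const", 1.0)
    arr = exog.to_numpy(float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise ValueError("design matrix is rank-deficient")

    model = BetaModel(y, exog)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=500, disp=False)
    k = len(res.params)
    return FitResult(
        terms=terms,
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        loglik=float(res.llf),
        aic=float(-2.0 * res.llf + 2.0 * k),
        nobs=int(len(y)),
        converged=bool(res.mle_retvals.get("converged", True)),
        model=res,
    )


def stepwise_aic(
    y, X: pd.DataFrame, start_terms: list[str] | None = None, squeeze: bool = False,
    trace: list | None = None,
) -> FitResult:
    """Greedy both-direction AIC search over the columns of X.

    From the starting set (default: all columns), at each step the single
    add or drop lowering AIC the most is accepted; terminates when no move
    improves. The accepted AIC sequence is appended to ``trace`` if given.
    """
    all_terms = list(X.columns)
    current = list(all_terms if start_terms is None else start_terms)
    best = fit_beta(y, X[current], squeeze=squeeze)
    if trace is not None:
        trace.append((tuple(current), best.aic))
    while True:
        moves = []
        for t in current:
            moves.append([c for c in current if c != t])
        for t in all_terms:
            if t not in current:
                moves.append(current + [t])
        candidate = None
        for terms in moves:
            try:
                fit = fit_beta(y, X[terms], squeeze=squeeze)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if fit.aic < best.aic - 1e-9 and (candidate is None or fit.aic < candidate.aic):
                candidate = fit
        if candidate is None:
            return best
        best = candidate
        current = list(best.terms)
        if trace is not None:
            trace.append((tuple(current), best.aic))


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors 1/(1 - R^2_j) via OLS of each column on
    the rest (with intercept)."""
    cols = list(X.columns)
    arr = X.to_numpy(float)
    out = {}
    for j, c in enumerate(cols):
        yj = arr[:, j]
        others = np.delete(arr, j, axis=1)
        design = np.column_stack([np.ones(len(yj)), others])
        beta, *_ = np.linalg.lstsq(design, yj, rcond=None)
        resid = yj - design @ beta
        ss_tot = ((yj - yj.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
        out[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_loop(X: pd.DataFrame, vif_max: float = 3.0) -> pd.DataFrame:
    """Iteratively drop the covariate with the largest VIF above vif_max."""
    X = X.copy()
    while X.shape[1] > 1:
        v = vif(X)
        if v.max() <= vif_max:
            break
        X = X.drop(columns=v.idxmax())
    return X


def generalized_r2(loglik_model: float, loglik_null: float, n: int) -> float:
    """Cox-Snell 1 - (L0/L1)^(2/n) from log-likelihoods."""
    if n <= 0:
        raise ValueError("n must be positive")
    return float(1.0 - np.exp(-2.0 / n * (loglik_model - loglik_null)))


def run_env_model(
    env: pd.DataFrame,
    response: str,
    covariates: list[str],
    r_max: float = 0.7,
    vif_max: float = 3.0,
    primary_set: list[str] | None = None,
    preferences: list[str] | None = None,
    squeeze: bool = True,
) -> dict:
    """The full selection chain: correlation filter -> standardize ->
    VIF loop -> both-direction stepwise AIC -> generalized R^2."""
    env = env.dropna(subset=[response] + covariates)
    kept = correlation_filter(env, covariates, r_max, primary_set, preferences)
    env = standardize(env, kept)
    X = vif_loop(env[kept], vif_max)
    y = env[response].to_numpy(float)
    trace: list = []
    final = stepwise_aic(y, X, squeeze=squeeze, trace=trace)
    null = fit_beta(y, X[[]], squeeze=squeeze)
    r2 = generalized_r2(final.loglik, null.loglik, final.nobs)
    return {
        "retained_after_corr": kept,
        "retained_after_vif": list(X.columns),
        "final": final,
        "null": null,
        "generalized_r2": r2,
        "trace": trace,
    }
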