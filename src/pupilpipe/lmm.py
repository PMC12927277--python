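"""Linear mixed-effects fitting with Satterthwaite degrees of freedom.

A thin layer over :class:`statsmodels.regression.mixed_linear_model.MixedLM`
(REML) adding the two things the analysis needs and statsmodels does not
provide:

* a fixed, logged convergence fallback ladder -- full correlated random
  effects, then independent (diagonal) random effects, then progressively
  dropping random slopes down to a random intercept; a fit is accepted at
  the first rung that converges with a non-singular random-effects
  covariance;
* Satterthwaite approximate degrees of freedom for each fixed-effect test,
  computed from the REML criterion: for contrast ``c``,
  ``df = 2 f^2 / (g' A g)`` with ``f = c' Var(beta) c``, ``g`` its gradient
  with respect to the variance parameters, and ``A`` the inverse observed
  information of the restricted likelihood (both obtained by central finite
  differences). When the information matrix is not invertible (boundary
  fits) the residual degrees of freedom ``n - p`` are used with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
import statsmodels.formula.api as smf
from statsmodels.regression.mixed_linear_model import MixedLMParams
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = ["FitResult", "fit_mixed_model", "satterthwaite_df"]


@dataclass
class FitResult:
    """Fixed-effect table plus the model state needed downstream."""

    table: pd.DataFrame  # term, estimate, se, df, t, p, ci_low, ci_high
    terms: list[str]
    fe_params: np.ndarray
    fe_cov: np.ndarray
    cov_re: np.ndarray
    scale: float
    converged: bool
    singular: bool
    re_structure: str  # ladder rung actually fitted
    df_method: str
    method: str = "REML"
    n_obs: int = 0
    n_groups: int = 0
    frame_means: dict = field(default_factory=dict)
    frame_ranges: dict = field(default_factory=dict)

    def coef(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "estimate"])

    def pvalue(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "p"])


# ---------------------------------------------------------------------------
# REML criterion on grouped data
# ---------------------------------------------------------------------------

def _split_by_group(model) -> tuple[list, list, list]:
    labels = np.asarray(model.groups)
    X = np.asarray(model.exog, float)
    Z = np.asarray(model.exog_re, float)
    y = np.asarray(model.endog, float)
    Xs, Zs, ys = [], [], []
    for g in pd.unique(labels):
        m = labels == g
        Xs.append(X[m])
        Zs.append(Z[m])
        ys.append(y[m])
    return Xs, Zs, ys


def _unpack_theta(theta: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    G = np.zeros((k, k))
    tri = np.tril_indices(k)
    G[tri] = theta[:-1]
    G = G + np.tril(G, -1).T
    return G, float(theta[-1])


def _pack_theta(cov_re: np.ndarray, scale: float) -> np.ndarray:
    tri = np.tril_indices(cov_re.shape[0])
    return np.concatenate([np.asarray(cov_re)[tri], [scale]])


def _gls_pieces(theta, Xs, Zs, ys):
    """Accumulate X'V^-1X, X'V^-1y, y'V^-1y and sum log|V| over groups."""
    k = Zs[0].shape[1]
    G, s2 = _unpack_theta(theta, k)
    p = Xs[0].shape[1]
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    ytViy = 0.0
    logdet = 0.0
    for X, Z, y in zip(Xs, Zs, ys):
        V = Z @ G @ Z.T + s2 * np.eye(len(y))
        c, low = cho_factor(V, lower=True)
        logdet += 2.0 * np.sum(np.log(np.diag(c)))
        Vx = cho_solve((c, low), X)
        Vy = cho_solve((c, low), y)
        XtViX += X.T @ Vx
        XtViy += X.T @ Vy
        ytViy += float(y @ Vy)
    return XtViX, XtViy, ytViy, logdet


def _reml_loglike(theta, Xs, Zs, ys) -> float:
    XtViX, XtViy, ytViy, logdet = _gls_pieces(theta, Xs, Zs, ys)
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtViX, XtViy)
    rss = ytViy - float(beta @ XtViy)
    return -0.5 * (logdet + logdet_x + rss)


def _fe_cov_at(theta, Xs, Zs, ys) -> np.ndarray:
    XtViX, *_ = _gls_pieces(theta, Xs, Zs, ys)
    return np.linalg.inv(XtViX)


def satterthwaite_df(model, cov_re: np.ndarray, scale: float) -> np.ndarray:
    """Satterthwaite df for each fixed-effect coefficient of a MixedLM fit.

    Returns one df per fixed-effect column, or NaN entries when the REML
    information matrix cannot be inverted (caller falls back to residual df).
    """
    Xs, Zs, ys = _split_by_group(model)
    theta = _pack_theta(cov_re, scale)
    q = len(theta)
    n = sum(len(y) for y in ys)
    p = Xs[0].shape[1]
    steps = 1e-4 * (np.abs(theta) + 1e-2 * scale)

    # observed information of the restricted likelihood (central differences)
    def f(th):
        return _reml_loglike(th, Xs, Zs, ys)

    H = np.zeros((q, q))
    f0 = f(theta)
    if not np.isfinite(f0):
        return np.full(p, np.nan)
    for i in range(q):
        ei = np.zeros(q)
        ei[i] = steps[i]
        for j in range(i, q):
            ej = np.zeros(q)
            ej[j] = steps[j]
            if i == j:
                H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / steps[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej)
                    - f(theta + ei - ej)
                    - f(theta - ei + ej)
                    + f(theta - ei - ej)
                ) / (4 * steps[i] * steps[j])
    try:
        A = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)
    if not np.all(np.isfinite(A)) or np.any(np.diag(A) < 0):
        return np.full(p, np.nan)

    # gradient of Var(beta) wrt theta, one matrix derivative per parameter
    C0 = _fe_cov_at(theta, Xs, Zs, ys)
    dC = []
    for i in range(q):
        ei = np.zeros(q)
        ei[i] = steps[i]
        dC.append(
            (_fe_cov_at(theta + ei, Xs, Zs, ys) - _fe_cov_at(theta - ei, Xs, Zs, ys))
            / (2 * steps[i])
        )
    dfs = np.empty(p)
    for j in range(p):
        fj = C0[j, j]
        g = np.array([d[j, j] for d in dC])
        denom = float(g @ A @ g)
        if denom <= 0 or fj <= 0:
            dfs[j] = np.nan
        else:
            dfs[j] = min(2.0 * fj**2 / denom, n - p)
    return dfs


# ---------------------------------------------------------------------------
# Fitting with the fallback ladder
# ---------------------------------------------------------------------------

def _re_ladder(re_formula: str) -> list[tuple[str, bool, str]]:
    """(re_formula, diagonal_only, label) rungs in the order tried."""
    rungs = [(re_formula, False, "correlated"), (re_formula, True, "independent")]
    terms = [t.strip() for t in re_formula.replace("*", "+").split("+")]
    terms = [t for t in terms if t not in ("", "1")]
    # interaction expansion: a * b contributes a:b as well
    if "*" in re_formula:
        parts = [t.strip() for t in re_formula.split("*")]
        if len(parts) == 2:
            terms = [p.lstrip("1 +").strip() for p in parts]
            terms = [t for t in terms if t] + [":".join(terms)]
    while terms:
        terms = terms[:-1]
        sub = "1" + "".join(f" + {t}" for t in terms)
        rungs.append((sub, False, f"reduced:{sub}"))
    return rungs


def _is_singular(cov_re: np.ndarray, scale: float) -> bool:
    eig = np.linalg.eigvalsh(np.atleast_2d(cov_re))
    return bool(eig.min() <= 1e-8 * max(eig.max(), scale, 1e-12))


def fit_mixed_model(
    data: pd.DataFrame,
    formula: str,
    groups: str = "participant",
    re_formula: str = "1",
    df_method: str = "satterthwaite",
    alpha: float = 0.05,
) -> FitResult:
    """REML mixed-model fit with fallback ladder and approximate df.

    ``df_method`` is ``"satterthwaite"`` (default) or ``"residual"``
    (``n - p``); Satterthwaite silently degrades to residual df, with a
    warning, when the REML information is not invertible.
    """
    data = data.reset_index(drop=True)
    last = None
    chosen = None
    for sub_re, diagonal, label in _re_ladder(re_formula):
        model = smf.mixedlm(formula, data, groups=data[groups], re_formula=sub_re)
        free = None
        if diagonal:
            k = model.exog_re.shape[1]
            free = MixedLMParams.from_components(
                fe_params=np.ones(model.exog.shape[1]), cov_re=np.eye(k)
            )
        # optimizers are tried one at a time: an optimizer can report
        # convergence yet leave a broken fixed-effect covariance, in which
        # case the next optimizer on the same rung may still succeed
        res = None
        p_fe = model.exog.shape[1]
        for optimizer in ("lbfgs", "bfgs", "powell"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    warnings.simplefilter("ignore", RuntimeWarning)
                    warnings.simplefilter("ignore", UserWarning)
                    cand = model.fit(reml=True, free=free, method=optimizer)
            except (np.linalg.LinAlgError, ValueError):
                continue
            fe_var = np.diag(np.asarray(cand.cov_params()))[:p_fe]
            if np.all(np.isfinite(fe_var)) and np.all(fe_var > 0):
                res = cand
                if bool(getattr(cand, "converged", True)):
                    break
        if res is None:
            continue  # no optimizer produced a usable fit; try the next rung
        converged = bool(getattr(res, "converged", True))
        singular = _is_singular(np.atleast_2d(res.cov_re), res.scale)
        last = (model, res, label, converged, singular)
        if converged and not singular:
            chosen = last
            break
    if chosen is None:
        if last is None:
            raise RuntimeError("mixed model could not be fitted at any ladder rung")
        chosen = last  # best effort: last rung, possibly singular
    model, res, label, converged, singular = chosen

    terms = list(model.exog_names)
    p = len(terms)
    n = model.exog.shape[0]
    est = np.asarray(res.fe_params, float)
    # model-based GLS covariance (X' V^-1 X)^-1 at the fitted variance
    # parameters; statsmodels' cov_params() is Hessian-based and can be
    # noticeably wider for between-group covariates
    try:
        fe_cov = _fe_cov_at(
            _pack_theta(np.atleast_2d(res.cov_re), res.scale),
            *_split_by_group(model),
        )
    except np.linalg.LinAlgError:
        fe_cov = np.asarray(res.cov_params())[:p, :p]
    se = np.sqrt(np.diag(fe_cov))

    used_method = df_method
    dfs = np.full(p, float(n - p))
    if df_method == "satterthwaite":
        sat = satterthwaite_df(model, np.atleast_2d(res.cov_re), res.scale)
        if np.all(np.isfinite(sat)):
            dfs = sat
        else:
            finite = np.isfinite(sat)
            if finite.any():
                dfs[finite] = sat[finite]
            warnings.warn(
                "Satterthwaite df unavailable for some terms; residual df used"
            )
            used_method = "satterthwaite+residual"
    elif df_method != "residual":
        raise ValueError(f"unknown df_method {df_method!r}")

    tvals = est / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dfs)
    tcrit = stats.t.ppf(1 - alpha / 2.0, dfs)
    table = pd.DataFrame(
        {
            "term": terms,
            "estimate": est,
            "se": se,
            "df": dfs,
            "t": tvals,
            "p": pvals,
            "ci_low": est - tcrit * se,
            "ci_high": est + tcrit * se,
        }
    )
    numeric = data.select_dtypes(include=[np.number])
    return FitResult(
        table=table,
        terms=terms,
        fe_params=est,
        fe_cov=fe_cov,
        cov_re=np.atleast_2d(res.cov_re),
        scale=float(res.scale),
        converged=converged,
        singular=singular,
        re_structure=label,
        df_method=used_method,
        n_obs=n,
        n_groups=len(pd.unique(np.asarray(model.groups))),
        frame_means={c: float(numeric[c].mean()) for c in numeric.columns},
        frame_ranges={
            c: (float(numeric[c].min()), float(numeric[c].max()))
            for c in numeric.columns
        },
    )
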