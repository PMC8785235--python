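"""Shared statistical machinery for the behavioral analyses.

All assay modules express their models through this layer:

* random-intercept linear mixed models (REML estimates for reporting, ML
  refits for likelihood-ratio comparisons), fitted with
  :class:`statsmodels.regression.mixed_linear_model.MixedLM`;
* beta regression by maximum likelihood (logit mean link, constant
  precision), fitted with :class:`statsmodels.othermod.betareg.BetaModel`;
* likelihood-ratio tests between nested ML fits with a chi-squared
  reference;
* Tukey-style single-step multiplicity adjustment of all pairwise
  contrasts, using the max-|z| distribution under a multivariate-normal
  reference on the estimated contrast covariance.

Condition factors use treatment coding with the control level as reference,
so interaction coefficients read directly as treated-minus-control slope
differences.  Pairwise contrasts use a normal (z) reference rather than
finite-sample degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.othermod.betareg import BetaModel
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "Contrast",
    "ModelResult",
    "build_condition_design",
    "fit_lmm",
    "fit_betareg",
    "lrt",
    "tukey_contrasts",
    "smithson_verkuilen",
]


@dataclass
class Contrast:
    """One pairwise difference with its multiplicity-adjusted p-value."""

    name: str
    estimate: float
    se: float
    z: float
    p_unadjusted: float
    p_adjusted: float


@dataclass
class ModelResult:
    """Container for a fitted model and its derived tests."""

    family: str  # "lmm" | "betareg" | "ols"
    formula: str
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    random_effect_var: float | None = None
    residual_var: float | None = None
    llf_ml: float | None = None
    n_params_ml: int | None = None
    nobs: int = 0
    slopes: dict[str, tuple[float, float]] | None = None
    omnibus: tuple[float, float, float] | None = None  # (chi2, df, p)
    lrt_result: tuple[float, float, float] | None = None
    contrasts: list[Contrast] = field(default_factory=list)
    converged: bool = True
    singular: bool = False
    warnings: list[str] = field(default_factory=list)


def smithson_verkuilen(y: np.ndarray, n: int) -> np.ndarray:
    """Compress proportions off the [0, 1] boundary: y' = (y(n-1) + 1/2) / n.

    The standard fix for boundary observations in beta regression; ``n`` is
    the number of observations behind each proportion (subjects per
    condition for responder curves, total scored subjects for ratios).
    """
    if n < 2:
        raise ValueError("compression requires n >= 2")
    return (np.asarray(y, dtype=float) * (n - 1) + 0.5) / n


def build_condition_design(
    data: pd.DataFrame,
    *,
    condition_col: str = "condition",
    control: str = "control",
    covariate: str | None = None,
    interaction: bool = False,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Treatment-coded design matrix for condition (+ covariate models).

    Returns ``(X, names, levels)`` where ``levels`` lists condition levels
    with the control first.  Columns: intercept, one dummy per non-control
    level, then (if requested) the covariate and its per-level interactions.
    """
    cond = data[condition_col].astype(str)
    levels = [control] + sorted(c for c in cond.unique() if c != control)
    if control not in set(cond):
        raise ValueError(f"control level {control!r} absent from {condition_col!r}")
    n = len(data)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["Intercept"]
    for lev in levels[1:]:
        cols.append((cond == lev).to_numpy(dtype=float))
        names.append(f"cond[{lev}]")
    if covariate is not None:
        x = data[covariate].to_numpy(dtype=float)
        cols.append(x)
        names.append(covariate)
        if interaction:
            for lev in levels[1:]:
                cols.append((cond == lev).to_numpy(dtype=float) * x)
                names.append(f"cond[{lev}]:{covariate}")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the first column whose removal restores full rank
        for j in range(X.shape[1] - 1, -1, -1):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                raise ValueError(f"design is rank deficient: term {names[j]!r} is aliased")
        raise ValueError("design is rank deficient")
    return X, names, levels


def _ols(y: np.ndarray, X: np.ndarray, names: list[str], formula: str) -> ModelResult:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(y) - X.shape[1], 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.pinv(X.T @ X)
    params = pd.Series(beta, index=names)
    return ModelResult(
        family="ols",
        formula=formula,
        params=params,
        bse=pd.Series(np.sqrt(np.diag(cov)), index=names),
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        residual_var=s2,
        nobs=len(y),
        random_effect_var=0.0,
        singular=True,
        warnings=["degenerate fit: ordinary least squares used"],
    )


def fit_lmm(
    data: pd.DataFrame,
    response: str,
    exog: np.ndarray,
    exog_names: list[str],
    groups: str,
    *,
    omnibus_cols: list[str] | None = None,
    formula: str = "",
) -> ModelResult:
    """Random-intercept linear mixed model.

    REML estimates are reported; when ``omnibus_cols`` is given, full and
    reduced models are refitted by ML and compared with a likelihood-ratio
    test whose statistic is referred to chi-squared (the omnibus condition
    test).  Data rows with a missing response are dropped.  A fit whose
    between-subject variance collapses to ~0 is flagged singular, not
    rejected; if the *residual* variance is ~0 (noise-free input) the model
    degenerates to OLS and is flagged.
    """
    y = data[response].to_numpy(dtype=float)
    keep = np.isfinite(y)
    y, X = y[keep], exog[keep]
    grp = data.loc[keep, groups].to_numpy()
    if len(np.unique(grp)) < 2:
        raise ValueError("need >= 2 grouping-factor levels for a mixed model")

    # noise-free degenerate case: OLS residuals identically zero
    beta0, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    ssr = float(np.sum((y - X @ beta0) ** 2))
    scale = float(np.sum(y**2)) or 1.0
    if ssr / scale < 1e-18:
        return _ols(y, X, exog_names, formula)

    Xdf = pd.DataFrame(X, columns=exog_names)
    caught: list[str] = []
    try:
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")
            model = MixedLM(y, Xdf, groups=grp)
            res = model.fit(reml=True)
            caught += [
                str(w.message) for w in wrec
                if issubclass(w.category, ConvergenceWarning)
            ]
    except np.linalg.LinAlgError:
        # variance component pinned at the boundary: report the OLS fit
        out = _ols(y, X, exog_names, formula)
        out.warnings.append("REML fit degenerate at zero variance; OLS reported")
        res = None
    if res is None:
        if omnibus_cols:
            drop_idx = [exog_names.index(c) for c in omnibus_cols]
            keep_idx = [j for j in range(X.shape[1]) if j not in drop_idx]
            llf_full = _random_intercept_ml_llf(y, X, grp)
            llf_red = _random_intercept_ml_llf(y, X[:, keep_idx], grp)
            out.llf_ml = llf_full
            out.n_params_ml = X.shape[1] + 2
            out.omnibus = lrt((llf_red, len(keep_idx) + 2), (llf_full, out.n_params_ml))
        return out

    out = ModelResult(
        family="lmm",
        formula=formula,
        params=pd.Series(np.asarray(res.fe_params), index=exog_names),
        bse=pd.Series(np.asarray(res.bse_fe), index=exog_names),
        cov_params=pd.DataFrame(
            np.asarray(res.cov_params())[: len(exog_names), : len(exog_names)],
            index=exog_names,
            columns=exog_names,
        ),
        random_effect_var=float(np.asarray(res.cov_re).ravel()[0]),
        residual_var=float(res.scale),
        nobs=int(res.nobs),
        converged=bool(res.converged),
        warnings=caught,
    )
    if out.random_effect_var is not None and out.residual_var:
        out.singular = out.random_effect_var < 1e-8 * out.residual_var

    if omnibus_cols:
        drop_idx = [exog_names.index(c) for c in omnibus_cols]
        keep_idx = [j for j in range(X.shape[1]) if j not in drop_idx]
        llf_full = _random_intercept_ml_llf(y, X, grp)
        llf_red = _random_intercept_ml_llf(y, X[:, keep_idx], grp)
        out.llf_ml = llf_full
        out.n_params_ml = X.shape[1] + 2  # fixed effects + 2 variance components
        stat, df, p = lrt(
            (llf_red, len(keep_idx) + 2), (out.llf_ml, out.n_params_ml)
        )
        out.omnibus = (stat, df, p)
    return out


def _random_intercept_ml_llf(y: np.ndarray, X: np.ndarray, groups: np.ndarray) -> float:
    """Maximized ML log-likelihood of the random-intercept model.

    Profiles the fixed effects and residual variance out in closed form for
    a given variance ratio theta = var(intercept)/var(residual) and
    maximizes over theta >= 0 in one dimension.  Stable at the theta = 0
    boundary, where a Hessian-based fit degenerates.
    """
    from scipy.optimize import minimize_scalar

    n, p = X.shape
    _, inv = np.unique(groups, return_inverse=True)
    n_groups = inv.max() + 1
    sizes = np.bincount(inv).astype(float)
    # per-group sufficient statistics
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    Sx = np.zeros((n_groups, p))  # group sums of rows of X
    np.add.at(Sx, inv, X)
    Sy = np.bincount(inv, weights=y)

    def neg_llf(log_theta: float) -> float:
        return -_llf_at(np.exp(log_theta))

    def _llf_at(theta: float) -> float:
        c = theta / (1.0 + theta * sizes)  # per-group shrinkage
        A = XtX - (Sx * c[:, None]).T @ Sx
        b_vec = Xty - Sx.T @ (c * Sy)
        quad_y = yty - float(c @ Sy**2)
        beta = np.linalg.lstsq(A, b_vec, rcond=None)[0]
        rss = max(quad_y - float(beta @ b_vec), 1e-300)
        sigma2 = rss / n
        logdet = float(np.sum(np.log1p(theta * sizes)))
        return -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet)

    best = _llf_at(0.0)
    res = minimize_scalar(neg_llf, bounds=(-12.0, 8.0), method="bounded")
    if res.success and -res.fun > best:
        best = float(-res.fun)
    return best


def fit_betareg(
    proportions: np.ndarray,
    exog: np.ndarray,
    exog_names: list[str],
    *,
    omnibus_cols: list[str] | None = None,
    formula: str = "",
) -> ModelResult:
    """Maximum-likelihood beta regression, logit mean link, constant precision.

    Responses must already sit strictly inside (0, 1); boundary compression
    (:func:`smithson_verkuilen`) is the caller's responsibility.
    """
    y = np.asarray(proportions, dtype=float)
    if np.any(y <= 0) or np.any(y >= 1):
        raise ValueError("beta regression requires responses strictly inside (0, 1)")

    def _fit(Xm: np.ndarray, nm: list[str]):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mod = BetaModel(y, Xm)
            r = mod.fit(disp=False)
        return r

    res = _fit(exog, exog_names)
    k = len(exog_names)
    cov = np.asarray(res.cov_params())[:k, :k]
    out = ModelResult(
        family="betareg",
        formula=formula,
        params=pd.Series(np.asarray(res.params)[:k], index=exog_names),
        bse=pd.Series(np.asarray(res.bse)[:k], index=exog_names),
        cov_params=pd.DataFrame(cov, index=exog_names, columns=exog_names),
        llf_ml=float(res.llf),
        n_params_ml=k + 1,  # + precision parameter
        nobs=len(y),
        converged=bool(getattr(res.mle_retvals, "get", lambda *_: True)("converged", True))
        if hasattr(res, "mle_retvals")
        else True,
    )
    if omnibus_cols:
        keep_idx = [j for j, nm in enumerate(exog_names) if nm not in omnibus_cols]
        red = _fit(exog[:, keep_idx], [exog_names[j] for j in keep_idx])
        stat, df, _ = lrt(
            (float(red.llf), len(keep_idx) + 1), (out.llf_ml, out.n_params_ml)
        )
        # small-sample reference: the asymptotic chi-squared is markedly
        # anticonservative at the sample sizes proportion models see (tens
        # of observations), so refer stat/df to F(df, n - k) instead
        denom_df = max(out.nobs - out.n_params_ml, 1)
        p = float(stats.f.sf(stat / df, df, denom_df))
        out.omnibus = (stat, df, p)
    return out


def lrt(
    nested: tuple[float, int], full: tuple[float, int]
) -> tuple[float, float, float]:
    """Likelihood-ratio test between nested ML fits.

    Parameters are ``(log-likelihood, n_parameters)`` pairs.  Returns
    ``(statistic, df, p)`` with the statistic clamped at 0 (optimizer noise
    can make the full fit infinitesimally worse).
    """
    llf_n, k_n = nested
    llf_f, k_f = full
    df = k_f - k_n
    if df <= 0:
        if df == 0 and abs(llf_f - llf_n) < 1e-8:
            return 0.0, 0.0, 1.0
        raise ValueError("models are not nested (full has no extra parameters)")
    stat = max(2.0 * (llf_f - llf_n), 0.0)
    return stat, float(df), float(stats.chi2.sf(stat, df))


def tukey_contrasts(
    level_vectors: dict[str, np.ndarray],
    params: pd.Series,
    cov_params: pd.DataFrame,
    *,
    seed: int = 20220413,
    n_draws: int = 200_000,
) -> list[Contrast]:
    """All pairwise level differences with single-step max-|z| adjustment.

    ``level_vectors[level]`` is the coefficient combination giving that
    level's effect.  The familywise adjustment evaluates, under a
    multivariate normal with the estimated contrast correlation, the
    distribution of the maximum absolute z over the family (the single-step
    method of the multcomp tradition); for a family of one the adjusted and
    unadjusted p coincide.  A seeded quasi-random sample approximates the
    max-|z| tail, so results are deterministic for a fixed seed.
    """
    levels = list(level_vectors)
    if len(levels) < 2:
        raise ValueError("need >= 2 levels for pairwise contrasts")
    V = cov_params.to_numpy()
    b = params.to_numpy()
    rows, ests, names = [], [], []
    for i in range(1, len(levels)):
        for j in range(i):
            c = level_vectors[levels[i]] - level_vectors[levels[j]]
            rows.append(c)
            ests.append(float(c @ b))
            names.append(f"{levels[i]} - {levels[j]}")
    C = np.vstack(rows)
    cov_c = C @ V @ C.T
    ses = np.sqrt(np.clip(np.diag(cov_c), 1e-300, None))
    zs = np.array(ests) / ses
    p_un = 2.0 * stats.norm.sf(np.abs(zs))

    if len(names) == 1:
        p_adj = p_un.copy()
    else:
        D = np.diag(1.0 / ses)
        R = D @ cov_c @ D
        R = (R + R.T) / 2.0
        vals, vecs = np.linalg.eigh(R)
        L = vecs * np.sqrt(np.clip(vals, 0.0, None))
        rng = np.random.default_rng(seed)
        zdraw = rng.standard_normal((n_draws // 2, R.shape[0]))
        zdraw = np.vstack([zdraw, -zdraw])  # antithetic halves
        maxabs = np.abs(zdraw @ L.T).max(axis=1)
        p_adj = np.array([np.mean(maxabs >= abs(z)) for z in zs])
        p_adj = np.maximum(p_adj, p_un)  # adjustment can never help
    return [
        Contrast(names[k], ests[k], float(ses[k]), float(zs[k]), float(p_un[k]), float(p_adj[k]))
        for k in range(len(names))
    ]


def fit_condition_lmm(
    data: pd.DataFrame,
    response: str = "distance_mm",
    *,
    condition_col: str = "condition",
    group_col: str = "subject_id",
    control: str = "control",
) -> ModelResult:
    """Mixed model `response ~ condition + (1 | subject)` with the omnibus
    condition LRT and Tukey-adjusted pairwise condition contrasts."""
    X, names, levels = build_condition_design(
        data, condition_col=condition_col, control=control
    )
    if len(levels) < 2:
        raise ValueError("need >= 2 conditions")
    dummies = [n for n in names if n.startswith("cond[")]
    out = fit_lmm(
        data, response, X, names, group_col,
        omnibus_cols=dummies,
        formula=f"{response} ~ condition + (1|{group_col})",
    )
    vectors = {}
    for lev in levels:
        v = np.zeros(len(names))
        v[names.index("Intercept")] = 1.0
        if lev != control:
            v[names.index(f"cond[{lev}]")] = 1.0
        vectors[lev] = v
    out.contrasts = tukey_contrasts(vectors, out.params, out.cov_params)
    return out


def fit_condition_time_lmm(
    data: pd.DataFrame,
    response: str = "distance_mm",
    time_col: str = "t",
    *,
    condition_col: str = "condition",
    group_col: str = "subject_id",
    control: str = "control",
) -> ModelResult:
    """Mixed model `response ~ condition * time + (1 | subject)`.

    Reports per-condition time slopes (control slope = the time coefficient;
    other conditions add their interaction term), the omnibus condition LRT
    (condition main effects and interactions dropped jointly), and
    Tukey-adjusted pairwise *slope* contrasts.
    """
    if data[time_col].nunique() < 3:
        raise ValueError("need >= 3 distinct time points to estimate slopes")
    X, names, levels = build_condition_design(
        data, condition_col=condition_col, control=control,
        covariate=time_col, interaction=True,
    )
    if len(levels) < 2:
        raise ValueError("need >= 2 conditions")
    cond_cols = [n for n in names if n.startswith("cond[")]
    out = fit_lmm(
        data, response, X, names, group_col,
        omnibus_cols=cond_cols,
        formula=f"{response} ~ condition*{time_col} + (1|{group_col})",
    )
    V = out.cov_params.to_numpy()
    slopes: dict[str, tuple[float, float]] = {}
    vectors = {}
    for lev in levels:
        v = np.zeros(len(names))
        v[names.index(time_col)] = 1.0
        if lev != control:
            v[names.index(f"cond[{lev}]:{time_col}")] = 1.0
        vectors[lev] = v
        est = float(v @ out.params.to_numpy())
        se = float(np.sqrt(v @ V @ v))
        slopes[lev] = (est, se)
    out.slopes = slopes
    out.contrasts = tukey_contrasts(vectors, out.params, out.cov_params)
    return out
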