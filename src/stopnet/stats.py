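"""Inferential stages: hierarchical regression, quartile ANCOVA, recursive
path analysis with indirect effects and fit indices, multiple imputation
with Rubin pooling, Cronbach's alpha and Cramér's V.

All regression-type models are fit on standardized variables, so
coefficients are standardized betas.  Directional hypotheses are reported
one-tailed: the one-tailed p is half the two-tailed p when the estimate's
sign matches the expected direction, and 1 minus half otherwise; with no
declared direction the estimate's own sign is taken as the direction.

The path-analysis fitter estimates each endogenous equation of a recursive
observed-variable model by ordinary least squares on standardized data (for
such models these coincide in population with maximum-likelihood SEM
estimates) and computes covariance-structure fit indices — chi-square, CFI,
RMSEA, SRMR — from the sample versus model-implied correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .cohort import CohortTable
from .pathmodel import PathModelSpec

__all__ = [
    "StepResult",
    "RegressionSteps",
    "AncovaResult",
    "PathFit",
    "PathEstimate",
    "IndirectEffect",
    "PooledEstimate",
    "hierarchical_regression",
    "quartile_ancova",
    "fit_path_model",
    "impute_and_pool",
    "rubin_pool",
    "cronbach_alpha",
    "cramers_v",
    "one_tailed_p",
    "significance_mark",
]


class CollinearityError(ValueError):
    """Design matrix is rank deficient."""


def _as_frame(table) -> pd.DataFrame:
    return table.data if isinstance(table, CohortTable) else table


def _standardize(df: pd.DataFrame) -> pd.DataFrame:
    return (df - df.mean()) / df.std(ddof=1)


def one_tailed_p(estimate: float, p_two: float, direction: float | None = None) -> float:
    """One-tailed p for a directional hypothesis.

    ``direction`` is the expected sign (+1/-1); default is the estimate's
    own sign (i.e. p_two / 2).
    """
    half = p_two / 2.0
    if direction is None or direction == 0 or np.sign(estimate) == np.sign(direction):
        return half
    return 1.0 - half


def significance_mark(p: float) -> str:
    """Report-style marks: + p<.10, * p<.05, ** p<.01, *** p<.001."""
    for threshold, mark in ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.10, "+")):
        if p < threshold:
            return mark
    return ""


# ---------------------------------------------------------------------------
# hierarchical regression


@dataclass(frozen=True)
class StepResult:
    predictors: tuple[str, ...]          # all predictors in this cumulative step
    entered: tuple[str, ...]             # predictors added at this step
    beta: pd.Series
    p_two_tailed: pd.Series
    p_one_tailed: pd.Series
    r_squared: float
    adj_r_squared: float
    delta_r_squared: float
    f_change: float
    p_change: float


@dataclass(frozen=True)
class RegressionSteps:
    outcome: str
    steps: tuple[StepResult, ...]
    n: int


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # Identify a collinear subset: columns whose removal restores rank.
        involved = [
            c
            for c in X.columns
            if np.linalg.matrix_rank(X.drop(columns=c).to_numpy()) == rank
        ]
        raise CollinearityError(f"collinear predictor set: {involved or list(X.columns)}")


def hierarchical_regression(
    table,
    outcome: str,
    blocks: Sequence[Sequence[str]],
    covariates: Sequence[str] | None = None,
    directions: Mapping[str, float] | None = None,
) -> RegressionSteps:
    """Blockwise (hierarchical) OLS on standardized variables.

    ``covariates`` enter as an implicit first block.  Each step refits the
    cumulative predictor set; the change-in-R² F test compares consecutive
    steps.  Complete cases only.
    """
    df = _as_frame(table)
    step_sets: list[list[str]] = []
    if covariates:
        step_sets.append(list(covariates))
    for block in blocks:
        step_sets.append(list(block))
    all_predictors = [p for block in step_sets for p in block]
    used = df[[outcome, *all_predictors]].dropna()
    n = len(used)
    if n <= len(all_predictors) + 2:
        raise ValueError("too few complete cases for the predictor count")
    z = _standardize(used)

    steps: list[StepResult] = []
    cumulative: list[str] = []
    prev_r2, prev_k = 0.0, 0
    for entered in step_sets:
        cumulative.extend(entered)
        X = z[cumulative]
        _check_rank(X)
        fit = sm.OLS(z[outcome], sm.add_constant(X)).fit()
        beta = fit.params.drop("const")
        p_two = fit.pvalues.drop("const")
        p_one = pd.Series(
            {
                name: one_tailed_p(
                    beta[name], p_two[name], (directions or {}).get(name)
                )
                for name in beta.index
            }
        )
        r2 = float(fit.rsquared)
        k = len(cumulative)
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
        dr2 = r2 - prev_r2
        q = k - prev_k
        denom_df = n - k - 1
        if dr2 <= 0 or 1.0 - r2 <= 0:
            f_change = 0.0 if dr2 <= 0 else np.inf
        else:
            f_change = (dr2 / q) / ((1.0 - r2) / denom_df)
        p_change = float(sps.f.sf(f_change, q, denom_df)) if np.isfinite(f_change) else 0.0
        steps.append(
            StepResult(
                predictors=tuple(cumulative),
                entered=tuple(entered),
                beta=beta,
                p_two_tailed=p_two,
                p_one_tailed=p_one,
                r_squared=r2,
                adj_r_squared=adj,
                delta_r_squared=dr2,
                f_change=f_change,
                p_change=p_change,
            )
        )
        prev_r2, prev_k = r2, k
    return RegressionSteps(outcome=outcome, steps=tuple(steps), n=n)


# ---------------------------------------------------------------------------
# quartile ANCOVA


@dataclass(frozen=True)
class AncovaResult:
    omnibus_f: float
    omnibus_df: tuple[int, int]
    omnibus_p: float
    mse: float
    omnibus_eta_sq_partial: float
    contrast_f: float
    contrast_df: tuple[int, int]
    contrast_p: float
    contrast_eta_sq_partial: float
    group_sizes: tuple[int, ...]
    group_adjusted_means: tuple[float, ...]


def quartile_ancova(table, outcome: str, grouping: str, covariate: str) -> AncovaResult:
    """ANCOVA of ``outcome`` on quartiles of ``grouping``, adjusting for a
    covariate, with the planned lowest-quartile-versus-rest contrast.

    Quartile cuts are the sample 25/50/75 percentiles; boundary values fall
    into the lower group.  The omnibus F compares the covariate-only model
    with the covariate + group model; the 1-df contrast tests the adjusted
    mean of the lowest quartile against the average of the other three.
    """
    df = _as_frame(table)[[outcome, grouping, covariate]].dropna()
    g = df[grouping].to_numpy(dtype=float)
    if len(np.unique(g)) < 4:
        raise ValueError("grouping variable needs >= 4 distinct values")
    cuts = np.quantile(g, [0.25, 0.50, 0.75])
    group = np.searchsorted(cuts, g, side="left")
    sizes = tuple(int((group == k).sum()) for k in range(4))
    if min(sizes) == 0:
        raise ValueError(
            f"empty quartile after tie handling (sizes {sizes}); use fewer bins"
        )

    y = df[outcome].to_numpy(dtype=float)
    cov = df[covariate].to_numpy(dtype=float)
    n = len(y)
    dummies = np.column_stack([(group == k).astype(float) for k in (1, 2, 3)])
    X_full = sm.add_constant(np.column_stack([cov, dummies]))
    X_cov = sm.add_constant(cov)
    fit_full = sm.OLS(y, X_full).fit()
    fit_cov = sm.OLS(y, X_cov).fit()

    sse_full = float(fit_full.ssr)
    df_err = n - X_full.shape[1]
    mse = sse_full / df_err
    ss_group = float(fit_cov.ssr) - sse_full
    f_omni = (ss_group / 3.0) / mse
    eta_omni = ss_group / (ss_group + sse_full)
    p_omni = float(sps.f.sf(f_omni, 3, df_err))

    # Adjusted means at the grand covariate mean; contrast mu0 - mean(mu1..3)
    # equals -(d1 + d2 + d3)/3 in dummy coding.
    L = np.array([0.0, 0.0, -1 / 3, -1 / 3, -1 / 3])
    tt = fit_full.t_test(L)
    f_con = float(tt.tvalue.item() ** 2)
    ss_con = f_con * mse
    eta_con = ss_con / (ss_con + sse_full)
    p_con = float(sps.f.sf(f_con, 1, df_err))

    const, b_cov, d1, d2, d3 = fit_full.params
    base = const + b_cov * cov.mean()
    adj_means = (base, base + d1, base + d2, base + d3)

    return AncovaResult(
        omnibus_f=float(f_omni),
        omnibus_df=(3, df_err),
        omnibus_p=p_omni,
        mse=float(mse),
        omnibus_eta_sq_partial=float(eta_omni),
        contrast_f=f_con,
        contrast_df=(1, df_err),
        contrast_p=p_con,
        contrast_eta_sq_partial=float(eta_con),
        group_sizes=sizes,
        group_adjusted_means=tuple(float(m) for m in adj_means),
    )


# ---------------------------------------------------------------------------
# path analysis


@dataclass(frozen=True)
class PathEstimate:
    source: str
    target: str
    coefficient: float
    se: float
    z: float
    p_one_tailed: float
    p_two_tailed: float


@dataclass(frozen=True)
class IndirectEffect:
    chain: tuple[str, ...]  # variable sequence source -> ... -> target
    effect: float
    se: float               # first-order (Sobel) delta-method SE
    z: float
    p_one_tailed: float
    p_two_tailed: float


@dataclass(frozen=True)
class PathFit:
    spec: PathModelSpec
    estimates: tuple[PathEstimate, ...]
    indirect_effects: tuple[IndirectEffect, ...]
    r_squared: dict[str, float]
    chi_square: float
    df: int
    cfi: float
    rmsea: float
    srmr: float
    n: int

    def coefficient(self, source: str, target: str) -> float:
        for est in self.estimates:
            if est.source == source and est.target == target:
                return est.coefficient
        raise KeyError((source, target))


def _simple_paths(spec: PathModelSpec, src: str, dst: str) -> list[tuple[str, ...]]:
    children: dict[str, list[str]] = {}
    for a, b in spec.arrows:
        children.setdefault(a, []).append(b)
    out: list[tuple[str, ...]] = []

    def walk(node: str, trail: tuple[str, ...]) -> None:
        if node == dst:
            out.append(trail)
            return
        for nxt in children.get(node, []):
            walk(nxt, trail + (nxt,))

    walk(src, (src,))
    return [p for p in out if len(p) >= 3]


def fit_path_model(
    table,
    spec: PathModelSpec,
    directions: Mapping[tuple[str, str], float] | None = None,
) -> PathFit:
    """Fit a recursive observed-variable path model.

    Each endogenous equation is estimated by OLS on standardized complete
    cases.  Indirect effects are products of coefficients along every
    directed chain of length >= 2, with first-order delta-method (Sobel)
    standard errors.  Fit indices compare the sample correlation matrix
    with the model-implied matrix: chi2 = (n-1) * F_ML; CFI against the
    independence baseline; RMSEA = sqrt(max(chi2 - df, 0) / (df (n-1)));
    SRMR = RMS of the residual correlations.
    """
    df = _as_frame(table)
    order = list(spec.topological_order())
    used = df[order].dropna()
    n = len(used)
    z = _standardize(used)

    estimates: list[PathEstimate] = []
    coefs: dict[tuple[str, str], float] = {}
    ses: dict[tuple[str, str], float] = {}
    disturbances: dict[str, float] = {}
    r_squared: dict[str, float] = {}
    for v in spec.endogenous:
        parents = list(spec.parents(v))
        X = z[parents]
        _check_rank(X)
        fit = sm.OLS(z[v], sm.add_constant(X)).fit()
        r_squared[v] = float(fit.rsquared)
        # MLE-consistent residual variance so a saturated model reproduces
        # the sample matrix exactly.
        resid = z[v] - fit.fittedvalues
        disturbances[v] = float((resid @ resid) / (n - 1))
        for p_ in parents:
            b = float(fit.params[p_])
            se = float(fit.bse[p_])
            zval = b / se if se > 0 else np.inf * np.sign(b)
            p_two = float(fit.pvalues[p_])
            coefs[(p_, v)] = b
            ses[(p_, v)] = se
            estimates.append(
                PathEstimate(
                    source=p_,
                    target=v,
                    coefficient=b,
                    se=se,
                    z=zval,
                    p_one_tailed=one_tailed_p(
                        b, p_two, (directions or {}).get((p_, v))
                    ),
                    p_two_tailed=p_two,
                )
            )

    indirect: list[IndirectEffect] = []
    sinks = set(spec.variables) - {a for a, _ in spec.arrows}
    for src in spec.exogenous:
        for dst in sorted(sinks):
            for chain in _simple_paths(spec, src, dst):
                links = list(zip(chain[:-1], chain[1:]))
                bs = np.array([coefs[l] for l in links])
                ss = np.array([ses[l] for l in links])
                effect = float(np.prod(bs))
                var = 0.0
                for i in range(len(links)):
                    others = np.prod(np.delete(bs, i))
                    var += (others**2) * ss[i] ** 2
                se = float(np.sqrt(var))
                zval = effect / se if se > 0 else 0.0
                p_two = 2.0 * float(sps.norm.sf(abs(zval)))
                indirect.append(
                    IndirectEffect(
                        chain=chain,
                        effect=effect,
                        se=se,
                        z=zval,
                        p_one_tailed=one_tailed_p(effect, p_two),
                        p_two_tailed=p_two,
                    )
                )

    S = z.corr().loc[order, order]
    exog = list(spec.exogenous)
    exog_corr = S.loc[exog, exog]
    implied = spec.implied_correlation(
        exog_corr=exog_corr, coefficients=coefs, disturbances=disturbances
    ).loc[order, order]

    p = len(order)
    S_m = S.to_numpy()
    Sig = implied.to_numpy()
    sign_S, logdet_S = np.linalg.slogdet(S_m)
    sign_Sig, logdet_Sig = np.linalg.slogdet(Sig)
    f_ml = float(logdet_Sig - logdet_S + np.trace(S_m @ np.linalg.inv(Sig)) - p)
    f_ml = max(f_ml, 0.0)
    chi2 = (n - 1) * f_ml
    dof = spec.degrees_of_freedom()

    # Independence baseline: identity implied matrix.
    f_base = float(-logdet_S)
    chi2_base = (n - 1) * f_base
    df_base = p * (p - 1) // 2
    denom = max(chi2_base - df_base, chi2 - dof, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(chi2 - dof, 0.0) / denom
    rmsea = 0.0 if dof == 0 else float(np.sqrt(max(chi2 - dof, 0.0) / (dof * (n - 1))))
    resid = S_m - Sig
    tril = np.tril_indices(p)
    srmr = float(np.sqrt(np.mean(resid[tril] ** 2)))

    return PathFit(
        spec=spec,
        estimates=tuple(estimates),
        indirect_effects=tuple(indirect),
        r_squared=r_squared,
        chi_square=float(chi2),
        df=dof,
        cfi=float(cfi),
        rmsea=rmsea,
        srmr=srmr,
        n=n,
    )


# ---------------------------------------------------------------------------
# multiple imputation


@dataclass(frozen=True)
class PooledEstimate:
    name: str
    estimate: float
    within: float
    between: float
    total: float
    df: float
    statistic: float
    p: float
    m: int


def rubin_pool(name: str, estimates: Sequence[float], variances: Sequence[float]) -> PooledEstimate:
    """Pool m completed-data estimates by Rubin's rules.

    Pooled point estimate = mean; total variance T = W + (1 + 1/m) B where
    W is the mean within-imputation variance and B the between-imputation
    variance.  Normal-reference df (m - 1)(1 + W / ((1 + 1/m) B))^2.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = len(q)
    if m < 2:
        raise ValueError("Rubin pooling needs m >= 2 imputations")
    qbar = float(q.mean())
    w = float(u.mean())
    b = float(q.var(ddof=1))
    t = w + (1.0 + 1.0 / m) * b
    ratio = w / ((1.0 + 1.0 / m) * b) if b > 0 else np.inf
    if np.isfinite(ratio) and ratio < 1e8:
        df = (m - 1) * (1.0 + ratio) ** 2
        stat = qbar / np.sqrt(t) if t > 0 else np.inf
        p = 2.0 * float(sps.t.sf(abs(stat), df))
    else:
        df = np.inf
        stat = qbar / np.sqrt(t) if t > 0 else np.inf
        p = 2.0 * float(sps.norm.sf(abs(stat)))
    return PooledEstimate(
        name=name, estimate=qbar, within=w, between=b, total=t, df=float(df),
        statistic=float(stat), p=p, m=m,
    )


def _conditional_impute(
    data: pd.DataFrame, mu: np.ndarray, cov: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Fill missing cells from their conditional normal given observed cells.

    Rows are processed grouped by missingness pattern so each distinct
    pattern costs one linear solve.
    """
    out = data.to_numpy(dtype=float).copy()
    isna = np.isnan(out)
    patterns = {}
    for i, row_pattern in enumerate(map(tuple, isna)):
        if any(row_pattern):
            patterns.setdefault(row_pattern, []).append(i)
    for pattern, rows in patterns.items():
        miss = np.array(pattern)
        obs = ~miss
        rows = np.array(rows)
        if not obs.any():
            out[rows] = rng.multivariate_normal(mu, cov, size=len(rows))
            continue
        c_oo = cov[np.ix_(obs, obs)]
        c_mo = cov[np.ix_(miss, obs)]
        resid = out[np.ix_(rows, np.where(obs)[0])] - mu[obs]
        cond_mu = mu[miss] + resid @ np.linalg.solve(c_oo, c_mo.T)
        cond_cov = cov[np.ix_(miss, miss)] - c_mo @ np.linalg.solve(c_oo, c_mo.T)
        cond_cov = (cond_cov + cond_cov.T) / 2.0  # symmetrize round-off
        draw = rng.multivariate_normal(np.zeros(miss.sum()), cond_cov, size=len(rows))
        out[np.ix_(rows, np.where(miss)[0])] = cond_mu + draw
    return pd.DataFrame(out, index=data.index, columns=data.columns)


def impute_and_pool(
    table,
    analysis: Callable[[pd.DataFrame], Mapping[str, tuple[float, float]]],
    m: int = 20,
    seed: int = 0,
) -> dict[str, PooledEstimate]:
    """Joint-normal multiple imputation + Rubin pooling.

    Each imputation perturbs the imputation-model parameters by
    re-estimating the mean and covariance on a bootstrap resample of the
    rows (an approximate posterior draw), then fills every missing cell
    from its conditional normal given that row's observed cells.
    ``analysis`` maps a completed table to ``{name: (estimate, variance)}``.
    With no missing cells the pooled estimates equal the complete-data
    estimates and the between-imputation variance is zero.
    """
    df = _as_frame(table).astype(float)
    fully_missing = [c for c in df.columns if df[c].isna().all()]
    if fully_missing:
        raise ValueError(f"variables fully missing: {fully_missing}")
    rng = np.random.default_rng(seed)
    has_missing = bool(df.isna().to_numpy().any())

    results: dict[str, list[tuple[float, float]]] = {}
    for _ in range(m):
        if has_missing:
            boot = df.sample(n=len(df), replace=True, random_state=rng.integers(2**31))
            mu = boot.mean().to_numpy()
            cov = boot.cov().to_numpy()
            # Guard against singular bootstrap covariance.
            cov += 1e-8 * np.eye(cov.shape[0])
            completed = _conditional_impute(df, mu, cov, rng)
        else:
            completed = df
        for name, (est, var) in analysis(completed).items():
            results.setdefault(name, []).append((float(est), float(var)))
    return {
        name: rubin_pool(name, [e for e, _ in pairs], [v for _, v in pairs])
        for name, pairs in results.items()
    }


# ---------------------------------------------------------------------------
# scale reliability and association


def cronbach_alpha(items) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum of item variances / total variance)."""
    X = np.asarray(_as_frame(items) if isinstance(items, (pd.DataFrame, CohortTable)) else items,
                   dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("alpha needs >= 2 items and >= 3 observations")
    k = X.shape[1]
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def cramers_v(contingency) -> float:
    """Cramér's V = sqrt(chi2 / (n * (min(rows, cols) - 1)))."""
    obs = np.asarray(contingency, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be nonnegative")
    total = obs.sum()
    if total == 0:
        raise ValueError("contingency table is all zero")
    chi2 = sps.chi2_contingency(obs, correction=False).statistic
    return float(np.sqrt(chi2 / (total * (min(obs.shape) - 1))))
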