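"""Heteroscedastic group comparisons on log concentrations.

Groups are compared with a generalised least squares linear model that
allows a different residual variance in every diagnostic group — an
extension of the t test / one-way ANOVA that drops the equal-variance
assumption, which is untenable for immunoassay panels where spread differs
markedly between groups.  Estimation is by maximum likelihood (alternating
weighted least squares for the mean parameters and closed-form per-group
variance updates); global tests are likelihood-ratio tests of equal group
means against a covariate-retaining null, and post-hoc pairwise contrasts
are two-sided z tests on the fitted log-scale mean differences, reusing
the single all-groups fit so the 15 pairwise tests are internally
consistent.

Pairwise significance is reported at two fixed thresholds: an unadjusted
0.05 ("+") and a conservative Bonferroni-adjusted 0.003 ("++"), i.e.
0.05 over the 15 unordered pairs of the six groups, rounded as printed.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DEMENTIA_GROUPS, GROUPS

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-12
ADJUSTMENT_COVARIATES = ("age_at_lp", "sex", "onset_to_lp_months")


@dataclass
class HeteroGlsFit:
    """Maximum-likelihood fit of a group-means model with per-group variances."""

    groups: list[str]
    coef: np.ndarray              # group means first, then covariate slopes
    cov: np.ndarray               # covariance of coef at the ML variances
    group_variances: dict[str, float]
    loglik: float
    converged: bool
    n_iter: int
    n_obs: int
    equal_variances: bool = False
    # retained inputs so the equal-means null can be refitted for the LR test
    _y: np.ndarray = field(repr=False, default=None)
    _group_idx: np.ndarray = field(repr=False, default=None)
    _covariates: np.ndarray | None = field(repr=False, default=None)

    def group_mean(self, group: str) -> float:
        return float(self.coef[self.groups.index(group)])

    def contrast(self, group_a: str, group_b: str) -> tuple[float, float]:
        """Adjusted log-scale mean difference a − b and its standard error."""
        c = np.zeros(len(self.coef))
        c[self.groups.index(group_a)] = 1.0
        c[self.groups.index(group_b)] = -1.0
        return float(c @ self.coef), float(np.sqrt(c @ self.cov @ c))


@dataclass(frozen=True)
class GlobalTestResult:
    biomarker: str
    scope: str          # "with_controls" | "dementia_only"
    adjusted: bool
    statistic: float
    df: int
    p_value: float
    converged: bool = True
    n_obs: int = 0


@dataclass(frozen=True)
class PairwiseComparison:
    biomarker: str
    group_a: str
    group_b: str
    estimate: float      # log-scale mean difference a − b
    p_value: float
    tier: str            # "none" | "single" | "double"


def assign_tier(p_value: float, alpha: float = 0.05, bonferroni: float = 0.003) -> str:
    """Tier a pairwise p-value: '++' below the Bonferroni threshold, '+' below alpha."""
    if p_value < bonferroni:
        return "double"
    if p_value < alpha:
        return "single"
    return "none"


def _ml_fit(y: np.ndarray, group_idx: np.ndarray, n_groups_total: int,
            X_extra: np.ndarray | None, equal_means: bool,
            equal_variances: bool = False,
            tol: float = 1e-10, max_iter: int = 200):
    """Alternating WLS / variance-update ML for the heteroscedastic model.

    ``equal_means`` replaces the per-group mean columns with a single
    intercept (the covariate-retaining null of the global test).  Returns
    (beta, cov_beta, variances, loglik, converged, iterations, X).

    A group whose covariate-adjusted values can be interpolated exactly
    (possible for very small groups) drives its ML variance to zero and
    the likelihood to infinity; such variances are floored at a
    scale-aware minimum with a warning, which bounds the likelihood and
    restores convergence.
    """
    n = y.size
    floor = max(VARIANCE_FLOOR, 1e-6 * float(np.var(y)))
    if equal_means:
        X_mean = np.ones((n, 1))
    else:
        X_mean = np.zeros((n, n_groups_total))
        X_mean[np.arange(n), group_idx] = 1.0
    X = X_mean if X_extra is None else np.hstack([X_mean, X_extra])

    sigma2 = np.ones(n_groups_total)
    loglik_old = -np.inf
    converged = False
    beta = None
    floored_warned = False
    for it in range(1, max_iter + 1):
        w = 1.0 / sigma2[group_idx]
        Xw = X * w[:, None]
        xtwx = X.T @ Xw
        beta = np.linalg.solve(xtwx, Xw.T @ y)
        resid = y - X @ beta
        if equal_variances:
            sigma2[:] = max(float(np.mean(resid ** 2)), floor)
            counts = np.bincount(group_idx, minlength=n_groups_total)
            loglik = -0.5 * (n * np.log(2 * np.pi)
                             + float(counts @ np.log(sigma2)) + n)
            if abs(loglik - loglik_old) < tol:
                converged = True
                break
            loglik_old = loglik
            continue
        for g in range(n_groups_total):
            mask = group_idx == g
            if mask.any():
                v = float(np.mean(resid[mask] ** 2))
                if v < floor:
                    if not floored_warned:
                        warnings.warn(
                            f"group {g} residual variance {v:.3g} floored at "
                            f"{floor:.3g}", RuntimeWarning)
                        floored_warned = True
                    v = floor
                sigma2[g] = v
        counts = np.bincount(group_idx, minlength=n_groups_total)
        loglik = -0.5 * (n * np.log(2 * np.pi) + float(counts @ np.log(sigma2)) + n)
        if abs(loglik - loglik_old) < tol:
            converged = True
            break
        loglik_old = loglik
    if not converged:
        logger.warning("heteroscedastic GLS did not converge in %d iterations", max_iter)
    w = 1.0 / sigma2[group_idx]
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    return beta, cov, sigma2, loglik, converged, it, X


def hetero_gls_fit(
    y: np.ndarray,
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
    equal_variances: bool = False,
) -> HeteroGlsFit:
    """Fit group means (optionally covariate-adjusted) with per-group variances.

    Requires at least two groups with at least two observations each.
    ``covariates`` is an optional (n, p) design block appended to the group
    indicator columns.  ``equal_variances`` constrains all groups to a
    single pooled variance (the classical homoscedastic model, kept for
    cross-checks).
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    keep = np.isfinite(y)
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        keep &= np.isfinite(covariates).all(axis=1)
    y, groups = y[keep], groups[keep]
    X_extra = covariates[keep] if covariates is not None else None

    labels, group_idx = np.unique(groups, return_inverse=True)
    counts = np.bincount(group_idx)
    if len(labels) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 observations each")

    beta, cov, sigma2, ll, converged, n_iter, _ = _ml_fit(
        y, group_idx, len(labels), X_extra, equal_means=False,
        equal_variances=equal_variances)
    return HeteroGlsFit(
        groups=list(labels), coef=beta, cov=cov,
        group_variances={g: float(v) for g, v in zip(labels, sigma2)},
        loglik=ll, converged=converged, n_iter=n_iter, n_obs=y.size,
        equal_variances=equal_variances,
        _y=y, _group_idx=group_idx, _covariates=X_extra,
    )


def global_test(fit: HeteroGlsFit, biomarker: str = "",
                scope: str = "", adjusted: bool = False) -> GlobalTestResult:
    """Likelihood-ratio test of equal group means against the fitted model.

    The null retains the covariates and the per-group variance structure;
    the statistic is referred to a chi-square with (groups − 1) df.
    """
    _, _, _, ll_null, conv_null, _, _ = _ml_fit(
        fit._y, fit._group_idx, len(fit.groups), fit._covariates,
        equal_means=True, equal_variances=fit.equal_variances)
    statistic = max(0.0, 2.0 * (fit.loglik - ll_null))
    df = len(fit.groups) - 1
    p = float(stats.chi2.sf(statistic, df)) if statistic > 0 else 1.0
    return GlobalTestResult(
        biomarker=biomarker, scope=scope, adjusted=adjusted,
        statistic=float(statistic), df=df, p_value=p,
        converged=fit.converged and conv_null, n_obs=fit.n_obs,
    )


def _design_for(table: pd.DataFrame, biomarker: str, groups: tuple[str, ...],
                adjusted: bool):
    sub = table[table["group"].isin(groups)]
    y = np.log(sub[biomarker].to_numpy(dtype=float))
    g = sub["group"].to_numpy()
    if not adjusted:
        return y, g, None
    cov = np.column_stack([
        sub["age_at_lp"].to_numpy(dtype=float),
        (sub["sex"] == "male").to_numpy(dtype=float),
        sub["onset_to_lp_months"].to_numpy(dtype=float),
    ])
    return y, g, cov


def run_global_tests(table: pd.DataFrame, biomarkers: list[str]) -> pd.DataFrame:
    """The three global tests per biomarker on log data, complete-case.

    Columns mirror the published layout: a test across all groups
    including controls, a dementia-only test, and a dementia-only test
    adjusted for age, sex and symptom-onset-to-LP time (controls lack a
    disease duration, so the adjusted analysis is necessarily
    dementia-only).
    """
    rows = []
    variants = [
        ("with_controls", GROUPS, False),
        ("dementia_only", DEMENTIA_GROUPS, False),
        ("dementia_only", DEMENTIA_GROUPS, True),
    ]
    for biomarker in biomarkers:
        for scope, groups, adjusted in variants:
            if biomarker not in table.columns or table[biomarker].notna().sum() == 0:
                rows.append({"biomarker": biomarker, "scope": scope,
                             "adjusted": adjusted, "statistic": np.nan,
                             "df": np.nan, "p_value": np.nan, "n_obs": 0,
                             "computed": False})
                continue
            y, g, cov = _design_for(table, biomarker, groups, adjusted)
            fit = hetero_gls_fit(y, g, cov)
            res = global_test(fit, biomarker, scope, adjusted)
            rows.append({"biomarker": biomarker, "scope": scope,
                         "adjusted": adjusted, "statistic": res.statistic,
                         "df": res.df, "p_value": res.p_value,
                         "n_obs": res.n_obs, "computed": True})
    return pd.DataFrame(rows)


def pairwise_gate(global_results: pd.DataFrame, biomarker: str,
                  alpha: float = 0.05) -> bool:
    """Post-hoc gate: dementia-only unadjusted p < alpha, or unadjusted
    p > alpha while the adjusted p < alpha."""
    sub = global_results[(global_results["biomarker"] == biomarker)
                         & (global_results["scope"] == "dementia_only")]
    p_unadj = sub.loc[~sub["adjusted"], "p_value"]
    p_adj = sub.loc[sub["adjusted"], "p_value"]
    if p_unadj.empty or not np.isfinite(p_unadj.iloc[0]):
        return False
    if p_unadj.iloc[0] < alpha:
        return True
    return (not p_adj.empty and np.isfinite(p_adj.iloc[0])
            and p_adj.iloc[0] < alpha)


def pairwise_tests(
    table: pd.DataFrame,
    biomarker: str,
    gate: pd.DataFrame | bool,
    alpha: float = 0.05,
    bonferroni: float = 0.003,
) -> list[PairwiseComparison]:
    """All 15 unordered pairwise contrasts among the six groups.

    Contrasts come from the single all-groups (controls included,
    unadjusted) heteroscedastic fit; each is a two-sided z test on the
    log-scale mean difference.  When the gate fails the result is
    explicitly empty.
    """
    if isinstance(gate, pd.DataFrame):
        passed = pairwise_gate(gate, biomarker, alpha)
    else:
        passed = bool(gate)
    if not passed:
        return []
    y, g, _ = _design_for(table, biomarker, GROUPS, adjusted=False)
    fit = hetero_gls_fit(y, g)
    out = []
    for a, b in itertools.combinations(GROUPS, 2):
        if a not in fit.groups or b not in fit.groups:
            out.append(PairwiseComparison(biomarker, a, b, np.nan, np.nan, "not_computed"))
            continue
        est, se = fit.contrast(a, b)
        z = est / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        out.append(PairwiseComparison(biomarker, a, b, est, p,
                                      assign_tier(p, alpha, bonferroni)))
    return out


def run_pairwise_tests(
    table: pd.DataFrame,
    biomarkers: list[str],
    global_results: pd.DataFrame,
    alpha: float = 0.05,
    bonferroni: float = 0.003,
) -> pd.DataFrame:
    """Gated pairwise contrasts for every biomarker, as a tidy frame."""
    rows = []
    for biomarker in biomarkers:
        for c in pairwise_tests(table, biomarker, global_results, alpha, bonferroni):
            rows.append({
                "biomarker": c.biomarker, "group_a": c.group_a,
                "group_b": c.group_b, "estimate": c.estimate,
                "p_value": c.p_value, "tier": c.tier,
            })
    return pd.DataFrame(rows, columns=["biomarker", "group_a", "group_b",
                                       "estimate", "p_value", "tier"])
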