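"""Multi-biomarker logistic combinations with leave-one-out validation.

Up to five best-performing biomarkers enter a logistic regression on
natural-log concentrations.  Because AD cases can greatly outnumber a
comparator group, in-sample AUCs from such joint models are optimistic;
every subject is therefore scored out-of-fold ("leave one out"): the model
is refitted without the subject and the held-out probability is recorded.
The AUC of the pooled out-of-fold scores carries a bias-corrected
percentile bootstrap confidence interval (stratified resampling, 2000
replications by default).  Joint models are only fitted when both groups
have more than 10 subjects, to avoid over-fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .roc import auc as _auc
from .roc import cutpoint_at_sensitivity, specificity_at_cutpoint

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LogisticFit:
    coef: np.ndarray          # intercept first
    converged: bool
    n_iter: int
    separated: bool = False   # complete separation detected; ridge fallback used

    def predict(self, X: np.ndarray) -> np.ndarray:
        eta = np.clip(self.coef[0] + X @ self.coef[1:], -700, 700)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass(frozen=True)
class BootstrapConfig:
    replications: int = 2000
    stratified: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.replications < 1:
            raise ValueError("replications must be >= 1")


@dataclass(frozen=True)
class CombinationResult:
    comparison: str
    biomarkers: tuple[str, ...]
    coef: np.ndarray
    loo_scores: np.ndarray
    y: np.ndarray
    auc: float
    ci_lower: float
    ci_upper: float
    specificity: float
    spec_ci_lower: float
    spec_ci_upper: float
    n_cases: int
    n_controls: int
    n_excluded: int
    separated: bool = False


def joint_model_eligible(n_cases: int, n_controls: int, min_size: int = 10) -> bool:
    """Both compared groups must exceed ``min_size`` subjects (strictly)."""
    if n_cases < 0 or n_controls < 0:
        raise ValueError("group sizes must be non-negative")
    return n_cases > min_size and n_controls > min_size


def logistic_fit(X: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                 max_iter: int = 100, start: np.ndarray | None = None) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS.

    Converges when the largest coefficient change drops below ``tol``.
    Complete separation is detected as a diverging coefficient norm and
    reported; the returned fit then uses a small ridge penalty (1e-4) and
    is flagged.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != np.asarray(y).size:
        X = X.T
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("need at least one subject of each class")
    Xd = np.hstack([np.ones((y.size, 1)), X])

    def irls(ridge: float):
        beta = (start.copy() if start is not None and start.size == Xd.shape[1]
                else np.zeros(Xd.shape[1]))
        pen = ridge * np.eye(Xd.shape[1])
        pen[0, 0] = 0.0  # never penalise the intercept
        diverged = False
        for it in range(1, max_iter + 1):
            eta = np.clip(Xd @ beta, -30, 30)
            p = 1.0 / (1.0 + np.exp(-eta))
            w = p * (1.0 - p)
            w = np.maximum(w, 1e-10)
            grad = Xd.T @ (y - p) - pen @ beta
            hess = (Xd * w[:, None]).T @ Xd + pen
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                # Hessian degenerates when fitted probabilities saturate
                diverged = True
                return beta, False, it, diverged
            beta = beta + step
            if np.linalg.norm(beta) > 1e4:
                diverged = True
                return beta, False, it, diverged
            if np.max(np.abs(step)) < tol:
                return beta, True, it, diverged
        return beta, False, max_iter, diverged

    beta, converged, n_iter, diverged = irls(ridge=0.0)
    p_hat = 1.0 / (1.0 + np.exp(-np.clip(Xd @ beta, -30, 30)))
    saturated = bool(np.all(np.abs(y - p_hat) < 1e-4))
    separated = diverged or np.linalg.norm(beta[1:]) > 1e3 or \
        (not converged and saturated)
    if separated:
        logger.warning("complete separation detected; refitting with ridge 1e-4")
        beta, converged, n_iter, _ = irls(ridge=1e-4)
    return LogisticFit(coef=beta, converged=converged, n_iter=n_iter,
                       separated=separated)


def loo_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Out-of-fold probability for every subject.

    For each subject the model is refitted on all other subjects (warm
    started at the full fit) and the held-out subject scored.  Entirely
    deterministic: leave-one-out involves no randomness.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        X = X.T
    n = y.size
    full = logistic_fit(X, y)
    scores = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        y_i = y[keep]
        if y_i.min() == y_i.max():
            raise ValueError("leave-one-out refit lost one class entirely")
        fit = logistic_fit(X[keep], y_i, start=full.coef)
        scores[i] = fit.predict(X[i:i + 1])[0]
    return scores


def bootstrap_auc_ci(
    scores: np.ndarray,
    y: np.ndarray,
    config: BootstrapConfig | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Bias-corrected percentile bootstrap interval for the AUC of scores.

    Subjects are resampled with replacement (stratified within class by
    default); the bias term z0 comes from the fraction of replicate AUCs
    below the point estimate.  No acceleration term.  Degenerate
    replicates (one class absent, possible only unstratified) are redrawn
    and counted.
    """
    config = config or BootstrapConfig()
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    cases, controls = scores[y == 1], scores[y == 0]
    if cases.size < 2 or controls.size < 2:
        raise ValueError("need at least two subjects per class")
    point = _auc(cases, controls, "higher")

    rng = np.random.default_rng(config.seed)
    reps = np.empty(config.replications)
    n_degenerate = 0
    for b in range(config.replications):
        if config.stratified:
            rc = rng.choice(cases, cases.size)
            rk = rng.choice(controls, controls.size)
        else:
            while True:
                take = rng.integers(0, y.size, y.size)
                yy = y[take]
                if 0 < yy.sum() < y.size:
                    break
                n_degenerate += 1
            ss = scores[take]
            rc, rk = ss[yy == 1], ss[yy == 0]
        reps[b] = _auc(rc, rk, "higher")
    if n_degenerate:
        logger.info("redrew %d degenerate bootstrap replicates", n_degenerate)

    frac_below = np.mean(reps < point)
    # guard the probit at the boundary
    frac_below = np.clip(frac_below, 0.5 / config.replications,
                         1.0 - 0.5 / config.replications)
    z0 = stats.norm.ppf(frac_below)
    alpha = 1.0 - level
    zlo, zhi = stats.norm.ppf(alpha / 2), stats.norm.ppf(1 - alpha / 2)
    plo = stats.norm.cdf(2 * z0 + zlo)
    phi = stats.norm.cdf(2 * z0 + zhi)
    lo, hi = np.quantile(reps, [plo, phi])
    return float(lo), float(hi)


def fit_combination(
    comparison: str,
    X: np.ndarray,
    y: np.ndarray,
    biomarkers: tuple[str, ...],
    target_sensitivity: float = 0.85,
    level: float = 0.95,
    bootstrap: BootstrapConfig | None = None,
    n_excluded: int = 0,
) -> CombinationResult:
    """Full joint-model evaluation: LOO scores, AUC with bootstrap CI, and
    specificity at the fixed-sensitivity cut-point on the LOO score scale.

    The cut-point is derived from the LOO scores of the AD subjects (case
    side = higher probability), mirroring the single-biomarker rule.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        X = X.T
    full = logistic_fit(X, y)
    scores = loo_scores(X, y)
    cases, controls = scores[y == 1], scores[y == 0]
    point = _auc(cases, controls, "higher")
    lo, hi = bootstrap_auc_ci(scores, y, bootstrap, level)
    cut = cutpoint_at_sensitivity(cases, "higher", target_sensitivity)
    spec, slo, shi, _ = specificity_at_cutpoint(controls, cut, "higher", level)
    return CombinationResult(
        comparison=comparison, biomarkers=tuple(biomarkers), coef=full.coef,
        loo_scores=scores, y=y, auc=point, ci_lower=lo, ci_upper=hi,
        specificity=spec, spec_ci_lower=slo, spec_ci_upper=shi,
        n_cases=int(y.sum()), n_controls=int((1 - y).sum()),
        n_excluded=n_excluded, separated=full.separated,
    )
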