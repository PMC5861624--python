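"""Empirical ROC analysis with fixed-sensitivity cut-points.

The AUC is the tie-corrected Mann–Whitney probability that a randomly
selected case lies on the case side of a randomly selected comparator.
Decision thresholds are not optimised freely: sensitivity is fixed in
advance (85% by default, following consensus recommendations for AD
biomarkers) and the cut-point is the most case-side observed AD value
whose positivity fraction among AD cases still meets that target.  Because
the cut-point depends only on the AD sample, it is identical whichever
comparator group is evaluated — only the specificity changes.

Uncertainty in binomial proportions (sensitivity, specificity) is
expressed with conservative exact Clopper–Pearson intervals; the cut-point
interval maps the exact binomial sensitivity interval back onto the AD
order statistics (a bootstrap alternative is available behind a switch).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RocCurve:
    """Empirical operating points over the observed threshold sweep."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    direction: str
    n_cases: int
    n_controls: int


@dataclass(frozen=True)
class CutpointResult:
    biomarker: str
    direction: str
    cutpoint: float
    ci_lower: float
    ci_upper: float
    target_sensitivity: float
    achieved_sensitivity: float
    n_cases: int
    #: comparator label -> (specificity, ci_lower, ci_upper, n)
    specificities: dict = field(default_factory=dict)


@dataclass(frozen=True)
class AucResult:
    comparison: str
    biomarker: str
    auc: float
    ci_lower: float
    ci_upper: float
    specificity: float
    spec_ci_lower: float
    spec_ci_upper: float
    n_cases: int
    n_controls: int


def _oriented(values: np.ndarray, direction: str) -> np.ndarray:
    """Map values so that 'case side' is always 'larger'."""
    if direction == "higher":
        return values
    if direction == "lower":
        return -values
    raise ValueError(f"invalid direction {direction!r}")


def auc(cases, controls, direction: str = "higher") -> float:
    """Tie-corrected pair-counting AUC.

    Over all case–comparator pairs: 1 when the case lies on the case side
    of the comparator, 0.5 on ties, divided by n_cases * n_controls.
    Computed via midranks, which is algebraically identical to the pair
    count.
    """
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    cases = cases[np.isfinite(cases)]
    controls = controls[np.isfinite(controls)]
    if cases.size == 0 or controls.size == 0:
        raise ValueError("need at least one case and one comparator value")
    x = _oriented(np.concatenate([cases, controls]), direction)
    ranks = stats.rankdata(x)
    r_cases = ranks[: cases.size].sum()
    n1, n0 = cases.size, controls.size
    return float((r_cases - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_curve(cases, controls, direction: str = "higher") -> RocCurve:
    """Empirical ROC operating points at every observed threshold.

    The positivity rule includes equality with the threshold; the sweep
    runs from the most case-side observed value (sensitivity 0 ... 1 as
    thresholds relax).
    """
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    cases = cases[np.isfinite(cases)]
    controls = controls[np.isfinite(controls)]
    xc = _oriented(cases, direction)
    xk = _oriented(controls, direction)
    thresholds = np.unique(np.concatenate([xc, xk]))[::-1]
    sens = np.array([(xc >= t).mean() for t in thresholds])
    spec = np.array([(xk < t).mean() for t in thresholds])
    return RocCurve(
        thresholds=_oriented(thresholds, direction),
        sensitivity=sens, specificity=spec, direction=direction,
        n_cases=cases.size, n_controls=controls.size,
    )


def cutpoint_at_sensitivity(ad_values, direction: str = "higher",
                            target: float = 0.85) -> float:
    """Most case-side observed AD value meeting the sensitivity target.

    A test is positive when the value is on the case side of, or equal to,
    the cut-point.  Among thresholds with positivity fraction >= target
    this choice maximises specificity against any comparator, and depends
    only on the AD sample.
    """
    if not (0 < target <= 1):
        raise ValueError(f"target sensitivity must lie in (0, 1]: got {target}")
    v = np.asarray(ad_values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least two AD values")
    x = np.sort(_oriented(v, direction))[::-1]  # case side first
    k = int(np.ceil(target * x.size))           # minimal positives needed
    # threshold at the k-th most case-side value; ties can only add positives
    cut = x[k - 1]
    return float(cut if direction == "higher" else -cut)


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (conservative) binomial confidence interval by beta inversion."""
    if n < 1 or not (0 <= k <= n):
        raise ValueError(f"invalid binomial counts k={k}, n={n}")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def cutpoint_ci(
    ad_values,
    direction: str = "higher",
    target: float = 0.85,
    level: float = 0.95,
    method: str = "binomial",
    n_boot: int = 2000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Confidence interval for the fixed-sensitivity cut-point.

    Default method: take the exact binomial interval for the positive
    count at the cut-point and map its bounds back onto the AD order
    statistics — the thresholds whose positivity fractions reach each
    bound.  ``method="bootstrap"`` instead resamples the AD values and
    takes percentiles of the re-estimated cut-point.
    """
    v = np.asarray(ad_values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least two AD values")
    cut = cutpoint_at_sensitivity(v, direction, target)

    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for i in range(n_boot):
            reps[i] = cutpoint_at_sensitivity(rng.choice(v, v.size), direction, target)
        alpha = 1.0 - level
        lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
        return float(min(lo, cut)), float(max(hi, cut))
    if method != "binomial":
        raise ValueError(f"unknown cut-point CI method {method!r}")

    x = _oriented(v, direction)
    n = x.size
    k = int((x >= _oriented(np.asarray(cut), direction)).sum())
    p_lo, p_hi = clopper_pearson(k, n, level)

    def threshold_for(frac: float) -> float:
        kk = max(1, int(np.ceil(frac * n)))
        t = np.sort(x)[::-1][kk - 1]
        return float(t if direction == "higher" else -t)

    a, b = threshold_for(p_hi), threshold_for(p_lo)
    lo, hi = min(a, b), max(a, b)
    return float(min(lo, cut)), float(max(hi, cut))


def is_positive(values, cutpoint: float, direction: str = "higher") -> np.ndarray:
    """Positivity rule: on the case side of, or equal to, the cut-point."""
    values = np.asarray(values, dtype=float)
    if direction == "higher":
        return values >= cutpoint
    return values <= cutpoint


def sensitivity_at_cutpoint(case_values, cutpoint: float, direction: str = "higher",
                            level: float = 0.95):
    """Fraction of cases testing positive, with its exact binomial CI."""
    v = np.asarray(case_values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no case values")
    k = int(is_positive(v, cutpoint, direction).sum())
    lo, hi = clopper_pearson(k, v.size, level)
    return k / v.size, lo, hi, v.size


def specificity_at_cutpoint(comparator_values, cutpoint: float,
                            direction: str = "higher", level: float = 0.95):
    """Fraction of comparators testing negative, with its exact binomial CI."""
    v = np.asarray(comparator_values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no comparator values")
    k = int((~is_positive(v, cutpoint, direction)).sum())
    lo, hi = clopper_pearson(k, v.size, level)
    return k / v.size, lo, hi, v.size


def estimate_cutpoint(
    biomarker: str,
    ad_values,
    comparators: dict,
    direction: str = "higher",
    target: float = 0.85,
    level: float = 0.95,
    ci_method: str = "binomial",
    seed: int | None = None,
) -> CutpointResult:
    """Fixed-sensitivity cut-point with CI and per-comparator specificities."""
    cut = cutpoint_at_sensitivity(ad_values, direction, target)
    lo, hi = cutpoint_ci(ad_values, direction, target, level,
                         method=ci_method, seed=seed)
    sens, _, _, n_cases = sensitivity_at_cutpoint(ad_values, cut, direction, level)
    specs = {}
    for label, vals in comparators.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            logger.info("no comparator values for %s vs %s", biomarker, label)
            continue
        specs[label] = specificity_at_cutpoint(vals, cut, direction, level)
    return CutpointResult(
        biomarker=biomarker, direction=direction, cutpoint=cut,
        ci_lower=lo, ci_upper=hi, target_sensitivity=target,
        achieved_sensitivity=sens, n_cases=n_cases, specificities=specs,
    )


def rank_biomarkers(aucs: dict[str, float], candidates: list[str] | None = None,
                    k: int = 5) -> list[str]:
    """Top-k candidate biomarkers by AUC, ties broken by name.

    ``candidates`` restricts the pool (e.g. to biomarkers with at least a
    single '+' pairwise tier for the comparison); None means all.
    """
    pool = list(aucs) if candidates is None else [c for c in candidates if c in aucs]
    if not pool:
        logger.info("empty candidate biomarker set")
        return []
    ranked = sorted(pool, key=lambda b: (-aucs[b], b))
    return ranked[:k]
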