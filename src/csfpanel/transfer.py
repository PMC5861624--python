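"""Cut-point transfer to an independent validation cohort.

Cut-points estimated on the test cohort are applied unchanged — never
re-estimated — to the validation cohort and to the pathology/genetically
confirmed sub-cohort.  Because several validation diagnostic groups are
very small, discrimination is only assessed for AD against controls,
against the other dementias pooled, and against both combined.  Each cell
reports sensitivity and specificity with exact binomial intervals and its
complete-case denominators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import OTHER_DEMENTIA_GROUPS
from .roc import CutpointResult, is_positive, clopper_pearson

logger = logging.getLogger(__name__)

#: the three comparison sets assessed in the validation cohort
COMPARISONS: dict[str, tuple[str, ...]] = {
    "controls": ("HC",),
    "other_dementias": OTHER_DEMENTIA_GROUPS,
    "combined": OTHER_DEMENTIA_GROUPS + ("HC",),
}


@dataclass(frozen=True)
class TransferResult:
    biomarker: str
    comparison: str       # "controls" | "other_dementias" | "combined"
    sensitivity: float
    sens_ci_lower: float
    sens_ci_upper: float
    specificity: float
    spec_ci_lower: float
    spec_ci_upper: float
    n_cases: int
    n_comparators: int
    cutpoint: float
    direction: str


def _binomial_cell(values: np.ndarray, cutpoint: float, direction: str,
                   positive_is_success: bool, level: float):
    v = values[np.isfinite(values)]
    if v.size == 0:
        return np.nan, np.nan, np.nan, 0
    pos = is_positive(v, cutpoint, direction)
    k = int(pos.sum()) if positive_is_success else int((~pos).sum())
    lo, hi = clopper_pearson(k, v.size, level)
    return k / v.size, lo, hi, v.size


def apply_cutpoints(
    validation_table: pd.DataFrame,
    cutpoints: dict[str, CutpointResult],
    level: float = 0.95,
) -> list[TransferResult]:
    """Sensitivity/specificity of transferred cut-points, per biomarker
    and comparison set, complete-case per biomarker."""
    results = []
    for biomarker, cp in cutpoints.items():
        if biomarker not in validation_table.columns or \
                validation_table[biomarker].notna().sum() == 0:
            logger.info("biomarker %s absent from validation data; skipped", biomarker)
            continue
        ad_vals = validation_table.loc[
            validation_table["group"] == "AD", biomarker].to_numpy(dtype=float)
        sens, slo, shi, n_cases = _binomial_cell(
            ad_vals, cp.cutpoint, cp.direction, True, level)
        for comparison, groups in COMPARISONS.items():
            comp_vals = validation_table.loc[
                validation_table["group"].isin(groups), biomarker
            ].to_numpy(dtype=float)
            spec, plo, phi, n_comp = _binomial_cell(
                comp_vals, cp.cutpoint, cp.direction, False, level)
            if n_comp == 0:
                continue
            results.append(TransferResult(
                biomarker=biomarker, comparison=comparison,
                sensitivity=sens, sens_ci_lower=slo, sens_ci_upper=shi,
                specificity=spec, spec_ci_lower=plo, spec_ci_upper=phi,
                n_cases=n_cases, n_comparators=n_comp,
                cutpoint=cp.cutpoint, direction=cp.direction,
            ))
    return results


def subcohort_accuracy(
    table: pd.DataFrame,
    cutpoints: dict[str, CutpointResult],
    confirmed_only: bool = True,
    level: float = 0.95,
) -> list[TransferResult]:
    """Identical computation restricted to confirmed subjects.

    With ~26 pathology/genetically confirmed subjects the exact intervals
    are necessarily wide; comparisons with no comparator subjects (e.g.
    controls, which are never autopsy-confirmed here) are omitted.
    """
    sub = table[table["confirmed"] == 1] if confirmed_only else table
    if sub.empty:
        logger.info("no confirmed subjects; empty sub-cohort result")
        return []
    return apply_cutpoints(sub, cutpoints, level)


def transfer_to_frame(results: list[TransferResult]) -> pd.DataFrame:
    """Tidy frame of transfer results (Table-S1-shaped block)."""
    return pd.DataFrame([r.__dict__ for r in results], columns=[
        "biomarker", "comparison", "sensitivity", "sens_ci_lower",
        "sens_ci_upper", "specificity", "spec_ci_lower", "spec_ci_upper",
        "n_cases", "n_comparators", "cutpoint", "direction",
    ])
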