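"""End-to-end pipeline orchestration and report tables.

Runs the full analysis on a test and a validation cohort table and emits
five delimited reports:

* global heteroscedastic tests per biomarker (three variants),
* the pairwise significance grid with "+" / "++" tier glyphs,
* fixed-sensitivity cut-points with exact intervals,
* per-comparison top-5 AUC/specificity rows plus joint-model rows,
* the cut-point transfer block (test, validation, confirmed sub-cohort),

together with a plain-text run log recording configuration, seeds,
convergence notes and complete-case counts, and optionally the ROC
operating points for plotting.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (ALL_BIOMARKERS, GROUPS, OTHER_DEMENTIA_GROUPS,
                     default_biomarker_definitions)
from .combine import BootstrapConfig, bootstrap_auc_ci, fit_combination, joint_model_eligible
from .config import AnalysisConfig
from .gls import run_global_tests, run_pairwise_tests
from .roc import (_oriented, auc, estimate_cutpoint, rank_biomarkers,
                  roc_curve, specificity_at_cutpoint)
from .transfer import apply_cutpoints, subcohort_accuracy, transfer_to_frame

logger = logging.getLogger(__name__)

#: the five measures carried into the validation cohort
TRANSFER_BIOMARKERS: tuple[str, ...] = (
    "abeta_1_42", "t_tau", "p_tau_181", "t_tau_abeta_1_42", "abx42_abx40",
)

#: comparison label -> comparator groups (AD is always the case group)
COMPARISONS: dict[str, tuple[str, ...]] = {
    "AD vs HC": ("HC",),
    "AD vs DLB": ("DLB",),
    "AD vs bvFTD": ("bvFTD",),
    "AD vs PNFA": ("PNFA",),
    "AD vs SD": ("SD",),
    "AD vs non-AD dementia": OTHER_DEMENTIA_GROUPS,
    "AD vs all others": OTHER_DEMENTIA_GROUPS + ("HC",),
}

TIER_GLYPH = {"none": "", "single": "+", "double": "++", "not_computed": "NC"}


@dataclass
class ReportBundle:
    global_tests: pd.DataFrame
    pairwise: pd.DataFrame
    cutpoints: dict
    cutpoint_table: pd.DataFrame
    top5: pd.DataFrame
    transfer: pd.DataFrame
    roc_coordinates: pd.DataFrame | None = None
    log_lines: list[str] = field(default_factory=list)


def _case_comparator_values(table, biomarker, comparator_groups):
    vals = table[biomarker]
    cases = vals[table["group"] == "AD"].dropna().to_numpy(dtype=float)
    comps = vals[table["group"].isin(comparator_groups)].dropna().to_numpy(dtype=float)
    return cases, comps


def _candidates_for(comparison, comparator_groups, pairwise):
    """Candidate biomarkers: any '+' tier on the pair; all for pooled sets."""
    if len(comparator_groups) > 1:
        return None
    other = comparator_groups[0]
    if pairwise.empty:
        return []
    mask = (
        ((pairwise["group_a"] == "AD") & (pairwise["group_b"] == other))
        | ((pairwise["group_a"] == other) & (pairwise["group_b"] == "AD"))
    ) & pairwise["tier"].isin(["single", "double"])
    return sorted(pairwise.loc[mask, "biomarker"].unique())


def run_pipeline(
    test_table: pd.DataFrame,
    validation_table: pd.DataFrame,
    analysis: AnalysisConfig | None = None,
    seed: int | None = None,
    export_roc: bool = False,
) -> ReportBundle:
    """Run the full analysis on the two cohort tables.

    Every random stage (the bootstrap intervals) consumes a named child
    stream of the master seed, recorded in the run log, so a full run is
    reproducible bit for bit.
    """
    analysis = analysis or AnalysisConfig()
    seed = analysis.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    log: list[str] = [f"csfpanel {__version__}", f"master seed: {seed}",
                      f"analysis config: {analysis}"]

    defs = default_biomarker_definitions(directions=analysis.directions)
    biomarkers = [b for b in ALL_BIOMARKERS if b in test_table.columns]

    # --- global tests and gated pairwise grid -------------------------------
    global_tests = run_global_tests(test_table, biomarkers)
    pairwise = run_pairwise_tests(
        test_table, biomarkers, global_tests,
        alpha=analysis.pairwise_alpha, bonferroni=analysis.bonferroni_threshold)
    for b in biomarkers:
        n_pairs = int((pairwise["biomarker"] == b).sum())
        log.append(f"pairwise {b}: {n_pairs} comparisons "
                   f"({'gate passed' if n_pairs else 'gate failed'})")

    # --- fixed-sensitivity cut-points (comparator-independent) -------------
    cutpoints = {}
    cut_rows = []
    for b in biomarkers:
        cases = test_table.loc[test_table["group"] == "AD", b].dropna()
        if len(cases) < 2:
            continue
        comparators = {
            g: test_table.loc[test_table["group"] == g, b].dropna().to_numpy()
            for g in GROUPS if g != "AD"
        }
        cp = estimate_cutpoint(
            b, cases.to_numpy(dtype=float), comparators,
            direction=defs[b].ad_direction,
            target=analysis.target_sensitivity, level=analysis.ci_level)
        cutpoints[b] = cp
        cut_rows.append({
            "biomarker": b, "direction": cp.direction,
            "glyph": "<" if cp.direction == "lower" else ">",
            "cutpoint": cp.cutpoint, "ci_lower": cp.ci_lower,
            "ci_upper": cp.ci_upper,
            "achieved_sensitivity": cp.achieved_sensitivity,
            "n_cases": cp.n_cases,
        })
        log.append(f"cutpoint {b}: n={cp.n_cases} complete cases, "
                   f"achieved sensitivity {cp.achieved_sensitivity:.3f}")
    cutpoint_table = pd.DataFrame(cut_rows)

    # --- per-comparison top-5 single biomarkers + joint models --------------
    boot_streams = iter(ss.spawn(512))
    top5_rows = []
    for comparison, comp_groups in COMPARISONS.items():
        aucs = {}
        for b in biomarkers:
            cases, comps = _case_comparator_values(test_table, b, comp_groups)
            if cases.size and comps.size:
                aucs[b] = auc(cases, comps, defs[b].ad_direction)
        candidates = _candidates_for(comparison, comp_groups, pairwise)
        top = rank_biomarkers(aucs, candidates, k=5)
        if not top:
            log.append(f"{comparison}: empty candidate set, no rows")
            continue
        for b in top:
            cases, comps = _case_comparator_values(test_table, b, comp_groups)
            y = np.concatenate([np.ones(cases.size), np.zeros(comps.size)])
            scores = _oriented(np.concatenate([cases, comps]), defs[b].ad_direction)
            child = next(boot_streams)
            lo, hi = bootstrap_auc_ci(
                scores, y,
                BootstrapConfig(replications=analysis.bootstrap_replications,
                                seed=child),
                level=analysis.ci_level)
            spec, slo, shi, n_comp = specificity_at_cutpoint(
                comps, cutpoints[b].cutpoint, defs[b].ad_direction,
                analysis.ci_level)
            top5_rows.append({
                "comparison": comparison, "biomarker": b, "auc": aucs[b],
                "auc_ci_lower": lo, "auc_ci_upper": hi,
                "specificity_pct": 100.0 * spec,
                "spec_ci_lower_pct": 100.0 * slo, "spec_ci_upper_pct": 100.0 * shi,
                "n_cases": cases.size, "n_comparators": comps.size,
            })

        # joint model ("All the above") where both groups are large enough
        n_ad = int((test_table["group"] == "AD").sum())
        n_comp_group = int(test_table["group"].isin(comp_groups).sum())
        if not joint_model_eligible(n_ad, n_comp_group, analysis.joint_min_group_size):
            log.append(f"{comparison}: no joint model "
                       f"(n={n_ad} vs {n_comp_group}, need both > "
                       f"{analysis.joint_min_group_size})")
            continue
        sub = test_table[test_table["group"].isin(("AD",) + tuple(comp_groups))]
        complete = sub[list(top)].notna().all(axis=1)
        n_excluded = int((~complete).sum())
        sub = sub[complete]
        y = (sub["group"] == "AD").to_numpy(dtype=float)
        if y.sum() < 2 or (1 - y).sum() < 2:
            log.append(f"{comparison}: too few complete cases for joint model")
            continue
        X = np.log(sub[list(top)].to_numpy(dtype=float))
        child = next(boot_streams)
        res = fit_combination(
            comparison, X, y, tuple(top),
            target_sensitivity=analysis.target_sensitivity,
            level=analysis.ci_level,
            bootstrap=BootstrapConfig(
                replications=analysis.bootstrap_replications, seed=child),
            n_excluded=n_excluded)
        log.append(f"{comparison} joint model: biomarkers {top}, "
                   f"n={res.n_cases}+{res.n_controls}, excluded {n_excluded} "
                   f"incomplete, separated={res.separated}")
        top5_rows.append({
            "comparison": comparison, "biomarker": "all_above", "auc": res.auc,
            "auc_ci_lower": res.ci_lower, "auc_ci_upper": res.ci_upper,
            "specificity_pct": 100.0 * res.specificity,
            "spec_ci_lower_pct": 100.0 * res.spec_ci_lower,
            "spec_ci_upper_pct": 100.0 * res.spec_ci_upper,
            "n_cases": res.n_cases, "n_comparators": res.n_controls,
        })
    top5 = pd.DataFrame(top5_rows)

    # --- cut-point transfer --------------------------------------------------
    transfer_cutpoints = {b: cutpoints[b] for b in TRANSFER_BIOMARKERS
                          if b in cutpoints}
    blocks = []
    for label, frame in (
        ("test", transfer_to_frame(
            apply_cutpoints(test_table, transfer_cutpoints, analysis.ci_level))),
        ("validation", transfer_to_frame(
            apply_cutpoints(validation_table, transfer_cutpoints, analysis.ci_level))),
        ("confirmed", transfer_to_frame(
            subcohort_accuracy(test_table, transfer_cutpoints,
                               level=analysis.ci_level))),
    ):
        frame.insert(0, "cohort", label)
        blocks.append(frame)
    transfer = pd.concat(blocks, ignore_index=True)

    roc_coords = None
    if export_roc:
        coord_rows = []
        for comparison, comp_groups in COMPARISONS.items():
            for b in biomarkers:
                cases, comps = _case_comparator_values(test_table, b, comp_groups)
                if not (cases.size and comps.size):
                    continue
                curve = roc_curve(cases, comps, defs[b].ad_direction)
                coord_rows.append(pd.DataFrame({
                    "comparison": comparison, "biomarker": b,
                    "threshold": curve.thresholds,
                    "sensitivity": curve.sensitivity,
                    "specificity": curve.specificity,
                }))
        roc_coords = pd.concat(coord_rows, ignore_index=True)

    return ReportBundle(
        global_tests=global_tests, pairwise=pairwise, cutpoints=cutpoints,
        cutpoint_table=cutpoint_table, top5=top5, transfer=transfer,
        roc_coordinates=roc_coords, log_lines=log,
    )


def pairwise_grid(pairwise: pd.DataFrame, biomarkers: list[str]) -> pd.DataFrame:
    """Wide significance grid: rows = group pairs, columns = biomarkers,
    cells = tier glyphs ('' / '+' / '++')."""
    pairs = [f"{a} vs {b}" for a, b in itertools.combinations(GROUPS, 2)]
    grid = pd.DataFrame("", index=pairs, columns=biomarkers)
    for _, row in pairwise.iterrows():
        key = f"{row['group_a']} vs {row['group_b']}"
        if key in grid.index and row["biomarker"] in grid.columns:
            grid.loc[key, row["biomarker"]] = TIER_GLYPH.get(row["tier"], "")
    grid.index.name = "pair"
    return grid


def write_reports(bundle: ReportBundle, outdir) -> list[str]:
    """Write the five report tables plus the run log; return the paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = []

    def _write(df: pd.DataFrame, name: str, index=False):
        p = os.path.join(outdir, name)
        df.to_csv(p, index=index)
        paths.append(p)

    gt = bundle.global_tests.copy()
    gt["variant"] = np.where(
        gt["scope"] == "with_controls", "including_hc",
        np.where(gt["adjusted"], "excluding_hc_adjusted", "excluding_hc"))
    table2 = gt.pivot_table(index="biomarker", columns="variant",
                            values="p_value", sort=False)
    table2 = table2.reindex(columns=["including_hc", "excluding_hc",
                                     "excluding_hc_adjusted"])
    _write(table2.reset_index(), "global_tests.csv")

    biomarkers = list(dict.fromkeys(bundle.pairwise["biomarker"])) \
        if not bundle.pairwise.empty else []
    _write(pairwise_grid(bundle.pairwise, biomarkers), "pairwise_tiers.csv",
           index=True)
    _write(bundle.cutpoint_table, "cutpoints.csv")
    _write(bundle.top5, "top5_auc.csv")
    _write(bundle.transfer, "validation_transfer.csv")
    if bundle.roc_coordinates is not None:
        _write(bundle.roc_coordinates, "roc_coordinates.csv")

    log_path = os.path.join(outdir, "run_log.txt")
    with open(log_path, "w") as fh:
        fh.write("\n".join(bundle.log_lines) + "\n")
    paths.append(log_path)
    return paths
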