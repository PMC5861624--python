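"""Configuration: analysis parameters and cohort-design documents.

One YAML document configures the whole pipeline: fixed target sensitivity,
confidence level, pairwise significance thresholds, bootstrap replications,
joint-model eligibility, the biomarker panel with AD-side orientations,
the between-biomarker log-scale correlation assumption, and per-cohort
generative designs (group sizes, per-group per-biomarker median/Q1/Q3 and
available n, demographics).  A packaged default encodes the published
test- and validation-cohort summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

from .cohort import MEASURED_BIOMARKERS, RATIO_DEFINITIONS

AMYLOID_FAMILY = ("abeta_1_42", "abx_38", "abx_40", "abx_42", "sappa", "sappb")
TAU_PAIR = ("t_tau", "p_tau_181")


class ConfigError(ValueError):
    """Malformed configuration; message names the offending key."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline-wide analysis parameters.

    ``bonferroni_threshold`` is the fixed pairwise significance threshold,
    0.05 over the 15 unordered group pairs rounded to three decimals;
    ``joint_min_group_size`` is exclusive (both groups must exceed it).
    """

    target_sensitivity: float = 0.85
    ci_level: float = 0.95
    pairwise_alpha: float = 0.05
    bonferroni_threshold: float = 0.003
    bootstrap_replications: int = 2000
    joint_min_group_size: int = 10
    seed: int = 20180320
    directions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in ("target_sensitivity", "ci_level", "pairwise_alpha",
                    "bonferroni_threshold"):
            v = getattr(self, key)
            if not (0 < v <= 1) or (key != "target_sensitivity" and v >= 1):
                raise ConfigError(f"{key} must lie in (0, 1): got {v}")
        if self.bootstrap_replications < 1:
            raise ConfigError("bootstrap_replications must be >= 1")
        if self.joint_min_group_size < 0:
            raise ConfigError("joint_min_group_size must be non-negative")


def build_correlation(
    biomarkers: tuple[str, ...],
    amyloid_family: float = 0.5,
    tau_pair: float = 0.7,
    default: float = 0.3,
) -> np.ndarray:
    """Log-scale correlation matrix over the base biomarkers.

    Block structure: one common correlation within the amyloid-processing
    family, a stronger one between total and phosphorylated tau, and a weak
    positive value for all remaining pairs.  Validated to be symmetric PSD.
    """
    k = len(biomarkers)
    corr = np.full((k, k), default)
    for i, a in enumerate(biomarkers):
        for j, b in enumerate(biomarkers):
            if i == j:
                corr[i, j] = 1.0
            elif a in AMYLOID_FAMILY and b in AMYLOID_FAMILY:
                corr[i, j] = amyloid_family
            elif a in TAU_PAIR and b in TAU_PAIR:
                corr[i, j] = tau_pair
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        raise ConfigError("correlation matrix is not positive semi-definite")
    return corr


@dataclass
class CohortConfig:
    """Generative design for one cohort (sizes, distributions, demographics)."""

    label: str
    group_sizes: dict[str, int]
    biomarker_specs: dict[str, dict[str, dict]]  # group -> biomarker -> {median,q1,q3,n}
    demographics: dict[str, dict]
    confirmed: dict[str, int]
    measured: tuple[str, ...]
    availability_fraction: dict[str, float]
    correlation: np.ndarray
    detection_lower_factor: float = 0.1
    detection_upper_factor: float = 10.0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 0:
                raise ConfigError(f"group size for {g} is negative")


@dataclass
class PipelineConfig:
    analysis: AnalysisConfig
    test: CohortConfig
    validation: CohortConfig
    raw: dict


def _cohort_config(label: str, doc: dict, full: dict) -> CohortConfig:
    corr_doc = full.get("correlation", {})
    measured = tuple(doc.get("measured", MEASURED_BIOMARKERS))
    corr = build_correlation(
        measured,
        amyloid_family=corr_doc.get("amyloid_family", 0.5),
        tau_pair=corr_doc.get("tau_pair", 0.7),
        default=corr_doc.get("default", 0.3),
    )
    source = doc
    if "distributions_from" in doc:
        source = full["cohorts"][doc["distributions_from"]]
    specs = {
        g: {b: dict(v) for b, v in per_group.items() if b in measured}
        for g, per_group in source["biomarkers"].items()
    }
    demo = {g: dict(v) for g, v in source["demographics"].items()}
    limits = full.get("detection_limits", {})
    return CohortConfig(
        label=label,
        group_sizes=dict(doc["groups"]),
        biomarker_specs=specs,
        demographics=demo,
        confirmed=dict(doc.get("confirmed", {})),
        measured=measured,
        availability_fraction=dict(doc.get("availability_fraction", {})),
        correlation=corr,
        detection_lower_factor=limits.get("lower_factor", 0.1),
        detection_upper_factor=limits.get("upper_factor", 10.0),
    )


def load_config(path=None, overrides: Mapping | None = None) -> PipelineConfig:
    """Load a pipeline configuration (packaged default when ``path`` is None)."""
    if path is None:
        text = resources.files("csfpanel.data").joinpath("default_config.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    if overrides:
        doc.setdefault("analysis", {}).update(overrides)
    a = doc.get("analysis", {})
    directions = {
        name: spec["direction"]
        for section in ("biomarkers", "ratios")
        for name, spec in doc.get(section, {}).items()
        if "direction" in spec
    }
    unknown = set(directions) - set(MEASURED_BIOMARKERS) - set(RATIO_DEFINITIONS)
    if unknown:
        raise ConfigError(f"unknown biomarker(s) in config: {sorted(unknown)}")
    analysis = AnalysisConfig(
        target_sensitivity=a.get("target_sensitivity", 0.85),
        ci_level=a.get("ci_level", 0.95),
        pairwise_alpha=a.get("pairwise_alpha", 0.05),
        bonferroni_threshold=a.get("bonferroni_threshold", 0.003),
        bootstrap_replications=a.get("bootstrap_replications", 2000),
        joint_min_group_size=a.get("joint_min_group_size", 10),
        seed=a.get("seed", 20180320),
        directions=directions,
    )
    test = _cohort_config("test", doc["cohorts"]["test"], doc)
    validation = _cohort_config("validation", doc["cohorts"]["validation"], doc)
    return PipelineConfig(analysis=analysis, test=test, validation=validation, raw=doc)
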