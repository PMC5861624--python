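"""Synthetic cohort generation calibrated to published group summaries.

Only group-level summaries (median and interquartile range per diagnostic
group, with per-biomarker available n) are published for these cohorts, so
patient-level data are emulated: each biomarker is log-normal within each
group, with log-scale parameters chosen so the implied distribution has
exactly the published median and quartiles; biomarkers are coupled through
an assumed log-scale correlation structure; missingness is missing
completely at random at the published per-group rates; values outside a
configurable detection range are clamped.  Ratio markers are computed from
their generated constituents, not drawn directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import cohort as _cohort
from .config import CohortConfig

#: standard-normal upper-quartile deviate
Z75 = float(stats.norm.ppf(0.75))


@dataclass(frozen=True)
class GroupDistributionSpec:
    """Published summary of one biomarker in one diagnostic group."""

    group: str
    biomarker: str
    median: float
    q1: float
    q3: float
    n_available: int
    n_group: int

    def __post_init__(self) -> None:
        if not (0 < self.q1 < self.median < self.q3):
            raise ValueError(
                f"{self.group}/{self.biomarker}: quartiles must satisfy "
                f"0 < q1 < median < q3, got ({self.q1}, {self.median}, {self.q3})"
            )
        if not (0 <= self.n_available <= self.n_group):
            raise ValueError(
                f"{self.group}/{self.biomarker}: n_available {self.n_available} "
                f"outside [0, {self.n_group}]"
            )


@dataclass(frozen=True)
class DemographicSpec:
    """Published demographic summary of one group (duration absent for HC)."""

    group: str
    age_median: float
    age_q1: float
    age_q3: float
    pct_male: float
    duration_median: float | None = None
    duration_q1: float | None = None
    duration_q3: float | None = None
    duration_n: int | None = None
    mmse_median: float | None = None
    mmse_q1: float | None = None
    mmse_q3: float | None = None
    mmse_n: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.pct_male <= 100):
            raise ValueError(f"{self.group}: pct_male outside [0, 100]")
        if not (self.age_q1 <= self.age_median <= self.age_q3):
            raise ValueError(f"{self.group}: age quartiles unordered")


@dataclass
class CohortDesign:
    """Everything needed to generate one cohort reproducibly."""

    label: str
    group_sizes: dict[str, int]
    specs: dict[str, dict[str, GroupDistributionSpec]]  # group -> biomarker -> spec
    demographics: dict[str, DemographicSpec]
    confirmed: dict[str, int]
    biomarkers: tuple[str, ...]
    correlation: np.ndarray
    seed: int
    detection_lower_factor: float = 0.1
    detection_upper_factor: float = 10.0

    def __post_init__(self) -> None:
        k = len(self.biomarkers)
        c = np.asarray(self.correlation, dtype=float)
        if c.shape != (k, k):
            raise ValueError("correlation dimension does not match biomarker count")
        if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ValueError("correlation must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError("correlation must be positive semi-definite")


def lognormal_params_from_quartiles(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Log-normal (mu, sigma) whose median and quartiles match the inputs.

    mu = ln(median); sigma = (ln q3 - ln q1) / (2 * z_{0.75}).  The implied
    distribution reproduces the requested median/Q1/Q3 exactly.
    """
    if not (0 < q1 < median < q3):
        raise ValueError(f"quartiles must satisfy 0 < q1 < median < q3, "
                         f"got ({q1}, {median}, {q3})")
    mu = np.log(median)
    sigma = (np.log(q3) - np.log(q1)) / (2.0 * Z75)
    return float(mu), float(sigma)


def _normal_params_from_quartiles(median: float, q1: float, q3: float) -> tuple[float, float]:
    return float(median), float((q3 - q1) / (2.0 * Z75))


def _correlated_standard_normals(rng: np.random.Generator, n: int, corr: np.ndarray) -> np.ndarray:
    k = corr.shape[0]
    z = rng.standard_normal((n, k))
    if k == 1 or np.allclose(corr, np.eye(k)):
        return z
    # small jitter tolerates numerically semi-definite inputs
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(k))
    return z @ chol.T


def generate_group(
    specs: dict[str, GroupDistributionSpec],
    demo: DemographicSpec,
    n: int,
    correlation: np.ndarray,
    rng: np.random.Generator,
    biomarkers: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Generate ``n`` subjects for one diagnostic group.

    Biomarker vectors follow a correlated multivariate log-normal with
    per-biomarker parameters quantile-matched to the group's published
    summary; age is normal (truncated below at 18 y), sex Bernoulli, and
    disease duration log-normal matched to its quartiles.
    """
    if biomarkers is None:
        biomarkers = tuple(specs)
    missing = [b for b in biomarkers if b not in specs]
    if missing:
        raise ValueError(f"{demo.group}: no distribution spec for {missing}")
    correlation = np.asarray(correlation, dtype=float)
    if correlation.shape != (len(biomarkers),) * 2:
        raise ValueError("correlation dimension does not match biomarker count")
    if np.linalg.eigvalsh(correlation).min() < -1e-10:
        raise ValueError("correlation must be positive semi-definite")

    cols: dict[str, np.ndarray] = {}
    z = _correlated_standard_normals(rng, n, correlation)
    for j, b in enumerate(biomarkers):
        s = specs[b]
        mu, sigma = lognormal_params_from_quartiles(s.median, s.q1, s.q3)
        cols[b] = np.exp(mu + sigma * z[:, j])

    age_mu, age_sd = _normal_params_from_quartiles(demo.age_median, demo.age_q1, demo.age_q3)
    if age_sd > 0:
        a = (18.0 - age_mu) / age_sd
        age = stats.truncnorm.rvs(a, np.inf, loc=age_mu, scale=age_sd,
                                  size=n, random_state=rng)
    else:
        age = np.full(n, age_mu)
    sex = np.where(rng.random(n) < demo.pct_male / 100.0, "male", "female")

    if demo.duration_median is not None:
        dmu, dsigma = lognormal_params_from_quartiles(
            demo.duration_median, demo.duration_q1, demo.duration_q3)
        onset = np.exp(dmu + dsigma * rng.standard_normal(n))
    else:
        onset = np.full(n, np.nan)

    if demo.mmse_median is not None:
        if demo.mmse_q1 == demo.mmse_q3:
            mmse = np.full(n, float(demo.mmse_median))
        else:
            mmu, msd = _normal_params_from_quartiles(
                demo.mmse_median, demo.mmse_q1, demo.mmse_q3)
            mmse = np.clip(np.round(mmu + msd * rng.standard_normal(n)), 0, 30)
    else:
        mmse = np.full(n, np.nan)

    df = pd.DataFrame({
        "subject_id": [f"{demo.group}_{i:05d}" for i in range(n)],
        "group": demo.group,
        "cohort": "",
        "confirmed": 0,
        "age_at_lp": age,
        "sex": sex,
        "onset_to_lp_months": onset,
        "mmse": mmse,
    })
    for b in _cohort.MEASURED_BIOMARKERS:
        df[b] = cols.get(b, np.full(n, np.nan))
    return df


def apply_missingness(
    table: pd.DataFrame,
    specs: list[GroupDistributionSpec],
    seed: int | np.random.SeedSequence,
) -> pd.DataFrame:
    """Delete values completely at random at the published per-group rates.

    Each group × biomarker cell is set missing independently with
    probability 1 − n_available/n_group, from an independent random stream
    per biomarker, so missingness is unrelated to values and covariates.
    """
    out = table.copy()
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    by_biomarker: dict[str, list[GroupDistributionSpec]] = {}
    for s in specs:
        by_biomarker.setdefault(s.biomarker, []).append(s)
    streams = ss.spawn(len(by_biomarker))
    for stream, (biomarker, spec_list) in zip(streams, sorted(by_biomarker.items())):
        if biomarker not in out.columns:
            continue
        rng = np.random.default_rng(stream)
        for s in spec_list:
            if s.n_group == 0:
                continue
            p_miss = 1.0 - s.n_available / s.n_group
            if p_miss <= 0:
                continue
            mask = (out["group"] == s.group).to_numpy()
            drop = rng.random(int(mask.sum())) < p_miss
            idx = np.flatnonzero(mask)[drop]
            out.iloc[idx, out.columns.get_loc(biomarker)] = np.nan
    return out


def _pooled_weighted_median(design: CohortDesign, biomarker: str) -> float:
    meds, weights = [], []
    for g, per in design.specs.items():
        if biomarker in per and design.group_sizes.get(g, 0) > 0:
            meds.append(per[biomarker].median)
            weights.append(design.group_sizes[g])
    order = np.argsort(meds)
    meds, weights = np.asarray(meds)[order], np.asarray(weights)[order]
    cum = np.cumsum(weights)
    return float(meds[np.searchsorted(cum, cum[-1] / 2.0)])


def detection_ranges(design: CohortDesign) -> list[_cohort.AssayRange]:
    """Default assay ranges: (lower_factor, upper_factor) × pooled median."""
    ranges = []
    for b in design.biomarkers:
        med = _pooled_weighted_median(design, b)
        ranges.append(_cohort.AssayRange(
            b, design.detection_lower_factor * med, design.detection_upper_factor * med))
    return ranges


def generate_cohort(design: CohortDesign) -> pd.DataFrame:
    """Generate one complete cohort table from a design.

    Pipeline order: draw complete data per group, delete values MCAR,
    clamp to detection ranges, then derive the ratio columns.  Bit-identical
    given the same design and seed.
    """
    ss = np.random.SeedSequence(design.seed)
    group_stream, miss_stream = ss.spawn(2)
    group_streams = group_stream.spawn(len(_cohort.GROUPS))

    frames, all_specs = [], []
    for stream, group in zip(group_streams, _cohort.GROUPS):
        n = design.group_sizes.get(group, 0)
        if n == 0:
            continue
        rng = np.random.default_rng(stream)
        df = generate_group(
            design.specs[group], design.demographics[group], n,
            design.correlation, rng, biomarkers=design.biomarkers)
        n_conf = design.confirmed.get(group, 0)
        if n_conf:
            df.iloc[:n_conf, df.columns.get_loc("confirmed")] = 1
        # demographic availability (duration / MMSE) handled as MCAR too
        demo = design.demographics[group]
        for col, n_avail in (("onset_to_lp_months", demo.duration_n),
                             ("mmse", demo.mmse_n)):
            if n_avail is not None and n_avail < n:
                drop = rng.random(n) < 1.0 - n_avail / n
                df.loc[drop, col] = np.nan
        frames.append(df)
        all_specs.extend(design.specs[group].values())

    if not frames:
        return _cohort.compute_ratios(_cohort.empty_cohort())

    table = pd.concat(frames, ignore_index=True)
    table["cohort"] = design.label
    prefix = design.label[:1].upper()
    table["subject_id"] = [f"{prefix}{i:04d}" for i in range(len(table))]
    table = apply_missingness(table, all_specs, miss_stream)
    table = _cohort.clamp_to_range(table, detection_ranges(design))
    return _cohort.compute_ratios(table)


def generate_cohorts(
    design_test: CohortDesign, design_validation: CohortDesign
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the test and validation cohorts from their designs."""
    return generate_cohort(design_test), generate_cohort(design_validation)


def design_from_config(cc: CohortConfig, seed: int | None = None) -> CohortDesign:
    """Build a generation design from a cohort configuration document."""
    specs: dict[str, dict[str, GroupDistributionSpec]] = {}
    for group, n_group in cc.group_sizes.items():
        per = {}
        for b in cc.measured:
            entry = cc.biomarker_specs[group][b]
            n_avail = entry.get("n", n_group)
            frac = cc.availability_fraction.get(b)
            if frac is not None:
                n_avail = int(round(frac * n_group))
            per[b] = GroupDistributionSpec(
                group=group, biomarker=b,
                median=float(entry["median"]), q1=float(entry["q1"]),
                q3=float(entry["q3"]),
                n_available=min(n_avail, n_group), n_group=n_group,
            )
        specs[group] = per
    demographics = {}
    for group, d in cc.demographics.items():
        onset = d.get("onset")
        mmse = d.get("mmse")
        demographics[group] = DemographicSpec(
            group=group,
            age_median=d["age"][0], age_q1=d["age"][1], age_q3=d["age"][2],
            pct_male=d["pct_male"],
            duration_median=onset[0] if onset else None,
            duration_q1=onset[1] if onset else None,
            duration_q3=onset[2] if onset else None,
            duration_n=d.get("onset_n"),
            mmse_median=mmse[0] if mmse else None,
            mmse_q1=mmse[1] if mmse else None,
            mmse_q3=mmse[2] if mmse else None,
            mmse_n=d.get("mmse_n"),
        )
    return CohortDesign(
        label=cc.label,
        group_sizes=dict(cc.group_sizes),
        specs=specs,
        demographics=demographics,
        confirmed=dict(cc.confirmed),
        biomarkers=cc.measured,
        correlation=cc.correlation,
        seed=seed if seed is not None else 0,
        detection_lower_factor=cc.detection_lower_factor,
        detection_upper_factor=cc.detection_upper_factor,
    )
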