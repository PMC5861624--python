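"""ROC, fixed-sensitivity cut-points and exact binomial intervals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csfpanel.roc import (
    auc,
    clopper_pearson,
    cutpoint_at_sensitivity,
    cutpoint_ci,
    estimate_cutpoint,
    is_positive,
    rank_biomarkers,
    roc_curve,
    sensitivity_at_cutpoint,
    specificity_at_cutpoint,
)


def brute_force_auc(cases, controls, direction="higher"):
    """Exhaustive pair-counting oracle with 0.5 tie credit."""
    sign = 1.0 if direction == "higher" else -1.0
    total = 0.0
    for c in cases:
        for k in controls:
            if sign * c > sign * k:
                total += 1.0
            elif c == k:
                total += 0.5
    return total / (len(cases) * len(controls))


def scan_cutpoint(ad_values, direction, target):
    """Exhaustive threshold-scan oracle: among observed AD values whose
    positivity fraction meets the target, pick the most case-side one."""
    v = np.asarray(ad_values, dtype=float)
    best = None
    for t in v:
        if direction == "higher":
            frac = np.mean(v >= t)
            better = best is None or t > best
        else:
            frac = np.mean(v <= t)
            better = best is None or t < best
        if frac >= target and better:
            best = t
    return best


class TestAuc:
    @pytest.mark.parametrize("cases,controls,direction,expected", [
        ([3, 5, 7], [1, 2, 6], "higher", 7 / 9),
        ([1, 2, 3], [1, 2, 3], "higher", 0.5),
        ([2, 2], [2, 1], "higher", 0.75),
        ([3, 5, 7], [1, 2, 6], "lower", 2 / 9),
    ])
    def test_frozen_examples(self, cases, controls, direction, expected):
        assert auc(cases, controls, direction) == pytest.approx(expected)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        cases=st.lists(st.integers(0, 12), min_size=1, max_size=30),
        controls=st.lists(st.integers(0, 12), min_size=1, max_size=30),
        direction=st.sampled_from(["higher", "lower"]),
    )
    def test_matches_brute_force(self, cases, controls, direction):
        assert auc(cases, controls, direction) == pytest.approx(
            brute_force_auc(cases, controls, direction), abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        cases=st.lists(st.floats(0, 100), min_size=1, max_size=20),
        controls=st.lists(st.floats(0, 100), min_size=1, max_size=20),
    )
    def test_complement_symmetry(self, cases, controls):
        """Swapping sides while flipping direction preserves the AUC, and
        swapping without flipping complements it (tie-corrected)."""
        a = auc(cases, controls, "higher")
        assert auc(controls, cases, "lower") == pytest.approx(a, abs=1e-12)
        assert auc(controls, cases, "higher") == pytest.approx(1 - a, abs=1e-12)

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            auc([], [1.0])


class TestRocCurve:
    def test_monotone_sweep(self):
        rng = np.random.default_rng(0)
        curve = roc_curve(rng.normal(1, 1, 40), rng.normal(0, 1, 40))
        assert (np.diff(curve.sensitivity) >= 0).all()
        assert curve.sensitivity[0] == min(curve.sensitivity)
        assert curve.sensitivity[-1] == 1.0


class TestCutpoint:
    @pytest.mark.parametrize("direction,expected", [
        ("higher", 2.0), ("lower", 9.0),
    ])
    def test_decile_example(self, direction, expected):
        assert cutpoint_at_sensitivity(range(1, 11), direction, 0.85) == expected

    def test_target_one_gives_extreme(self):
        assert cutpoint_at_sensitivity(range(1, 11), "higher", 1.0) == 1.0
        assert cutpoint_at_sensitivity(range(1, 11), "lower", 1.0) == 10.0

    @pytest.mark.parametrize("target", [0.0, -0.2, 1.5])
    def test_invalid_target_rejected(self, target):
        with pytest.raises(ValueError):
            cutpoint_at_sensitivity([1.0, 2.0], "higher", target)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        values=st.lists(st.integers(0, 40), min_size=2, max_size=40),
        direction=st.sampled_from(["higher", "lower"]),
        target=st.floats(0.05, 1.0),
    )
    def test_matches_scan_oracle(self, values, direction, target):
        got = cutpoint_at_sensitivity(values, direction, target)
        assert got == scan_cutpoint(values, direction, target)

    def test_comparator_independence(self):
        """The cut-point never sees comparator data: identical for any
        comparator set, as the design requires."""
        ad = np.array([5.0, 7.0, 9.0, 11.0, 13.0, 2.0, 8.0])
        r1 = estimate_cutpoint("x", ad, {"HC": [1.0, 2.0]}, "higher", 0.85)
        r2 = estimate_cutpoint("x", ad, {"HC": [100.0], "DLB": [0.1, 55.0]},
                               "higher", 0.85)
        assert r1.cutpoint == r2.cutpoint
        assert (r1.ci_lower, r1.ci_upper) == (r2.ci_lower, r2.ci_upper)

    def test_specificity_monotone_in_target(self):
        """Raising the sensitivity target can only relax the cut-point, so
        specificity is non-increasing."""
        rng = np.random.default_rng(3)
        ad = rng.normal(2, 1, 60)
        hc = rng.normal(0, 1, 60)
        prev = 1.1
        for target in (0.5, 0.65, 0.8, 0.9, 0.99):
            cut = cutpoint_at_sensitivity(ad, "higher", target)
            spec, *_ = specificity_at_cutpoint(hc, cut, "higher")
            assert spec <= prev + 1e-12
            prev = spec


class TestCutpointCi:
    def test_degenerate_sample(self):
        lo, hi = cutpoint_ci([4.0, 4.0, 4.0], "higher", 0.85)
        assert lo == hi == 4.0

    def test_order_statistic_mapping(self):
        """Endpoints are order statistics of the AD sample bracketing the
        cut-point, matching an exhaustive mapping oracle."""
        v = np.arange(1.0, 21.0)
        cut = cutpoint_at_sensitivity(v, "higher", 0.85)
        lo, hi = cutpoint_ci(v, "higher", 0.85)
        assert lo in v and hi in v
        assert lo <= cut <= hi
        # oracle: map the exact binomial CI for k=17/20 back to thresholds
        p_lo, p_hi = clopper_pearson(17, 20)
        desc = np.sort(v)[::-1]
        assert lo == desc[int(np.ceil(p_hi * 20)) - 1]
        assert hi == desc[max(1, int(np.ceil(p_lo * 20))) - 1]

    def test_nesting(self):
        v = np.arange(1.0, 21.0)
        lo95, hi95 = cutpoint_ci(v, "higher", 0.85, level=0.95)
        lo99, hi99 = cutpoint_ci(v, "higher", 0.85, level=0.99)
        assert lo99 <= lo95 and hi99 >= hi95

    def test_bootstrap_switch(self):
        v = np.arange(1.0, 41.0)
        lo, hi = cutpoint_ci(v, "higher", 0.85, method="bootstrap", seed=0)
        cut = cutpoint_at_sensitivity(v, "higher", 0.85)
        assert lo <= cut <= hi

    @pytest.mark.parametrize("direction", ["higher", "lower"])
    def test_contains_cutpoint_random(self, direction):
        rng = np.random.default_rng(9)
        for _ in range(200):
            v = rng.lognormal(0, 1, rng.integers(2, 60))
            cut = cutpoint_at_sensitivity(v, direction, 0.85)
            lo, hi = cutpoint_ci(v, direction, 0.85)
            assert lo <= cut <= hi


class TestClopperPearson:
    def test_closed_forms(self):
        lo, hi = clopper_pearson(0, 10)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** 0.1, abs=1e-10)
        lo, hi = clopper_pearson(10, 10)
        assert hi == 1.0
        assert lo == pytest.approx(0.025 ** 0.1, abs=1e-10)

    def test_beta_quantile_oracle(self):
        lo, hi = clopper_pearson(9, 10)
        assert lo == pytest.approx(0.5550, abs=1e-4)
        assert hi == pytest.approx(0.9975, abs=1e-4)

    @pytest.mark.parametrize("k,n", [(-1, 10), (11, 10), (0, 0)])
    def test_invalid_counts(self, k, n):
        with pytest.raises(ValueError):
            clopper_pearson(k, n)


class TestSpecificity:
    def test_counting_example(self):
        spec, lo, hi, n = specificity_at_cutpoint([0, 1, 1, 3], 2.0, "higher")
        assert spec == 0.75 and n == 4
        assert lo < 0.75 < hi

    def test_extremes(self):
        spec, *_ = specificity_at_cutpoint([5, 6, 7], 2.0, "higher")
        assert spec == 0.0
        spec, *_ = specificity_at_cutpoint([0, 1], 2.0, "higher")
        assert spec == 1.0

    def test_positivity_includes_equality(self):
        assert is_positive([2.0], 2.0, "higher")[0]
        assert is_positive([2.0], 2.0, "lower")[0]

    def test_sensitivity_counts(self):
        sens, lo, hi, n = sensitivity_at_cutpoint([10, 9, 2], 8.0, "higher")
        assert sens == pytest.approx(2 / 3) and n == 3


class TestRanking:
    def test_sorted_descending(self):
        assert rank_biomarkers({"a": 0.9, "b": 0.8, "c": 0.85}) == ["a", "c", "b"]

    def test_candidate_restriction_and_k(self):
        aucs = {x: 0.9 - i * 0.01 for i, x in enumerate("abcdefg")}
        assert rank_biomarkers(aucs, candidates=["b", "e", "g"], k=5) == \
            ["b", "e", "g"]
        assert len(rank_biomarkers(aucs, k=5)) == 5

    def test_tie_broken_by_name(self):
        assert rank_biomarkers({"z": 0.7, "m": 0.7}) == ["m", "z"]

    def test_empty_candidates(self):
        assert rank_biomarkers({"a": 0.9}, candidates=[]) == []
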