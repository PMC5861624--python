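"""Synthetic cohort generator: quantile matching, determinism, MCAR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from csfpanel import (
    DemographicSpec,
    GroupDistributionSpec,
    apply_missingness,
    design_from_config,
    generate_cohort,
    generate_cohorts,
    generate_group,
    lognormal_params_from_quartiles,
)
from csfpanel.roc import auc
from csfpanel.synthetic import Z75


class TestQuantileMatching:
    @pytest.mark.parametrize("median,q1,q3,mu,sigma", [
        (1.0, np.exp(-0.67449), np.exp(0.67449), 0.0, 1.0),
        (0.043, 0.036, 0.053, -3.1466, 0.2867),   # AD amyloid ratio summary
        (2.3, 1.2, 3.7, 0.8329, 0.8346),          # AD tau/amyloid summary
    ])
    def test_matches_frozen_values(self, median, q1, q3, mu, sigma):
        got_mu, got_sigma = lognormal_params_from_quartiles(median, q1, q3)
        assert got_mu == pytest.approx(mu, abs=2e-4)
        assert got_sigma == pytest.approx(sigma, abs=2e-4)

    @pytest.mark.parametrize("median,q1,q3", [
        (1.0, -0.5, 2.0), (1.0, 1.5, 2.0), (1.0, 0.5, 0.9), (0.0, 0.0, 0.0),
    ])
    def test_rejects_invalid_quartiles(self, median, q1, q3):
        with pytest.raises(ValueError):
            lognormal_params_from_quartiles(median, q1, q3)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(median=st.floats(1e-3, 1e4), r1=st.floats(0.05, 0.95),
           r3=st.floats(1.05, 20.0))
    def test_implied_distribution_recovers_quartiles(self, median, r1, r3):
        """Analytic check, no sampling: the implied log-normal reproduces the
        requested median and interquartile ratio exactly (a two-parameter
        family cannot also pin both quartiles unless they are geometrically
        symmetric about the median; that case is checked below)."""
        q1, q3 = median * r1, median * r3
        mu, sigma = lognormal_params_from_quartiles(median, q1, q3)
        dist = stats.lognorm(s=sigma, scale=np.exp(mu))
        assert dist.ppf(0.5) == pytest.approx(median, rel=1e-9)
        assert dist.ppf(0.75) / dist.ppf(0.25) == pytest.approx(q3 / q1, rel=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(median=st.floats(1e-3, 1e4), ratio=st.floats(1.05, 20.0))
    def test_symmetric_quartiles_recovered_exactly(self, median, ratio):
        """With log-symmetric quartiles all three percentiles are recovered
        to better than 6 significant figures."""
        q1, q3 = median / np.sqrt(ratio), median * np.sqrt(ratio)
        mu, sigma = lognormal_params_from_quartiles(median, q1, q3)
        dist = stats.lognorm(s=sigma, scale=np.exp(mu))
        for target, p in [(q1, 0.25), (median, 0.5), (q3, 0.75)]:
            assert dist.ppf(p) == pytest.approx(target, rel=1e-7)

    def test_z75_is_standard_normal_upper_quartile(self):
        assert Z75 == pytest.approx(0.67449, abs=1e-5)


def _spec(group="AD", biomarker="abeta_1_42", median=310.5, q1=218.0,
          q3=451.5, n_available=None, n_group=100):
    return GroupDistributionSpec(group, biomarker, median, q1, q3,
                                 n_available if n_available is not None else n_group,
                                 n_group)


def _demo(group="AD"):
    return DemographicSpec(group, 62.5, 57.0, 68.0, 42.3,
                           duration_median=36, duration_q1=24, duration_q3=60)


class TestGenerateGroup:
    def test_empty_group(self):
        df = generate_group({"abeta_1_42": _spec()}, _demo(), 0,
                            np.eye(1), np.random.default_rng(0))
        assert len(df) == 0

    def test_large_sample_quantile_recovery(self):
        df = generate_group({"abeta_1_42": _spec()}, _demo(), 100_000,
                            np.eye(1), np.random.default_rng(5))
        v = df["abeta_1_42"].to_numpy()
        assert np.median(v) == pytest.approx(310.5, rel=0.01)
        assert np.quantile(v, 0.25) == pytest.approx(218.0, rel=0.02)
        assert np.quantile(v, 0.75) == pytest.approx(451.5, rel=0.02)

    def test_correlation_recovery(self):
        specs = {"abeta_1_42": _spec(), "t_tau": _spec(biomarker="t_tau")}
        corr = np.array([[1.0, 0.8], [0.8, 1.0]])
        df = generate_group(specs, _demo(), 100_000, corr,
                            np.random.default_rng(7))
        r = np.corrcoef(np.log(df["abeta_1_42"]), np.log(df["t_tau"]))[0, 1]
        assert r == pytest.approx(0.8, abs=0.02)

    def test_missing_spec_rejected(self):
        with pytest.raises(ValueError, match="no distribution spec"):
            generate_group({}, _demo(), 5, np.eye(1), np.random.default_rng(0),
                           biomarkers=("abeta_1_42",))

    def test_non_psd_correlation_rejected(self):
        specs = {"abeta_1_42": _spec(), "t_tau": _spec(biomarker="t_tau")}
        bad = np.array([[1.0, 1.5], [1.5, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            generate_group(specs, _demo(), 5, bad, np.random.default_rng(0))

    def test_age_truncated_at_18(self):
        demo = DemographicSpec("AD", 25.0, 15.0, 35.0, 50.0)
        df = generate_group({"abeta_1_42": _spec()}, demo, 5000, np.eye(1),
                            np.random.default_rng(0))
        assert df["age_at_lp"].min() >= 18.0


class TestMissingness:
    def test_full_availability_removes_nothing(self, toy_cohort):
        spec = _spec(n_available=12, n_group=12)
        out = apply_missingness(toy_cohort, [spec], seed=0)
        assert out["abeta_1_42"].notna().all()

    def test_zero_availability_removes_all(self, toy_cohort):
        spec0 = GroupDistributionSpec("AD", "abeta_1_42", 310.5, 218.0, 451.5, 0, 12)
        out = apply_missingness(toy_cohort, [spec0], seed=0)
        assert out.loc[out["group"] == "AD", "abeta_1_42"].isna().all()
        assert out.loc[out["group"] == "HC", "abeta_1_42"].notna().all()

    def test_invalid_availability_rejected(self):
        with pytest.raises(ValueError, match="n_available"):
            GroupDistributionSpec("AD", "nfl", 1191.5, 857.6, 1584.0, 200, 156)

    def test_binomial_missing_count(self, toy_cohort):
        """AD NFL availability 119/156 deletes ~37/156 values; the pooled
        count over many seeds must sit inside the 99% binomial band."""
        spec = GroupDistributionSpec("AD", "abeta_1_42", 310.5, 218.0, 451.5,
                                     119, 156)
        table = toy_cohort.copy()
        p_miss = 1 - 119 / 156
        n_ad = int((table["group"] == "AD").sum())
        n_seeds = 400
        total = sum(
            int(apply_missingness(table, [spec], seed=s)
                .loc[table["group"] == "AD", "abeta_1_42"].isna().sum())
            for s in range(n_seeds)
        )
        n_trials = n_seeds * n_ad
        lo, hi = stats.binom.ppf([0.005, 0.995], n_trials, p_miss)
        assert lo <= total <= hi

    def test_mcar_slope_centred_on_zero(self):
        """Missingness indicator regressed on the pre-deletion value has
        slope centred on 0 over 2000 simulated groups (vectorised)."""
        rng = np.random.default_rng(11)
        n_sims, n = 2000, 40
        x = rng.lognormal(0.0, 0.5, size=(n_sims, n))
        miss = rng.random((n_sims, n)) < 0.3
        xc = x - x.mean(axis=1, keepdims=True)
        mc = miss - miss.mean(axis=1, keepdims=True)
        slopes = (xc * mc).sum(axis=1) / (xc ** 2).sum(axis=1)
        se = slopes.std(ddof=1) / np.sqrt(n_sims)
        assert abs(slopes.mean()) < 4 * se + 1e-12


class TestCohortAssembly:
    def test_default_sizes(self, pipeline_config, default_cohorts):
        test, val = default_cohorts
        assert len(test) == 275
        assert len(val) == 143
        assert int((test["group"] != "HC").sum()) == 245
        assert int(val["group"].isin(["DLB", "bvFTD", "PNFA", "SD"]).sum()) == 29
        assert int(test["confirmed"].sum()) == 26

    def test_validation_panel_restricted(self, validation_cohort):
        assert validation_cohort["nfl"].isna().all()
        assert validation_cohort["ykl_40"].isna().all()
        assert validation_cohort["abeta_1_42"].notna().all()
        assert validation_cohort["abx42_abx40"].notna().sum() > 100

    def test_seed_determinism(self, pipeline_config):
        d = design_from_config(pipeline_config.test, seed=77)
        a = generate_cohort(d)
        b = generate_cohort(d)
        assert a.equals(b)
        c = generate_cohort(design_from_config(pipeline_config.test, seed=78))
        assert not a.equals(c)

    def test_all_sizes_zero(self, pipeline_config):
        d = design_from_config(pipeline_config.test, seed=1)
        d.group_sizes = {g: 0 for g in d.group_sizes}
        d2 = design_from_config(pipeline_config.validation, seed=2)
        d2.group_sizes = {g: 0 for g in d2.group_sizes}
        t, v = generate_cohorts(d, d2)
        assert len(t) == 0 and len(v) == 0

    def test_closed_form_auc_limit(self):
        """Empirical AUC between two generated log-normal groups approaches
        Phi(|mu1-mu2| / sqrt(s1^2+s2^2))."""
        rng = np.random.default_rng(13)
        mu1, s1 = np.log(310.5), 0.5
        mu2, s2 = np.log(953.0), 0.3
        a = rng.lognormal(mu1, s1, 50_000)
        b = rng.lognormal(mu2, s2, 50_000)
        expected = stats.norm.cdf(abs(mu1 - mu2) / np.hypot(s1, s2))
        assert auc(a, b, "lower") == pytest.approx(expected, abs=0.01)
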