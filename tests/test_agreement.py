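"""Bland-Altman statistics: oracles, printed-value consistency, properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nodulevar import (
    Cohort,
    DegenerateDesignError,
    InsufficientDataError,
    MeasurementPair,
    ValidationError,
    bland_altman,
    interobserver_agreement,
    interscan_agreement,
    paired_differences,
    proportional_bias_test,
    results_table,
    round_display,
    subgroup_agreement,
)


def scaled_to_moments(n, mean, sd, seed=0):
    """Sample of size n with exactly the requested sample mean and SD (ddof=1)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestPairedDifferences:
    def test_identical_scans(self, make_pair):
        d = paired_differences(make_pair(100.0, 100.0))
        assert d.abs_diff == 0.0 and d.rel_diff == 0.0 and d.v_mean == 100.0

    def test_hand_arithmetic(self, make_pair):
        d = paired_differences(make_pair(90.0, 110.0))
        assert d.abs_diff == -20.0
        assert d.v_mean == 100.0
        assert d.rel_diff == -20.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        v1=st.floats(min_value=1.0, max_value=1e4),
        v2=st.floats(min_value=1.0, max_value=1e4),
    )
    def test_antisymmetry_and_consistency(self, v1, v2):
        """Swapping the scans flips the sign; rel * mean / 100 == abs."""
        a = paired_differences(MeasurementPair("N", "P", v1, v2))
        b = paired_differences(MeasurementPair("N", "P", v2, v1))
        assert a.abs_diff == -b.abs_diff
        assert a.rel_diff == pytest.approx(-b.rel_diff, rel=1e-12, abs=1e-12)
        assert a.rel_diff * a.v_mean / 100.0 == pytest.approx(a.abs_diff, rel=1e-12, abs=1e-9)


class TestBlandAltman:
    @pytest.mark.parametrize(
        "diffs",
        [
            [1.0, 2.0],
            [-3.0, 0.0, 5.5],
            [2.0, 2.0, 7.0, -1.0],
            [0.1, 0.2, 0.3, 0.4, 0.5, 10.0],
        ],
    )
    def test_matches_hand_computation(self, diffs):
        """Direct sums (independent of numpy reductions in the implementation)."""
        n = len(diffs)
        mean = sum(diffs) / n
        sd = math.sqrt(sum((d - mean) ** 2 for d in diffs) / (n - 1))
        r = bland_altman(diffs)
        assert r.mean_diff == pytest.approx(mean, rel=1e-12)
        assert r.sd_diff == pytest.approx(sd, rel=1e-12)
        assert r.loa_lower == pytest.approx(mean - 1.96 * sd, rel=1e-12)
        assert r.loa_upper == pytest.approx(mean + 1.96 * sd, rel=1e-12)
        assert r.diff_min == min(diffs) and r.diff_max == max(diffs)

    def test_zero_variance(self):
        r = bland_altman([5.0, 5.0, 5.0, 5.0])
        assert (r.mean_diff, r.sd_diff) == (5.0, 0.0)
        assert (r.loa_lower, r.loa_upper) == (5.0, 5.0)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            bland_altman([1.0])

    def test_reproduces_printed_relative_limits(self):
        """Differences with the published moments (mean -0.90%, SD 7.908%)
        give 95% limits of agreement of -16.4% and 14.6% at 1 dp."""
        diffs = scaled_to_moments(100, -0.90, (14.6 + 16.4) / 2 / 1.96)
        r = bland_altman(diffs)
        assert round_display(r.loa_lower) == -16.4
        assert round_display(r.loa_upper) == 14.6

    def test_reproduces_printed_t_interval(self):
        """Absolute differences with mean -1.09 mm^3 and the SD implied by
        the printed limits (-14.2, 12.0) give the printed t-based 95% CI of
        the mean, (-2.42, 0.24) mm^3; a z-interval would give (-2.40, 0.22)."""
        sd = (12.0 + 14.2) / 2 / 1.96
        diffs = scaled_to_moments(100, -1.09, sd)
        r = bland_altman(diffs)
        assert round_display(r.ci_mean_lower, 2) == -2.42
        assert round_display(r.ci_mean_upper, 2) == 0.24

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        diffs=st.lists(
            st.floats(min_value=-1e3, max_value=1e3), min_size=2, max_size=40
        )
    )
    def test_limits_symmetric_about_mean(self, diffs):
        r = bland_altman(diffs)
        assert r.loa_lower + r.loa_upper == pytest.approx(2 * r.mean_diff, rel=1e-9, abs=1e-9)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        diffs=st.lists(
            st.floats(min_value=-1e3, max_value=1e3), min_size=4, max_size=60
        )
    )
    def test_ci_nested_within_limits(self, diffs):
        """For n >= 4 the t-interval of the mean sits inside the limits of
        agreement (t_crit/sqrt(n) < 1.96 from n=4 up)."""
        r = bland_altman(diffs)
        eps = 1e-9 * (1 + abs(r.mean_diff) + r.sd_diff)
        assert r.loa_lower - eps <= r.ci_mean_lower <= r.mean_diff + eps
        assert r.mean_diff - eps <= r.ci_mean_upper <= r.loa_upper + eps


class TestScaleEquivariance:
    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        c=st.floats(min_value=0.01, max_value=100.0),
        volumes=st.lists(
            st.tuples(
                st.floats(min_value=5.0, max_value=200.0),
                st.floats(min_value=5.0, max_value=200.0),
            ),
            min_size=2,
            max_size=12,
        ),
    )
    def test_rescaling_volumes(self, c, volumes):
        """Multiplying all volumes by c leaves relative statistics unchanged
        and scales absolute statistics by c."""
        base = Cohort([MeasurementPair(f"N{i}", "P", v1, v2) for i, (v1, v2) in enumerate(volumes)])
        scaled = Cohort(
            [MeasurementPair(f"N{i}", "P", c * v1, c * v2) for i, (v1, v2) in enumerate(volumes)]
        )
        abs0, rel0 = interscan_agreement(base)
        abs1, rel1 = interscan_agreement(scaled)
        for attr in ("mean_diff", "sd_diff", "loa_lower", "loa_upper"):
            assert getattr(rel1, attr) == pytest.approx(getattr(rel0, attr), rel=1e-9, abs=1e-9)
            assert getattr(abs1, attr) == pytest.approx(c * getattr(abs0, attr), rel=1e-9, abs=1e-9)


class TestSubgroup:
    def test_stratum_sizes(self, make_pair):
        pairs = [make_pair(40.0 + 0.1 * i, 40.0 + 0.1 * i) for i in range(58)]
        pairs += [make_pair(90.0 + 0.1 * i, 90.0 + 0.1 * i) for i in range(42)]
        low, high = subgroup_agreement(Cohort(pairs), cut=80.0)
        assert (low.n, high.n) == (58, 42)

    def test_identical_scans_give_zero_limits(self, make_pair):
        pairs = [make_pair(50.0, 50.0), make_pair(60.0, 60.0),
                 make_pair(90.0, 90.0), make_pair(120.0, 120.0)]
        low, high = subgroup_agreement(Cohort(pairs))
        assert (low.loa_lower, low.loa_upper) == (0.0, 0.0)
        assert (high.loa_lower, high.loa_upper) == (0.0, 0.0)

    def test_empty_stratum_named(self, make_pair):
        cohort = Cohort([make_pair(40.0, 41.0), make_pair(50.0, 51.0)])
        with pytest.raises(InsufficientDataError, match=">= 500"):
            subgroup_agreement(cohort, cut=500.0)

    def test_strata_disjoint_exhaustive(self, study_cohort):
        low, high = subgroup_agreement(study_cohort)
        assert low.n + high.n == len(study_cohort)


class TestProportionalBias:
    def test_constant_magnitudes_flat(self):
        slope, p = proportional_bias_test([5.0, -5.0, 5.0, -5.0], [30.0, 60.0, 90.0, 120.0])
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_recovers_planted_slope(self):
        """Simulate |rel_diff| = 0.1 * v_mean + noise and refit."""
        rng = np.random.default_rng(42)
        v = rng.uniform(30, 150, size=200)
        y = 0.1 * v + rng.normal(0, 0.05, size=200)
        slope, p = proportional_bias_test(y, v)
        se = 0.05 / np.sqrt(np.sum((v - v.mean()) ** 2))
        assert abs(slope - 0.1) < 3 * se
        assert p < 1e-6

    def test_degenerate_design(self):
        with pytest.raises(DegenerateDesignError):
            proportional_bias_test([1.0, 2.0, 3.0], [80.0, 80.0, 80.0])

    def test_length_mismatch_and_small_n(self):
        with pytest.raises(ValueError):
            proportional_bias_test([1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(InsufficientDataError):
            proportional_bias_test([1.0, 2.0], [30.0, 40.0])


class TestInterobserver:
    def test_perfect_agreement(self, make_pair):
        pairs = [make_pair(50.0, 51.0, v1_obs2=50.0), make_pair(80.0, 79.0, v1_obs2=80.0)]
        abs_r, rel_r = interobserver_agreement(Cohort(pairs))
        assert abs_r.mean_diff == 0.0 and (abs_r.loa_lower, abs_r.loa_upper) == (0.0, 0.0)
        assert rel_r.mean_diff == 0.0

    def test_mostly_identical_cohort(self, make_pair):
        """95 identical re-measurements + 5 differing ones: n stays 100 and
        the few discordant pairs drive a nonzero SD."""
        pairs = [make_pair(50.0 + i * 0.5, 50.0 + i * 0.5, v1_obs2=50.0 + i * 0.5)
                 for i in range(95)]
        pairs += [make_pair(100.0 + i, 100.0 + i, v1_obs2=98.0 + i) for i in range(5)]
        abs_r, _ = interobserver_agreement(Cohort(pairs))
        assert abs_r.n == 100
        assert abs_r.sd_diff > 0

    def test_missing_second_observer_lists_ids(self, make_pair):
        pairs = [make_pair(50.0, 51.0, v1_obs2=50.0, nodule_id="A"),
                 make_pair(60.0, 61.0, nodule_id="B")]
        with pytest.raises(ValidationError, match="B"):
            interobserver_agreement(Cohort(pairs))


class TestResultsTable:
    def test_six_rows_with_second_observer(self, study_cohort):
        table = results_table(study_cohort)
        assert list(table["analysis"]) == [
            "interscan-absolute",
            "interscan-relative",
            "subgroup-low",
            "subgroup-high",
            "interobserver-absolute",
            "interobserver-relative",
        ]

    def test_four_rows_without_second_observer(self, make_pair):
        pairs = [make_pair(40.0, 41.0), make_pair(50.0, 52.0),
                 make_pair(90.0, 88.0), make_pair(120.0, 119.0)]
        table = results_table(Cohort(pairs))
        assert len(table) == 4
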