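"""Bland-Altman agreement statistics for paired volumetry measurements.

Two same-day scans of the same nodule should report the same volume; they do
not, and the spread of their differences is the interscan variability that a
growth threshold must exceed before a volume increase can be called real.
The Bland-Altman method summarises that spread: with paired differences
d_i = V1_i - V2_i (or their relative form, d as a percent of the pair mean
(V1+V2)/2), it reports the mean difference (bias), the sample SD, and the
95% limits of agreement mean +/- 1.96 SD, expected to contain ~95% of
differences.  The confidence interval of the mean difference uses the t
distribution with n-1 degrees of freedom.

Differences are signed scan 1 minus scan 2 (observer 1 minus observer 2 for
the interobserver analysis); reports may display the magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import Cohort, MeasurementPair
from .errors import DegenerateDesignError, InsufficientDataError, ValidationError

__all__ = [
    "PairedDifference",
    "AgreementResult",
    "paired_differences",
    "bland_altman",
    "interscan_agreement",
    "subgroup_agreement",
    "proportional_bias_test",
    "interobserver_agreement",
    "results_table",
    "plot_data",
]


@dataclass(frozen=True)
class PairedDifference:
    """One nodule's paired difference in absolute and relative form.

    ``abs_diff`` is V1 - V2 in mm^3; ``v_mean`` is (V1 + V2)/2, the best
    available proxy for the unknown true volume; ``rel_diff`` is the
    difference as a percent of ``v_mean``.
    """

    abs_diff: float
    rel_diff: float
    v_mean: float


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman summary for one set of paired differences.

    ``loa_lower``/``loa_upper`` are mean_diff -/+ z * sd_diff; the CI bounds
    are the two-sided 95% t-interval for the mean difference.  Units follow
    the input differences (mm^3 or %).
    """

    n: int
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    ci_mean_lower: float
    ci_mean_upper: float
    diff_min: float
    diff_max: float

    @property
    def loa_halfwidth(self) -> float:
        return (self.loa_upper - self.loa_lower) / 2.0


def paired_differences(pair: MeasurementPair) -> PairedDifference:
    """Compute the signed absolute and relative difference for one pair."""
    if pair.v1 <= 0 or pair.v2 <= 0:
        raise ValidationError(f"volumes must be positive, got v1={pair.v1}, v2={pair.v2}")
    abs_diff = pair.v1 - pair.v2
    v_mean = (pair.v1 + pair.v2) / 2.0
    return PairedDifference(abs_diff=abs_diff, rel_diff=abs_diff / v_mean * 100.0, v_mean=v_mean)


def bland_altman(diffs: Sequence[float], z: float = 1.96, ci_level: float = 0.95) -> AgreementResult:
    """Bland-Altman summary of a sample of paired differences.

    Parameters
    ----------
    diffs
        The paired differences, in mm^3 or %.
    z
        Coverage multiplier for the limits of agreement (1.96 for 95%).
    ci_level
        Two-sided coverage of the t-based CI of the mean difference.
    """
    d = np.asarray(diffs, dtype=float)
    n = d.size
    if n < 2:
        raise InsufficientDataError(f"need at least 2 differences, got {n}")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    sem = sd / np.sqrt(n)
    tcrit = float(stats.t.ppf(0.5 + ci_level / 2.0, n - 1))
    return AgreementResult(
        n=n,
        mean_diff=mean,
        sd_diff=sd,
        loa_lower=mean - z * sd,
        loa_upper=mean + z * sd,
        ci_mean_lower=mean - tcrit * sem,
        ci_mean_upper=mean + tcrit * sem,
        diff_min=float(d.min()),
        diff_max=float(d.max()),
    )


def interscan_agreement(cohort: Cohort) -> tuple[AgreementResult, AgreementResult]:
    """Scan 1 vs scan 2 agreement, as (absolute mm^3, relative %) results."""
    pds = [paired_differences(p) for p in cohort.pairs]
    if len(pds) < 2:
        raise InsufficientDataError(f"need at least 2 pairs, got {len(pds)}")
    return (
        bland_altman([pd_.abs_diff for pd_ in pds]),
        bland_altman([pd_.rel_diff for pd_ in pds]),
    )


def subgroup_agreement(cohort: Cohort, cut: float = 80.0) -> tuple[AgreementResult, AgreementResult]:
    """Size-stratified agreement of relative differences.

    Pairs are split on the pair-mean volume V_mean (the Bland-Altman x-axis):
    the low stratum is V_mean < ``cut``, the high stratum V_mean >= ``cut``.
    Strata are disjoint and exhaustive.  Returns (low, high) results.
    """
    pds = [paired_differences(p) for p in cohort.pairs]
    low = [pd_.rel_diff for pd_ in pds if pd_.v_mean < cut]
    high = [pd_.rel_diff for pd_ in pds if pd_.v_mean >= cut]
    if len(low) < 2:
        raise InsufficientDataError(
            f"stratum V_mean < {cut} mm^3 has {len(low)} pair(s); need at least 2"
        )
    if len(high) < 2:
        raise InsufficientDataError(
            f"stratum V_mean >= {cut} mm^3 has {len(high)} pair(s); need at least 2"
        )
    return bland_altman(low), bland_altman(high)


def proportional_bias_test(
    rel_diffs: Sequence[float], v_means: Sequence[float]
) -> tuple[float, float]:
    """Test whether relative measurement variability depends on nodule size.

    The relative differences are converted to magnitudes (signs removed) and
    regressed by OLS against the pair-mean volume.  Returns the slope
    (% per mm^3) and its two-sided p-value; a non-significant slope supports
    a size-independent multiplicative error model.
    """
    y = np.abs(np.asarray(rel_diffs, dtype=float))
    x = np.asarray(v_means, dtype=float)
    if y.size != x.size:
        raise ValueError(f"length mismatch: {y.size} differences vs {x.size} volumes")
    if y.size < 3:
        raise InsufficientDataError(f"need at least 3 observations, got {y.size}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all mean volumes identical; slope is unidentifiable")
    if np.ptp(y) == 0:
        # constant response: exactly flat, no evidence of proportional bias
        return 0.0, 1.0
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(fit.params[1])
    p = float(fit.pvalues[1])
    if not np.isfinite(p):
        # zero residual variance: an exact fit is certain (p=0) unless flat
        p = 1.0 if slope == 0.0 else 0.0
    return slope, p


def interobserver_agreement(cohort: Cohort) -> tuple[AgreementResult, AgreementResult]:
    """Observer 1 vs observer 2 agreement on scan 1.

    Differences are observer 1 minus observer 2, relative to the two
    observers' mean.  Returns (absolute mm^3, relative %) results.  Every
    retained pair must carry a second-observer measurement.
    """
    missing = [p.nodule_id for p in cohort.pairs if p.v1_obs2 is None]
    if missing:
        raise ValidationError(
            f"second-observer measurement missing for nodule(s): {', '.join(missing)}"
        )
    if len(cohort.pairs) < 2:
        raise InsufficientDataError(f"need at least 2 pairs, got {len(cohort.pairs)}")
    abs_diffs = [p.v1 - p.v1_obs2 for p in cohort.pairs]
    rel_diffs = [
        (p.v1 - p.v1_obs2) / ((p.v1 + p.v1_obs2) / 2.0) * 100.0 for p in cohort.pairs
    ]
    return bland_altman(abs_diffs), bland_altman(rel_diffs)


_TABLE_COLUMNS = [
    "analysis",
    "n",
    "mean",
    "sd",
    "loa_lower",
    "loa_upper",
    "ci_lower",
    "ci_upper",
    "min",
    "max",
]


def _row(name: str, r: AgreementResult) -> dict:
    return {
        "analysis": name,
        "n": r.n,
        "mean": r.mean_diff,
        "sd": r.sd_diff,
        "loa_lower": r.loa_lower,
        "loa_upper": r.loa_upper,
        "ci_lower": r.ci_mean_lower,
        "ci_upper": r.ci_mean_upper,
        "min": r.diff_min,
        "max": r.diff_max,
    }


def results_table(cohort: Cohort, cut: float = 80.0) -> pd.DataFrame:
    """Tidy one-row-per-analysis summary table.

    Rows: interscan-absolute, interscan-relative, subgroup-low, subgroup-high
    and, when a second observer is present on all pairs, interobserver
    absolute and relative rows.  Values are full precision.
    """
    abs_r, rel_r = interscan_agreement(cohort)
    low_r, high_r = subgroup_agreement(cohort, cut=cut)
    rows = [
        _row("interscan-absolute", abs_r),
        _row("interscan-relative", rel_r),
        _row("subgroup-low", low_r),
        _row("subgroup-high", high_r),
    ]
    if cohort.has_second_observer():
        obs_abs, obs_rel = interobserver_agreement(cohort)
        rows.append(_row("interobserver-absolute", obs_abs))
        rows.append(_row("interobserver-relative", obs_rel))
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def plot_data(cohort: Cohort) -> pd.DataFrame:
    """Per-nodule Bland-Altman plot data with mean and limit lines.

    Columns: v_mean, abs_diff, rel_diff plus the constant interscan mean and
    limit levels for both scales, ready for plotting difference against mean.
    """
    pds = [paired_differences(p) for p in cohort.pairs]
    abs_r, rel_r = interscan_agreement(cohort)
    return pd.DataFrame(
        {
            "nodule_id": [p.nodule_id for p in cohort.pairs],
            "v_mean": [d.v_mean for d in pds],
            "abs_diff": [d.abs_diff for d in pds],
            "rel_diff": [d.rel_diff for d in pds],
            "abs_mean_line": abs_r.mean_diff,
            "abs_loa_lower": abs_r.loa_lower,
            "abs_loa_upper": abs_r.loa_upper,
            "rel_mean_line": rel_r.mean_diff,
            "rel_loa_lower": rel_r.loa_lower,
            "rel_loa_upper": rel_r.loa_upper,
        }
    )
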