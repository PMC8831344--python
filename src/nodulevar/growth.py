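"""Exponential nodule growth, volume doubling time, and management modelling.

A solid nodule growing at a constant fractional rate g per surveillance
interval follows V(k) = V0 * (1+g)^k after k whole intervals.  The same
growth expressed as a volume doubling time (VDT) over an interval of t days
is VDT = t * ln 2 / ln(1+g).  Surveillance protocols only observe the nodule
at scheduled visits, so the time at which an intervention threshold
(conventionally 200 mm^3) is deemed crossed is quantised to the visit grid;
the management question modelled here is how long investigation is delayed
when growth below the conventional 25% interscan threshold — but above the
measurement-variability floor of ~15% — is presumed to be stable until a
later routine review.

Volumes in mm^3, intervals in days, schedule times in months.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Sequence

from .display import round_display
from .errors import ThresholdNeverReachedError, ValidationError

__all__ = [
    "GrowthScenario",
    "ManagementRow",
    "GrowthCall",
    "vdt_from_fractional_growth",
    "fractional_growth_from_vdt",
    "project_volume",
    "time_to_threshold",
    "management_delay",
    "build_management_table",
    "classify_growth",
]

#: Days per 3-month surveillance interval used to express growth as a VDT.
DEFAULT_INTERVAL_DAYS = 92.0
#: Volume at which investigation of a growing nodule is warranted (mm^3).
DEFAULT_INTERVENTION_THRESHOLD = 200.0


@dataclass(frozen=True)
class GrowthScenario:
    """One nodule's growth trajectory and the surveillance schedule around it.

    Parameters
    ----------
    v0
        Baseline volume, mm^3.
    g
        Fractional growth per interval (0.15 means +15% per interval).
    interval_days
        Days per growth interval; used only for VDT conversion.
    visit_interval_months
        Months between scheduled surveillance scans; threshold crossings are
        detected only at these visits.
    intervention_threshold
        Volume (mm^3) triggering further investigation of a growing nodule.
    current_review_month
        Month of the routine review under current management, against which
        delays are measured.
    volume_resolution_mm3
        Reporting resolution of the volumetry software; projected volumes are
        rounded to this resolution before comparison with the threshold
        (1 mm^3 by default, so a projected 199.9 mm^3 reads as 200).
    """

    v0: float
    g: float
    interval_days: float = DEFAULT_INTERVAL_DAYS
    visit_interval_months: int = 3
    intervention_threshold: float = DEFAULT_INTERVENTION_THRESHOLD
    current_review_month: int = 12
    volume_resolution_mm3: float = 1.0

    def __post_init__(self) -> None:
        if self.v0 <= 0:
            raise ValidationError(f"v0 must be positive, got {self.v0}")
        if self.g <= -1:
            raise ValidationError(f"g must exceed -1, got {self.g}")
        if self.interval_days <= 0:
            raise ValidationError(f"interval_days must be positive, got {self.interval_days}")
        if self.intervention_threshold <= 0:
            raise ValidationError(
                f"intervention_threshold must be positive, got {self.intervention_threshold}"
            )
        if self.volume_resolution_mm3 <= 0:
            raise ValidationError(
                f"volume_resolution_mm3 must be positive, got {self.volume_resolution_mm3}"
            )


@dataclass(frozen=True)
class ManagementRow:
    """One baseline volume's row of the management model table."""

    v0: float
    v_3m_low: float
    v_3m_high: float
    v_12m_low: float
    v_12m_high: float
    intervene_month_earliest: int
    intervene_month_latest: int
    delay_months: int
    implication: str


def vdt_from_fractional_growth(g: float, interval_days: float = DEFAULT_INTERVAL_DAYS) -> float:
    """Volume doubling time (days) of growth g per ``interval_days``-day interval.

    VDT = interval_days * ln 2 / ln(1+g).  Growth of 15%/24% per 92-day
    quarter corresponds to VDTs of 456/296 days (rounded).
    """
    if g <= 0:
        raise ValidationError(f"doubling time undefined for non-growth (g={g})")
    return interval_days * math.log(2.0) / math.log1p(g)


def fractional_growth_from_vdt(vdt: float, interval_days: float = DEFAULT_INTERVAL_DAYS) -> float:
    """Fractional growth per interval implied by a VDT in days; inverse of
    :func:`vdt_from_fractional_growth`."""
    if vdt <= 0:
        raise ValidationError(f"vdt must be positive, got {vdt}")
    return 2.0 ** (interval_days / vdt) - 1.0


def project_volume(v0: float, g: float, k: int) -> float:
    """Volume after k whole intervals of compounding: v0 * (1+g)^k.

    Compounding is discrete per interval (growth is only assessed at
    scans), not continuous between visits.
    """
    if v0 <= 0:
        raise ValidationError(f"v0 must be positive, got {v0}")
    if g <= -1:
        raise ValidationError(f"g must exceed -1, got {g}")
    if not isinstance(k, (int,)) or k < 0:
        raise ValueError(f"k must be a non-negative integer, got {k!r}")
    return v0 * (1.0 + g) ** k


def _reported(v: float, resolution: float) -> float:
    return round(v / resolution) * resolution


def time_to_threshold(scenario: GrowthScenario) -> int:
    """Earliest scheduled month at which the intervention threshold is met.

    Returns ``visit_interval_months * k*`` where k* is the smallest whole
    number of intervals for which the projected volume, rounded to the
    volumetry reporting resolution, reaches the threshold; 0 when the
    baseline already qualifies.  Detection happens only at scheduled visits.
    """
    thr = scenario.intervention_threshold
    res = scenario.volume_resolution_mm3
    if _reported(scenario.v0, res) >= thr:
        return 0
    if scenario.g <= 0:
        raise ThresholdNeverReachedError(
            f"v0={scenario.v0} below threshold {thr} and g={scenario.g} <= 0: never reached"
        )
    k = 0
    v = scenario.v0
    while _reported(v, res) < thr:
        k += 1
        v = project_volume(scenario.v0, scenario.g, k)
    return scenario.visit_interval_months * k


def management_delay(scenario: GrowthScenario) -> int:
    """Months by which waiting for the routine review delays intervention.

    max(0, current_review_month - time_to_threshold): a nodule whose growth
    is presumed stability until the scheduled review crosses the threshold
    earlier than it is acted upon.  Evaluated at the scenario's own growth
    rate; for a growth band, use the fast rate (the worst case).
    """
    return max(0, scenario.current_review_month - time_to_threshold(scenario))


def build_management_table(
    baselines: Sequence[float] = (30.0, 50.0, 80.0, 115.0, 130.0, 150.0),
    g_low: float = 0.15,
    g_high: float = 0.24,
    scenario: GrowthScenario | None = None,
) -> list[ManagementRow]:
    """Management model over a band of growth rates [g_low, g_high].

    For each baseline volume: the 3-month projected range, the 12-month
    range under consistent quarterly compounding, the window of scheduled
    months in which intervention is first warranted (fast growth gives the
    early bound, slow growth the late bound), and the delay incurred by
    waiting until the routine review — computed at the fast rate, the worst
    case.  Projected volumes are reported at 1 dp; the comparison with the
    threshold uses the scenario's reporting resolution.
    """
    if not 0 < g_low < g_high:
        raise ValueError(f"need 0 < g_low < g_high, got g_low={g_low}, g_high={g_high}")
    template = scenario if scenario is not None else GrowthScenario(v0=1.0, g=g_low)
    intervals_per_year = round(12 / template.visit_interval_months)
    rows = []
    for v0 in baselines:
        slow = replace(template, v0=v0, g=g_low)
        fast = replace(template, v0=v0, g=g_high)
        earliest = time_to_threshold(fast)
        latest = time_to_threshold(slow)
        delay = management_delay(fast)
        if delay == 0:
            implication = f"No change in management at {template.current_review_month} m"
        else:
            implication = f"Up to {delay} m delay in investigation"
        rows.append(
            ManagementRow(
                v0=v0,
                v_3m_low=round_display(project_volume(v0, g_low, 1)),
                v_3m_high=round_display(project_volume(v0, g_high, 1)),
                v_12m_low=round_display(project_volume(v0, g_low, intervals_per_year)),
                v_12m_high=round_display(project_volume(v0, g_high, intervals_per_year)),
                intervene_month_earliest=earliest,
                intervene_month_latest=latest,
                delay_months=delay,
                implication=implication,
            )
        )
    return rows


class GrowthCall(enum.Enum):
    """Binary growth classification outcome."""

    GROWTH = "growth"
    STABLE = "stable"


def classify_growth(v_prev: float, v_curr: float, threshold_pct: float = 25.0) -> GrowthCall:
    """Classify an interscan volume change as growth or stability.

    Growth is called when the percent increase relative to the PRIOR volume
    strictly exceeds ``threshold_pct`` — the convention of screening
    protocols (25%), distinct from the Bland-Altman mean-referenced relative
    difference.  A 15% threshold reflects the measurement-variability floor
    for small nodules measured under identical scan parameters.
    """
    if v_prev <= 0 or v_curr <= 0:
        raise ValidationError(f"volumes must be positive, got {v_prev}, {v_curr}")
    change_pct = (v_curr - v_prev) / v_prev * 100.0
    return GrowthCall.GROWTH if change_pct > threshold_pct else GrowthCall.STABLE
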