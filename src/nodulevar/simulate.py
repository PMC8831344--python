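"""Synthetic test-retest volumetry cohorts.

Emulates the structure of a same-day double-scan ("coffee-break") study of
small solid nodules: true volumes on 30-150 mm^3, two measurements per
nodule with independent multiplicative Gaussian noise, a second observer who
reproduces the first observer's scan-1 value for most nodules, the observed
morphology/location mix, and planted exclusions (nodules beyond the size
window on both scans, or poorly segmented) so the inclusion filter has work
to do.

The noise model is multiplicative and size-independent — measured volume =
true volume * (1 + eps), eps ~ N(0, sd^2) per scan — because observed
relative differences show no dependence on nodule size.  Under this model
the relative difference of a pair has SD ~= sqrt(2) * sd, so 95% limits of
agreement of +/-15.5% correspond to a per-scan sd of
0.155 / (1.96 * sqrt(2)) ~= 0.056, the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, Location, MeasurementPair, Morphology

__all__ = ["SyntheticConfig", "generate_cohort", "calibrate_noise"]

_MORPHOLOGIES = tuple(Morphology)
_LOCATIONS = tuple(Location)


def calibrate_noise(target_rel_loa_halfwidth: float) -> float:
    """Per-scan relative noise sd giving 95% relative-difference limits of
    +/- ``target_rel_loa_halfwidth`` percent.

    Two independent equally-noisy measurements differ (relatively) with SD
    sqrt(2) * sd, so the half-width of the 1.96-SD limits is
    1.96 * sqrt(2) * sd * 100 (%); this inverts that relation.
    """
    if target_rel_loa_halfwidth <= 0:
        raise ValueError(f"target half-width must be positive, got {target_rel_loa_halfwidth}")
    return target_rel_loa_halfwidth / (1.96 * math.sqrt(2.0) * 100.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults mirror the emulated study cohort.

    ``n_nodules`` is the number of includable nodules (true volumes inside
    [volume_low, volume_high]); the planted exclusions come on top, so the
    raw cohort has n_nodules + n_oversize + n_undersize + n_poorseg pairs —
    by default 100 + 4 + 1 + 2 = 107, of which the inclusion filter retains
    exactly 100.  Morphology probabilities are (spherical-smooth,
    non-spherical smooth, non-spherical irregular); location probabilities
    (intraparenchymal, juxtapleural, perifissural, juxtavascular).
    """

    n_nodules: int = 100
    n_participants: int = 45
    volume_low: float = 30.0
    volume_high: float = 150.0
    per_scan_rel_sd: float = 0.056
    morphology_probs: tuple[float, float, float] = (0.28, 0.07, 0.65)
    location_probs: tuple[float, float, float, float] = (0.80, 0.02, 0.05, 0.13)
    obs2_identical_prob: float = 0.95
    n_oversize: int = 4
    n_undersize: int = 1
    n_poorseg: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_nodules", "n_oversize", "n_undersize", "n_poorseg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_participants < 1:
            raise ValueError(f"n_participants must be >= 1, got {self.n_participants}")
        total = self.n_nodules + self.n_oversize + self.n_undersize + self.n_poorseg
        if self.n_participants > total:
            raise ValueError(
                f"n_participants={self.n_participants} exceeds total nodules {total}"
            )
        if not 0 < self.volume_low < self.volume_high:
            raise ValueError(
                f"need 0 < volume_low < volume_high, got {self.volume_low}, {self.volume_high}"
            )
        if self.per_scan_rel_sd < 0:
            raise ValueError(f"per_scan_rel_sd must be >= 0, got {self.per_scan_rel_sd}")
        if not 0 <= self.obs2_identical_prob <= 1:
            raise ValueError(f"obs2_identical_prob must be in [0,1], got {self.obs2_identical_prob}")
        for name, probs, k in (
            ("morphology_probs", self.morphology_probs, 3),
            ("location_probs", self.location_probs, 4),
        ):
            if len(probs) != k or any(p < 0 for p in probs):
                raise ValueError(f"{name} must be {k} non-negative values")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {sum(probs)}")


def _measure(rng: np.random.Generator, true_vol: float, sd: float) -> float:
    return true_vol * (1.0 + rng.normal(0.0, sd)) if sd > 0 else true_vol


def _measure_pair_within(
    rng: np.random.Generator, true_vol: float, sd: float, low: float, high: float
) -> tuple[float, float]:
    """Noisy pair for an includable nodule.

    Redraws the (rare) realisations in which both scans land outside the
    inclusion window on the same side, which would silently change the
    planted exclusion accounting.
    """
    for _ in range(1000):
        v1, v2 = _measure(rng, true_vol, sd), _measure(rng, true_vol, sd)
        if (v1 > high and v2 > high) or (v1 < low and v2 < low) or v1 <= 0 or v2 <= 0:
            continue
        return v1, v2
    raise RuntimeError("could not draw an in-window measurement pair; sd implausibly large")


def _measure_pair_beyond(
    rng: np.random.Generator, true_vol: float, sd: float, bound: float, side: str
) -> tuple[float, float]:
    """Noisy pair guaranteed outside the window on ``side`` of ``bound`` on both scans."""
    for _ in range(1000):
        v1, v2 = _measure(rng, true_vol, sd), _measure(rng, true_vol, sd)
        if side == "above" and v1 > bound and v2 > bound:
            return v1, v2
        if side == "below" and 0 < v1 < bound and 0 < v2 < bound:
            return v1, v2
    raise RuntimeError(f"could not draw a pair {side} {bound}")


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a reproducible synthetic cohort from ``config``.

    True volumes are uniform on [volume_low, volume_high]; each scan's
    measurement is true * (1 + eps) with independent eps ~ N(0, sd^2); the
    second observer's scan-1 value equals observer 1's with probability
    ``obs2_identical_prob`` and is independently re-noised otherwise.
    Planted oversize/undersize nodules have both scans beyond the respective
    bound; planted poor-segmentation nodules are in-range but flagged.
    Nodules are assigned to participants round-robin.  The exclusion ledger
    starts empty — planting only stages nodules for the inclusion filter.
    """
    rng = np.random.default_rng(config.seed)
    sd = config.per_scan_rel_sd
    low, high = config.volume_low, config.volume_high

    specs: list[tuple[str, bool]] = [("in_range", True)] * config.n_nodules
    specs += [("oversize", True)] * config.n_oversize
    specs += [("undersize", True)] * config.n_undersize
    specs += [("poorseg", False)] * config.n_poorseg

    pairs: list[MeasurementPair] = []
    width = max(3, len(str(len(specs))))
    for i, (kind, well_segmented) in enumerate(specs):
        if kind == "oversize":
            true_vol = rng.uniform(1.3 * high, 2.0 * high)
            v1, v2 = _measure_pair_beyond(rng, true_vol, sd, high, "above")
        elif kind == "undersize":
            true_vol = rng.uniform(0.5 * low, 0.9 * low)
            v1, v2 = _measure_pair_beyond(rng, true_vol, sd, low, "below")
        else:
            true_vol = rng.uniform(low, high)
            v1, v2 = _measure_pair_within(rng, true_vol, sd, low, high)
        if rng.uniform() < config.obs2_identical_prob:
            v1_obs2 = v1
        else:
            v1_obs2 = true_vol * (1.0 + rng.normal(0.0, sd)) if sd > 0 else true_vol
            v1_obs2 = max(v1_obs2, 1e-9)
        morph = _MORPHOLOGIES[rng.choice(3, p=np.asarray(config.morphology_probs, float))]
        loc = _LOCATIONS[rng.choice(4, p=np.asarray(config.location_probs, float))]
        pairs.append(
            MeasurementPair(
                nodule_id=f"N{i + 1:0{width}d}",
                participant_id=f"P{(i % config.n_participants) + 1:02d}",
                v1=v1,
                v2=v2,
                v1_obs2=v1_obs2,
                morphology=morph,
                location=loc,
                well_segmented=well_segmented,
            )
        )
    return Cohort(pairs)
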