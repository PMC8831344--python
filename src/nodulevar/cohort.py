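"""Nodule cohort data model, CSV I/O and inclusion/exclusion filtering.

The atomic record is a :class:`MeasurementPair`: one solid nodule measured by
volumetry on two same-day CT scans (a test-retest or "coffee-break" design),
optionally re-measured on scan 1 by a second observer.  A :class:`Cohort`
bundles the pairs with an exclusion ledger so that every nodule entering the
pipeline is accounted for: retained + excluded = input, always.

Volumes are in mm^3 throughout.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "Morphology",
    "Location",
    "ExclusionReason",
    "MeasurementPair",
    "Exclusion",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "apply_inclusion_filter",
    "CSV_COLUMNS",
]


class Morphology(enum.Enum):
    """Nodule shape/margin category as read from CT."""

    SPHERICAL_SMOOTH = "spherical_smooth"
    NONSPHERICAL_SMOOTH = "nonspherical_smooth"
    NONSPHERICAL_IRREGULAR = "nonspherical_irregular"


class Location(enum.Enum):
    """Nodule position relative to surrounding structures.

    Attachment to pleura, fissure or vessels complicates automatic
    segmentation and is recorded because it drives measurement variability.
    """

    INTRAPARENCHYMAL = "intraparenchymal"
    JUXTAPLEURAL = "juxtapleural"
    PERIFISSURAL = "perifissural"
    JUXTAVASCULAR = "juxtavascular"


class ExclusionReason(enum.Enum):
    OVERSIZE = "oversize"
    UNDERSIZE = "undersize"
    POOR_SEGMENTATION = "poor_segmentation"


def _check_volume(name: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
        raise ValidationError(f"{name} must be a positive finite volume (mm^3), got {value!r}")


@dataclass(frozen=True)
class MeasurementPair:
    """One nodule's two same-day volume measurements plus metadata.

    Parameters
    ----------
    nodule_id, participant_id
        Opaque identifiers; several nodules may share a participant.
    v1, v2
        Volumes (mm^3) from scan 1 and scan 2, observer 1.  Must be > 0.
    v1_obs2
        Optional scan-1 volume re-measured by a second observer.
    morphology, location
        Categorical nodule descriptors.
    well_segmented
        False when the volumetry software's segmentation was judged poor;
        such nodules are excluded from agreement analysis.
    """

    nodule_id: str
    participant_id: str
    v1: float
    v2: float
    v1_obs2: float | None = None
    morphology: Morphology = Morphology.NONSPHERICAL_IRREGULAR
    location: Location = Location.INTRAPARENCHYMAL
    well_segmented: bool = True

    def __post_init__(self) -> None:
        _check_volume("v1", self.v1)
        _check_volume("v2", self.v2)
        if self.v1_obs2 is not None:
            _check_volume("v1_obs2", self.v1_obs2)
        if not isinstance(self.morphology, Morphology):
            raise ValidationError(f"morphology must be a Morphology member, got {self.morphology!r}")
        if not isinstance(self.location, Location):
            raise ValidationError(f"location must be a Location member, got {self.location!r}")


@dataclass(frozen=True)
class Exclusion:
    nodule_id: str
    reason: ExclusionReason


@dataclass(frozen=True)
class Cohort:
    """A collection of measurement pairs plus the ledger of excluded nodules.

    Invariants: no nodule id appears both among the retained pairs and in the
    exclusion ledger, and the number of distinct participants never exceeds
    the number of pairs.
    """

    pairs: tuple[MeasurementPair, ...] = ()
    exclusions: tuple[Exclusion, ...] = ()

    def __init__(self, pairs: Iterable[MeasurementPair] = (), exclusions: Iterable[Exclusion] = ()):
        object.__setattr__(self, "pairs", tuple(pairs))
        object.__setattr__(self, "exclusions", tuple(exclusions))
        retained = {p.nodule_id for p in self.pairs}
        excluded = {e.nodule_id for e in self.exclusions}
        overlap = retained & excluded
        if overlap:
            raise ValidationError(
                f"nodule ids present both retained and excluded: {sorted(overlap)}"
            )

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def participant_ids(self) -> tuple[str, ...]:
        """Distinct participants with at least one retained nodule, in order of appearance."""
        seen: dict[str, None] = {}
        for p in self.pairs:
            seen.setdefault(p.participant_id, None)
        return tuple(seen)

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    def has_second_observer(self) -> bool:
        """True when every retained pair carries a second-observer measurement."""
        return len(self.pairs) > 0 and all(p.v1_obs2 is not None for p in self.pairs)


CSV_COLUMNS = (
    "nodule_id",
    "participant_id",
    "v1_mm3",
    "v2_mm3",
    "v1_obs2_mm3",
    "morphology",
    "location",
    "well_segmented",
)

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False}


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort from the package's delimited-text schema.

    The file must carry the header
    ``nodule_id,participant_id,v1_mm3,v2_mm3,v1_obs2_mm3,morphology,location,well_segmented``;
    ``v1_obs2_mm3`` may be empty.  Rows with missing or non-positive primary
    volumes are rejected with an error citing the row, never silently dropped.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

    pairs: list[MeasurementPair] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        rec = dict(zip(df.columns, row))
        for col in ("v1_mm3", "v2_mm3"):
            if rec[col].strip() == "":
                raise ValidationError(f"{path}, line {i}: missing value in column {col}")
        try:
            v1 = float(rec["v1_mm3"])
            v2 = float(rec["v2_mm3"])
            obs2 = float(rec["v1_obs2_mm3"]) if rec["v1_obs2_mm3"].strip() != "" else None
        except ValueError as exc:
            raise ValidationError(f"{path}, line {i}: non-numeric volume ({exc})") from None
        try:
            morph = Morphology(rec["morphology"])
            loc = Location(rec["location"])
        except ValueError as exc:
            raise ValidationError(f"{path}, line {i}: {exc}") from None
        seg = _BOOL_MAP.get(rec["well_segmented"].strip().lower())
        if seg is None:
            raise ValidationError(
                f"{path}, line {i}: well_segmented must be true/false, got {rec['well_segmented']!r}"
            )
        try:
            pairs.append(
                MeasurementPair(
                    nodule_id=rec["nodule_id"],
                    participant_id=rec["participant_id"],
                    v1=v1,
                    v2=v2,
                    v1_obs2=obs2,
                    morphology=morph,
                    location=loc,
                    well_segmented=seg,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, line {i}: {exc}") from None
    return Cohort(pairs)


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write retained pairs to CSV in the documented schema.

    Volumes are written with ``repr`` precision so that a write/read
    round-trip reproduces every field bit-identically.
    """
    path = Path(path)
    rows = []
    for p in cohort.pairs:
        rows.append(
            {
                "nodule_id": p.nodule_id,
                "participant_id": p.participant_id,
                "v1_mm3": repr(float(p.v1)),
                "v2_mm3": repr(float(p.v2)),
                "v1_obs2_mm3": "" if p.v1_obs2 is None else repr(float(p.v1_obs2)),
                "morphology": p.morphology.value,
                "location": p.location.value,
                "well_segmented": "true" if p.well_segmented else "false",
            }
        )
    pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(path, index=False)
    return path


def apply_inclusion_filter(cohort: Cohort, vmin: float = 30.0, vmax: float = 150.0) -> Cohort:
    """Apply the study's inclusion rules, appending exclusions to the ledger.

    A nodule is excluded as ``oversize`` only when BOTH scans exceed ``vmax``,
    and as ``undersize`` only when BOTH scans fall below ``vmin``: a nodule
    with a single-scan excursion outside the window is retained (which is why
    retained volumes can range slightly beyond the nominal window).  Bounds
    are strict, so a volume exactly at a bound is retained.  Poorly segmented
    nodules are excluded regardless of size.  Retained order is preserved and
    the filter is idempotent.
    """
    if not vmin < vmax:
        raise ValueError(f"vmin must be < vmax, got vmin={vmin}, vmax={vmax}")
    retained: list[MeasurementPair] = []
    new_exclusions: list[Exclusion] = []
    for p in cohort.pairs:
        if p.v1 > vmax and p.v2 > vmax:
            new_exclusions.append(Exclusion(p.nodule_id, ExclusionReason.OVERSIZE))
        elif p.v1 < vmin and p.v2 < vmin:
            new_exclusions.append(Exclusion(p.nodule_id, ExclusionReason.UNDERSIZE))
        elif not p.well_segmented:
            new_exclusions.append(Exclusion(p.nodule_id, ExclusionReason.POOR_SEGMENTATION))
        else:
            retained.append(p)
    return Cohort(retained, cohort.exclusions + tuple(new_exclusions))
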