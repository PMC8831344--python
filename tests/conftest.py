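import pytest

from nodulevar import (
    Cohort,
    Location,
    MeasurementPair,
    Morphology,
    SyntheticConfig,
    apply_inclusion_filter,
    generate_cohort,
)


@pytest.fixture
def make_pair():
    """Factory for measurement pairs with sensible defaults."""

    counter = {"i": 0}

    def _make(v1, v2, *, v1_obs2=None, participant=None, well_segmented=True,
              morphology=Morphology.NONSPHERICAL_IRREGULAR,
              location=Location.INTRAPARENCHYMAL, nodule_id=None):
        counter["i"] += 1
        i = counter["i"]
        return MeasurementPair(
            nodule_id=nodule_id or f"N{i:03d}",
            participant_id=participant or f"P{i:02d}",
            v1=v1,
            v2=v2,
            v1_obs2=v1_obs2,
            morphology=morphology,
            location=location,
            well_segmented=well_segmented,
        )

    return _make


@pytest.fixture(scope="session")
def study_config():
    """Study-mirroring generator settings: 100 includable nodules plus the
    planted 4 oversize / 1 undersize / 2 poorly segmented exclusions."""
    return SyntheticConfig(seed=20210927)


@pytest.fixture(scope="session")
def raw_cohort(study_config):
    return generate_cohort(study_config)


@pytest.fixture(scope="session")
def study_cohort(raw_cohort):
    """The raw synthetic cohort after the 30-150 mm^3 inclusion filter."""
    return apply_inclusion_filter(raw_cohort)


@pytest.fixture
def tiny_cohort(make_pair):
    return Cohort(
        [
            make_pair(100.0, 104.0, v1_obs2=100.0),
            make_pair(50.0, 48.0, v1_obs2=51.0),
            make_pair(90.0, 110.0, v1_obs2=90.0),
            make_pair(60.0, 61.5, v1_obs2=60.0),
        ]
    )
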