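import pytest

from clnmscore import (
    CLNMDiscriminant,
    bin_patient,
    load_published_scores,
    load_retrospective_frequencies,
)


@pytest.fixture(scope="session")
def retro_table():
    """Bundled retrospective class-conditional frequency table (412 cases)."""
    return load_retrospective_frequencies()


@pytest.fixture(scope="session")
def published_scores():
    """Bundled published score table (1-dp printed values)."""
    return load_published_scores()


@pytest.fixture(scope="session")
def fitted_results(retro_table):
    """Score table fitted from the retrospective frequencies."""
    return CLNMDiscriminant(retro_table).fit()


@pytest.fixture(scope="session")
def worked_example_profile():
    """The published worked example: 28-year-old male, unifocal 1.6 cm
    tumor at the lower pole, no capsular invasion."""
    return bin_patient(
        {
            "sex": "male",
            "age": 28,
            "tumor_diameter": 1.6,
            "capsular_invasion": "N",
            "multifocality": "N",
            "tumor_location": "lower pole",
        }
    )
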