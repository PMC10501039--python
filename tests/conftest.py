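import logging

import pytest

from vocscreen.diff_extraction import extract_differential
from vocscreen.synthetic_data import default_calibration, generate

logging.getLogger("vocscreen").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def default_config():
    return default_calibration(seed=2015)


@pytest.fixture(scope="session")
def fixture_tables(default_config):
    """The packaged default synthetic cohort (seed 2015): 9 + 9 subjects,
    157 VOC species calibrated to the published summary tables."""
    return generate(default_config)


@pytest.fixture(scope="session")
def fixture_table(fixture_tables):
    return fixture_tables[0]


@pytest.fixture(scope="session")
def fixture_cohort(fixture_tables):
    return fixture_tables[1]


@pytest.fixture(scope="session")
def fixture_biomarkers(fixture_table):
    return extract_differential(fixture_table)
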