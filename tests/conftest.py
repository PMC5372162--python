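import numpy as np
import pytest

from coralguild.datasets import ANALYSIS_STRATA, KEY_TAXA, load_survey
from coralguild.community import to_incidence


@pytest.fixture(scope="session")
def survey():
    """The packaged 234-colony survey: (records, taxa)."""
    return load_survey()


@pytest.fixture(scope="session")
def survey_records(survey):
    return survey[0]


@pytest.fixture(scope="session")
def survey_taxa(survey):
    return survey[1]


@pytest.fixture(scope="session")
def stratum_matrices(survey_records):
    """Key-species incidence matrix per analysis stratum (all colonies kept)."""
    out = {}
    for name, st in ANALYSIS_STRATA.items():
        members = [r for r in survey_records if st.matches(r)]
        out[name] = to_incidence(members, KEY_TAXA, drop_empty=False)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
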