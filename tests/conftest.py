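import json
from importlib import resources

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")

from simcyto import lineage
from simcyto.karyotype import load_registry
from simcyto.popgen import frequency_table


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def records():
    return lineage.build_records()


@pytest.fixture(scope="session")
def table(records):
    return frequency_table(records, lineage.ALL_NAMES)


@pytest.fixture(scope="session")
def matrix(table):
    from simcyto.phylogeny import polarize
    m = lineage.character_matrix(table)
    return polarize(m)


@pytest.fixture(scope="session")
def scenarios():
    doc = json.loads(resources.files("simcyto.data")
                     .joinpath("scenarios.json").read_text())
    return doc["scenarios"]
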