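import pytest

from ftree import build_pedigree
from ftree.fixtures import scenario_questionnaire


@pytest.fixture
def d_questionnaire():
    return scenario_questionnaire("D")


@pytest.fixture
def d_pedigree(d_questionnaire):
    return build_pedigree(d_questionnaire)


@pytest.fixture
def p_questionnaire():
    return scenario_questionnaire("P")


@pytest.fixture
def p_pedigree(p_questionnaire):
    return build_pedigree(p_questionnaire)


@pytest.fixture
def ultimate_pedigree():
    return build_pedigree(scenario_questionnaire("ultimate"))
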