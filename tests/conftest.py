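import pytest

import interva5 as iv
from interva5.synthetic import SimulationConfig, generate_cohort, generate_kb

TINY_KB_CSV = """\
indicator,text,substantive,sex,ages,group,role,formats,01.01,02.01,PREG:pregnant at death,PREG:recently delivered,PREG:not pregnant or not applicable
PRIOR,,,,,,,,0.5,0.5,0.1,0.1,0.8
SEX,,,,,,,,any,any,,,
AGE,,,,,,,,adult|child|neonate,adult,,,
fever,Did she/he have a fever?,yes,any,,,,who2016|who2012|tariff2,A+,A-,A,A,A
placenta,Was the placenta completely delivered?,no,female,adult,,,who2016|who2012,A,A,A+,A-,B
cough,Did she/he have a cough?,yes,any,,,,who2016,A,B+,A,A,A
"""


@pytest.fixture()
def tiny_kb_path(tmp_path):
    path = tmp_path / "kb.csv"
    path.write_text(TINY_KB_CSV)
    return path


@pytest.fixture()
def tiny_kb(tiny_kb_path):
    """3 indicators x 2 causes, with a pregnancy block; no role indicators."""
    return iv.load_knowledge_base(tiny_kb_path)


PLANTED = {"01.01": 0.30, "02.01": 0.25, "04.01": 0.20, "06.01": 0.15,
           "12.01": 0.10}

RECOVERY_CONFIG = SimulationConfig(
    n_indicators=30, n_causes=5, n_cases=2000, planted_csmf=PLANTED,
    informativeness=0.9, missingness=0.05, seed=11)


@pytest.fixture(scope="session")
def recovery_run():
    """One seeded 2000-case cohort classified end to end (shared: ~4 s)."""
    kb = generate_kb(RECOVERY_CONFIG)
    records, truth = generate_cohort(kb, RECOVERY_CONFIG)
    cleaned, report = iv.check_consistency(records, kb)
    classifications = iv.classify_cohort(cleaned, kb)
    return kb, records, truth, report, classifications


ROLE_KB_CSV = """\
indicator,substantive,sex,ages,role,group,01.01,02.01,PREG:pregnant at death,PREG:recently delivered,PREG:not pregnant or not applicable
PRIOR,,,,,,0.5,0.5,0.1,0.1,0.8
i_adult,yes,any,,adult,,A,A,A,A,A
i_neonate,yes,any,,neonate,,A,A,A,A,A
i_male,yes,any,,male,,A,A,A,A,A
i_female,yes,any,,female,,A,A,A,A,A
preg,yes,female,adult,,,A+,A-,A+,A,B
neonate_only,yes,any,neonate,,,A,A,A,A,A
"""


@pytest.fixture(scope="session")
def role_kb(tmp_path_factory):
    """KB with demographic role indicators for consistency-rule tests."""
    path = tmp_path_factory.mktemp("rolekb") / "kb.csv"
    path.write_text(ROLE_KB_CSV)
    return iv.load_knowledge_base(path)


@pytest.fixture(scope="module")
def format_kb(tmp_path_factory):
    """Module-scoped copy of the tiny KB (usable inside hypothesis tests)."""
    path = tmp_path_factory.mktemp("fmtkb") / "kb.csv"
    path.write_text(TINY_KB_CSV)
    return iv.load_knowledge_base(path)


@pytest.fixture(scope="session")
def demo_kb():
    """Small synthetic KB with role indicators, deterministic."""
    return generate_kb(SimulationConfig(n_indicators=12, n_causes=3, n_cases=0,
                                        seed=1))
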