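import pytest

from pvscreen import datasets
from pvscreen.faers_io import CaseReport, EventTermSet


@pytest.fixture(scope="session")
def terms() -> EventTermSet:
    return datasets.default_event_terms()


@pytest.fixture
def make_report():
    def _make(case_id="1", drugs=("BEVACIZUMAB",), reactions=("HYPERTENSION",),
              age=None, sex="unknown"):
        return CaseReport(
            case_id=str(case_id),
            age_years=age,
            sex=sex,
            drugs=frozenset(drugs),
            reactions=frozenset(reactions),
        )

    return _make


@pytest.fixture
def faers_dir(tmp_path):
    """Three-case FAERS-dialect fixture: 3 demo rows, 5 drug rows, 4 reac rows."""
    (tmp_path / "DEMO23Q1.txt").write_text(
        "case_id$version$age$age_unit$sex\n"
        "100$1$55$YR$M\n"
        "101$1$6$DEC$F\n"
        "102$1$$$UNK\n"
    )
    (tmp_path / "DRUG23Q1.txt").write_text(
        "case_id$version$drug_name\n"
        "100$1$BEVACIZUMAB\n"
        "100$1$omeprazole \n"
        "101$1$BEVACIZUMAB\n"
        "101$1$ERLOTINIB\n"
        "102$1$ASPIRIN\n"
    )
    (tmp_path / "REAC23Q1.txt").write_text(
        "case_id$version$reaction\n"
        "100$1$HYPERTENSION\n"
        "100$1$NAUSEA\n"
        "101$1$Blood Pressure Increased\n"
        "102$1$HEADACHE\n"
    )
    return tmp_path
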