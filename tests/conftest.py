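import numpy as np
import pytest

from gbsnet.report_io import Report, ReportTable
from gbsnet.synthetic_data import OUTCOME_TERM, fixture_network


@pytest.fixture(scope="session")
def fixture_bn():
    return fixture_network()


def make_report(rid, age, gender, terms=(), outcome=False):
    terms = set(terms)
    if outcome:
        terms.add(OUTCOME_TERM)
    return Report(str(rid), age, gender, frozenset(terms), outcome)


@pytest.fixture
def toy_table():
    """Five clean reports with a small AE vocabulary."""
    records = [
        make_report("r1", 12.0, "female", {"headache", "pyrexia"}),
        make_report("r2", 30.0, "male", {"headache"}, outcome=True),
        make_report("r3", 55.0, "male", {"headache", "nausea"}),
        make_report("r4", 70.0, "female", {"pyrexia"}),
        make_report("r5", 40.0, "female", set()),
    ]
    return ReportTable(records, outcome_term=OUTCOME_TERM)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
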