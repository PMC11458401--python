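import datetime

import pytest

from pvsignals import CaseReport, DrugRecord, Reaction


def make_case(
    caseid="C1",
    primaryid=None,
    caseversion=1,
    sex="F",
    age=60.0,
    reporter="physician",
    country="US",
    fda_date=datetime.date(2021, 3, 1),
    event_date=datetime.date(2021, 1, 1),
    drugs=(("CAPMATINIB", "CAPMATINIB", "PS"),),
    reactions=("PT_A",),
    outcomes=(),
):
    """Terse CaseReport factory for unit tests."""
    return CaseReport(
        caseid=caseid,
        primaryid=primaryid if primaryid is not None else f"{caseid}{caseversion}",
        caseversion=caseversion,
        event_date=event_date,
        age=age,
        sex=sex,
        reporter=reporter,
        country=country,
        fda_date=fda_date,
        drugs=[DrugRecord(*d) for d in drugs],
        reactions=[Reaction(pt) if isinstance(pt, str) else Reaction(*pt) for pt in reactions],
        outcomes=frozenset(outcomes),
    )


@pytest.fixture
def case_factory():
    return make_case
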