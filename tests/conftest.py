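import random

import pytest

from pvdispro.cleaning import Report
from pvdispro.faers_io import (
    DemoRecord,
    DrugRecord,
    RawDate,
    ReactionRecord,
    RoleCode,
    parse_date,
)


def make_demo(primaryid, caseid, fda="20230101", **kw):
    return DemoRecord(primaryid=str(primaryid), caseid=str(caseid),
                      fda_dt=parse_date(fda), **kw)


def make_report(primaryid, events, drug="DRUG_A", role=RoleCode.PS,
                fda="20230101", event_dt="", start_dt="", caseid=None, **kw):
    drugs = []
    if drug is not None:
        drugs = [DrugRecord(primaryid=str(primaryid), drug_name=drug,
                            active_ingredient=drug, role_code=role,
                            start_dt=parse_date(start_dt))]
    return Report(
        primaryid=str(primaryid),
        caseid=str(caseid if caseid is not None else primaryid),
        fda_dt=parse_date(fda),
        event_dt=parse_date(event_dt),
        events=frozenset(events),
        drugs=drugs,
        **kw,
    )


@pytest.fixture
def rng():
    return random.Random(20240901)


def random_demo_records(rnd, n_cases=30, n_records=60):
    """Randomized DEMO fixtures exercising dedup ties and date spread."""
    records = []
    for i in range(n_records):
        caseid = str(rnd.randrange(n_cases))
        fda = f"2023{rnd.randrange(1, 13):02d}{rnd.randrange(1, 29):02d}"
        records.append(make_demo(str(1000 + i), caseid, fda))
    # force some exact (caseid, fda_dt) ties to hit the primaryid rule
    for _ in range(n_records // 5):
        src = rnd.choice(records)
        records.append(make_demo(str(rnd.randrange(1000, 9999)), src.caseid,
                                 src.fda_dt.text))
    rnd.shuffle(records)
    return records
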