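import datetime

import pytest

from icivig.cohort import CaseReport, DrugRecord, ReactionRecord
from icivig import synthgen


@pytest.fixture(scope="session")
def paper_fixture():
    """The deterministic 345-report case series."""
    return synthgen.gen_paper_fixture()


def make_report(
    pid="1",
    case_id=None,
    receipt=datetime.date(2020, 6, 1),
    drugs=("NIVOLUMAB",),
    roles=None,
    reactions=("Immune thrombocytopenia",),
    age=60.0,
    outcomes=("HO",),
    indications=("Malignant melanoma",),
    therapy_start=None,
    event_date=None,
):
    """Compact builder for hand-crafted case reports."""
    case_id = case_id or f"C{pid}"
    roles = roles or ["PS"] * len(drugs)
    return CaseReport(
        primary_id=pid,
        case_id=case_id,
        fda_receipt_date=receipt,
        age_years=age,
        sex="M",
        country="US",
        reporter_type="MD",
        drugs=[
            DrugRecord(
                primary_id=pid,
                drug_name_raw=name,
                role_code=role,
                therapy_start_date=therapy_start,
            )
            for name, role in zip(drugs, roles)
        ],
        reactions=[
            ReactionRecord(primary_id=pid, pt=pt, event_onset_date=event_date)
            for pt in reactions
        ],
        outcomes=list(outcomes),
        indications=list(indications),
    )
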