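import pandas as pd
import pytest
from hypothesis import settings

from pvsignal.hierarchy import TermHierarchy
from pvsignal.io import RawTables, apply_exclusions

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


@pytest.fixture
def toy_hierarchy() -> TermHierarchy:
    return TermHierarchy(
        pt_to_hlgt={"p1": "H", "p2": "H", "p3": "H2", "p4": "H3"},
        hlgt_to_soc={"H": "S1", "H2": "S1", "H3": "S2"},
    )


def make_tables(cases) -> RawTables:
    """Build the four raw tables from a list of case dicts.

    Each dict: case_id, sex, age, drugs=[(name, role)], reactions=[(pt,
    outcome)], hist=True.
    """
    demo, drug, reac, hist = [], [], [], []
    for case in cases:
        demo.append(
            {"case_id": case["case_id"], "sex": case.get("sex", "female"),
             "age": case.get("age", "70s")}
        )
        for name, role in case.get("drugs", []):
            drug.append({"case_id": case["case_id"], "drug_name": name, "role": role})
        for pt, outcome in case.get("reactions", []):
            reac.append({"case_id": case["case_id"], "pt": pt, "outcome": outcome})
        if case.get("hist", True):
            hist.append({"case_id": case["case_id"], "primary_disease": "insomnia"})
    return RawTables(
        demo=pd.DataFrame(demo, columns=["case_id", "sex", "age"]).astype(str),
        drug=pd.DataFrame(drug, columns=["case_id", "drug_name", "role"]).astype(str),
        reac=pd.DataFrame(reac, columns=["case_id", "pt", "outcome"]).astype(str),
        hist=pd.DataFrame(hist, columns=["case_id", "primary_disease"]).astype(str),
    )


def make_dataset(cases):
    return apply_exclusions(make_tables(cases))
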