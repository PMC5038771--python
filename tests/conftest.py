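import numpy as np
import pytest

from roughpd.datasets import (
    EXTRACT_CUTS,
    EXTRACT_DECISION_CUTS,
    extract_decision_table,
    patient_extract,
)
from roughpd.discretize import CutSet, apply_cuts
from roughpd.tables import AttributeSpec, DecisionTable, InformationTable


@pytest.fixture
def extract():
    return patient_extract()


@pytest.fixture
def extract_dt():
    return extract_decision_table()


@pytest.fixture
def extract_disc(extract_dt):
    """The 8 printed rows discretized under the published cuts."""
    cutset = CutSet(cuts={k: list(v) for k, v in EXTRACT_CUTS.items()})
    return apply_cuts(extract_dt, cutset, EXTRACT_DECISION_CUTS)


def make_table(rows, decision="d", kinds=None):
    """Small labelled decision table from a list of dicts (the last key,
    or ``decision``, is the decision attribute)."""
    names = list(rows[0].keys())
    kinds = kinds or {}
    schema = [
        AttributeSpec(
            n,
            kinds.get(n, "nominal"),
            "decision" if n == decision else "condition",
        )
        for n in names
    ]
    return DecisionTable(InformationTable(schema, rows), decision)


@pytest.fixture
def toy_table():
    """Consistent table where attribute 'a' alone determines the decision."""
    rows = [
        {"a": "x", "b": "p", "d": "yes"},
        {"a": "x", "b": "q", "d": "yes"},
        {"a": "y", "b": "p", "d": "no"},
        {"a": "y", "b": "q", "d": "no"},
        {"a": "x", "b": "p", "d": "yes"},
        {"a": "y", "b": "q", "d": "no"},
    ]
    return make_table(rows)


def random_label_table(rng, n_obj=8, n_attr=5, n_vals=3, n_dec=2):
    rows = []
    for _ in range(n_obj):
        rec = {f"a{k}": str(rng.integers(n_vals)) for k in range(n_attr)}
        rec["d"] = str(rng.integers(n_dec))
        rows.append(rec)
    return make_table(rows)
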