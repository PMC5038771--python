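"""Cut generation, interval labelling, and the worked-example table."""

from itertools import chain, combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_table
from roughpd.datasets import (
    EXTRACT_CUTS,
    EXTRACT_DECISION_CUTS,
    extract_decision_table,
)
from roughpd.discretize import (
    STAR,
    CutSet,
    apply_cuts,
    candidate_cuts,
    equal_frequency_cuts,
    interval_label,
    md_select_cuts,
    value_bin,
)
from roughpd.roughcore import partition
from roughpd.tables import MISSING

MINUS = "−"

#: the published discretized table of the two-patient extract, row by row
PRINTED_ROWS = [
    ("28", f"({MINUS}Inf, 55.0)", "*", "1", "*", f"({MINUS}Inf, 45.5)",
     "(260.0, Inf)", "(10.5, Inf)", "(55.0, Inf)"),
    ("28", f"({MINUS}Inf, 55.0)", "*", "2", "*", "(45.5, Inf)",
     "(260.0, Inf)", "(10.5, Inf)", "(22.5, 55.0)"),
    ("28", f"({MINUS}Inf, 55.0)", "*", "2", "*", "(45.5, Inf)",
     f"({MINUS}Inf, 260.0)", f"({MINUS}Inf, 10.5)", "(22.5, 55.0)"),
    ("28", f"({MINUS}Inf, 55.0)", "*", "4", "*", "(45.5, Inf)",
     f"({MINUS}Inf, 260.0)", f"({MINUS}Inf, 10.5)", "(14.0, 22.5)"),
    ("38", "(55.0, Inf)", "*", "1", "*", f"({MINUS}Inf, 45.5)",
     "(260.0, Inf)", "(10.5, Inf)", "(22.5, 55.0)"),
    ("38", "(55.0, Inf)", "*", "2", "*", "(45.5, Inf)",
     f"({MINUS}Inf, 260.0)", "(10.5, Inf)", "(14.0, 22.5)"),
    ("38", "(55.0, Inf)", "*", "3", "*", f"({MINUS}Inf, 45.5)",
     "(260.0, Inf)", "(10.5, Inf)", "(22.5, 55.0)"),
    ("38", "(55.0, Inf)", "*", "4", "*", f"({MINUS}Inf, 45.5)",
     f"({MINUS}Inf, 260.0)", f"({MINUS}Inf, 10.5)", f"({MINUS}Inf, 14.0)"),
]
PRINTED_COLS = ("Pat", "age", "t_dur", "Sess", "HYsc", "SccDur", "SccLat",
                "SccAmp", "UPDRS")


def test_worked_example_reproduces_printed_labels(extract_disc):
    for rec, printed in zip(extract_disc.records, PRINTED_ROWS):
        assert tuple(rec[c] for c in PRINTED_COLS) == printed


def test_candidate_cuts_boundary_points():
    rows = [{"v": 12.0, "d": "lo"}, {"v": 16.0, "d": "hi"}]
    dt = make_table(rows, kinds={"v": "numeric"})
    assert candidate_cuts(dt, "v") == [14.0]
    same = make_table([{"v": 1.0, "d": "x"}, {"v": 2.0, "d": "x"}],
                      kinds={"v": "numeric"})
    assert candidate_cuts(same, "v") == []


def test_candidate_cuts_updrs_column(extract_dt):
    from roughpd.tables import as_decision_table, project

    dt = as_decision_table(project(extract_dt.base, ["UPDRS"]), "UPDRS")
    cands = candidate_cuts(dt, "UPDRS", EXTRACT_DECISION_CUTS)
    assert 14.0 in cands
    assert cands == [14.0, 29.5, 53.5]


def test_md_stars_duration_and_hoehn_yahr(extract_dt):
    cutset = md_select_cuts(extract_dt, EXTRACT_DECISION_CUTS)
    starred = cutset.starred()
    assert "t_dur" in starred and "HYsc" in starred
    # completeness: labelled rows with different decisions stay distinct
    disc = apply_cuts(extract_dt, cutset, EXTRACT_DECISION_CUTS)
    for i, ri in enumerate(disc.records):
        for rj in disc.records[i + 1:]:
            if ri[disc.decision] != rj[disc.decision]:
                assert any(ri[a] != rj[a] for a in disc.condition_names)


def test_md_single_separating_cut():
    rows = [{"v": float(v), "d": "lo" if v < 5 else "hi"} for v in (1, 2, 3, 7, 8, 9)]
    dt = make_table(rows, kinds={"v": "numeric"})
    cutset = md_select_cuts(dt)
    assert cutset.cuts["v"] == [5.0]


def _discerns_all(cut_subset, dt):
    recs, dec = dt.records, [r["d"] for r in dt.records]
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            if dec[i] == dec[j]:
                continue
            if not any(
                (recs[i][a] < c) != (recs[j][a] < c) for a, c in cut_subset
            ):
                return False
    return True


def test_md_matches_bruteforce_minimum():
    """Greedy cut set discerns everything with the brute-force minimum
    number of cuts on a small two-attribute table."""
    rows = [
        {"x": 1.0, "y": 10.0, "d": "a"},
        {"x": 2.0, "y": 30.0, "d": "b"},
        {"x": 5.0, "y": 12.0, "d": "b"},
        {"x": 6.0, "y": 28.0, "d": "a"},
        {"x": 9.0, "y": 11.0, "d": "a"},
        {"x": 10.0, "y": 29.0, "d": "b"},
    ]
    dt = make_table(rows, kinds={"x": "numeric", "y": "numeric"})
    pool = [("x", c) for c in candidate_cuts(dt, "x")] + [
        ("y", c) for c in candidate_cuts(dt, "y")
    ]
    best = None
    for size in range(1, len(pool) + 1):
        for combo in combinations(pool, size):
            if _discerns_all(combo, dt):
                best = combo
                break
        if best:
            break
    chosen = md_select_cuts(dt)
    n_chosen = sum(len(v) for v in chosen.cuts.values())
    assert _discerns_all(
        [(a, c) for a, cs in chosen.cuts.items() for c in cs], dt
    )
    assert n_chosen == len(best)


def test_equal_frequency_cuts():
    dt = make_table([{"v": float(v), "d": "x"} for v in range(1, 9)],
                    kinds={"v": "numeric"})
    assert equal_frequency_cuts(dt, "v", 4) == [2.5, 4.5, 6.5]


def test_equal_frequency_constant_column_warns():
    dt = make_table([{"v": 3.0, "d": "x"}] * 4, kinds={"v": "numeric"})
    with pytest.warns(UserWarning):
        assert equal_frequency_cuts(dt, "v", 2) == []


def test_equal_frequency_median_cut(extract_dt):
    cuts = equal_frequency_cuts(extract_dt, "SccLat", 2)
    assert len(cuts) == 1 and 227 < cuts[0] < 285


def test_apply_cuts_star_and_missing():
    rows = [
        {"v": 1.0, "w": MISSING, "d": "a"},
        {"v": 9.0, "w": 2.0, "d": "b"},
    ]
    dt = make_table(rows, kinds={"v": "numeric", "w": "numeric"})
    disc = apply_cuts(dt, CutSet(cuts={"v": [5.0], "w": []}))
    assert disc.records[0]["w"] == STAR  # starred attrs carry * everywhere
    disc2 = apply_cuts(dt, CutSet(cuts={"v": [5.0], "w": [1.5]}))
    assert disc2.records[0]["w"] is MISSING  # MISSING propagates


def test_empty_cutset_collapses_to_one_granule(extract_dt):
    cutset = CutSet(cuts={n: [] for n in extract_dt.condition_names
                          if extract_dt.base.attribute(n).kind == "numeric"},
                    excluded={"Pat", "sex", "Sess"})
    disc = apply_cuts(extract_dt, cutset, EXTRACT_DECISION_CUTS)
    assert all(
        rec[a] == STAR for rec in disc.records for a in disc.condition_names
    )
    assert len(partition(disc, disc.condition_names)) == 1


def test_bracket_dialect():
    assert interval_label(30.0, [25.0, 40.0, 55.0], "bracket", 6, 94) == "(25, 40]"
    assert interval_label(6.0, [25.0, 40.0, 55.0], "bracket", 6, 94) == "[6, 25]"
    assert interval_label(60.0, [25.0, 40.0, 55.0], "bracket", 6, 94) == "(55, 94]"


def test_boundary_value_goes_to_upper_interval():
    assert value_bin(55.0, [55.0]) == 1
    assert interval_label(55.0, [55.0]) == "(55.0, Inf)"


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(-100, 100), min_size=2, max_size=6, unique=True),
       st.floats(-100, 100), st.floats(-100, 100))
def test_labelling_is_monotone(cuts, v1, v2):
    cuts = sorted(cuts)
    if v1 > v2:
        v1, v2 = v2, v1
    assert value_bin(v1, cuts) <= value_bin(v2, cuts)
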