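"""Cut generation and interval labelling for decision tables.

Two discretizers are provided:

* :func:`md_select_cuts` — supervised, maximal-discernibility style: a
  greedy loop keeps choosing the candidate cut that separates ("discerns")
  the largest number of still-confused object pairs with different
  decisions, until no cut helps.  Numeric condition attributes that end
  up with no cuts are *starred* (dropped as not significant); nominal
  condition attributes pass through unchanged.
* :func:`equal_frequency_cuts` — unsupervised quantile binning.

Labelling convention: a value equal to a cut falls in the upper interval
(half-open ``[c_i, c_{i+1})`` bins).  Two rendering dialects are
supported: ``rses`` prints ``(−Inf, 55.0)`` / ``(55.0, Inf)`` (with the
typographic minus), ``bracket`` prints data-bounded ``[6, 25]`` /
``(25, 40]`` labels.
"""

from __future__ import annotations

import json
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .tables import MISSING, DecisionTable, InformationTable

__all__ = [
    "STAR",
    "CutSet",
    "DiscretizedTable",
    "candidate_cuts",
    "md_select_cuts",
    "equal_frequency_cuts",
    "apply_cuts",
    "render_interval",
    "value_bin",
]

STAR = "*"

_MINUS = "−"  # typographic minus used in printed interval labels


def _fmt_rses(x: float) -> str:
    return str(float(x))


def _fmt_bracket(x: float) -> str:
    return str(int(x)) if float(x) == int(x) else str(float(x))


def value_bin(v: float, cuts: Sequence[float]) -> int:
    """Bin index of ``v`` under sorted ``cuts`` (v == cut -> upper bin)."""
    return bisect_right(list(cuts), v)


def render_interval(
    i: int,
    cuts: Sequence[float],
    dialect: str = "rses",
    lo: float | None = None,
    hi: float | None = None,
) -> str:
    """Render bin ``i`` of ``cuts`` in the requested dialect."""
    cuts = list(cuts)
    if dialect == "rses":
        left = f"{_MINUS}Inf" if i == 0 else _fmt_rses(cuts[i - 1])
        right = "Inf" if i == len(cuts) else _fmt_rses(cuts[i])
        return f"({left}, {right})"
    if dialect == "bracket":
        if lo is None or hi is None:
            raise ValueError("bracket dialect needs observed lo/hi bounds")
        if i == 0:
            right = _fmt_bracket(cuts[0]) if cuts else _fmt_bracket(hi)
            return f"[{_fmt_bracket(lo)}, {right}]"
        right = _fmt_bracket(hi) if i == len(cuts) else _fmt_bracket(cuts[i])
        return f"({_fmt_bracket(cuts[i - 1])}, {right}]"
    raise ValueError(f"unknown dialect {dialect!r}")


def interval_label(
    v: float,
    cuts: Sequence[float],
    dialect: str = "rses",
    lo: float | None = None,
    hi: float | None = None,
) -> str:
    return render_interval(value_bin(v, cuts), cuts, dialect, lo, hi)


@dataclass
class CutSet:
    """Selected cuts per numeric attribute plus excluded nominals.

    ``cuts[a]`` is a strictly increasing (possibly empty) sequence; a
    numeric attribute with an empty sequence is *starred*.  Nominal
    condition attributes are kept unless listed in ``excluded``.
    """

    cuts: dict[str, list[float]] = field(default_factory=dict)
    excluded: set[str] = field(default_factory=set)

    def starred(self, numeric_names: Sequence[str] | None = None) -> set[str]:
        out = {a for a, cs in self.cuts.items() if not cs}
        out |= set(self.excluded)
        return out

    def to_json(self) -> str:
        obj: dict[str, object] = {a: cs if cs else STAR for a, cs in self.cuts.items()}
        for a in sorted(self.excluded):
            obj[a] = STAR
        return json.dumps(obj, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CutSet":
        raw = json.loads(text)
        cs = cls()
        for a, v in raw.items():
            if v == STAR:
                cs.cuts[a] = []
            else:
                cs.cuts[a] = [float(x) for x in v]
        return cs

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")


def _decision_classes(dt: DecisionTable, decision_cuts: Sequence[float] | None):
    """Per-object decision class (bin index for a cut-binned numeric
    decision, otherwise the raw decision value)."""
    spec = dt.base.attribute(dt.decision)
    col = dt.base.column(dt.decision)
    if spec.kind == "numeric" and decision_cuts:
        return [value_bin(v, decision_cuts) for v in col]
    return list(col)


def candidate_cuts(
    dt: DecisionTable,
    attr: str,
    decision_cuts: Sequence[float] | None = None,
) -> list[float]:
    """Boundary-point candidates: midpoints between consecutive distinct
    values whose value-groups carry differing decision classes."""
    spec = dt.base.attribute(attr)
    if spec.kind != "numeric":
        raise ValueError(f"{attr!r} is not numeric")
    dec = _decision_classes(dt, decision_cuts)
    groups: dict[float, set] = {}
    for rec, d in zip(dt.records, dec):
        v = rec[attr]
        if v is MISSING:
            continue
        groups.setdefault(v, set()).add(d)
    values = sorted(groups)
    out = []
    for a, b in zip(values, values[1:]):
        ga, gb = groups[a], groups[b]
        if len(ga) > 1 or len(gb) > 1 or ga != gb:
            out.append((a + b) / 2.0)
    return out


def md_select_cuts(
    dt: DecisionTable,
    decision_cuts: Sequence[float] | None = None,
) -> CutSet:
    """Greedy maximal-discernibility cut selection over the numeric
    condition attributes.

    At each step the candidate cut discerning the most not-yet-discerned
    object pairs with different decisions is taken (ties: schema order,
    then smaller cut).  The loop stops when every such pair separable by
    some cut has been discerned or no candidate adds discernment.
    """
    names = [n for n in dt.condition_names if dt.base.attribute(n).kind == "numeric"]
    dec = _decision_classes(dt, decision_cuts)
    n = len(dt)
    # pairs with differing decisions, encoded as a bitmask over pair index
    pairs = [
        (i, j) for i in range(n) for j in range(i + 1, n) if dec[i] != dec[j]
    ]
    pair_index = {p: k for k, p in enumerate(pairs)}
    remaining = (1 << len(pairs)) - 1

    candidates: list[tuple[int, float, str, int]] = []  # (attr order, cut, name, mask)
    for order, name in enumerate(names):
        col = dt.base.column(name)
        for cut in candidate_cuts(dt, name, decision_cuts):
            mask = 0
            for (i, j), k in pair_index.items():
                vi, vj = col[i], col[j]
                if vi is MISSING or vj is MISSING:
                    continue
                if (vi < cut) != (vj < cut):
                    mask |= 1 << k
            if mask:
                candidates.append((order, cut, name, mask))

    selected = CutSet(cuts={name: [] for name in names})
    candidates.sort(key=lambda c: (c[0], c[1]))  # tie-break: schema order, then cut
    while remaining:
        best = None
        best_gain = 0
        for cand in candidates:
            gain = (cand[3] & remaining).bit_count()
            if gain > best_gain:
                best, best_gain = cand, gain
        if best is None or best_gain == 0:
            break
        remaining &= ~best[3]
        selected.cuts[best[2]].append(best[1])
        candidates.remove(best)
    for name in names:
        selected.cuts[name].sort()
    return selected


def equal_frequency_cuts(
    table: InformationTable | DecisionTable,
    attr: str,
    k: int,
) -> list[float]:
    """``k-1`` quantile cuts splitting the observed values into (near)
    equal-count bins; duplicates collapse with a warning."""
    if k < 2:
        raise ValueError("k must be >= 2")
    base = table.base if isinstance(table, DecisionTable) else table
    values = sorted(v for v in base.column(attr) if v is not MISSING)
    n = len(values)
    if len(set(values)) < k:
        warnings.warn(f"{attr!r}: fewer distinct values than {k} bins; reducing")
    cuts: list[float] = []
    for j in range(1, k):
        idx = round(j * n / k)
        if 0 < idx < n and values[idx - 1] != values[idx]:
            c = (values[idx - 1] + values[idx]) / 2.0
            if not cuts or c > cuts[-1]:
                cuts.append(c)
    return cuts


class DiscretizedTable:
    """A decision table with interval-labelled conditions.

    Per-object labels: nominal condition -> raw value; numeric condition
    with cuts -> rendered interval; starred attribute -> ``"*"``; MISSING
    propagates.  The decision is binned by its own cuts when numeric.
    """

    def __init__(
        self,
        base: DecisionTable,
        cutset: CutSet,
        decision_cuts: Sequence[float] | None = None,
        dialect: str = "rses",
    ):
        self.base = base
        self.cutset = cutset
        self.decision_cuts = list(decision_cuts) if decision_cuts else []
        self.dialect = dialect
        self.decision = base.decision
        self.ids = list(base.ids)
        self._bounds = {}
        for name in base.base.names:
            spec = base.base.attribute(name)
            if spec.kind == "numeric":
                vals = [v for v in base.base.column(name) if v is not MISSING]
                self._bounds[name] = (min(vals), max(vals)) if vals else (0.0, 0.0)
        self.records: list[dict] = [self._label_record(rec) for rec in base.records]

    def _label_value(self, name: str, v):
        spec = self.base.base.attribute(name)
        if name == self.decision:
            if spec.kind == "numeric" and self.decision_cuts:
                lo, hi = self._bounds[name]
                return interval_label(v, self.decision_cuts, self.dialect, lo, hi)
            return v
        if name in self.cutset.excluded:
            return STAR
        if spec.kind == "nominal":
            return v
        cuts = self.cutset.cuts.get(name)
        if cuts is None:
            raise ValueError(f"no cuts defined for numeric condition {name!r}")
        if not cuts:
            return STAR  # starred attribute: every object carries "*"
        if v is MISSING:
            return MISSING
        lo, hi = self._bounds[name]
        return interval_label(v, cuts, self.dialect, lo, hi)

    def _label_record(self, rec: dict) -> dict:
        out = {}
        for name in self.condition_names + [self.decision]:
            v = rec[name]
            if v is MISSING and self.base.base.attribute(name).kind == "nominal":
                out[name] = MISSING
            else:
                out[name] = self._label_value(name, v)
        return out

    @property
    def condition_names(self) -> list[str]:
        return self.base.condition_names

    @property
    def active_names(self) -> list[str]:
        """Condition attributes that survived starring."""
        starred = self.cutset.starred()
        return [n for n in self.condition_names if n not in starred]

    def __len__(self) -> int:
        return len(self.base)

    def subset(self, keep_ids) -> "DiscretizedTable":
        sub = DiscretizedTable.__new__(DiscretizedTable)
        sub.base = self.base.subset(keep_ids)
        sub.cutset = self.cutset
        sub.decision_cuts = self.decision_cuts
        sub.dialect = self.dialect
        sub.decision = self.decision
        sub.ids = list(sub.base.ids)
        sub._bounds = self._bounds
        keep = set(sub.ids)
        sub.records = [r for oid, r in zip(self.ids, self.records) if oid in keep]
        return sub

    def record_for(self, oid: int) -> dict:
        return self.records[self.ids.index(oid)]

    def label_row(self, rec: dict) -> dict:
        """Label an out-of-table raw record with this table's cuts."""
        return self._label_record(rec)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        cols = self.condition_names + [self.decision]
        rows = [
            {c: ("MISSING" if r[c] is MISSING else r[c]) for c in cols}
            for r in self.records
        ]
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def apply_cuts(
    dt: DecisionTable,
    cutset: CutSet,
    decision_cuts: Sequence[float] | None = None,
    dialect: str = "rses",
) -> DiscretizedTable:
    """Label every object of ``dt`` under ``cutset`` (and bin a numeric
    decision by ``decision_cuts``)."""
    return DiscretizedTable(dt, cutset, decision_cuts, dialect)
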