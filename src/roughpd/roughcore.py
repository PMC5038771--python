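"""Indiscernibility, granules, approximations, dependency and reducts.

For an attribute subset ``B`` the indiscernibility relation IND(B)
groups objects with identical values on every attribute of B; its
equivalence classes are the B-elementary granules.  A concept
``X ⊆ U`` is approximated from below by the union of granules wholly
inside X and from above by the union of granules meeting X; the
difference is the boundary region (X is rough iff it is nonempty).

A *reduct* is a minimal attribute subset preserving the positive region
of the full condition set.  Exhaustive reducts are computed as minimal
hitting sets of the discernibility matrix; a greedy forward/backward
variant scales to wider tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .tables import MISSING, DecisionTable
from .discretize import DiscretizedTable

__all__ = [
    "Granule",
    "Approximation",
    "Reduct",
    "partition",
    "approximate",
    "positive_region",
    "dependency",
    "discernibility_matrix",
    "reducts_exhaustive",
    "reduct_greedy",
    "approximation_report",
    "reducts_report",
    "CapacityError",
]

Table = DecisionTable | DiscretizedTable

MAX_EXHAUSTIVE_ATTRS = 20


class CapacityError(RuntimeError):
    """Raised when exhaustive reduct search would be intractable."""


@dataclass
class Granule:
    """One IND(B)-equivalence class: shared signature plus its members."""

    attributes: tuple[str, ...]
    signature: dict
    members: frozenset[int]


@dataclass
class Approximation:
    concept: frozenset[int]
    lower: frozenset[int]
    upper: frozenset[int]

    @property
    def boundary(self) -> frozenset[int]:
        return self.upper - self.lower

    @property
    def crisp(self) -> bool:
        return not self.boundary


@dataclass
class Reduct:
    attributes: tuple[str, ...]
    kind: str = "exhaustive"


def _records(table: Table) -> list[dict]:
    return table.records


def _all_names(table: Table) -> list[str]:
    return table.condition_names + [table.decision]


def partition(table: Table, B: Sequence[str]) -> list[Granule]:
    """B-elementary granules of the table (empty B -> one granule).

    MISSING equals only MISSING, so IND stays an equivalence relation.
    """
    valid = set(_all_names(table))
    for name in B:
        if name not in valid:
            raise KeyError(f"unknown attribute {name!r}")
    groups: dict[tuple, list[int]] = {}
    for oid, rec in zip(table.ids, _records(table)):
        key = tuple(rec[a] for a in B)
        groups.setdefault(key, []).append(oid)
    out = []
    for key, members in groups.items():
        out.append(Granule(tuple(B), dict(zip(B, key)), frozenset(members)))
    return out


def approximate(table: Table, B: Sequence[str], X: Iterable[int]) -> Approximation:
    """Lower/upper approximation of concept X under IND(B)."""
    X = frozenset(X)
    unknown = X - set(table.ids)
    if unknown:
        raise KeyError(f"object ids not in table: {sorted(unknown)}")
    lower: set[int] = set()
    upper: set[int] = set()
    for g in partition(table, B):
        if g.members <= X:
            lower |= g.members
        if g.members & X:
            upper |= g.members
    return Approximation(X, frozenset(lower), frozenset(upper))


def positive_region(table: Table, B: Sequence[str]) -> frozenset[int]:
    """Union of lower approximations of the decision classes."""
    classes: dict[object, set[int]] = {}
    for oid, rec in zip(table.ids, _records(table)):
        classes.setdefault(rec[table.decision], set()).add(oid)
    pos: set[int] = set()
    for X in classes.values():
        pos |= approximate(table, B, X).lower
    return frozenset(pos)


def dependency(table: Table, B: Sequence[str]) -> float:
    """Degree to which B determines the decision: |POS_B| / |U|."""
    n = len(table.ids)
    return len(positive_region(table, B)) / n if n else 0.0


def discernibility_matrix(table: Table) -> list[frozenset[str]]:
    """Distinct attribute sets distinguishing object pairs that carry
    different decisions.  Pairs distinguished by no condition attribute
    (genuine inconsistencies) are omitted."""
    names = table.condition_names
    recs = _records(table)
    dec = [r[table.decision] for r in recs]
    entries: set[frozenset[str]] = set()
    n = len(recs)
    for i in range(n):
        for j in range(i + 1, n):
            if dec[i] == dec[j]:
                continue
            diff = frozenset(a for a in names if recs[i][a] != recs[j][a])
            if diff:
                entries.add(diff)
    return sorted(entries, key=lambda s: (len(s), sorted(s)))


def _hits_all(subset: frozenset[str], entries: list[frozenset[str]]) -> bool:
    return all(subset & e for e in entries)


def reducts_exhaustive(table: Table) -> list[Reduct]:
    """All minimal attribute subsets preserving the positive region,
    via minimal hitting sets of the discernibility matrix."""
    names = table.condition_names
    if len(names) > MAX_EXHAUSTIVE_ATTRS:
        raise CapacityError(
            f"{len(names)} condition attributes exceeds the exhaustive limit "
            f"({MAX_EXHAUSTIVE_ATTRS}); use reduct_greedy"
        )
    entries = discernibility_matrix(table)
    if not entries:
        return [Reduct((), "exhaustive")]
    found: list[frozenset[str]] = []
    for size in range(1, len(names) + 1):
        for combo in combinations(names, size):
            s = frozenset(combo)
            if any(prev <= s for prev in found):
                continue
            if _hits_all(s, entries):
                found.append(s)
    # subset-minimality is enforced during the size-ordered search
    order = {n: i for i, n in enumerate(names)}
    reducts = [
        Reduct(tuple(sorted(f, key=order.get)), "exhaustive") for f in found
    ]
    reducts.sort(key=lambda r: (len(r.attributes), [order[a] for a in r.attributes]))
    return reducts


def approximation_report(table: Table, B: Sequence[str]) -> dict:
    """JSON-ready report of the decision classes' approximations and
    the dependency of B."""
    classes: dict[object, set[int]] = {}
    for oid, rec in zip(table.ids, _records(table)):
        classes.setdefault(rec[table.decision], set()).add(oid)
    report = {"attributes": list(B), "dependency": dependency(table, B),
              "classes": []}
    for label, X in classes.items():
        ap = approximate(table, B, X)
        report["classes"].append(
            {
                "decision": str(label),
                "concept": sorted(ap.concept),
                "lower": sorted(ap.lower),
                "upper": sorted(ap.upper),
                "boundary": sorted(ap.boundary),
                "crisp": ap.crisp,
            }
        )
    return report


def reducts_report(table: Table) -> list[dict]:
    """JSON-ready listing of all exhaustive reducts with dependencies."""
    return [
        {
            "attributes": list(r.attributes),
            "kind": r.kind,
            "dependency": dependency(table, list(r.attributes)),
        }
        for r in reducts_exhaustive(table)
    ]


def reduct_greedy(table: Table) -> Reduct:
    """Greedy forward cover of the discernibility matrix, then backward
    pruning.

    Dependency gain alone can stall (it is not submodular: a pair may
    need two attributes before either shows a gain), so the forward pass
    instead adds the attribute hitting the most still-unhit
    discernibility entries — covering all entries restores the
    full-condition positive region.  The result preserves the
    full-condition dependency and is superset-minimal."""
    names = table.condition_names
    target = dependency(table, names)
    entries = discernibility_matrix(table)
    unhit = list(entries)
    chosen: list[str] = []
    while unhit:
        best, best_hits = None, 0
        for a in names:
            if a in chosen:
                continue
            hits = sum(1 for e in unhit if a in e)
            if hits > best_hits:
                best, best_hits = a, hits
        if best is None:
            break
        chosen.append(best)
        unhit = [e for e in unhit if best not in e]
    for a in list(chosen):
        trimmed = [x for x in chosen if x != a]
        if dependency(table, trimmed) >= target:
            chosen = trimmed
    order = {n: i for i, n in enumerate(names)}
    return Reduct(tuple(sorted(chosen, key=order.get)), "greedy")
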