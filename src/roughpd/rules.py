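"""Decision-rule induction, rule voting, templates and decomposition trees.

Every row of a discretized decision table proposes a conjunctive rule

    (‘Pat’ = 38) & (‘age’ = “(55.0, Inf)”) & ... => (‘UPDRS’ = “(−Inf, 14.0)”)

read as: *if* the object satisfies every descriptor on the left *then*
its decision is the label on the right.  Identical antecedents merge;
an antecedent matched by objects of several decision classes yields one
rule per class, each carrying its empirical confidence.  A rule set
classifies by weighted voting among matching rules and *abstains* on
objects no rule matches — abstention defines coverage, and accuracy is
always measured on covered objects only.

A decomposition tree splits the training objects recursively by the
best *template* (attribute = label descriptor): each internal node
routes an object by whether it matches the template, each leaf carries
the rules induced from its own objects.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

from .tables import MISSING, DecisionTable
from .discretize import STAR, DiscretizedTable

__all__ = [
    "ABSTAIN",
    "DecisionRule",
    "Template",
    "TreeNode",
    "DecompositionTree",
    "induce_rules",
    "local_rules",
    "reduct_rules",
    "classify",
    "format_rule",
    "parse_rule",
    "best_template",
    "build_tree",
    "classify_tree",
    "save_rules",
]


class _Abstain:
    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "ABSTAIN"


#: Returned when no rule matches an object (the object is uncovered).
ABSTAIN = _Abstain()

_LQ, _RQ = "‘", "’"  # ‘ ’
_LDQ, _RDQ = "“", "”"  # “ ”


@dataclass
class DecisionRule:
    antecedent: dict  # attribute -> required label, in schema order
    consequent: object  # decision label
    decision: str
    support: int = 1
    confidence: float = 1.0

    def matches(self, labels: dict) -> bool:
        return all(labels.get(a) == v for a, v in self.antecedent.items())


@dataclass
class Template:
    descriptors: tuple[tuple[str, object], ...]
    fitness: int

    def matches(self, labels: dict) -> bool:
        return all(labels.get(a) == v for a, v in self.descriptors)


@dataclass
class TreeNode:
    template: Template | None = None
    match: "TreeNode | None" = None
    no_match: "TreeNode | None" = None
    object_ids: frozenset[int] = frozenset()
    rules: list[DecisionRule] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.template is None


@dataclass
class DecompositionTree:
    root: TreeNode
    min_leaf: int

    def leaves(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.no_match, node.match])
        return out


def _rule_attrs(table: DecisionTable | DiscretizedTable, attrs) -> list[str]:
    if attrs is not None:
        return list(attrs)
    if isinstance(table, DiscretizedTable):
        return table.active_names
    return table.condition_names


def induce_rules(
    table: DecisionTable | DiscretizedTable,
    attrs: Sequence[str] | None = None,
) -> list[DecisionRule]:
    """One rule per distinct antecedent pattern (and per decision label
    for inconsistent patterns); support/confidence by recount."""
    attrs = _rule_attrs(table, attrs)
    groups: dict[tuple, dict] = {}
    for rec in table.records:
        ante = {
            a: rec[a]
            for a in attrs
            if rec[a] is not MISSING and rec[a] != STAR
        }
        key = tuple(ante.items())
        g = groups.setdefault(key, {"ante": ante, "decisions": {}})
        d = rec[table.decision]
        g["decisions"][d] = g["decisions"].get(d, 0) + 1
    rules: list[DecisionRule] = []
    for g in groups.values():
        ante = g["ante"]
        matching = [r for r in table.records if all(r.get(a) == v for a, v in ante.items())]
        support = len(matching)
        counts: dict[object, int] = {}
        for r in matching:
            counts[r[table.decision]] = counts.get(r[table.decision], 0) + 1
        for d in g["decisions"]:
            rules.append(
                DecisionRule(
                    antecedent=dict(ante),
                    consequent=d,
                    decision=table.decision,
                    support=support,
                    confidence=counts[d] / support,
                )
            )
    return rules


def local_rules(
    table: DecisionTable | DiscretizedTable,
    attrs: Sequence[str] | None = None,
    objects: Sequence[int] | None = None,
    max_length: int = 6,
) -> list[DecisionRule]:
    """Minimal certain rules via object-related reducts.

    For each described object the minimal attribute subsets are found
    whose projection discerns it from *every* object of a different
    decision class in the table; each such subset yields one rule (the
    object's projection on it).  Objects with an indiscernible
    differently-labelled twin fall back to their full-row pattern with
    confidence below 1.  Support and confidence are recounted over the
    whole table; duplicate rules merge.

    ``objects`` restricts which objects contribute rules (used by the
    decomposition tree: leaf objects against the full training table);
    ``max_length`` caps the antecedent search.
    """
    attrs = _rule_attrs(table, attrs)
    nbits = len(attrs)
    rows = [tuple(rec[a] for a in attrs) for rec in table.records]
    dec = [rec[table.decision] for rec in table.records]
    n = len(rows)
    id_pos = {oid: k for k, oid in enumerate(table.ids)}
    describe = range(n) if objects is None else [id_pos[o] for o in objects]

    def recount(ante: dict, d):
        matching = [
            k for k in range(n)
            if all(rows[k][attrs.index(a)] == v for a, v in ante.items())
        ]
        sup = len(matching)
        conf = sum(1 for k in matching if dec[k] == d) / sup
        return sup, conf

    seen: dict[tuple, DecisionRule] = {}

    def emit(ante: dict, d):
        key = (tuple(ante.items()), d)
        if key in seen:
            return
        sup, conf = recount(ante, d)
        seen[key] = DecisionRule(dict(ante), d, table.decision, sup, conf)

    for i in describe:
        entries = []
        inconsistent = False
        for j in range(n):
            if dec[j] == dec[i]:
                continue
            mask = 0
            for b in range(nbits):
                if rows[i][b] != rows[j][b]:
                    mask |= 1 << b
            if mask == 0:
                inconsistent = True
                break
            entries.append(mask)
        full_ante = {
            a: rows[i][b]
            for b, a in enumerate(attrs)
            if rows[i][b] != STAR
        }
        if inconsistent or not entries:
            # boundary object (or single-class table): full-row pattern
            emit(full_ante, dec[i])
            continue
        found: list[int] = []
        for size in range(1, min(nbits, max_length) + 1):
            for combo in combinations(range(nbits), size):
                m = 0
                for b in combo:
                    m |= 1 << b
                if any(f & m == f for f in found):
                    continue
                if all(m & e for e in entries):
                    found.append(m)
        if not found:
            emit(full_ante, dec[i])
            continue
        for m in found:
            ante = {
                a: rows[i][b]
                for b, a in enumerate(attrs)
                if (m >> b) & 1 and rows[i][b] != STAR
            }
            emit(ante, dec[i])
    return list(seen.values())


def reduct_rules(
    table: DecisionTable | DiscretizedTable,
    reducts: Sequence[Sequence[str]] | None = None,
) -> list[DecisionRule]:
    """Rules from row projections onto (all exhaustive) reducts.

    Each training row, projected onto each reduct, proposes one rule;
    identical rules merge.  Antecedents span a whole reduct, so a test
    object is covered only when it reproduces a training row's complete
    reduct signature — the classifier abstains otherwise.  This is the
    default classifier's rule set; pass precomputed ``reducts`` (e.g.
    those of the full training table) to reuse them on a subtable.
    """
    if reducts is None:
        from .roughcore import reducts_exhaustive

        reducts = [r.attributes for r in reducts_exhaustive(table)]
    seen: dict[tuple, DecisionRule] = {}
    for attrs in reducts:
        for rule in induce_rules(table, list(attrs)):
            key = (tuple(rule.antecedent.items()), rule.consequent)
            if key not in seen:
                seen[key] = rule
    return list(seen.values())


def classify(
    rules: Sequence[DecisionRule],
    labels: dict,
    scheme: str = "weighted",
):
    """Vote among matching rules; weight = support x confidence
    (``scheme="simple"``: one rule, one vote).  Ties go to the label with
    larger total support, then first-seen order; no match -> ABSTAIN."""
    votes: dict[object, float] = {}
    supports: dict[object, int] = {}
    order: dict[object, int] = {}
    for idx, rule in enumerate(rules):
        if not rule.matches(labels):
            continue
        w = 1.0 if scheme == "simple" else rule.support * rule.confidence
        votes[rule.consequent] = votes.get(rule.consequent, 0.0) + w
        supports[rule.consequent] = supports.get(rule.consequent, 0) + rule.support
        order.setdefault(rule.consequent, idx)
    if not votes:
        return ABSTAIN
    return max(votes, key=lambda d: (votes[d], supports[d], -order[d]))


# -- rendering -----------------------------------------------------------

def _fmt_value(v) -> str:
    s = str(v)
    if s and s[0] in "([":  # interval label
        return f"{_LDQ}{s}{_RDQ}"
    return s


def format_rule(rule: DecisionRule) -> str:
    """Render a rule in the conjunctive descriptor syntax with curly
    quotes, e.g. ``(‘Pat’ = 38) & ... => (‘UPDRS’ = “(−Inf, 14.0)”)``."""
    parts = [
        f"({_LQ}{a}{_RQ} = {_fmt_value(v)})" for a, v in rule.antecedent.items()
    ]
    head = " & ".join(parts)
    tail = f"=> ({_LQ}{rule.decision}{_RQ} = {_fmt_value(rule.consequent)})"
    return f"{head} {tail}" if head else tail


_DESC_RE = re.compile(
    rf"\({_LQ}(?P<attr>[^{_RQ}]+){_RQ} = (?:{_LDQ}(?P<interval>[^{_RDQ}]+){_RDQ}|(?P<bare>[^)]+))\)"
)


def parse_rule(text: str) -> DecisionRule:
    """Inverse of :func:`format_rule` on antecedent and consequent
    (support/confidence are not part of the textual form)."""
    if "=>" not in text:
        raise ValueError("not a rule: missing '=>'")
    head, tail = text.split("=>", 1)
    def descs(chunk):
        return [
            (m.group("attr"), m.group("interval") or m.group("bare"))
            for m in _DESC_RE.finditer(chunk)
        ]
    ante = descs(head)
    cons = descs(tail)
    if len(cons) != 1:
        raise ValueError("rule must have exactly one consequent descriptor")
    return DecisionRule(
        antecedent=dict(ante),
        consequent=cons[0][1],
        decision=cons[0][0],
    )


def save_rules(rules: Sequence[DecisionRule], path: str | Path) -> None:
    """One formatted rule per line, plus a JSON sidecar with counts."""
    path = Path(path)
    path.write_text("\n".join(format_rule(r) for r in rules) + "\n", encoding="utf-8")
    side = [
        dict(
            rule=format_rule(r),
            support=r.support,
            confidence=r.confidence,
        )
        for r in rules
    ]
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(side, indent=1, ensure_ascii=False), encoding="utf-8"
    )


# -- templates and the decomposition tree --------------------------------

def best_template(
    table: DiscretizedTable,
    pool: Sequence[tuple[str, object]] | None = None,
) -> Template | None:
    """Highest-fitness template that splits the objects into two
    nonempty parts.

    Fitness (match count) can only shrink as descriptors are added, so
    the greedy conjunction growth stops at a single descriptor; ties are
    broken by fewer descriptors, then schema order, then label.  Returns
    None when no descriptor splits the node (all rows identical)."""
    attrs = table.active_names
    if pool is None:
        pool = []
        seen = set()
        for rec in table.records:
            for a in attrs:
                v = rec[a]
                if v is MISSING or v == STAR:
                    continue
                if (a, v) not in seen:
                    seen.add((a, v))
                    pool.append((a, v))
    n = len(table)
    order = {a: i for i, a in enumerate(table.condition_names)}
    best: Template | None = None
    for a, v in pool:
        fit = sum(1 for rec in table.records if rec.get(a) == v)
        if not 0 < fit < n:
            continue
        cand = Template(((a, v),), fit)
        if best is None or fit > best.fitness or (
            fit == best.fitness
            and (order[a], str(v)) < (order[best.descriptors[0][0]], str(best.descriptors[0][1]))
        ):
            best = cand
    return best


def build_tree(table: DiscretizedTable, min_leaf: int = 3) -> DecompositionTree:
    """Recursive binary decomposition by best templates.

    Leaf rules are the leaf rows projected onto the reducts of the full
    training table, so with ``min_leaf >= |U|`` the single leaf carries
    exactly the flat :func:`reduct_rules` classifier."""
    if min_leaf < 1:
        raise ValueError("min_leaf must be >= 1")
    from .roughcore import reducts_exhaustive

    reducts = [r.attributes for r in reducts_exhaustive(table)]

    def leaf(sub: DiscretizedTable) -> TreeNode:
        return TreeNode(
            object_ids=frozenset(sub.ids),
            rules=reduct_rules(sub, reducts),
        )

    def grow(sub: DiscretizedTable) -> TreeNode:
        if len(sub) <= min_leaf:
            return leaf(sub)
        tpl = best_template(sub)
        if tpl is None:
            return leaf(sub)
        match_ids = [oid for oid, rec in zip(sub.ids, sub.records) if tpl.matches(rec)]
        rest_ids = [oid for oid in sub.ids if oid not in set(match_ids)]
        node = TreeNode(template=tpl)
        node.match = grow(sub.subset(match_ids))
        node.no_match = grow(sub.subset(rest_ids))
        node.object_ids = frozenset(sub.ids)
        return node

    return DecompositionTree(grow(table), min_leaf)


def classify_tree(tree: DecompositionTree, labels: dict, scheme: str = "weighted"):
    """Route an object down the tree by template matches, then vote
    among the reached leaf's rules (ABSTAIN if none match)."""
    node = tree.root
    while not node.is_leaf:
        node = node.match if node.template.matches(labels) else node.no_match
    return classify(node.rules, labels, scheme)
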