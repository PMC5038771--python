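"""Native reference classifiers for the comparison experiments.

Four families, mirroring the usual small-data tabular baselines: a
categorical naive Bayes (default probability 0 for unseen values, at
most 20 nominal values per attribute), a gini decision tree (multiway
splits on the discretized labels, minimum node size 2, no pruning), a
majority decision table (greedy attribute-subset lookup with majority
fallback), and a bagged tree ensemble (100 trees, per-node square-root
attribute sampling, bootstrap rows, majority vote).

Unlike the rule/tree rough-set classifiers these never abstain: their
coverage is always 1, so their accuracy is accuracy-on-all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tables import MISSING
from .discretize import STAR, DiscretizedTable

__all__ = ["BaselineSpec", "train", "predict", "KINDS"]

KINDS = ("naive-bayes", "decision-tree", "decision-table-majority", "tree-ensemble")


@dataclass
class BaselineSpec:
    kind: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown baseline kind {self.kind!r}")
        allowed = {
            "naive-bayes": {"max_nominal"},
            "decision-tree": {"min_node"},
            "decision-table-majority": set(),
            "tree-ensemble": {"n_trees", "min_node"},
        }[self.kind]
        bad = set(self.hyperparameters) - allowed
        if bad:
            raise ValueError(f"invalid hyperparameters for {self.kind}: {sorted(bad)}")

    @classmethod
    def from_dict(cls, spec: dict) -> "BaselineSpec":
        extra = {k: v for k, v in spec.items() if k not in ("kind", "vote")}
        return cls(spec["kind"], extra)


def _training_data(table: DiscretizedTable):
    attrs = table.active_names
    X = [{a: rec[a] for a in attrs} for rec in table.records]
    y = [rec[table.decision] for rec in table.records]
    classes: list = []
    for lab in y:
        if lab not in classes:
            classes.append(lab)
    return attrs, X, y, classes


def _majority(y: Sequence, classes: Sequence):
    counts = {c: 0 for c in classes}
    for lab in y:
        counts[lab] = counts.get(lab, 0) + 1
    return max(classes, key=lambda c: counts.get(c, 0))


# -- naive Bayes ---------------------------------------------------------

class _NaiveBayes:
    def __init__(self, table: DiscretizedTable, max_nominal: int = 20):
        attrs, X, y, classes = _training_data(table)
        for a in attrs:
            values = {x[a] for x in X}
            if len(values) > max_nominal:
                raise ValueError(
                    f"attribute {a!r} has {len(values)} nominal values "
                    f"(cap {max_nominal})"
                )
        self.attrs, self.classes = attrs, classes
        n = len(y)
        self.prior = {c: y.count(c) / n for c in classes}
        self.like: dict = {}
        for c in classes:
            rows = [x for x, lab in zip(X, y) if lab == c]
            nc = len(rows)
            self.like[c] = {
                a: {v: sum(1 for x in rows if x[a] == v) / nc for v in {x[a] for x in rows}}
                for a in attrs
            }

    def predict(self, labels: dict):
        scores = {}
        for c in self.classes:
            p = self.prior[c]
            for a in self.attrs:
                # default probability 0: unseen attribute values zero the class
                p *= self.like[c][a].get(labels.get(a), 0.0)
            scores[c] = p
        best = max(scores.values())
        if best == 0.0:
            return _majority([], self.classes) if not self.prior else max(
                self.classes, key=lambda c: self.prior[c]
            )
        return next(c for c in self.classes if scores[c] == best)


# -- gini decision tree --------------------------------------------------

def _gini(y: Sequence) -> float:
    n = len(y)
    if n == 0:
        return 0.0
    counts: dict = {}
    for lab in y:
        counts[lab] = counts.get(lab, 0) + 1
    return 1.0 - sum((c / n) ** 2 for c in counts.values())


class _TreeNode:
    __slots__ = ("attr", "children", "fallback")

    def __init__(self, attr=None, children=None, fallback=None):
        self.attr, self.children, self.fallback = attr, children or {}, fallback


def _grow_tree(X, y, attrs, classes, min_node, rng=None, sample_attrs=False):
    node_majority = _majority(y, classes)
    if len(set(y)) <= 1 or len(y) < min_node or not attrs:
        return _TreeNode(fallback=node_majority)
    pool = list(attrs)
    if sample_attrs and rng is not None and len(pool) > 1:
        m = max(1, int(math.sqrt(len(pool))))
        idx = rng.choice(len(pool), size=m, replace=False)
        pool = [pool[i] for i in sorted(idx)]
    parent = _gini(y)
    best, best_gain = None, 0.0
    for a in pool:
        groups: dict = {}
        for x, lab in zip(X, y):
            groups.setdefault(x[a], []).append(lab)
        if len(groups) < 2:
            continue
        child = sum(len(g) / len(y) * _gini(g) for g in groups.values())
        gain = parent - child
        if gain > best_gain + 1e-12:
            best, best_gain = a, gain
    if best is None:
        return _TreeNode(fallback=node_majority)
    node = _TreeNode(attr=best, fallback=node_majority)
    rest = [a for a in attrs if a != best]
    groups: dict = {}
    for x, lab in zip(X, y):
        groups.setdefault(x[best], []).append((x, lab))
    for v, rows in groups.items():
        Xs = [x for x, _ in rows]
        ys = [lab for _, lab in rows]
        node.children[v] = _grow_tree(Xs, ys, rest, classes, min_node, rng, sample_attrs)
    return node


def _tree_predict(node: _TreeNode, labels: dict):
    while node.attr is not None:
        child = node.children.get(labels.get(node.attr))
        if child is None:
            return node.fallback
        node = child
    return node.fallback


class _DecisionTree:
    def __init__(self, table: DiscretizedTable, min_node: int = 2):
        attrs, X, y, classes = _training_data(table)
        self.root = _grow_tree(X, y, attrs, classes, min_node)

    def predict(self, labels: dict):
        return _tree_predict(self.root, labels)


# -- majority decision table ---------------------------------------------

class _DecisionTableMajority:
    """Lookup over a greedily selected attribute subset; keys unseen at
    training time fall back to the global majority class."""

    def __init__(self, table: DiscretizedTable):
        attrs, X, y, classes = _training_data(table)
        self.fallback = _majority(y, classes)
        chosen: list[str] = []

        def accuracy(subset: list[str]) -> float:
            lut: dict = {}
            for x, lab in zip(X, y):
                lut.setdefault(tuple(x[a] for a in subset), []).append(lab)
            lut = {k: _majority(v, classes) for k, v in lut.items()}
            hits = sum(
                1
                for x, lab in zip(X, y)
                if lut.get(tuple(x[a] for a in subset), self.fallback) == lab
            )
            return hits / len(y)

        current = accuracy(chosen)
        improved = True
        while improved:
            improved = False
            for a in attrs:
                if a in chosen:
                    continue
                acc = accuracy(chosen + [a])
                if acc > current + 1e-12:
                    chosen, current, improved = chosen + [a], acc, True
                    break
        self.subset = chosen
        lut: dict = {}
        for x, lab in zip(X, y):
            lut.setdefault(tuple(x[a] for a in chosen), []).append(lab)
        self.lut = {k: _majority(v, classes) for k, v in lut.items()}

    def predict(self, labels: dict):
        key = tuple(labels.get(a) for a in self.subset)
        return self.lut.get(key, self.fallback)


# -- bagged tree ensemble ------------------------------------------------

class _TreeEnsemble:
    def __init__(
        self,
        table: DiscretizedTable,
        n_trees: int = 100,
        min_node: int = 2,
        seed: int = 0,
    ):
        attrs, X, y, classes = _training_data(table)
        self.classes = classes
        rng = np.random.default_rng(seed)
        self.roots = []
        n = len(y)
        sample = n_trees > 1  # a single tree with full attributes == _DecisionTree
        for _ in range(n_trees):
            idx = rng.integers(n, size=n) if n_trees > 1 else np.arange(n)
            Xb = [X[i] for i in idx]
            yb = [y[i] for i in idx]
            self.roots.append(
                _grow_tree(Xb, yb, attrs, classes, min_node, rng, sample_attrs=sample)
            )

    def predict(self, labels: dict):
        votes: dict = {}
        for root in self.roots:
            lab = _tree_predict(root, labels)
            votes[lab] = votes.get(lab, 0) + 1
        return max(self.classes, key=lambda c: votes.get(c, 0))


def train(spec: BaselineSpec, table: DiscretizedTable, seed: int = 0):
    """Fit a baseline on a discretized table; deterministic given seed."""
    hp = spec.hyperparameters
    if spec.kind == "naive-bayes":
        return _NaiveBayes(table, hp.get("max_nominal", 20))
    if spec.kind == "decision-tree":
        return _DecisionTree(table, hp.get("min_node", 2))
    if spec.kind == "decision-table-majority":
        return _DecisionTableMajority(table)
    return _TreeEnsemble(
        table, hp.get("n_trees", 100), hp.get("min_node", 2), seed=seed
    )


def predict(model, labels: dict):
    return model.predict(labels)
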