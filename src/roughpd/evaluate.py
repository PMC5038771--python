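"""Cross-validation, fold-averaged confusion matrices and metrics.

Protocol: objects are shuffled once (seeded) and dealt into k near-equal
folds; each fold in turn is held out, the classifier is trained on the
rest, and integer prediction counts are accumulated over *covered*
objects (rule classifiers may abstain).  The reported matrix entries are
the accumulated counts divided by k — which is why published entries
like 0.83 or 1.17 are multiples of 1/6 under six-fold — while every
metric is computed from the raw accumulated counts:

* coverage  = covered / tested        (pooled over folds)
* accuracy  = correct / covered
* TPR(c)    = m[c][c] / column-sum(c)   (predicted-c that are c)
* ACC(c)    = m[c][c] / row-sum(c)      (actual-c recovered)

plus the multiclass Matthews correlation coefficient and Cohen's kappa.
A SMOTE-style oversampler for the raw numeric tables is included.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tables import MISSING, DecisionTable, InformationTable
from .discretize import DiscretizedTable
from .rules import ABSTAIN, build_tree, classify, classify_tree, induce_rules, local_rules, reduct_rules

__all__ = [
    "FoldPlan",
    "ConfusionMatrix",
    "make_folds",
    "cross_validate",
    "global_metrics",
    "per_class_metrics",
    "mcc",
    "kappa",
    "smote_oversample",
]


@dataclass
class FoldPlan:
    k: int
    seed: int
    assignment: dict[int, int]  # object id -> fold index
    stratified: bool = False

    def fold_ids(self, fold: int) -> list[int]:
        return [oid for oid, f in self.assignment.items() if f == fold]


def make_folds(
    ids: Sequence[int] | int,
    k: int,
    seed: int,
    labels: Sequence | None = None,
    stratified: bool = False,
) -> FoldPlan:
    """Seeded shuffle + round-robin deal; stratified mode deals within
    each decision class so labels balance across folds.  ``k == n`` is
    leave-one-out."""
    if isinstance(ids, int):
        ids = list(range(ids))
    ids = list(ids)
    n = len(ids)
    if k > n:
        raise ValueError(f"k={k} exceeds object count {n}")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assignment: dict[int, int] = {}
    if stratified:
        if labels is None:
            raise ValueError("stratified folds need labels")
        by_class: dict[object, list[int]] = {}
        for oid, lab in zip(ids, labels):
            by_class.setdefault(lab, []).append(oid)
        slot = 0
        for lab in by_class:
            members = list(by_class[lab])
            rng.shuffle(members)
            for oid in members:
                assignment[oid] = slot % k
                slot += 1
    else:
        order = list(ids)
        rng.shuffle(order)
        for pos, oid in enumerate(order):
            assignment[oid] = pos % k
    return FoldPlan(k=k, seed=seed, assignment=assignment, stratified=stratified)


@dataclass
class ConfusionMatrix:
    """Fold-averaged class x class counts over covered test objects."""

    labels: list
    counts: np.ndarray  # accumulated integer counts, actual x predicted
    k: int
    n_tested: int

    @property
    def entries(self) -> np.ndarray:
        """Published-style entries: accumulated counts / k."""
        return self.counts / self.k

    @property
    def n_covered(self) -> int:
        return int(self.counts.sum())

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.counts))

    def to_csv(self, path) -> None:
        import pandas as pd

        ent = self.entries
        rows = {}
        for i, lab in enumerate(self.labels):
            rows[str(lab)] = list(np.round(ent[i], 2)) + [
                round(per_class_metrics(self)[1][i], 2)
            ]
        rows["TPR"] = list(np.round(per_class_metrics(self)[0], 2)) + [float("nan")]
        df = pd.DataFrame.from_dict(
            rows, orient="index", columns=[str(l) for l in self.labels] + ["ACC"]
        )
        df.to_csv(path)


def _fit_predictor(table: DiscretizedTable, spec: dict, seed: int):
    kind = spec.get("kind", "decomposition-tree")
    scheme = spec.get("vote", "weighted")
    if kind == "rough-rules":
        if spec.get("attrs") is not None:
            rules = induce_rules(table, spec["attrs"])
        elif spec.get("minimal"):
            rules = local_rules(table)
        else:
            rules = reduct_rules(table)
        return lambda labels: classify(rules, labels, scheme)
    if kind == "decomposition-tree":
        tree = build_tree(table, spec.get("min_leaf", 3))
        return lambda labels: classify_tree(tree, labels, scheme)
    from . import baselines

    model = baselines.train(baselines.BaselineSpec.from_dict(spec), table, seed=seed)
    return lambda labels: baselines.predict(model, labels)


def cross_validate(
    table: DiscretizedTable | DecisionTable,
    spec: dict,
    folds: FoldPlan,
    discretizer=None,
) -> ConfusionMatrix:
    """k-fold cross-validation of a classifier spec; returns the
    accumulated (then /k) confusion matrix.

    Default mode takes an already (globally) discretized table.  With a
    ``discretizer`` callback (raw DecisionTable -> DiscretizedTable) the
    cuts are recomputed on each training fold and held-out objects are
    labelled with the training cuts — the leakage-free variant.  The
    decision binning must be fold-independent so that class labels agree
    across folds."""
    if discretizer is not None:
        reference = discretizer(table)
        raw = table
    else:
        reference = table
        raw = None
    labels_order: list = []
    for rec in reference.records:
        d = rec[reference.decision]
        if d not in labels_order:
            labels_order.append(d)
    index = {lab: i for i, lab in enumerate(labels_order)}
    m = len(labels_order)
    counts = np.zeros((m, m), dtype=int)
    tested = 0
    for fold in range(folds.k):
        test_ids = set(folds.fold_ids(fold))
        keep = [oid for oid in reference.ids if oid not in test_ids]
        if raw is not None:
            train = discretizer(raw.subset(keep))
        else:
            train = reference.subset(keep)
        train_classes = {rec[train.decision] for rec in train.records}
        if len(train_classes) < m:
            warnings.warn(
                f"fold {fold}: classes absent from training; objects may abstain"
            )
        predictor = _fit_predictor(train, spec, seed=folds.seed * folds.k + fold)
        for oid in sorted(test_ids):
            if raw is not None:
                pos = raw.ids.index(oid)
                rec = train.label_row(raw.records[pos])
                actual = reference.record_for(oid)[reference.decision]
            else:
                rec = reference.record_for(oid)
                actual = rec[reference.decision]
            tested += 1
            pred = predictor(rec)
            if pred is ABSTAIN or pred not in index:
                continue
            counts[index[actual], index[pred]] += 1
    return ConfusionMatrix(labels_order, counts, folds.k, tested)


def global_metrics(cm: ConfusionMatrix) -> tuple[float, float]:
    """(accuracy on covered, pooled coverage)."""
    cov = cm.n_covered / cm.n_tested if cm.n_tested else 0.0
    acc = cm.n_correct / cm.n_covered if cm.n_covered else 0.0
    return acc, cov


def per_class_metrics(cm: ConfusionMatrix) -> tuple[list[float], list[float]]:
    """(TPR per class, ACC per class); empty denominators give 0."""
    col = cm.counts.sum(axis=0)
    row = cm.counts.sum(axis=1)
    diag = np.diag(cm.counts)
    tpr = [d / c if c else 0.0 for d, c in zip(diag, col)]
    acc = [d / r if r else 0.0 for d, r in zip(diag, row)]
    return tpr, acc


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient (generalized multiclass form)."""
    C = cm.counts.astype(float)
    s = C.sum()
    c = np.trace(C)
    p = C.sum(axis=0)  # predicted totals
    t = C.sum(axis=1)  # actual totals
    num = c * s - float(p @ t)
    den = math.sqrt(s * s - float(p @ p)) * math.sqrt(s * s - float(t @ t))
    if den == 0:
        warnings.warn("MCC denominator zero; returning 0")
        return 0.0
    return num / den


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa: observed vs chance agreement."""
    C = cm.counts.astype(float)
    s = C.sum()
    if s == 0:
        warnings.warn("empty confusion matrix; kappa 0")
        return 0.0
    po = np.trace(C) / s
    pe = float(C.sum(axis=0) @ C.sum(axis=1)) / (s * s)
    if pe == 1.0:
        warnings.warn("kappa denominator zero; returning 0")
        return 0.0
    return (po - pe) / (1.0 - pe)


def smote_oversample(
    dt: DecisionTable,
    k_neighbors: int = 3,
    factor: int = 3,
    seed: int = 0,
) -> DecisionTable:
    """Interpolative oversampling: per record, ``factor - 1`` synthetic
    records on the segment toward a random one of its k nearest
    same-class neighbours (Euclidean on standardized numeric conditions;
    nominal attributes copied)."""
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    rng = np.random.default_rng(seed)
    numeric = [
        n for n in dt.condition_names if dt.base.attribute(n).kind == "numeric"
    ]
    cols = {}
    for n in numeric:
        v = np.array(
            [np.nan if x is MISSING else float(x) for x in dt.base.column(n)]
        )
        mu = np.nanmean(v) if not np.all(np.isnan(v)) else 0.0
        sd = np.nanstd(v)
        cols[n] = (v, mu, sd if sd > 0 else 1.0)
    n_obj = len(dt)
    dec = dt.base.column(dt.decision)
    Z = np.column_stack(
        [(cols[n][0] - cols[n][1]) / cols[n][2] for n in numeric]
    ) if numeric else np.zeros((n_obj, 0))

    new_records = list(dt.base.records)
    next_id = max(dt.base.ids) + 1 if dt.base.ids else 0
    new_ids = list(dt.base.ids)
    for i in range(n_obj):
        same = [j for j in range(n_obj) if j != i and dec[j] == dec[i]]
        if not same:
            neighbours = []
        else:
            zi = Z[i]
            dists = []
            for j in same:
                diff = Z[j] - zi
                diff = np.where(np.isnan(diff), 0.0, diff)
                dists.append((float(diff @ diff), j))
            dists.sort()
            if len(same) < k_neighbors:
                warnings.warn(
                    f"class {dec[i]!r}: only {len(same)} neighbours available"
                )
            neighbours = [j for _, j in dists[:k_neighbors]]
        for _ in range(factor - 1):
            rec = dict(dt.base.records[i])
            if neighbours:
                j = int(rng.integers(len(neighbours)))
                u = float(rng.random())
                nb = dt.base.records[neighbours[j]]
                for n in numeric:
                    vi, vj = rec[n], nb[n]
                    if vi is MISSING or vj is MISSING:
                        continue
                    rec[n] = float(vi) + u * (float(vj) - float(vi))
            new_records.append(rec)
            new_ids.append(next_id)
            next_id += 1
    base = InformationTable(dt.base.schema, new_records, new_ids)
    return DecisionTable(base, dt.decision)
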