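"""Cross-validation bookkeeping, metrics and SMOTE oversampling."""

import math

import numpy as np
import pytest

from conftest import make_table
from roughpd.discretize import CutSet, apply_cuts
from roughpd.evaluate import (
    ConfusionMatrix,
    cross_validate,
    global_metrics,
    kappa,
    make_folds,
    mcc,
    per_class_metrics,
    smote_oversample,
)
from roughpd.tables import AttributeSpec, DecisionTable, InformationTable


def _disc(dt):
    return apply_cuts(dt, CutSet(cuts={}))


def test_make_folds_shapes_and_determinism():
    plan = make_folds(36, 6, seed=1)
    sizes = [len(plan.fold_ids(f)) for f in range(6)]
    assert sizes == [6] * 6
    assert plan.assignment == make_folds(36, 6, seed=1).assignment
    assert plan.assignment != make_folds(36, 6, seed=2).assignment
    loo = make_folds(40, 40, seed=0)
    assert all(len(loo.fold_ids(f)) == 1 for f in range(40))
    with pytest.raises(ValueError):
        make_folds(5, 6, seed=0)


def test_stratified_folds_balance_labels():
    labels = ["a"] * 12 + ["b"] * 12
    plan = make_folds(24, 6, seed=3, labels=labels, stratified=True)
    for f in range(6):
        fold_labels = [labels[i] for i in plan.fold_ids(f)]
        assert fold_labels.count("a") == 2 and fold_labels.count("b") == 2


def _consistent_table(n=24):
    rows = [{"a": str(i % 3), "b": str(i % 2), "d": str(i % 3)} for i in range(n)]
    return _disc(make_table(rows))


def test_perfect_classifier_full_scores():
    disc = _consistent_table()
    plan = make_folds(disc.ids, 6, seed=0)
    cm = cross_validate(disc, {"kind": "rough-rules"}, plan)
    acc, cov = global_metrics(cm)
    assert acc == 1.0 and cov == 1.0


def test_entries_are_multiples_of_one_over_k():
    disc = _consistent_table()
    plan = make_folds(disc.ids, 6, seed=5)
    cm = cross_validate(disc, {"kind": "decomposition-tree", "min_leaf": 3}, plan)
    scaled = cm.entries * cm.k
    assert np.allclose(scaled, np.round(scaled))
    assert cm.n_covered == int(cm.counts.sum())


def test_accumulated_counts_equal_fold_sum():
    """Oracle: rebuild the matrix with an explicit per-fold loop."""
    from roughpd.evaluate import _fit_predictor
    from roughpd.rules import ABSTAIN

    disc = _consistent_table()
    plan = make_folds(disc.ids, 4, seed=2)
    spec = {"kind": "rough-rules"}
    cm = cross_validate(disc, spec, plan)
    index = {lab: i for i, lab in enumerate(cm.labels)}
    manual = np.zeros_like(cm.counts)
    for fold in range(4):
        test = set(plan.fold_ids(fold))
        train = disc.subset([i for i in disc.ids if i not in test])
        predict = _fit_predictor(train, spec, seed=0)
        for oid in sorted(test):
            rec = disc.record_for(oid)
            pred = predict(rec)
            if pred is not ABSTAIN:
                manual[index[rec[disc.decision]], index[pred]] += 1
    assert (manual == cm.counts).all()


def test_global_and_per_class_metrics():
    counts = np.array([[4, 0], [1, 0]])
    cm = ConfusionMatrix(["p", "n"], counts, k=2, n_tested=10)
    acc, cov = global_metrics(cm)
    assert cov == 0.5 and acc == 0.8
    tpr, cls_acc = per_class_metrics(cm)
    assert tpr == [0.8, 0.0]
    assert cls_acc == [1.0, 0.0]
    diag = ConfusionMatrix(["p", "n"], np.diag([3, 2]), k=1, n_tested=5)
    assert per_class_metrics(diag) == ([1.0, 1.0], [1.0, 1.0])


def test_metrics_invariant_under_label_permutation():
    counts = np.array([[5, 2, 0], [1, 7, 1], [0, 3, 4]])
    cm = ConfusionMatrix(["a", "b", "c"], counts, k=1, n_tested=23)
    perm = [2, 0, 1]
    cm2 = ConfusionMatrix(
        [cm.labels[i] for i in perm], counts[np.ix_(perm, perm)], k=1, n_tested=23
    )
    assert global_metrics(cm) == global_metrics(cm2)
    assert mcc(cm) == pytest.approx(mcc(cm2))
    assert kappa(cm) == pytest.approx(kappa(cm2))


def test_mcc_closed_forms():
    perfect = ConfusionMatrix(["p", "n"], np.diag([5, 5]), 1, 10)
    assert mcc(perfect) == pytest.approx(1.0)
    uniform = ConfusionMatrix(["p", "n"], np.full((2, 2), 2), 1, 8)
    assert mcc(uniform) == pytest.approx(0.0)
    # TP=3, FP=1, FN=2, TN=4 (actual x predicted, positive class first)
    counts = np.array([[3, 2], [1, 4]])
    cm = ConfusionMatrix(["p", "n"], counts, 1, 10)
    assert mcc(cm) == pytest.approx(10 / math.sqrt(600))


def test_mcc_kappa_against_sklearn():
    from sklearn.metrics import cohen_kappa_score, matthews_corrcoef

    rng = np.random.default_rng(11)
    actual = rng.integers(3, size=60)
    pred = rng.integers(3, size=60)
    counts = np.zeros((3, 3), dtype=int)
    for a, p in zip(actual, pred):
        counts[a, p] += 1
    cm = ConfusionMatrix([0, 1, 2], counts, 1, 60)
    assert mcc(cm) == pytest.approx(matthews_corrcoef(actual, pred))
    assert kappa(cm) == pytest.approx(cohen_kappa_score(actual, pred))


def test_random_guessing_calibrates_to_chance():
    rng = np.random.default_rng(0)
    m = 4
    counts = np.zeros((m, m), dtype=int)
    for _ in range(4000):
        counts[rng.integers(m), rng.integers(m)] += 1
    cm = ConfusionMatrix(list(range(m)), counts, 1, 4000)
    acc, _ = global_metrics(cm)
    assert acc == pytest.approx(1 / m, abs=3 * math.sqrt(0.25 * 0.75 / 4000))


def _numeric_dt(n=40, seed=0):
    rng = np.random.default_rng(seed)
    schema = [
        AttributeSpec("x"),
        AttributeSpec("y"),
        AttributeSpec("g", "nominal"),
        AttributeSpec("d", "nominal", "decision"),
    ]
    rows = [
        {
            "x": float(rng.normal()),
            "y": float(rng.normal(10, 3)),
            "g": str(rng.integers(2)),
            "d": str(rng.integers(2)),
        }
        for _ in range(n)
    ]
    return DecisionTable(InformationTable(schema, rows), "d")


def test_smote_size_and_geometry():
    dt = _numeric_dt()
    big = smote_oversample(dt, k_neighbors=3, factor=3, seed=1)
    assert len(big) == 120
    originals = {tuple((r["x"], r["y"])) for r in dt.base.records}
    by_class = {}
    for rec in dt.base.records:
        by_class.setdefault(rec["d"], []).append(rec)
    for rec in big.base.records[40:]:
        pts = np.array([[r["x"], r["y"]] for r in by_class[rec["d"]]])
        p = np.array([rec["x"], rec["y"]])
        # synthetic point lies on a segment between two same-class parents
        diffs = pts[:, None, :] - pts[None, :, :]
        on_segment = False
        for i in range(len(pts)):
            for j in range(len(pts)):
                if i == j:
                    continue
                seg = pts[j] - pts[i]
                denom = float(seg @ seg)
                if denom == 0:
                    continue
                t = float((p - pts[i]) @ seg) / denom
                if -1e-9 <= t <= 1 + 1e-9 and np.allclose(pts[i] + t * seg, p,
                                                          atol=1e-8):
                    on_segment = True
                    break
            if on_segment:
                break
        assert on_segment


def test_smote_identical_pair_and_determinism():
    schema = [AttributeSpec("x"), AttributeSpec("d", "nominal", "decision")]
    rows = [{"x": 2.0, "d": "a"}, {"x": 2.0, "d": "a"}]
    dt = DecisionTable(InformationTable(schema, rows), "d")
    with pytest.warns(UserWarning):
        big = smote_oversample(dt, k_neighbors=3, factor=3, seed=0)
    assert all(r["x"] == 2.0 for r in big.base.records)
    a = smote_oversample(_numeric_dt(), seed=9)
    b = smote_oversample(_numeric_dt(), seed=9)
    assert a.base.records == b.base.records
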