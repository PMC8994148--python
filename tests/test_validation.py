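"""ROC analysis, Youden thresholds and repeated cross-validation."""

import numpy as np
import pytest

from gbsnet.bn_structure import DAG
from gbsnet.bn_params import fit_mle
from gbsnet.report_io import CaseMatrix, Variable
from gbsnet.synthetic_data import fixture_network, sample_cohort
from gbsnet.validation import (
    auc,
    confusion_metrics,
    external_validate,
    repeated_cv,
    roc_curve,
    stratified_kfold,
    youden_threshold,
)

import oracles


# ---------------------------------------------------------------------------
# stratified folds
# ---------------------------------------------------------------------------

def test_kfold_exact_stratification():
    labels = np.array([1] * 5 + [0] * 5)
    assignment = stratified_kfold(10, labels, 5, seed=0)
    for fold in range(5):
        mask = assignment == fold
        assert mask.sum() == 2
        assert labels[mask].sum() == 1


def test_kfold_partition_and_balance():
    rng = np.random.default_rng(3)
    labels = (rng.random(1003) < 0.3).astype(int)
    assignment = stratified_kfold(1003, labels, 5, seed=1)
    sizes = np.bincount(assignment, minlength=5)
    assert sizes.sum() == 1003
    assert sizes.max() - sizes.min() <= 1
    positives = [labels[assignment == f].sum() for f in range(5)]
    assert max(positives) - min(positives) <= 1


def test_kfold_deterministic_and_seed_sensitive():
    labels = np.array([0, 1] * 50)
    a = stratified_kfold(100, labels, 5, seed=7)
    b = stratified_kfold(100, labels, 5, seed=7)
    c = stratified_kfold(100, labels, 5, seed=8)
    assert (a == b).all()
    assert (a != c).any()


def test_kfold_small_class_rejected():
    labels = np.array([1, 0, 0, 0, 0, 0, 0, 0, 0, 0])
    with pytest.raises(ValueError):
        stratified_kfold(10, labels, 5, seed=0)


# ---------------------------------------------------------------------------
# ROC / AUC / Youden
# ---------------------------------------------------------------------------

def test_roc_endpoints_and_monotonicity(rng):
    scores = rng.random(50)
    labels = rng.integers(0, 2, 50)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    curve = roc_curve(scores, labels)
    assert curve.tpr[0] == 1.0 and curve.fpr[0] == 1.0
    assert curve.tpr[-1] == 0.0 and curve.fpr[-1] == 0.0
    assert (np.diff(curve.tpr) <= 1e-12).all()
    assert (np.diff(curve.fpr) <= 1e-12).all()


def test_auc_perfect_and_uninformative():
    perfect = roc_curve([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
    assert auc(perfect) == pytest.approx(1.0)
    flat = roc_curve([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
    assert auc(flat) == pytest.approx(0.5)
    assert max(flat.youden()) == pytest.approx(0.0)


def test_auc_matches_pairwise_concordance(rng):
    """Trapezoidal AUC equals Mann-Whitney concordance (ties at 1/2) on
    random instances, including heavily tied scores."""
    for _ in range(100):
        n = int(rng.integers(10, 60))
        scores = np.round(rng.random(n), 1)  # force ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        got = auc(roc_curve(scores, labels))
        assert got == pytest.approx(oracles.concordance_auc(scores, labels), abs=1e-12)


def test_youden_matches_exhaustive_scan(rng):
    for _ in range(100):
        n = int(rng.integers(8, 40))
        scores = np.round(rng.random(n), 2)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        curve = roc_curve(scores, labels)
        t = youden_threshold(curve)
        best_j, best_t = oracles.youden_by_scan(scores, labels)
        sens, spec, _ = confusion_metrics(scores, labels, t)
        assert sens + spec - 1 == pytest.approx(best_j, abs=1e-12)
        assert t == pytest.approx(best_t, abs=1e-12)


def test_youden_separated_scores_sits_in_gap():
    curve = roc_curve([0.8, 0.9, 0.1, 0.2], [1, 1, 0, 0])
    t = youden_threshold(curve)
    assert 0.2 <= t < 0.8


def test_confusion_metrics_boundaries_and_manual_count():
    scores = np.array([0.9, 0.8, 0.6, 0.4, 0.55, 0.3, 0.2, 0.1])
    labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
    sens, spec, acc = confusion_metrics(scores, labels, 0.5)
    assert (sens, spec, acc) == (pytest.approx(0.75), pytest.approx(0.75), pytest.approx(0.75))
    sens, spec, acc = confusion_metrics(scores, labels, 0.0)
    assert sens == 1.0
    sens, spec, acc = confusion_metrics(scores, labels, 1.0)
    assert spec == 1.0


# ---------------------------------------------------------------------------
# repeated CV
# ---------------------------------------------------------------------------

def _independent_matrix(n, seed):
    rng = np.random.default_rng(seed)
    data = np.column_stack([
        (rng.random(n) < 0.05).astype(np.int8),
        rng.integers(0, 2, n).astype(np.int8),
        rng.integers(0, 2, n).astype(np.int8),
    ])
    variables = [Variable("Y", ("f", "t")), Variable("A", ("f", "t")),
                 Variable("B", ("f", "t"))]
    return CaseMatrix(variables, data, "Y")


def test_cv_null_calibration():
    """With the outcome independent of all predictors the mean CV AUC
    stays near 0.5."""
    matrix = _independent_matrix(20_000, seed=21)
    dag = DAG(["Y", "A", "B"], [("A", "Y"), ("B", "Y")])
    result = repeated_cv(matrix, dag, k=5, repeats=3, seed=0)
    assert abs(result.summary()["auc"]["mean"] - 0.5) < 0.05


def test_cv_perfect_signal():
    rng = np.random.default_rng(2)
    x = rng.integers(0, 2, 2000).astype(np.int8)
    data = np.column_stack([x, x])
    matrix = CaseMatrix([Variable("Y", ("f", "t")), Variable("X", ("f", "t"))], data, "Y")
    dag = DAG(["Y", "X"], [("Y", "X")])
    result = repeated_cv(matrix, dag, k=5, repeats=1, seed=0)
    assert result.summary()["auc"]["mean"] == pytest.approx(1.0)


def test_cv_reproducible_and_fold_invariants():
    matrix = _independent_matrix(3_000, seed=5)
    dag = DAG(["Y", "A", "B"], [("A", "Y")])
    r1 = repeated_cv(matrix, dag, k=5, repeats=2, seed=11)
    r2 = repeated_cv(matrix, dag, k=5, repeats=2, seed=11)
    assert r1.folds == r2.folds
    assert len(r1.folds) == 10
    for fold in r1.folds:
        assert 0 <= fold.auc <= 1
        assert 0 <= fold.threshold <= 1
    summary = r1.summary()
    for metric, stats in summary.items():
        assert stats["ci_low"] <= stats["mean"] <= stats["ci_high"]


def test_cv_fold_metrics_satisfy_identities(fixture_bn):
    """sens+spec-1 equals the fold's maximal Youden value, and accuracy
    equals the class-weighted combination of sensitivity and specificity."""
    matrix = sample_cohort(fixture_bn, 8_000, seed=17)
    from gbsnet.bn_structure import extract_mb_subnetwork

    dag = fixture_bn.dag
    result = repeated_cv(matrix, dag, k=4, repeats=1, seed=3)
    labels = matrix.column("GBS")
    assert result.folds
    for fold in result.folds:
        assignment = stratified_kfold(matrix.n, labels, 4, _fold_seed(3, fold.repeat))
        val = assignment == fold.fold
        bn = fit_mle(dag, matrix.subset_rows(~val))
        from gbsnet.bn_inference import predict_scores

        scores = predict_scores(bn, matrix.subset_rows(val), "GBS", impossible="parents")
        y = labels[val]
        best_j, _ = oracles.youden_by_scan(scores, y)
        assert fold.sensitivity + fold.specificity - 1 == pytest.approx(best_j, abs=1e-12)
        n_pos, n_neg = y.sum(), (1 - y).sum()
        acc = (fold.sensitivity * n_pos + fold.specificity * n_neg) / (n_pos + n_neg)
        assert fold.accuracy == pytest.approx(acc, abs=1e-12)


def _fold_seed(seed, repeat):
    rng = np.random.default_rng(seed)
    value = None
    for _ in range(repeat + 1):
        value = int(rng.integers(0, 2**31 - 1))
    return value


# ---------------------------------------------------------------------------
# external validation
# ---------------------------------------------------------------------------

def test_external_validation_shuffled_outcome_destroys_signal(fixture_bn):
    matrix = sample_cohort(fixture_bn, 20_000, seed=31)
    bn = fit_mle(fixture_bn.dag, matrix)
    rng = np.random.default_rng(0)
    aucs = []
    for _ in range(4):
        shuffled = matrix.data.copy()
        shuffled[:, 0] = shuffled[rng.permutation(matrix.n), 0]
        metrics = external_validate(
            bn, CaseMatrix(matrix.variables, shuffled, "GBS")
        )
        aucs.append(metrics["auc"])
    assert abs(np.mean(aucs) - 0.5) < 0.05


def test_external_validation_roundtrip_from_exported_scores(fixture_bn, tmp_path):
    """Metrics recomputed from exported per-report scores match."""
    import csv

    from gbsnet.bn_inference import predict_scores

    train = sample_cohort(fixture_bn, 30_000, seed=41)
    test = sample_cohort(fixture_bn, 10_000, seed=43)
    bn = fit_mle(fixture_bn.dag, train)
    metrics = external_validate(bn, test)

    scores = predict_scores(bn, test, "GBS", impossible="parents")
    path = tmp_path / "scores.csv"
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        for s, y in zip(scores, test.column("GBS")):
            writer.writerow([f"{s:.17g}", int(y)])
    with open(path) as handle:
        rows = [(float(s), int(y)) for s, y in csv.reader(handle)]
    re_scores = np.array([r[0] for r in rows])
    re_labels = np.array([r[1] for r in rows])
    assert auc(roc_curve(re_scores, re_labels)) == pytest.approx(metrics["auc"], abs=1e-9)
    sens, spec, acc = confusion_metrics(re_scores, re_labels, metrics["threshold"])
    assert sens == pytest.approx(metrics["sensitivity"], abs=1e-12)
    assert spec == pytest.approx(metrics["specificity"], abs=1e-12)


def test_external_validation_transferred_threshold(fixture_bn):
    train = sample_cohort(fixture_bn, 20_000, seed=51)
    bn = fit_mle(fixture_bn.dag, train)
    test = sample_cohort(fixture_bn, 10_000, seed=53)
    fixed = external_validate(bn, test, threshold=0.014)
    assert fixed["threshold"] == 0.014
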