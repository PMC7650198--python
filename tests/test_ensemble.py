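"""Disjoint-slice ensemble contract, metrics oracles, tuning, importance."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from svpath.ensemble import (
    DisjointSliceForestEnsemble,
    HYPERPARAM_RANGES,
    Hyperparams,
    aupr,
    auroc,
    classify_by_score,
    evaluate_cv,
    feature_importance,
    load_ensemble,
    make_score_table,
    partition_disjoint,
    save_ensemble,
    score_external,
    score_in_corpus,
    train_ensemble,
    tune_hyperparameters,
)
from svpath.genomic_io import SVRecord

from conftest import matrix_from_arrays


# ---------------------------------------------------------------------------
# Metric oracles
# ---------------------------------------------------------------------------

def auroc_oracle(y, s):
    """Concordant-pair fraction with ties counted 1/2."""
    y = np.asarray(y)
    s = np.asarray(s, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def aupr_oracle(y, s):
    """Step-wise precision-recall integration over distinct thresholds."""
    y = np.asarray(y)
    s = np.asarray(s, dtype=float)
    total_pos = y.sum()
    ap, prev_recall = 0.0, 0.0
    for t in sorted(set(s), reverse=True):
        called = s >= t
        tp = int((y[called] == 1).sum())
        precision = tp / called.sum()
        recall = tp / total_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def test_auroc_toy_concordance():
    y = [0, 0, 1, 0, 1, 1]
    s = [0.1, 0.4, 0.35, 0.8, 0.65, 0.9]
    assert auroc(y, s) == pytest.approx(auroc_oracle(y, s))
    assert auroc([0, 1], [0.2, 0.9]) == 1.0  # separable limit


def test_metrics_match_oracles_randomized():
    rng = np.random.default_rng(0)
    for _ in range(300):
        n = int(rng.integers(4, 14))
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        # coarse grid of scores induces plenty of ties
        s = rng.integers(0, 5, size=n) / 4.0
        assert auroc(y, s) == pytest.approx(auroc_oracle(y, s), abs=1e-12)
        assert aupr(y, s) == pytest.approx(aupr_oracle(y, s), abs=1e-12)


def test_auroc_null_calibration():
    rng = np.random.default_rng(1)
    vals = [
        auroc(rng.permutation([0] * 50 + [1] * 50), np.arange(100)) for _ in range(200)
    ]
    assert abs(np.mean(vals) - 0.5) < 0.02


# ---------------------------------------------------------------------------
# Partition / training contract
# ---------------------------------------------------------------------------

def test_partition_sizes_and_coverage():
    rng = np.random.default_rng(2)
    a = partition_disjoint(list(range(100)), 10, rng)
    assert np.bincount(a, minlength=10).tolist() == [10] * 10
    b = partition_disjoint(list(range(103)), 10, rng)
    counts = np.bincount(b, minlength=10)
    assert sorted(set(counts.tolist())) <= [10, 11] and counts.sum() == 103
    # every row appears in exactly one slice by construction
    assert len(b) == 103 and set(b) == set(range(10))
    with pytest.raises(ValueError):
        partition_disjoint(list(range(5)), 10, rng)


def test_partition_stratified_spreads_classes():
    rng = np.random.default_rng(3)
    y = np.array([0] * 50 + [1] * 50)
    a = partition_disjoint(np.arange(100), 10, rng, labels=y)
    for s in range(10):
        assert len(np.unique(y[a == s])) == 2


def _separable_matrix(rng, n=200, n_features=5):
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(0, 1, size=(n, n_features))
    X[:, 0] += 6 * y  # widely separated single feature
    return matrix_from_arrays(X, y)


def test_train_ensemble_slice_contract():
    rng = np.random.default_rng(4)
    matrix = _separable_matrix(rng)
    est = train_ensemble(matrix, Hyperparams(n_trees=30), seed=0)
    assert len(est.models_) == 10
    counts = np.bincount(est.slice_assignment_, minlength=10)
    assert counts.tolist() == [20] * 10
    # each model achieves high accuracy on its own training slice
    X, y = matrix.X, matrix.y
    for s, model in enumerate(est.models_):
        rows = est.slice_assignment_ == s
        assert (model.predict(X[rows]) == y[rows]).mean() >= 0.95


def test_training_locality_per_slice():
    """Perturbing only slice 3's rows changes only model 3."""
    rng = np.random.default_rng(5)
    matrix = _separable_matrix(rng)
    est1 = train_ensemble(matrix, Hyperparams(n_trees=30), seed=7)
    values2 = matrix.values.copy()
    rows3 = np.flatnonzero(est1.slice_assignment_ == 3)
    values2.iloc[rows3, 1:] += rng.normal(0, 2, size=(len(rows3), values2.shape[1] - 1))
    matrix2 = matrix_from_arrays(values2.to_numpy(), matrix.y)
    est2 = train_ensemble(matrix2, Hyperparams(n_trees=30), seed=7)
    assert np.array_equal(est1.slice_assignment_, est2.slice_assignment_)
    probe = rng.normal(0, 2, size=(30, matrix.values.shape[1]))
    for s in range(10):
        same = np.allclose(
            est1.models_[s].predict_proba(probe), est2.models_[s].predict_proba(probe)
        )
        assert same == (s != 3)


def test_oof_scores_average_exactly_nine_models():
    rng = np.random.default_rng(6)
    matrix = _separable_matrix(rng)
    est = train_ensemble(matrix, Hyperparams(n_trees=25), seed=1)
    X = matrix.X
    probas = np.stack(
        [m.predict_proba(X)[:, list(m.classes_).index(1)] for m in est.models_]
    )
    for i in range(len(X)):
        others = [s for s in range(10) if s != est.slice_assignment_[i]]
        assert len(others) == 9
        assert est.oof_scores_[i] == pytest.approx(probas[others, i].mean())


def test_score_in_corpus_and_external_tables():
    rng = np.random.default_rng(7)
    matrix = _separable_matrix(rng)
    svs = [
        SVRecord("c", 10 * i, 10 * i + 100, "DEL", int(lbl), id=rid)
        for i, (rid, lbl) in enumerate(zip(matrix.ids, matrix.y))
    ]
    est = train_ensemble(matrix, Hyperparams(n_trees=25), seed=2)
    table = score_in_corpus(est, matrix, svs)
    assert np.allclose(table["score"], est.oof_scores_)
    assert table["label"].tolist() == matrix.y.tolist()
    with pytest.raises(ValueError, match="training corpus"):
        score_in_corpus(est, matrix.subset_rows(matrix.ids[:50]))
    ext = score_external(est, matrix)
    manual = np.stack(
        [m.predict_proba(matrix.X)[:, list(m.classes_).index(1)] for m in est.models_]
    ).mean(axis=0)
    assert np.allclose(ext["score"], manual)  # 10-model enumeration oracle
    assert ext["score"].between(0, 1).all()
    renamed = matrix.values.rename(columns={"f0": "other"})
    bad = matrix_from_arrays(renamed.to_numpy(), matrix.y)
    bad.values.columns = renamed.columns
    with pytest.raises(ValueError, match="other"):
        score_external(est, bad)


def test_classify_by_score_thresholds():
    svs = [SVRecord("c", 0, 100, "DEL", 1, id=f"s{i}") for i in range(4)]
    table = make_score_table(svs, [0.95, 0.1, 0.5, 0.9])
    out = classify_by_score(table)
    assert out["group"].tolist() == [
        "pathogenic",
        "benign",
        "intermediate",
        "pathogenic",  # boundary: score >= high
    ]
    extreme = classify_by_score(make_score_table(svs, [1.0, 0.0, 0.5, 0.99]), 1.0, 0.0)
    assert extreme["group"].tolist() == [
        "pathogenic",
        "benign",
        "intermediate",
        "intermediate",
    ]
    assert out["group"].value_counts().sum() == len(out)
    with pytest.raises(ValueError):
        classify_by_score(table, high=0.2, low=0.9)


# ---------------------------------------------------------------------------
# Evaluation, tuning, importance
# ---------------------------------------------------------------------------

def test_evaluate_cv_separable_and_shuffled():
    rng = np.random.default_rng(8)
    matrix = _separable_matrix(rng, n=240)
    res = evaluate_cv(matrix, Hyperparams(n_trees=25, min_samples_split=10), folds=4, seed=0)
    assert res["mean_auroc"] >= 0.99
    shuffled = matrix_from_arrays(matrix.X, rng.permutation(matrix.y))
    res0 = evaluate_cv(shuffled, Hyperparams(n_trees=25), folds=4, seed=0)
    assert 0.35 < res0["mean_auroc"] < 0.65


def test_tune_returns_in_range_candidates():
    rng = np.random.default_rng(9)
    matrix = _separable_matrix(rng, n=120)
    hp = tune_hyperparameters(matrix, search_budget=2, seed=0, inner_folds=2)
    for name, (lo, hi) in HYPERPARAM_RANGES.items():
        assert lo <= getattr(hp, name) <= hi
    with pytest.raises(ValueError):
        tune_hyperparameters(matrix, search_budget=0, seed=0)


def test_tuning_avoids_underfitting_depth_on_striped_data():
    """Alternating strips on one feature need more than 4 leaves, so a
    depth-2 forest underfits; the tuned depth avoids 2 for most seeds."""
    rng = np.random.default_rng(10)
    n = 250
    X = rng.uniform(0, 1, size=(n, 3))
    y = (np.floor(X[:, 0] * 6).astype(int) % 2).astype(int)  # 6 strips
    matrix = matrix_from_arrays(X, y)
    picks = [
        tune_hyperparameters(matrix, search_budget=3, seed=s, inner_folds=2).max_depth
        for s in range(3)
    ]
    assert sorted(picks)[1] > 2  # majority of seeds avoid the underfit depth


def test_feature_importance_recovers_planted_column():
    rng = np.random.default_rng(11)
    n = 300
    X = rng.normal(0, 1, size=(n, 8))
    y = np.array([0, 1] * (n // 2))
    X[:, 3] += 2.0 * y  # planted informative column
    matrix = matrix_from_arrays(X, y)
    est = train_ensemble(matrix, Hyperparams(n_trees=40), seed=3)
    imp = feature_importance(est, matrix, n_repeats=3, seed=4)
    assert imp.idxmax() == "f3"
    noise = imp.drop("f3")
    assert noise.abs().max() < 0.1  # pure-noise columns stay in the noise band
    # scale robustness: duplicating one row barely moves importances
    dup = pd.concat([matrix.values, matrix.values.iloc[[0]].rename(index={matrix.ids[0]: "dup"})])
    est2 = train_ensemble(
        matrix_from_arrays(dup.to_numpy(), np.append(matrix.y, matrix.y[0])),
        Hyperparams(n_trees=40),
        seed=3,
    )
    imp2 = feature_importance(est2, matrix_from_arrays(dup.to_numpy(), np.append(matrix.y, matrix.y[0])), n_repeats=3, seed=4)
    assert imp2.idxmax() == "f3"
    assert abs(imp2["f3"] - imp["f3"]) < 0.15


def test_estimator_sklearn_protocol_and_determinism():
    rng = np.random.default_rng(12)
    matrix = _separable_matrix(rng, n=200)
    est = DisjointSliceForestEnsemble(n_estimators=20, random_state=5)
    cloned = clone(est)
    assert cloned.get_params() == est.get_params()
    est.fit(matrix.values, matrix.y)
    again = clone(est).fit(matrix.values, matrix.y)
    assert np.array_equal(est.oof_scores_, again.oof_scores_)
    assert np.array_equal(
        est.predict_proba(matrix.X), again.predict_proba(matrix.X)
    )
    assert (est.predict(matrix.X) == matrix.y).mean() > 0.95


def test_save_load_roundtrip(tmp_path):
    rng = np.random.default_rng(13)
    matrix = _separable_matrix(rng, n=100)
    est = train_ensemble(matrix, Hyperparams(n_trees=20), seed=6)
    path = tmp_path / "model.joblib"
    save_ensemble(est, path, config_hash="abc")
    back = load_ensemble(path)
    assert back.config_hash_ == "abc"
    assert np.allclose(
        back.predict_proba(matrix.X), est.predict_proba(matrix.X)
    )
    assert np.allclose(score_in_corpus(back, matrix)["score"], est.oof_scores_)
    import joblib

    joblib.dump({"format": "other"}, path)
    with pytest.raises(ValueError, match="archive"):
        load_ensemble(path)
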