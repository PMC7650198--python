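"""Disjoint-slice random-forest ensemble and its evaluation machinery.

The classifier splits the training corpus into ``k`` (default 10) disjoint
near-equal slices, fits one random forest per slice on that slice only, and
scores every training row as the mean class-1 probability of the ``k - 1``
forests that never saw it (out-of-slice scoring). External rows are scored
by averaging all ``k`` forests. The resulting score in [0, 1] is read as
the probability that the variant belongs to the disease cohort rather than
the benign set, and thresholds (default >= 0.9 / <= 0.2) partition SVs
into pathogenic / intermediate / benign groups.

`DisjointSliceForestEnsemble` follows the scikit-learn estimator contract
(``fit``/``predict_proba``/``get_params``; fitted attributes end in an
underscore) and composes with sklearn model selection on the Z-matrix; the
module-level functions wrap it for the pipeline.
"""

from __future__ import annotations

import hashlib
import json
from collections.abc import Sequence
from dataclasses import asdict, dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .features import FeatureMatrix
from .genomic_io import SVRecord

__all__ = [
    "HYPERPARAM_RANGES",
    "Hyperparams",
    "DisjointSliceForestEnsemble",
    "partition_disjoint",
    "train_ensemble",
    "score_in_corpus",
    "score_external",
    "make_score_table",
    "classify_by_score",
    "tune_hyperparameters",
    "evaluate_cv",
    "feature_importance",
    "auroc",
    "aupr",
    "save_ensemble",
    "load_ensemble",
]

# Tuning search ranges (inclusive).
HYPERPARAM_RANGES = {
    "max_depth": (2, 10),
    "n_trees": (10, 5000),
    "min_samples_split": (10, 100),
}


@dataclass(frozen=True)
class Hyperparams:
    """Forest hyperparameters exposed to tuning.

    ``min_samples_split`` is the minimum number of samples required to
    split an internal node (the usual forest control conflating "minimum
    leaves to split" phrasings found in the literature).
    """

    max_depth: int = 8
    n_trees: int = 300
    min_samples_split: int = 10

    def validate_in_ranges(self) -> None:
        for name, (lo, hi) in HYPERPARAM_RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside tuning range [{lo}, {hi}]")


def auroc(y_true, scores) -> float:
    """Area under the ROC curve (midrank tie handling)."""
    return float(roc_auc_score(y_true, scores))


def aupr(y_true, scores) -> float:
    """Area under the precision-recall curve via step-wise integration."""
    return float(average_precision_score(y_true, scores))


def partition_disjoint(
    row_ids: Sequence,
    k: int = 10,
    rng: np.random.Generator | None = None,
    labels: Sequence[int] | None = None,
) -> np.ndarray:
    """Random partition of rows into k disjoint near-equal slices.

    Returns the slice index (0..k-1) per row, aligned with ``row_ids``.
    Slice sizes differ by at most one. With ``labels`` the partition is
    stratified: each class is shuffled and dealt cyclically, so every slice
    receives a near-equal share of each class.
    """
    m = len(row_ids)
    if m < k:
        raise ValueError(f"cannot split {m} rows into {k} disjoint slices")
    if rng is None:
        rng = np.random.default_rng()
    if labels is None:
        order = rng.permutation(m)
    else:
        labels = np.asarray(labels)
        parts = [rng.permutation(np.flatnonzero(labels == c)) for c in np.unique(labels)]
        order = np.concatenate(parts)
    assignment = np.empty(m, dtype=np.int64)
    assignment[order] = np.arange(m) % k
    return assignment


class DisjointSliceForestEnsemble(BaseEstimator, ClassifierMixin):
    """k random forests on disjoint data slices with out-of-slice scoring.

    Parameters
    ----------
    n_slices : int
        Number of disjoint slices / forests (default 10, i.e. each forest
        trains on 10% of the corpus).
    max_depth, n_estimators, min_samples_split : int
        Per-forest hyperparameters.
    random_state : int or None
        Seeds the slice partition and, independently per slice index, each
        forest, so refitting with one slice's rows altered changes only
        that slice's forest.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
    models_ : list of fitted RandomForestClassifier, one per slice
    slice_assignment_ : ndarray, slice index per training row
    oof_scores_ : ndarray, out-of-slice class-1 probability per training row
    """

    def __init__(
        self,
        n_slices: int = 10,
        max_depth: int = 8,
        n_estimators: int = 300,
        min_samples_split: int = 10,
        random_state: int | None = None,
        partition_retries: int = 20,
    ):
        self.n_slices = n_slices
        self.max_depth = max_depth
        self.n_estimators = n_estimators
        self.min_samples_split = min_samples_split
        self.random_state = random_state
        self.partition_retries = partition_retries

    def fit(self, X, y):
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("DisjointSliceForestEnsemble requires exactly 2 classes")
        self.n_features_in_ = X.shape[1]
        ss = np.random.SeedSequence(self.random_state)
        part_seed, model_seed = ss.spawn(2)
        part_rng = np.random.default_rng(part_seed)
        assignment = None
        for _ in range(max(1, self.partition_retries)):
            cand = partition_disjoint(
                np.arange(len(y)), self.n_slices, part_rng, labels=y
            )
            ok = all(
                len(np.unique(y[cand == s])) == 2 for s in range(self.n_slices)
            )
            if ok:
                assignment = cand
                break
        if assignment is None:
            raise ValueError(
                "could not build a partition with both classes in every slice; "
                "provide more data per class or fewer slices"
            )
        # one independent seed stream per slice index -> training locality
        model_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in model_seed.spawn(self.n_slices)]
        self.models_ = []
        for s in range(self.n_slices):
            rows = assignment == s
            forest = RandomForestClassifier(
                n_estimators=self.n_estimators,
                max_depth=self.max_depth,
                min_samples_split=self.min_samples_split,
                random_state=model_seeds[s],
            )
            forest.fit(X[rows], y[rows])
            self.models_.append(forest)
        self.slice_assignment_ = assignment
        self.oof_scores_ = self._oof_scores(X)
        return self

    def _proba_matrix(self, X) -> np.ndarray:
        """Class-1 probability from each slice model; shape (k, n_rows)."""
        out = np.empty((self.n_slices, X.shape[0]))
        for s, model in enumerate(self.models_):
            col = int(np.flatnonzero(model.classes_ == self.classes_[1])[0])
            out[s] = model.predict_proba(X)[:, col]
        return out

    def _oof_scores(self, X) -> np.ndarray:
        """Mean of the k-1 out-of-slice model probabilities per training row."""
        P = self._proba_matrix(X)
        own = P[self.slice_assignment_, np.arange(X.shape[0])]
        return (P.sum(axis=0) - own) / (self.n_slices - 1)

    def oof_scores(self, X=None) -> np.ndarray:
        """Out-of-slice scores for the training corpus (optionally with
        perturbed feature values X aligned row-for-row with training rows)."""
        check_is_fitted(self, "models_")
        if X is None:
            return self.oof_scores_
        X = check_array(X)
        if X.shape[0] != len(self.slice_assignment_):
            raise ValueError("X must align row-for-row with the training corpus")
        return self._oof_scores(X)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "models_")
        X = check_array(X)
        p1 = self._proba_matrix(X).mean(axis=0)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]


# ---------------------------------------------------------------------------
# FeatureMatrix-level wrappers
# ---------------------------------------------------------------------------

def train_ensemble(
    matrix: FeatureMatrix,
    hyperparams: Hyperparams | None = None,
    seed: int | None = None,
    n_slices: int = 10,
) -> DisjointSliceForestEnsemble:
    """Fit the slice ensemble on a Z-normalized matrix (labels from rows)."""
    if matrix.state != "z_normalized":
        raise ValueError("train on a z_normalized matrix")
    hp = hyperparams or Hyperparams()
    est = DisjointSliceForestEnsemble(
        n_slices=n_slices,
        max_depth=hp.max_depth,
        n_estimators=hp.n_trees,
        min_samples_split=hp.min_samples_split,
        random_state=seed,
    )
    est.fit(matrix.values, matrix.y)
    est.train_ids_ = list(matrix.ids)
    return est


def make_score_table(
    svs: Sequence[SVRecord], scores: Sequence[float], group: str = "intermediate"
) -> pd.DataFrame:
    scores = np.asarray(scores, dtype=float)
    if len(svs) != len(scores):
        raise ValueError("svs and scores must align")
    return pd.DataFrame(
        {
            "id": [sv.id for sv in svs],
            "chrom": [sv.chrom for sv in svs],
            "start": [sv.start for sv in svs],
            "end": [sv.end for sv in svs],
            "sv_type": [sv.sv_type for sv in svs],
            "label": [sv.label for sv in svs],
            "score": scores,
            "group": group,
        }
    )


def _table_from_matrix(matrix: FeatureMatrix, scores, svs) -> pd.DataFrame:
    if svs is not None:
        by_id = {sv.id: sv for sv in svs}
        ordered = [by_id[i] for i in matrix.ids]
        return make_score_table(ordered, scores)
    return pd.DataFrame(
        {
            "id": matrix.ids,
            "chrom": "",
            "start": -1,
            "end": -1,
            "sv_type": "",
            "label": matrix.y,
            "score": np.asarray(scores, dtype=float),
            "group": "intermediate",
        }
    )


def score_in_corpus(
    ensemble: DisjointSliceForestEnsemble,
    matrix: FeatureMatrix,
    svs: Sequence[SVRecord] | None = None,
) -> pd.DataFrame:
    """Out-of-slice score table for the training corpus itself.

    Each row's score averages exactly the k-1 models not trained on its
    slice. Refuses matrices whose row ids differ from the training corpus.
    """
    check_is_fitted(ensemble, "models_")
    train_ids = getattr(ensemble, "train_ids_", None)
    if train_ids is None or list(matrix.ids) != list(train_ids):
        raise ValueError("matrix rows do not match the ensemble's training corpus")
    scores = ensemble.oof_scores(matrix.values)
    return _table_from_matrix(matrix, scores, svs)


def score_external(
    ensemble: DisjointSliceForestEnsemble,
    matrix: FeatureMatrix,
    svs: Sequence[SVRecord] | None = None,
) -> pd.DataFrame:
    """Score SVs outside the training corpus: mean of all k models."""
    check_is_fitted(ensemble, "models_")
    expected = list(getattr(ensemble, "feature_names_in_", []))
    if expected and list(matrix.feature_names) != expected:
        raise ValueError(
            "feature columns differ from the trained model: "
            f"expected {expected}, got {list(matrix.feature_names)}"
        )
    scores = ensemble.predict_proba(matrix.values)[:, 1]
    return _table_from_matrix(matrix, scores, svs)


def classify_by_score(
    table: pd.DataFrame, high: float = 0.9, low: float = 0.2
) -> pd.DataFrame:
    """Group SVs as pathogenic (score >= high) / benign (<= low) / intermediate."""
    if low >= high:
        raise ValueError(f"low threshold ({low}) must be below high ({high})")
    out = table.copy()
    out["group"] = np.where(
        out["score"] >= high,
        "pathogenic",
        np.where(out["score"] <= low, "benign", "intermediate"),
    )
    return out


# ---------------------------------------------------------------------------
# Tuning and evaluation
# ---------------------------------------------------------------------------

def _sample_hyperparams(rng: np.random.Generator) -> Hyperparams:
    lo_t, hi_t = HYPERPARAM_RANGES["n_trees"]
    n_trees = int(round(np.exp(rng.uniform(np.log(lo_t), np.log(hi_t)))))
    return Hyperparams(
        max_depth=int(rng.integers(*HYPERPARAM_RANGES["max_depth"], endpoint=True)),
        n_trees=int(np.clip(n_trees, lo_t, hi_t)),
        min_samples_split=int(
            rng.integers(*HYPERPARAM_RANGES["min_samples_split"], endpoint=True)
        ),
    )


def evaluate_cv(
    matrix: FeatureMatrix,
    hyperparams: Hyperparams | None = None,
    folds: int = 10,
    seed: int | None = None,
    n_slices: int = 10,
) -> dict:
    """Stratified k-fold CV of the slice ensemble: mean auROC/auPR.

    Each fold trains a fresh ensemble on the other k-1 folds and scores the
    held-out fold with the all-model average.
    """
    hp = hyperparams or Hyperparams()
    ss = np.random.SeedSequence(seed)
    fold_seed, model_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fold_seed)
    X, y = matrix.X, matrix.y
    aurocs, auprs = [], []
    for f, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        if len(np.unique(y[test_idx])) < 2:
            raise ValueError(f"fold {f} contains a single class")
        est = DisjointSliceForestEnsemble(
            n_slices=n_slices,
            max_depth=hp.max_depth,
            n_estimators=hp.n_trees,
            min_samples_split=hp.min_samples_split,
            random_state=model_seed + f,
        )
        est.fit(X[train_idx], y[train_idx])
        s = est.predict_proba(X[test_idx])[:, 1]
        aurocs.append(auroc(y[test_idx], s))
        auprs.append(aupr(y[test_idx], s))
    return {
        "mean_auroc": float(np.mean(aurocs)),
        "mean_aupr": float(np.mean(auprs)),
        "auroc_folds": aurocs,
        "aupr_folds": auprs,
        "folds": folds,
    }


def tune_hyperparameters(
    matrix: FeatureMatrix,
    search_budget: int = 20,
    seed: int | None = None,
    tune_fraction: float = 0.7,
    inner_folds: int = 3,
    n_slices: int = 10,
) -> Hyperparams:
    """Random search over the hyperparameter ranges on a 70% tuning split.

    Candidates are scored by ``inner_folds``-fold CV auROC on the tuning
    split only; the remaining rows stay untouched for holdout testing.
    Returns the argmax candidate.
    """
    if search_budget < 1:
        raise ValueError("search_budget must be >= 1")
    counts = np.bincount(matrix.y)
    if counts.min() < 20:
        raise ValueError("tuning requires at least 20 rows per class")
    ss = np.random.SeedSequence(seed)
    split_seed, sample_seed, eval_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    tune_idx, _ = train_test_split(
        np.arange(len(matrix)),
        train_size=tune_fraction,
        stratify=matrix.y,
        random_state=split_seed,
    )
    tune_matrix = matrix.subset_rows([matrix.ids[i] for i in np.sort(tune_idx)])
    rng = np.random.default_rng(sample_seed)
    best, best_score = None, -np.inf
    for _ in range(search_budget):
        cand = _sample_hyperparams(rng)
        res = evaluate_cv(
            tune_matrix, cand, folds=inner_folds, seed=eval_seed, n_slices=n_slices
        )
        if res["mean_auroc"] > best_score:
            best, best_score = cand, res["mean_auroc"]
    best.validate_in_ranges()
    return best


def feature_importance(
    ensemble: DisjointSliceForestEnsemble,
    matrix: FeatureMatrix,
    n_repeats: int = 3,
    seed: int | None = None,
) -> pd.Series:
    """Permutation importance: drop in out-of-slice auROC per shuffled column.

    Averaged over ``n_repeats`` permutations; the out-of-slice score already
    averages over the k models, so the drop reflects the whole ensemble.
    Non-informative features land in a noise band around 0.
    """
    check_is_fitted(ensemble, "models_")
    rng = np.random.default_rng(seed)
    X = matrix.X
    y = matrix.y
    baseline = auroc(y, ensemble.oof_scores(X))
    drops = {}
    for j, name in enumerate(matrix.feature_names):
        vals = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            vals.append(baseline - auroc(y, ensemble.oof_scores(Xp)))
        drops[name] = float(np.mean(vals))
    return pd.Series(drops, name="auroc_drop")


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

ARCHIVE_FORMAT = "svpath-ensemble-1"


def save_ensemble(ensemble: DisjointSliceForestEnsemble, path, config_hash: str = "") -> None:
    """Serialize a fitted ensemble (models, slices, feature order, params).

    Training SV coordinates are never embedded: row ids are opaque strings.
    """
    check_is_fitted(ensemble, "models_")
    payload = {
        "format": ARCHIVE_FORMAT,
        "params": ensemble.get_params(),
        "feature_names": list(getattr(ensemble, "feature_names_in_", [])),
        "classes": ensemble.classes_,
        "models": ensemble.models_,
        "slice_assignment": ensemble.slice_assignment_,
        "oof_scores": ensemble.oof_scores_,
        "train_ids": list(getattr(ensemble, "train_ids_", [])),
        "config_hash": config_hash,
    }
    joblib.dump(payload, path)


def load_ensemble(path) -> DisjointSliceForestEnsemble:
    payload = joblib.load(path)
    if payload.get("format") != ARCHIVE_FORMAT:
        raise ValueError(f"{path}: not a {ARCHIVE_FORMAT} archive")
    est = DisjointSliceForestEnsemble(**payload["params"])
    est.classes_ = payload["classes"]
    est.models_ = payload["models"]
    est.slice_assignment_ = payload["slice_assignment"]
    est.oof_scores_ = payload["oof_scores"]
    if payload["feature_names"]:
        est.feature_names_in_ = np.asarray(payload["feature_names"], dtype=object)
        est.n_features_in_ = len(payload["feature_names"])
    if payload["train_ids"]:
        est.train_ids_ = payload["train_ids"]
    est.config_hash_ = payload.get("config_hash", "")
    return est


def config_fingerprint(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
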