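"""Imbalance-aware ensemble: balanced partitioning, base predictors,
diversity-driven selection, majority vote.

Construction has four steps.  (1) The majority (non-binding) class is
split into n disjoint subsets of roughly the minority-class size and
each subset is paired with all minority samples, giving n balanced
training sets.  (2) Every instance is encoded in three feature blocks
(PSSM-RT, sequence, physicochemical).  (3) An RBF-kernel SVM (grid-
searched C/gamma) and a random forest are trained per block per set:
6n base predictors.  (4) A committee is grown greedily by disagreement
("diversity") on a validation set and combined by majority vote, with
ties resolved toward the rare binding class.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVC

FEATURE_BLOCKS = ("pssm-rt", "sequence", "physicochemical")
ALGORITHMS = ("svm-rbf", "random-forest")

DEFAULT_SVM_GRID: dict[str, list] = {"C": [1.0, 10.0], "gamma": ["scale"]}


@dataclass(frozen=True)
class BalancedPartition:
    """Disjoint split of the negative instance ids into n subsets."""

    n: int
    subsets: tuple[tuple[int, ...], ...]
    seed: int


@dataclass
class BasePredictor:
    """One fitted classifier: algorithm x feature block x balanced subset."""

    id: str
    algorithm: str
    feature_block: str
    subset_index: int
    estimator: object
    train_ids: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(X), dtype=int)


@dataclass
class EnsembleModel:
    """Selected committee with its selection trace and configuration."""

    predictors: list[BasePredictor]
    epsilon: float
    seed: int
    trace: list[dict]
    window_size: int
    schema_hash: str = ""
    pool_size: int = 0

    @property
    def selected_ids(self) -> list[str]:
        return [p.id for p in self.predictors]


def partition_negatives(
    negative_ids: Sequence[int], positive_count: int, seed: int
) -> BalancedPartition:
    """Shuffle the negatives and split them into n = round(|neg|/|pos|)
    disjoint subsets of as-equal-as-possible size (each within one of the
    positive count when the ratio divides evenly)."""
    if positive_count < 1:
        raise ValueError("positive_count must be >= 1")
    negative_ids = np.asarray(list(negative_ids))
    n = max(1, round(len(negative_ids) / positive_count))
    rng = np.random.default_rng(seed)
    shuffled = negative_ids[rng.permutation(len(negative_ids))]
    subsets = tuple(tuple(int(i) for i in part) for part in np.array_split(shuffled, n))
    return BalancedPartition(n, subsets, seed)


def build_balanced_sets(
    partition: BalancedPartition, positive_ids: Sequence[int]
) -> list[np.ndarray]:
    """Pair every negative subset with the full positive set."""
    positive_ids = np.asarray(list(positive_ids))
    pos_set = set(int(i) for i in positive_ids)
    for subset in partition.subsets:
        clash = pos_set.intersection(subset)
        if clash:
            raise ValueError(f"ids appear as both positive and negative: {sorted(clash)[:5]}")
    return [np.concatenate([positive_ids, np.asarray(s, dtype=int)]) for s in partition.subsets]


def _fit_one(
    algorithm: str,
    X: np.ndarray,
    y: np.ndarray,
    grid: Mapping[str, list],
    seed: int,
    svm_cv: int,
    rf_trees: int,
):
    if algorithm == "svm-rbf":
        est = GridSearchCV(
            SVC(kernel="rbf", random_state=seed, cache_size=300),
            dict(grid),
            cv=svm_cv,
            n_jobs=1,
        )
        est.fit(X, y)
        return est
    if algorithm == "random-forest":
        est = RandomForestClassifier(n_estimators=rf_trees, random_state=seed, n_jobs=1)
        est.fit(X, y)
        return est
    raise ValueError(f"unknown algorithm {algorithm!r}")


def train_base_predictors(
    sets: list[np.ndarray],
    features: Mapping[str, np.ndarray],
    y: np.ndarray,
    seed: int,
    svm_grid: Mapping[str, list] | None = None,
    svm_cv: int = 2,
    rf_trees: int = 100,
) -> list[BasePredictor]:
    """Fit 2 algorithms x |blocks| x n sets base predictors.

    ``features`` maps block name to an N x d matrix aligned with the
    global instance index; ``sets`` hold global indices.
    """
    grid = dict(svm_grid) if svm_grid is not None else DEFAULT_SVM_GRID
    if not grid:
        raise ValueError("empty hyperparameter grid")
    y = np.asarray(y, dtype=int)
    predictors: list[BasePredictor] = []
    for subset_index, ids in enumerate(sets):
        y_sub = y[ids]
        if len(np.unique(y_sub)) < 2:
            raise ValueError(f"training set {subset_index} has a single class")
        for block in features:
            X_sub = features[block][ids]
            for algorithm in ALGORITHMS:
                est = _fit_one(algorithm, X_sub, y_sub, grid, seed, svm_cv, rf_trees)
                pid = f"{algorithm}:{block}:{subset_index}"
                predictors.append(
                    BasePredictor(pid, algorithm, block, subset_index, est, np.asarray(ids))
                )
    return predictors


def diversity(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Disagreement rate: fraction of samples the two predictors label differently."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError(f"label vectors differ in length: {labels_a.shape} vs {labels_b.shape}")
    if labels_a.size == 0:
        raise ValueError("empty label vectors")
    return float(np.mean(labels_a != labels_b))


def _mean_pairwise(div: np.ndarray, idx: list[int]) -> float:
    if len(idx) < 2:
        return 0.0
    sub = div[np.ix_(idx, idx)]
    k = len(idx)
    return float(sub.sum() / (k * (k - 1)))


def select_predictors(
    pool: list[BasePredictor],
    val_features: Mapping[str, np.ndarray],
    epsilon: float,
    seed: int,
    window_size: int = 0,
    schema_hash: str = "",
) -> EnsembleModel:
    """Greedy diversity selection.

    Starting from a uniformly random (seeded) member, each iteration
    ranks the unselected predictors by mean disagreement with the
    current committee on the validation set and adds the best (ties by
    predictor id).  It stops when the diversity the best candidate
    would add — its mean disagreement with the selected committee —
    falls below ``epsilon``, or the pool is exhausted.  (Stopping on
    the change in mean pairwise diversity instead is degenerate: the
    greedy order makes that change negative from the third addition
    on, so any positive threshold would freeze every committee at two
    members.)
    """
    if not pool:
        raise ValueError("empty predictor pool")
    preds = np.vstack([p.predict(val_features[p.feature_block]) for p in pool])
    m = len(pool)
    div = np.zeros((m, m))
    for a in range(m):
        div[a] = np.mean(preds != preds[a], axis=1)

    rng = np.random.default_rng(seed)
    first = int(rng.integers(m))
    selected = [first]
    trace = [{"id": pool[first].id, "mean_diversity": None, "gain": None}]
    remaining = set(range(m)) - {first}
    current = 0.0  # mean pairwise diversity of the committee
    while remaining:
        scores = {c: float(np.mean(div[c, selected])) for c in remaining}
        best = min(remaining, key=lambda c: (-scores[c], pool[c].id))
        if scores[best] < epsilon:
            break
        gain = _mean_pairwise(div, selected + [best]) - current
        selected.append(best)
        remaining.discard(best)
        current += gain
        trace.append({"id": pool[best].id, "mean_diversity": scores[best], "gain": gain})
    return EnsembleModel(
        predictors=[pool[i] for i in selected],
        epsilon=epsilon,
        seed=seed,
        trace=trace,
        window_size=window_size,
        schema_hash=schema_hash,
        pool_size=m,
    )


def vote_predict(
    model: EnsembleModel, features: Mapping[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Majority vote over the committee.

    Returns integer labels and the fraction of positive votes (the
    ROC score).  An exact tie counts as positive: the committee is
    optimised for balanced accuracy, so the rare class gets the nod.
    """
    if not model.predictors:
        raise ValueError("model has no selected predictors")
    votes = np.vstack([p.predict(features[p.feature_block]) for p in model.predictors])
    score = votes.mean(axis=0)
    labels = (score >= 0.5).astype(int)
    return labels, score


# ---------------------------------------------------------------------------
# persistence

def save_model(model: EnsembleModel, directory: str | Path) -> None:
    """Persist the committee: one joblib file per predictor plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "epsilon": model.epsilon,
        "seed": model.seed,
        "window_size": model.window_size,
        "schema_hash": model.schema_hash,
        "pool_size": model.pool_size,
        "trace": model.trace,
        "predictors": [
            {
                "id": p.id,
                "algorithm": p.algorithm,
                "feature_block": p.feature_block,
                "subset_index": p.subset_index,
                "file": f"predictor_{i}.joblib",
            }
            for i, p in enumerate(model.predictors)
        ],
    }
    for i, p in enumerate(model.predictors):
        joblib.dump({"estimator": p.estimator, "train_ids": p.train_ids}, directory / f"predictor_{i}.joblib")
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_model(directory: str | Path) -> EnsembleModel:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    predictors = []
    for entry in manifest["predictors"]:
        payload = joblib.load(directory / entry["file"])
        predictors.append(
            BasePredictor(
                entry["id"],
                entry["algorithm"],
                entry["feature_block"],
                entry["subset_index"],
                payload["estimator"],
                np.asarray(payload["train_ids"]),
            )
        )
    return EnsembleModel(
        predictors=predictors,
        epsilon=manifest["epsilon"],
        seed=manifest["seed"],
        trace=manifest["trace"],
        window_size=manifest["window_size"],
        schema_hash=manifest.get("schema_hash", ""),
        pool_size=manifest.get("pool_size", len(predictors)),
    )


def manifest_hash(directory: str | Path) -> str:
    """Stable hash of a saved model's manifest (for reproducibility checks)."""
    text = (Path(directory) / "manifest.json").read_text()
    return hashlib.sha256(text.encode()).hexdigest()
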