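"""Discriminant-weight feature analysis.

Which amino-acid pair relationships drive the binding/non-binding
decision?  Given a per-training-instance classification weight vector A
(length n) and the n x d training feature matrix M, the discriminant
weight vector is W = A^T M: feature j receives the A-weighted sum of its
values over the training instances.  For margin-based learners A is
well defined: each support vector carries its signed dual coefficient
(positive toward the binding class), other instances carry zero.  The
400 pair-relationship weights are then ranked and laid out on a 20 x 20
amino-acid grid for heat-map inspection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV

from pssmrt.encoders import FeatureSchema
from pssmrt.ensemble import EnsembleModel
from pssmrt.pssm import PSSM_COLUMNS


@dataclass(frozen=True)
class ClassificationWeights:
    """Signed per-training-instance weights a_k with a strategy tag."""

    values: np.ndarray
    strategy: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite classification weights")


@dataclass(frozen=True)
class DiscriminantWeights:
    """Per-feature discriminant weights aligned to a feature schema."""

    values: np.ndarray
    schema: FeatureSchema

    def __post_init__(self) -> None:
        if len(self.values) != self.schema.length:
            raise ValueError(
                f"weight length {len(self.values)} does not match schema length {self.schema.length}"
            )


def discriminant_weights(A: ClassificationWeights, M: np.ndarray, schema: FeatureSchema) -> DiscriminantWeights:
    """W = A^T M, a length-d vector over the feature schema."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != len(A.values):
        raise ValueError(f"shape mismatch: A has {len(A.values)} entries, M is {M.shape}")
    return DiscriminantWeights(A.values @ M, schema)


def extract_classification_weights(
    model: EnsembleModel, n_instances: int, block: str = "pssm-rt", strategy: str = "svm-dual"
) -> ClassificationWeights:
    """Aggregate signed SVM dual coefficients into a per-instance weight vector.

    For every selected RBF-SVM base predictor trained on ``block``, each
    of its support vectors contributes its dual coefficient (sklearn's
    sign convention: positive pushes the decision toward the binding
    class) at the instance's global index; instances never selected as
    support vectors, or absent from every balanced subset, get zero.
    """
    if strategy != "svm-dual":
        raise ValueError(f"unknown weight-extraction strategy {strategy!r}")
    a = np.zeros(n_instances)
    used = 0
    for pred in model.predictors:
        if pred.algorithm != "svm-rbf" or pred.feature_block != block:
            continue
        est = pred.estimator
        if isinstance(est, GridSearchCV):
            est = est.best_estimator_
        local_sv = est.support_  # indices into the predictor's training subset
        dual = est.dual_coef_[0]
        a[pred.train_ids[local_sv]] += dual
        used += 1
    if used == 0:
        raise ValueError(f"no selected SVM base predictor trained on block {block!r}")
    return ClassificationWeights(a, strategy)


def rank_pair_relationships(
    W: DiscriminantWeights, signed: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank the 400 pair-relationship weights and lay them on a 20 x 20 grid.

    Returns ``(ranking, grid)``: the ranking sorted by weight descending
    (or by absolute weight when ``signed=False``), ties broken
    lexicographically by (r1, r2); the grid has context residues r1 as
    rows and target residues r2 as columns.
    """
    a, b = W.schema.offset("pair")
    pair = np.asarray(W.values[a:b], dtype=float)
    rows = [
        {"r1": r1, "r2": r2, "weight": pair[i * 20 + j]}
        for i, r1 in enumerate(PSSM_COLUMNS)
        for j, r2 in enumerate(PSSM_COLUMNS)
    ]
    df = pd.DataFrame(rows)
    key = df["weight"] if signed else df["weight"].abs()
    df = (
        df.assign(_key=-key)
        .sort_values(["_key", "r1", "r2"], kind="stable")
        .drop(columns="_key")
        .reset_index(drop=True)
    )
    grid = pd.DataFrame(
        pair.reshape(20, 20), index=list(PSSM_COLUMNS), columns=list(PSSM_COLUMNS)
    )
    return df, grid


def write_analysis(ranking: pd.DataFrame, grid: pd.DataFrame, directory: str | Path) -> None:
    """Write the ranked pair list and the 20 x 20 grid as TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ranking.to_csv(directory / "pair_ranking.tsv", sep="\t", index=False)
    grid.to_csv(directory / "pair_grid.tsv", sep="\t")
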