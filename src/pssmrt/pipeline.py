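"""End-to-end wiring: dataset encoding, ensemble training, prediction, CV.

The functions here connect the feature encoders to the ensemble core at
the dataset level: every residue of every chain becomes one instance,
encoded once per feature block into matrices aligned on a global
instance index, and chain identity is tracked throughout so that
train/validation/test splits are always cut between chains.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.svm import SVC

from pssmrt.encoders import (
    DEFAULT_PROPERTY_TABLE,
    PropertyTable,
    assemble_pssm_rt,
    encode_physicochemical,
    encode_sequence_features,
    physicochemical_schema,
    pssm_rt_schema,
    sequence_schema,
)
from pssmrt.ensemble import (
    DEFAULT_SVM_GRID,
    EnsembleModel,
    FEATURE_BLOCKS,
    build_balanced_sets,
    partition_negatives,
    select_predictors,
    train_base_predictors,
    vote_predict,
)
from pssmrt.evaluation import ConfusionCounts, RocCurve, confusion, kfold_cv, metrics, roc_auc
from pssmrt.pssm import NormalizedPssm, ProteinChain, Pssm, iter_windows, normalize


@dataclass(frozen=True)
class RunConfig:
    """Tunable knobs of the training/evaluation pipeline.

    window:
        Sliding-window size w (odd); 13 is where balanced accuracy
        saturates on the benchmark profiles, and the default.
    cutoff:
        Binding-distance cutoff in Angstrom for structure labelling.
    epsilon:
        Diversity-gain stopping threshold of committee selection.
    validation_fraction:
        Fraction of training chains held out (chain-level) for the
        diversity-selection validation set.
    """

    window: int = 13
    cutoff: float = 3.5
    epsilon: float = 0.01
    seed: int = 0
    folds: int = 5
    blocks: tuple[str, ...] = FEATURE_BLOCKS
    svm_grid: Mapping[str, tuple] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_SVM_GRID.items()}
    )
    svm_cv: int = 2
    rf_trees: int = 100
    validation_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")

    def schema_hash(self) -> str:
        """Fingerprint of the encoder schemas at this window size.

        A persisted model carries this hash; prediction refuses to run
        when the installed encoders would produce differently shaped
        feature vectors.
        """
        payload = json.dumps(
            {
                "window": self.window,
                "pssm-rt": pssm_rt_schema(self.window).blocks,
                "sequence": sequence_schema(self.window).blocks,
                "physicochemical": physicochemical_schema(self.window).blocks,
            }
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class EncodedDataset:
    """All residues of a chain collection, encoded per feature block."""

    features: dict[str, np.ndarray]  # block -> N x d
    y: np.ndarray  # N, 1 = binding
    chain_ids: np.ndarray  # N, chain id per instance
    positions: np.ndarray  # N, 1-based residue position
    window: int

    @property
    def n(self) -> int:
        return len(self.y)

    def chain_mask(self, chain_ids: Sequence[str]) -> np.ndarray:
        wanted = set(chain_ids)
        return np.array([cid in wanted for cid in self.chain_ids])

    def subset_features(self, mask: np.ndarray) -> dict[str, np.ndarray]:
        return {b: X[mask] for b, X in self.features.items()}


def encode_chain(
    chain: ProteinChain,
    npssm: NormalizedPssm,
    w: int,
    blocks: Sequence[str] = FEATURE_BLOCKS,
    ss: np.ndarray | None = None,
    acc: np.ndarray | None = None,
    table: PropertyTable = DEFAULT_PROPERTY_TABLE,
) -> dict[str, np.ndarray]:
    """Encode every residue of one chain: block name -> L x d matrix."""
    rows: dict[str, list[np.ndarray]] = {b: [] for b in blocks}
    for inst in iter_windows(npssm, w, chain):
        if "pssm-rt" in rows:
            rows["pssm-rt"].append(assemble_pssm_rt(inst).values)
        if "sequence" in rows:
            rows["sequence"].append(
                encode_sequence_features(inst, ss, acc, chain_length=chain.length).values
            )
        if "physicochemical" in rows:
            rows["physicochemical"].append(encode_physicochemical(inst, table).values)
    return {b: np.vstack(v) for b, v in rows.items()}


def encode_dataset(
    chains: Sequence[ProteinChain],
    pssms: Sequence[Pssm],
    labels: Mapping[str, np.ndarray],
    w: int,
    blocks: Sequence[str] = FEATURE_BLOCKS,
    tracks: Mapping[str, tuple[np.ndarray | None, np.ndarray | None]] | None = None,
    table: PropertyTable = DEFAULT_PROPERTY_TABLE,
) -> EncodedDataset:
    """Encode a whole chain collection into aligned feature matrices."""
    feats: dict[str, list[np.ndarray]] = {b: [] for b in blocks}
    ys, cids, poss = [], [], []
    pssm_by_id = {p.chain_id: p for p in pssms}
    for chain in chains:
        if chain.chain_id not in pssm_by_id:
            raise FileNotFoundError(f"no PSSM for chain {chain.chain_id}")
        npssm = normalize(pssm_by_id[chain.chain_id])
        ss, acc = (tracks or {}).get(chain.chain_id, (None, None))
        enc = encode_chain(chain, npssm, w, blocks, ss, acc, table)
        for b in blocks:
            feats[b].append(enc[b])
        lab = np.asarray(labels[chain.chain_id], dtype=int)
        if len(lab) != chain.length:
            raise ValueError(f"chain {chain.chain_id}: {len(lab)} labels for {chain.length} residues")
        ys.append(lab)
        cids += [chain.chain_id] * chain.length
        poss += list(range(1, chain.length + 1))
    return EncodedDataset(
        features={b: np.vstack(v) for b, v in feats.items()},
        y=np.concatenate(ys),
        chain_ids=np.array(cids),
        positions=np.array(poss),
        window=w,
    )


@dataclass
class TrainResult:
    model: EnsembleModel
    encoded: EncodedDataset
    train_mask: np.ndarray  # instances available for partitioning/training
    validation_chains: list[str]
    partition_sizes: list[int]


def _split_validation_chains(
    chain_ids: Sequence[str], fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    unique = list(dict.fromkeys(chain_ids))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    n_val = max(1, int(round(fraction * len(unique)))) if len(unique) > 1 else 0
    val = [unique[i] for i in order[:n_val]]
    train = [unique[i] for i in order[n_val:]]
    if not train:
        raise ValueError("validation split left no training chains")
    return train, val


def train_model(encoded: EncodedDataset, config: RunConfig) -> TrainResult:
    """Run the four construction steps on an encoded dataset.

    A seeded chain-level slice (``validation_fraction``) is held out as
    the diversity-selection validation set; the remaining chains supply
    the balanced partition and base-predictor training data.
    """
    train_chains, val_chains = _split_validation_chains(
        encoded.chain_ids, config.validation_fraction, config.seed
    )
    train_mask = encoded.chain_mask(train_chains)
    val_mask = encoded.chain_mask(val_chains) if val_chains else ~train_mask

    train_idx = np.flatnonzero(train_mask)
    y_train = encoded.y[train_idx]
    pos_ids = train_idx[y_train == 1]
    neg_ids = train_idx[y_train == 0]
    if len(pos_ids) == 0 or len(neg_ids) == 0:
        raise ValueError("training chains must contain both classes")

    partition = partition_negatives(neg_ids, len(pos_ids), config.seed)
    sets = build_balanced_sets(partition, pos_ids)
    pool = train_base_predictors(
        sets,
        encoded.features,
        encoded.y,
        seed=config.seed,
        svm_grid={k: list(v) for k, v in config.svm_grid.items()},
        svm_cv=config.svm_cv,
        rf_trees=config.rf_trees,
    )
    val_features = encoded.subset_features(val_mask)
    model = select_predictors(
        pool,
        val_features,
        epsilon=config.epsilon,
        seed=config.seed,
        window_size=config.window,
        schema_hash=config.schema_hash(),
    )
    return TrainResult(
        model=model,
        encoded=encoded,
        train_mask=train_mask,
        validation_chains=val_chains,
        partition_sizes=[len(s) for s in partition.subsets],
    )


def predict_chain(
    model: EnsembleModel,
    chain: ProteinChain,
    pssm: Pssm,
    ss: np.ndarray | None = None,
    acc: np.ndarray | None = None,
    table: PropertyTable = DEFAULT_PROPERTY_TABLE,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue labels (1 = binding) and vote-fraction scores for one chain."""
    blocks = sorted({p.feature_block for p in model.predictors})
    enc = encode_chain(chain, normalize(pssm), model.window_size, blocks, ss, acc, table)
    return vote_predict(model, enc)


def evaluate_split(
    encoded: EncodedDataset, config: RunConfig, test_chains: Sequence[str]
) -> tuple[ConfusionCounts, RocCurve, TrainResult]:
    """Train on all chains except ``test_chains``; score the held-out chains."""
    test_mask = encoded.chain_mask(test_chains)
    train_encoded = EncodedDataset(
        features=encoded.subset_features(~test_mask),
        y=encoded.y[~test_mask],
        chain_ids=encoded.chain_ids[~test_mask],
        positions=encoded.positions[~test_mask],
        window=encoded.window,
    )
    result = train_model(train_encoded, config)
    labels, scores = vote_predict(result.model, encoded.subset_features(test_mask))
    y_test = encoded.y[test_mask]
    return confusion(y_test, labels), roc_auc(scores, y_test), result


def cross_validate(encoded: EncodedDataset, config: RunConfig) -> dict:
    """Chain-level k-fold cross-validation of the full pipeline."""
    unique_chains = list(dict.fromkeys(encoded.chain_ids))

    def evaluate_fold(train_ids: list[str], test_ids: list[str]):
        counts, roc, _ = evaluate_split(encoded, config, test_ids)
        return counts, roc

    return kfold_cv(unique_chains, evaluate_fold, k=config.folds, seed=config.seed)


@dataclass
class SyntheticExperiment:
    """One held-out evaluation of the pipeline on generated data."""

    counts: ConfusionCounts
    roc: RocCurve
    train: TrainResult
    encoded: EncodedDataset
    test_chains: list[str]
    spec: "object"


def run_synthetic_experiment(
    seed: int,
    effect_size: float = 6.0,
    imbalance: float = 5.0,
    n_chains: int = 60,
    length_range: tuple[int, int] = (40, 60),
    config: RunConfig | None = None,
    test_fraction: float = 0.25,
) -> SyntheticExperiment:
    """Generate a labelled dataset, train on 1 - test_fraction of the
    chains and score the rest.

    The defaults emulate one benchmark-like condition: about 3000
    residues at 1:5 imbalance with the planted pair signal at raw-score
    shift 6.
    """
    from pssmrt.synthetic import SignalSpec, gen_labeled_dataset

    spec = SignalSpec(effect_size=effect_size, imbalance=imbalance)
    ds = gen_labeled_dataset(n_chains, length_range, spec, seed=seed)
    cfg = config if config is not None else RunConfig(seed=seed)
    encoded = encode_dataset(ds.chains, ds.pssms, ds.labels, cfg.window, cfg.blocks)
    unique = list(dict.fromkeys(encoded.chain_ids))
    rng = np.random.default_rng(seed)
    n_test = max(1, int(round(test_fraction * len(unique))))
    test_chains = [unique[i] for i in rng.permutation(len(unique))[:n_test]]
    counts, roc, result = evaluate_split(encoded, cfg, test_chains)
    return SyntheticExperiment(counts, roc, result, encoded, test_chains, spec)


def window_st(encoded_by_w: EncodedDataset, config: RunConfig) -> float:
    """Balanced accuracy of a single RBF-SVM on PSSM-RT at one window size.

    Used by the window-size sweep: chains are split 75/25 (seeded), one
    balanced training sample (all positives plus an equal-size seeded
    negative draw) trains the SVM, and ST is measured on the held-out
    chains.
    """
    unique = list(dict.fromkeys(encoded_by_w.chain_ids))
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(unique))
    n_test = max(1, len(unique) // 4)
    test_chains = [unique[i] for i in order[:n_test]]
    test_mask = encoded_by_w.chain_mask(test_chains)

    train_idx = np.flatnonzero(~test_mask)
    y_train = encoded_by_w.y[train_idx]
    pos = train_idx[y_train == 1]
    neg = train_idx[y_train == 0]
    neg_sample = neg[rng.permutation(len(neg))[: len(pos)]]
    ids = np.concatenate([pos, neg_sample])
    X = encoded_by_w.features["pssm-rt"]
    clf = SVC(kernel="rbf", C=1.0, gamma="scale", random_state=config.seed)
    clf.fit(X[ids], encoded_by_w.y[ids])
    pred = clf.predict(X[test_mask])
    m = metrics(confusion(encoded_by_w.y[test_mask], pred))
    return 0.0 if m.ST is None else m.ST
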