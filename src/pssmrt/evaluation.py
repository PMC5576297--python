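"""Confusion-based metrics, ROC/AUC, cross-validation and paired tests.

Residue-level binary predictions are scored with sensitivity SN =
TP/(TP+FN), specificity SP = TN/(TN+FP), strength ST = (SN+SP)/2,
accuracy ACC = (TP+TN)/N and the Matthews correlation coefficient.  ST
and MCC are the headline numbers because the two classes are heavily
imbalanced; ROC curves are swept over the vote-fraction score and AUC
integrated by the trapezoidal rule.  Cross-validation folds are cut at
the chain level so that near-identical windows from one chain never
straddle the train/test boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import wilcoxon


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.TN + other.TN, self.FP + other.FP, self.FN + other.FN
        )


@dataclass(frozen=True)
class MetricSet:
    """SN/SP/ST/ACC as fractions, MCC in [-1, 1], optional AUC in [0, 1].

    A metric whose denominator is zero is reported as None (undefined),
    never silently as 0.
    """

    SN: float | None
    SP: float | None
    ST: float | None
    ACC: float | None
    MCC: float | None
    AUC: float | None = None

    def as_percent(self) -> dict:
        out = {}
        for name in ("SN", "SP", "ST", "ACC"):
            v = getattr(self, name)
            out[name] = None if v is None else 100.0 * v
        out["MCC"] = self.MCC
        out["AUC"] = self.AUC
        return out


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def confusion(true_labels: Sequence[int], predicted_labels: Sequence[int]) -> ConfusionCounts:
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError(f"label vectors differ in length: {t.shape} vs {p.shape}")
    return ConfusionCounts(
        TP=int(np.sum((t == 1) & (p == 1))),
        TN=int(np.sum((t == 0) & (p == 0))),
        FP=int(np.sum((t == 0) & (p == 1))),
        FN=int(np.sum((t == 1) & (p == 0))),
    )


def _ratio(num: float, den: float, name: str) -> float | None:
    if den == 0:
        warnings.warn(f"{name} undefined: zero denominator", RuntimeWarning, stacklevel=3)
        return None
    return num / den


def metrics(c: ConfusionCounts, auc: float | None = None) -> MetricSet:
    """Compute SN, SP, ST, ACC and MCC from confusion counts."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    sn = _ratio(c.TP, c.TP + c.FN, "SN")
    sp = _ratio(c.TN, c.TN + c.FP, "SP")
    st = None if sn is None or sp is None else (sn + sp) / 2
    acc = (c.TP + c.TN) / c.total
    denom = (c.TP + c.FN) * (c.TP + c.FP) * (c.TN + c.FP) * (c.TN + c.FN)
    if denom == 0:
        warnings.warn("MCC undefined: zero denominator", RuntimeWarning, stacklevel=2)
        mcc = None
    else:
        mcc = (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom)
    return MetricSet(SN=sn, SP=sp, ST=st, ACC=acc, MCC=mcc, AUC=auc)


def roc_auc(scores: Sequence[float], true_labels: Sequence[int]) -> RocCurve:
    """ROC by sweeping every distinct score threshold; AUC by trapezoid.

    The trapezoidal area equals the probability that a random positive
    outscores a random negative, with ties counted one half.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(true_labels, dtype=int)
    if s.shape != t.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(t.sum())
    n_neg = len(t) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires at least one positive and one negative")
    order = np.argsort(-s, kind="stable")
    s_sorted, t_sorted = s[order], t[order]
    # cumulative counts at each distinct threshold
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tps = np.cumsum(t_sorted)[distinct]
    fps = np.cumsum(1 - t_sorted)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def chain_folds(chain_ids: Sequence[str], k: int, seed: int) -> list[list[str]]:
    """Deterministic chain-level partition into k folds."""
    ids = list(chain_ids)
    if len(ids) < k:
        raise ValueError(f"need at least {k} chains for {k}-fold CV, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    folds: list[list[str]] = [[] for _ in range(k)]
    for j, idx in enumerate(order):
        folds[j % k].append(ids[idx])
    return folds


def kfold_cv(
    chains: Sequence,
    evaluate_fold: Callable[[list[str], list[str]], tuple[ConfusionCounts, "RocCurve | None"]],
    k: int = 5,
    seed: int = 0,
) -> dict:
    """Chain-level k-fold cross-validation.

    ``evaluate_fold(train_chain_ids, test_chain_ids)`` must train on the
    first set and return confusion counts (and optionally a ROC curve)
    on the second.  Pooled metrics come from the summed confusion counts
    across folds (micro aggregation); per-fold metric sets are retained
    for paired significance testing.
    """
    chain_ids = [c if isinstance(c, str) else c.chain_id for c in chains]
    folds = chain_folds(chain_ids, k, seed)
    per_fold: list[MetricSet] = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    rocs: list[RocCurve] = []
    for j, test_ids in enumerate(folds):
        train_ids = [cid for cid in chain_ids if cid not in set(test_ids)]
        counts, roc = evaluate_fold(train_ids, test_ids)
        per_fold.append(metrics(counts, auc=None if roc is None else roc.auc))
        pooled = pooled + counts
        if roc is not None:
            rocs.append(roc)
    return {
        "folds": folds,
        "per_fold": per_fold,
        "pooled_counts": pooled,
        "pooled": metrics(pooled),
        "rocs": rocs,
    }


def sweep_window(
    candidate_w: Sequence[int],
    evaluate_w: Callable[[int], float],
) -> tuple[dict[int, float], int]:
    """Evaluate a pipeline at each odd window size and pick the ST-maximising w.

    Ties go to the smaller window.
    """
    if not candidate_w:
        raise ValueError("no candidate window sizes")
    for w in candidate_w:
        if w % 2 == 0:
            raise ValueError(f"window sizes must be odd, got {w}")
    st = {int(w): float(evaluate_w(int(w))) for w in candidate_w}
    best = min(st, key=lambda w: (-st[w], w))
    return st, best


def compare_methods(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired per-fold metrics.

    Uses the exact null distribution (appropriate at the small k of
    cross-validation).  Identical samples give p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 paired observations of equal length")
    diff = a - b
    if np.all(diff == 0):
        warnings.warn("all paired differences are zero; p = 1", RuntimeWarning, stacklevel=2)
        return 1.0
    res = wilcoxon(a, b, alternative="two-sided", method="exact", zero_method="wilcox")
    return float(res.pvalue)
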