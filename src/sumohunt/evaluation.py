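"""Evaluation protocols and accuracy measures.

Implements the full battery used to assess the predictor: a seeded
percentage split, k-fold cross-validation, leave-one-out (jackknife), and
the self-consistency test, each summarized by sensitivity, specificity,
accuracy, the Matthews correlation coefficient,

    SN  = TP/(TP+FN),   SP = TN/(TN+FP),   AC = (TP+TN)/(TP+TN+FP+FN),
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

and the area under the ROC curve computed from vote fractions by the
rank-sum (Mann-Whitney) statistic with mid-ranks for ties — equivalent to
trapezoidal integration of the ROC over all thresholds.

SN/SP/AC are reported as percentages.  When the MCC denominator is zero the
coefficient is defined as 0 (the undefined, chance-level case).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import forest as _forest
from .encoding import EncodedDataset
from .errors import MetricsError, SplitError

#: A trainer maps (training data, seed) to a scorer; a scorer maps a feature
#: matrix to per-instance vote fractions in [0, 1].
Trainer = Callable[[EncodedDataset, int], Callable[[np.ndarray], np.ndarray]]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP / FP / TN / FN of a binary evaluation."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise MetricsError("negative confusion count")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(
        cls, truth: np.ndarray, predicted: np.ndarray
    ) -> "ConfusionCounts":
        truth = np.asarray(truth, dtype=bool)
        predicted = np.asarray(predicted, dtype=bool)
        return cls(
            tp=int(np.sum(truth & predicted)),
            fp=int(np.sum(~truth & predicted)),
            tn=int(np.sum(~truth & ~predicted)),
            fn=int(np.sum(truth & ~predicted)),
        )

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricsReport:
    """SN/SP/AC (percent), MCC, optional AUC, and the underlying counts."""

    ac: float
    sn: float
    sp: float
    mcc: float
    counts: ConfusionCounts
    auc: Optional[float] = None
    protocol: str = ""

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "AC%": self.ac,
            "SN%": self.sn,
            "SP%": self.sp,
            "MCC": self.mcc,
            "AUC": self.auc,
            "TP": self.counts.tp,
            "FP": self.counts.fp,
            "TN": self.counts.tn,
            "FN": self.counts.fn,
        }

    def rounded(self) -> dict:
        """Display rounding: percentages and MCC to 2 decimals."""
        d = self.to_dict()
        for key in ("AC%", "SN%", "SP%"):
            d[key] = round(d[key], 2)
        d["MCC"] = round(d["MCC"], 2)
        if d["AUC"] is not None:
            d["AUC"] = round(d["AUC"], 2)
        return d


def compute_metrics(
    counts: ConfusionCounts, auc: Optional[float] = None, protocol: str = ""
) -> MetricsReport:
    """SN/SP/AC/MCC from confusion counts.

    Raises :class:`MetricsError` when all counts are zero or an SN/SP
    denominator vanishes; a zero MCC denominator yields MCC = 0.
    """
    if counts.total == 0:
        raise MetricsError("all confusion counts are zero")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if tp + fn == 0:
        raise MetricsError("no positive instances: SN undefined")
    if tn + fp == 0:
        raise MetricsError("no negative instances: SP undefined")
    sn = 100.0 * tp / (tp + fn)
    sp = 100.0 * tn / (tn + fp)
    ac = 100.0 * (tp + tn) / counts.total
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
    return MetricsReport(ac=ac, sn=sn, sp=sp, mcc=mcc, counts=counts,
                         auc=auc, protocol=protocol)


@dataclass(frozen=True)
class SplitPlan:
    """Indices of one train/test split (or one CV fold)."""

    train: tuple[int, ...]
    test: tuple[int, ...]
    seed: int
    description: str = ""


def percentage_split(
    dataset: EncodedDataset, train_pct: float, seed: int
) -> SplitPlan:
    """Seeded shuffle, first ``floor(n*train_pct/100)`` instances train.

    WEKA-era percentage splits claimed to extract the most favorable
    training instances, a behavior with no public specification; a seeded
    uniform shuffle with a prefix split is used instead, preferring exact
    reproducibility over fidelity to an unspecifiable procedure.
    """
    n = len(dataset)
    if not 0 < train_pct < 100:
        raise SplitError(f"train_pct must be in (0, 100), got {train_pct}")
    n_train = int(math.floor(n * train_pct / 100.0))
    if n_train == 0 or n_train == n:
        raise SplitError(f"split {train_pct}% of {n} leaves an empty side")
    perm = np.random.default_rng(seed).permutation(n)
    return SplitPlan(
        tuple(perm[:n_train].tolist()),
        tuple(perm[n_train:].tolist()),
        seed,
        f"split{train_pct:g}",
    )


def forest_trainer(
    n_trees: int = 10, mtry: Optional[int] = None, bootstrap: bool = True
) -> Trainer:
    """The default trainer: a ``n_trees``-tree random forest."""

    def trainer(train: EncodedDataset, seed: int):
        model = _forest.train_forest(
            train, n_trees=n_trees, mtry=mtry, seed=seed, bootstrap=bootstrap
        )
        return lambda X: _forest.vote_fractions(model, X)

    return trainer


def _evaluate_plan(
    dataset: EncodedDataset, plan: SplitPlan, trainer: Trainer, seed: int
) -> tuple[ConfusionCounts, np.ndarray, np.ndarray]:
    scorer = trainer(dataset.subset(plan.train), seed)
    test = dataset.subset(plan.test)
    scores = np.asarray(scorer(test.X), dtype=float)
    predicted = scores > 0.5
    return ConfusionCounts.from_predictions(test.y, predicted), scores, test.y


def evaluate_split(
    dataset: EncodedDataset,
    train_pct: float,
    trainer: Trainer,
    seed: int,
) -> MetricsReport:
    """Train on a seeded percentage split, report metrics on the held-out part."""
    plan = percentage_split(dataset, train_pct, seed)
    counts, scores, truth = _evaluate_plan(dataset, plan, trainer, seed)
    auc = None
    if truth.any() and not truth.all():
        auc, _ = roc_auc(scores, truth)
    return compute_metrics(counts, auc=auc, protocol=plan.description)


def k_fold_plan(n: int, k: int, seed: int) -> list[SplitPlan]:
    """Seeded partition of ``range(n)`` into k near-equal disjoint folds."""
    if not 2 <= k <= n:
        raise SplitError(f"k must be in [2, {n}], got {k}")
    perm = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(perm, k)
    plans = []
    for i, fold in enumerate(folds):
        test = tuple(fold.tolist())
        in_test = set(test)
        train = tuple(int(j) for j in perm if int(j) not in in_test)
        plans.append(SplitPlan(train, test, seed, f"fold{i + 1}/{k}"))
    return plans


def k_fold_cv(
    dataset: EncodedDataset,
    k: int,
    trainer: Trainer,
    seed: int,
) -> tuple[MetricsReport, list[MetricsReport]]:
    """k-fold cross-validation: every instance tested exactly once.

    Returns the pooled report (confusion counts summed over folds, AUC over
    the pooled out-of-fold scores) plus per-fold reports where the fold's
    metrics are defined.
    """
    plans = k_fold_plan(len(dataset), k, seed)
    pooled = ConfusionCounts(0, 0, 0, 0)
    all_scores = np.empty(len(dataset))
    all_truth = np.empty(len(dataset), dtype=bool)
    per_fold: list[MetricsReport] = []
    for plan in plans:
        counts, scores, truth = _evaluate_plan(dataset, plan, trainer, seed)
        pooled = pooled + counts
        idx = np.asarray(plan.test, dtype=int)
        all_scores[idx] = scores
        all_truth[idx] = truth
        try:
            per_fold.append(compute_metrics(counts, protocol=plan.description))
        except MetricsError:
            pass  # single-class fold: fold-level SN or SP undefined
    auc, _ = roc_auc(all_scores, all_truth)
    report = compute_metrics(pooled, auc=auc, protocol=f"{k}-fold-cv")
    return report, per_fold


def loocv(
    dataset: EncodedDataset, trainer: Trainer, seed: int
) -> MetricsReport:
    """Jackknife: k-fold cross-validation with k equal to the instance count."""
    report, _ = k_fold_cv(dataset, len(dataset), trainer, seed)
    return MetricsReport(
        ac=report.ac, sn=report.sn, sp=report.sp, mcc=report.mcc,
        counts=report.counts, auc=report.auc, protocol="loocv",
    )


def self_consistency(
    dataset: EncodedDataset, trainer: Trainer, seed: int
) -> MetricsReport:
    """Train on the full dataset and evaluate on the same instances."""
    scorer = trainer(dataset, seed)
    scores = np.asarray(scorer(dataset.X), dtype=float)
    counts = ConfusionCounts.from_predictions(dataset.y, scores > 0.5)
    auc, _ = roc_auc(scores, dataset.y)
    return compute_metrics(counts, auc=auc, protocol="self-consistency")


def roc_auc(
    scores: Sequence[float], truth: Sequence[bool]
) -> tuple[float, np.ndarray]:
    """AUC by the mid-rank Mann-Whitney statistic, plus ROC points.

    Returns ``(auc, points)`` where ``points`` is an array of (FPR, TPR)
    pairs from threshold (infinity) down to (-infinity), suitable for
    plotting; the rank-based AUC equals the trapezoidal area under these
    points.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    n_pos = int(truth.sum())
    n_neg = int(truth.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise MetricsError("ROC requires both classes in the truth labels")
    ranks = rankdata(scores)  # mid-ranks for ties
    auc = (ranks[truth].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    # ROC points: descending unique thresholds.
    order = np.argsort(-scores, kind="stable")
    sorted_truth = truth[order]
    sorted_scores = scores[order]
    tp = np.cumsum(sorted_truth)
    fp = np.cumsum(~sorted_truth)
    # keep the last index of each tied score block
    last = np.nonzero(np.append(sorted_scores[1:] != sorted_scores[:-1], True))[0]
    tpr = np.concatenate([[0.0], tp[last] / n_pos])
    fpr = np.concatenate([[0.0], fp[last] / n_neg])
    return float(auc), np.column_stack([fpr, tpr])


def window_sweep(
    datasets: dict[int, EncodedDataset],
    trainer: Trainer,
    seed: int,
    train_pct: float = 93.0,
) -> pd.DataFrame:
    """One percentage-split evaluation per window size.

    ``datasets`` maps flank (3/5/10) to the encoding of the *same* sites at
    that flank.  Returns one row per window size with the split
    composition and all accuracy measures.
    """
    rows = []
    for flank in sorted(datasets):
        ds = datasets[flank]
        plan = percentage_split(ds, train_pct, seed)
        train = ds.subset(plan.train)
        test = ds.subset(plan.test)
        report = evaluate_split(ds, train_pct, trainer, seed)
        rows.append(
            {
                "window": 2 * flank + 1,
                "split%": train_pct,
                "+train": int(train.y.sum()),
                "-train": int((~train.y).sum()),
                "AC%": round(report.ac, 2),
                "SN%": round(report.sn, 2),
                "SP%": round(report.sp, 2),
                "MCC": round(report.mcc, 2),
                "AUC": None if report.auc is None else round(report.auc, 2),
                "+test": int(test.y.sum()),
                "-test": int((~test.y).sum()),
            }
        )
    return pd.DataFrame(rows)
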