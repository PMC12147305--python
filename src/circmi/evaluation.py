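"""Negative sampling, fold construction, metrics, cross-validation.

Threshold metrics follow the standard confusion-matrix definitions
(accuracy, sensitivity, specificity, precision, F1, MCC); ranking metrics
are ROC AUC (Mann-Whitney, ties averaged) and AUPR (step-interpolated
precision-recall area).  Cross-validation is stratified five-fold: each
fold holds out 20% of pairs as test, and the classifier internally holds
out 1/8 of the remaining 80% (10% overall) for early stopping.

In leakage-safe mode (default) each fold's structural embedding is rebuilt
with that fold's test positives removed from the association matrix, so
structural features cannot encode the held-out answers.  The alternative
``leakage_safe=False`` embeds once on the full matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import sqrt

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from circmi.classifier import (
    ClassifierConfig,
    model_fit,
    predict_labels,
    predict_scores,
)
from circmi.config import PipelineConfig
from circmi.io_formats import AssociationMatrix, InteractionTable
from circmi.pipeline import (
    CmiDataset,
    SequenceCodes,
    assemble_pair_features,
    compute_sequence_codes,
    compute_structure_features,
    masked_association,
)

logger = logging.getLogger("circmi")

_METRIC_NAMES = ("acc", "sen", "spe", "pre", "f1", "mcc", "auc", "aupr")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    acc: float = float("nan")
    sen: float = float("nan")
    spe: float = float("nan")
    pre: float = float("nan")
    f1: float = float("nan")
    mcc: float = float("nan")
    auc: float = float("nan")
    aupr: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in _METRIC_NAMES}


@dataclass
class CvReport:
    folds: list[MetricReport]
    mean: MetricReport
    sd: MetricReport
    fold_assignment: dict[tuple[str, str], int]
    seed: int
    fold_scores: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def as_rows(self) -> list[dict]:
        """Table layout: one row per fold, then a mean and an sd row."""
        rows = [
            {"fold": str(i + 1), **m.as_dict()} for i, m in enumerate(self.folds)
        ]
        rows.append({"fold": "mean", **self.mean.as_dict()})
        rows.append({"fold": "sd", **self.sd.as_dict()})
        return rows


def negative_sample(
    assoc: AssociationMatrix, ratio: float, seed: int
) -> InteractionTable:
    """Uniformly sample round(ratio * #positives) distinct unobserved cells."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    zero_flat = np.flatnonzero(assoc.A.ravel() == 0)
    n_pos = int(assoc.A.sum())
    n_neg = int(round(ratio * n_pos))
    if n_neg > len(zero_flat):
        raise ValueError(
            f"requested {n_neg} negatives but only {len(zero_flat)} unobserved cells"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(zero_flat, size=n_neg, replace=False)
    n_mi = assoc.A.shape[1]
    pairs = [
        (assoc.row_ids[idx // n_mi], assoc.col_ids[idx % n_mi], 0) for idx in chosen
    ]
    return InteractionTable(pairs=pairs, provenance="sampled-negative")


def make_folds(
    positives: InteractionTable,
    negatives: InteractionTable,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], np.ndarray, list[np.ndarray]]:
    """Stratified partition of pos+neg pairs into ``n_folds`` test folds.

    Returns (pairs, labels, list of test-index arrays).  The union of the
    test folds is the full set and folds are pairwise disjoint.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    pairs = [(c, m) for c, m, _ in positives.pairs] + [
        (c, m) for c, m, _ in negatives.pairs
    ]
    labels = np.array([1] * len(positives.pairs) + [0] * len(negatives.pairs))
    if min(np.bincount(labels)) < n_folds:
        raise ValueError("each class needs at least n_folds members")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    test_folds = [test for _, test in skf.split(np.zeros(len(labels)), labels)]
    return pairs, labels, test_folds


def confusion(labels: np.ndarray, predicted: np.ndarray) -> ConfusionCounts:
    labels = np.asarray(labels).astype(int)
    predicted = np.asarray(predicted).astype(int)
    if labels.shape != predicted.shape:
        raise ValueError("labels/predictions length mismatch")
    return ConfusionCounts(
        tp=int(np.sum((labels == 1) & (predicted == 1))),
        fp=int(np.sum((labels == 0) & (predicted == 1))),
        tn=int(np.sum((labels == 0) & (predicted == 0))),
        fn=int(np.sum((labels == 1) & (predicted == 0))),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reported as NaN", name)
        return float("nan")
    return num / den


def metrics(counts: ConfusionCounts) -> MetricReport:
    """Confusion-derived metrics; undefined ratios are NaN with a warning."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    acc = (tp + tn) / counts.total
    sen = _ratio(tp, tp + fn, "sensitivity")
    spe = _ratio(tn, tn + fp, "specificity")
    pre = _ratio(tp, tp + fp, "precision")
    if np.isnan(pre) or np.isnan(sen) or (pre + sen) == 0:
        f1 = float("nan")
        if not np.isnan(pre) and not np.isnan(sen):
            logger.warning("F1 undefined (precision + sensitivity = 0)")
    else:
        f1 = 2 * pre * sen / (pre + sen)
    denom = sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _ratio(tp * tn - fp * fn, denom, "MCC")
    return MetricReport(acc=acc, sen=sen, spe=spe, pre=pre, f1=f1, mcc=mcc)


def rank_metrics(labels: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """(AUC, AUPR): Mann-Whitney ROC area and step-interpolated PR area."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("rank metrics need both classes present")
    return (
        float(roc_auc_score(labels, scores)),
        float(average_precision_score(labels, scores)),
    )


def _aggregate(fold_reports: list[MetricReport]) -> tuple[MetricReport, MetricReport]:
    mean, sd = MetricReport(), MetricReport()
    for name in _METRIC_NAMES:
        vals = np.array([getattr(r, name) for r in fold_reports])
        setattr(mean, name, float(np.nanmean(vals)))
        setattr(sd, name, float(np.nanstd(vals)))
    return mean, sd


def _classifier_config(config: PipelineConfig, seed: int) -> ClassifierConfig:
    return ClassifierConfig(
        hidden=config.hidden,
        l2=config.l2,
        lr=config.lr,
        max_iter=config.max_iter,
        batch_size=config.batch_size,
        early_stopping=config.early_stopping,
        val_frac=config.val_frac,
        patience=config.patience,
        attn_lr_scale=config.attn_lr_scale,
        fusion_mode=config.fusion_mode,
        fusion_ratios=config.fusion_ratios,
        seed=seed,
    )


def cross_validate(
    dataset: CmiDataset,
    config: PipelineConfig | None = None,
    seed: int = 0,
    codes: SequenceCodes | None = None,
    permute_labels: bool = False,
) -> CvReport:
    """Stratified k-fold evaluation of the full pipeline.

    ``codes`` lets callers reuse precomputed (label-free) sequence codes
    across repeated runs.  ``permute_labels=True`` shuffles the pair labels
    before fold construction: the null benchmark whose AUC should sit near
    0.5.
    """
    config = config or PipelineConfig()
    assoc = dataset.association()
    negatives = dataset.negatives
    if negatives is None:
        negatives = negative_sample(assoc, config.neg_ratio, seed)
    if codes is None:
        codes = compute_sequence_codes(
            dataset.records_circ, dataset.records_mi, config, seed=seed
        )

    pairs, labels, test_folds = make_folds(
        dataset.positives, negatives, n_folds=config.n_folds, seed=seed
    )
    if permute_labels:
        labels = np.random.default_rng(seed + 1).permutation(labels)
        # re-stratify on the permuted labels
        skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=seed)
        test_folds = [t for _, t in skf.split(np.zeros(len(labels)), labels)]

    struct_full = None
    if not config.leakage_safe:
        struct_full = compute_structure_features(assoc, config)

    fold_reports: list[MetricReport] = []
    fold_scores: list[tuple[np.ndarray, np.ndarray]] = []
    assignment: dict[tuple[str, str], int] = {}
    all_idx = np.arange(len(pairs))
    for fold_no, test_idx in enumerate(test_folds):
        test_mask = np.zeros(len(pairs), dtype=bool)
        test_mask[test_idx] = True
        train_idx = all_idx[~test_mask]
        for i in test_idx:
            assignment[pairs[i]] = fold_no

        if config.leakage_safe:
            # remove the *true* positive edges of the test fold from the graph
            held = [
                pairs[i]
                for i in test_idx
                if assoc.A[assoc.row_index[pairs[i][0]], assoc.col_index[pairs[i][1]]] == 1
            ]
            struct = compute_structure_features(masked_association(assoc, held), config)
        else:
            struct = struct_full

        X_train = assemble_pair_features([pairs[i] for i in train_idx], codes, struct)
        X_test = assemble_pair_features([pairs[i] for i in test_idx], codes, struct)
        model, _ = model_fit(
            X_train,
            labels[train_idx],
            seq_dim=config.sae_sizes[-1],
            struct_dim=config.struct_dim,
            config=_classifier_config(config, seed + fold_no),
        )
        scores = predict_scores(model, X_test)
        y_test = labels[test_idx]
        report = metrics(confusion(y_test, predict_labels(scores, config.threshold)))
        report.auc, report.aupr = rank_metrics(y_test, scores)
        fold_reports.append(report)
        fold_scores.append((y_test.copy(), scores))
        logger.info(
            "fold %d/%d: AUC %.4f AUPR %.4f acc %.4f",
            fold_no + 1,
            config.n_folds,
            report.auc,
            report.aupr,
            report.acc,
        )

    mean, sd = _aggregate(fold_reports)
    return CvReport(
        folds=fold_reports,
        mean=mean,
        sd=sd,
        fold_assignment=assignment,
        seed=seed,
        fold_scores=fold_scores,
    )


def imbalance_experiment(
    dataset: CmiDataset,
    ratios: list[float],
    config: PipelineConfig | None = None,
    seed: int = 0,
    codes: SequenceCodes | None = None,
) -> list[dict]:
    """Re-run CV at several negative:positive ratios; one row per ratio.

    Each row carries the ratio, the sampled negative count, and the eight
    mean metrics.
    """
    if any(r < 1 for r in ratios):
        raise ValueError("ratios must be >= 1")
    config = config or PipelineConfig()
    assoc = dataset.association()
    if codes is None:
        codes = compute_sequence_codes(
            dataset.records_circ, dataset.records_mi, config, seed=seed
        )
    rows = []
    for ratio in ratios:
        negatives = negative_sample(assoc, ratio, seed)
        ds = CmiDataset(
            records_circ=dataset.records_circ,
            records_mi=dataset.records_mi,
            positives=dataset.positives,
            negatives=negatives,
        )
        report = cross_validate(ds, config, seed=seed, codes=codes)
        rows.append(
            {
                "ratio": ratio,
                "n_negatives": len(negatives),
                **report.mean.as_dict(),
            }
        )
    return rows


def write_cv_report(report: CvReport, path) -> None:
    import pandas as pd

    pd.DataFrame(report.as_rows()).to_csv(path, sep="\t", index=False)


def write_imbalance_report(rows: list[dict], path) -> None:
    import pandas as pd

    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
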