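from math import sqrt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circmi.config import PipelineConfig
from circmi.evaluation import (
    ConfusionCounts,
    confusion,
    cross_validate,
    imbalance_experiment,
    make_folds,
    metrics,
    negative_sample,
    rank_metrics,
)
from circmi.io_formats import InteractionTable
from circmi.pipeline import compute_sequence_codes


def brute_force_metrics(tp, fp, tn, fn):
    """Direct integer-arithmetic transcription of the metric definitions."""
    out = {}
    total = tp + fp + tn + fn
    out["acc"] = (tp + tn) / total
    out["sen"] = tp / (tp + fn) if tp + fn else None
    out["spe"] = tn / (tn + fp) if tn + fp else None
    out["pre"] = tp / (tp + fp) if tp + fp else None
    if out["pre"] is not None and out["sen"] is not None and out["pre"] + out["sen"] > 0:
        out["f1"] = 2 * out["pre"] * out["sen"] / (out["pre"] + out["sen"])
    else:
        out["f1"] = None
    den = sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
    out["mcc"] = (tp * tn - fp * fn) / den if den else None
    return out


def brute_force_auc(labels, scores):
    """Exhaustive Mann-Whitney enumeration over positive-negative pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_aupr(labels, scores):
    """Step-curve enumeration: average precision over ranked positives."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    y = np.asarray(labels)[order]
    tp = 0
    area = 0.0
    for i, yi in enumerate(y, start=1):
        if yi == 1:
            tp += 1
            area += tp / i
    return area / y.sum()


class TestNegativeSampling:
    def _assoc(self):
        from circmi.io_formats import AssociationMatrix

        rng = np.random.default_rng(0)
        A = (rng.random((20, 15)) < 0.2).astype(np.int8)
        A[0, 0] = 1
        return AssociationMatrix(
            A=A,
            row_ids=[f"c{i}" for i in range(20)],
            col_ids=[f"m{j}" for j in range(15)],
        )

    def test_count_rule(self):
        assoc = self._assoc()
        neg = negative_sample(assoc, 1.0, seed=0)
        assert len(neg) == int(assoc.A.sum())

    def test_disjoint_from_positives(self):
        assoc = self._assoc()
        neg = negative_sample(assoc, 2.0, seed=1)
        for c, m, _ in neg.pairs:
            assert assoc.A[assoc.row_index[c], assoc.col_index[m]] == 0

    def test_seeded_determinism(self):
        assoc = self._assoc()
        assert negative_sample(assoc, 1.0, seed=3).pairs == negative_sample(
            assoc, 1.0, seed=3
        ).pairs

    def test_infeasible_ratio_rejected(self):
        assoc = self._assoc()
        with pytest.raises(ValueError):
            negative_sample(assoc, 1e6, seed=0)


class TestFolds:
    def _tables(self, n_pos=100, n_neg=100):
        pos = InteractionTable(
            pairs=[(f"c{i}", f"m{i}", 1) for i in range(n_pos)], provenance="observed"
        )
        neg = InteractionTable(
            pairs=[(f"c{i}", f"n{i}", 0) for i in range(n_neg)],
            provenance="sampled-negative",
        )
        return pos, neg

    def test_stratified_fold_sizes(self):
        pos, neg = self._tables()
        pairs, labels, folds = make_folds(pos, neg, n_folds=5, seed=0)
        for test_idx in folds:
            y = labels[test_idx]
            assert (y == 1).sum() == 20 and (y == 0).sum() == 20

    def test_folds_partition_the_full_set(self):
        pos, neg = self._tables(53, 47)
        pairs, labels, folds = make_folds(pos, neg, n_folds=5, seed=1)
        all_idx = np.concatenate(folds)
        assert len(all_idx) == len(set(all_idx)) == len(pairs)

    def test_fold_sizes_differ_by_at_most_one_per_class(self):
        pos, neg = self._tables(53, 47)
        _, labels, folds = make_folds(pos, neg, n_folds=5, seed=1)
        pos_sizes = sorted((labels[f] == 1).sum() for f in folds)
        neg_sizes = sorted((labels[f] == 0).sum() for f in folds)
        assert pos_sizes[-1] - pos_sizes[0] <= 1
        assert neg_sizes[-1] - neg_sizes[0] <= 1

    def test_too_small_class_rejected(self):
        pos, neg = self._tables(3, 100)
        with pytest.raises(ValueError):
            make_folds(pos, neg, n_folds=5, seed=0)


class TestConfusionAndMetrics:
    def test_enumerated_confusion(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_perfect_prediction(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert c.fp == 0 and c.fn == 0

    def test_all_positive_on_all_negative_truth(self):
        c = confusion([0, 0], [1, 1])
        assert c.tp == 0 and c.tn == 0 and c.fp == 2

    def test_hand_computed_example(self):
        rep = metrics(ConfusionCounts(tp=3, fn=1, tn=4, fp=2))
        assert rep.acc == pytest.approx(0.700)
        assert rep.sen == pytest.approx(0.750)
        assert rep.spe == pytest.approx(0.667, abs=5e-4)
        assert rep.pre == pytest.approx(0.600)
        assert rep.mcc == pytest.approx(0.408, abs=5e-4)

    def test_balanced_counts_give_zero_mcc(self):
        rep = metrics(ConfusionCounts(25, 25, 25, 25))
        assert rep.mcc == pytest.approx(0.0) and rep.acc == pytest.approx(0.5)

    def test_perfect_counts_give_unit_metrics(self):
        rep = metrics(ConfusionCounts(tp=10, fp=0, tn=10, fn=0))
        for name in ("acc", "sen", "spe", "pre", "f1", "mcc"):
            assert getattr(rep, name) == pytest.approx(1.0)

    def test_undefined_ratios_reported_as_nan(self):
        rep = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert np.isnan(rep.pre) and np.isnan(rep.mcc)

    @given(st.tuples(*[st.integers(0, 60)] * 4))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_on_random_counts(self, counts):
        tp, fp, tn, fn = counts
        if tp + fp + tn + fn == 0:
            return
        rep = metrics(ConfusionCounts(tp, fp, tn, fn)).as_dict()
        expected = brute_force_metrics(tp, fp, tn, fn)
        for name, want in expected.items():
            if want is None:
                assert np.isnan(rep[name])
            else:
                assert rep[name] == pytest.approx(want, abs=1e-12)


class TestRankMetrics:
    def test_scores_equal_labels(self):
        auc, aupr = rank_metrics([1, 0, 1, 0], [1.0, 0.0, 1.0, 0.0])
        assert auc == 1.0 and aupr == 1.0

    def test_constant_scores_give_half_auc(self):
        auc, _ = rank_metrics([1, 0, 1, 0], [0.5] * 4)
        assert auc == pytest.approx(0.5)

    def test_hand_enumerated_case(self):
        auc, _ = rank_metrics([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.1])
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rank_metrics([1, 1], [0.2, 0.4])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        coarse = np.round(rng.random(n), 1)  # coarse grid exercises ties
        auc, _ = rank_metrics(labels, coarse)
        assert auc == pytest.approx(brute_force_auc(labels, coarse), abs=1e-12)
        distinct = rng.permutation(n) / n  # all-distinct scores for the PR area
        auc2, aupr = rank_metrics(labels, distinct)
        assert auc2 == pytest.approx(brute_force_auc(labels, distinct), abs=1e-12)
        assert aupr == pytest.approx(brute_force_aupr(labels, distinct), abs=1e-12)


@pytest.fixture(scope="module")
def tiny_cv(tiny_dataset, fast_config):
    codes = compute_sequence_codes(
        tiny_dataset.circ_records, tiny_dataset.mi_records, fast_config, seed=0
    )
    report = cross_validate(tiny_dataset.to_dataset(), fast_config, seed=0, codes=codes)
    return report, codes


class TestCrossValidate:
    def test_report_layout(self, tiny_cv, fast_config):
        report, _ = tiny_cv
        rows = report.as_rows()
        assert len(rows) == fast_config.n_folds + 2
        assert rows[-2]["fold"] == "mean" and rows[-1]["fold"] == "sd"

    def test_every_pair_assigned_to_exactly_one_test_fold(self, tiny_cv, fast_config):
        report, _ = tiny_cv
        folds = list(report.fold_assignment.values())
        assert set(folds) <= set(range(fast_config.n_folds))
        assert len(report.fold_assignment) == sum(len(y) for y, _ in report.fold_scores)

    def test_mean_and_sd_recompute_from_fold_rows(self, tiny_cv):
        report, _ = tiny_cv
        aucs = [f.auc for f in report.folds]
        assert report.mean.auc == pytest.approx(np.mean(aucs))
        assert report.sd.auc == pytest.approx(np.std(aucs))

    def test_permuted_labels_sit_near_chance(self, tiny_dataset, fast_config, tiny_cv):
        _, codes = tiny_cv
        null = cross_validate(
            tiny_dataset.to_dataset(), fast_config, seed=0, codes=codes, permute_labels=True
        )
        assert 0.3 <= null.mean.auc <= 0.7  # wide band: tiny folds are noisy


class TestImbalance:
    def test_rows_counts_and_finiteness(self, tiny_dataset, fast_config, tiny_cv):
        _, codes = tiny_cv
        rows = imbalance_experiment(
            tiny_dataset.to_dataset(), [1, 2], fast_config, seed=0, codes=codes
        )
        n_pos = len(tiny_dataset.positives)
        assert [r["ratio"] for r in rows] == [1, 2]
        for r in rows:
            assert r["n_negatives"] == round(r["ratio"] * n_pos)
            assert np.isfinite(r["auc"]) and np.isfinite(r["acc"])

    def test_sub_unit_ratio_rejected(self, tiny_dataset, fast_config):
        with pytest.raises(ValueError):
            imbalance_experiment(tiny_dataset.to_dataset(), [0.5], fast_config)
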