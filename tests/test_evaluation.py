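import math

import numpy as np
import pytest

from _oracles import auc_pair_count, confusion_loop
from mlabdna import (
    ConfusionCounts,
    LabeledDataset,
    SimConfig,
    ThresholdStrategy,
    WsrcParams,
    confusion,
    cross_validate,
    grid_search,
    metrics,
    roc_and_pr,
    select_threshold,
    simulate,
)
from mlabdna.evaluation import candidate_thresholds, wilcoxon_rank_sum


class TestConfusion:
    def test_perfect_prediction(self):
        y = np.array([1] * 5 + [0] * 5)
        c = confusion(y, y)
        assert (c.TP, c.TN, c.FP, c.FN) == (5, 5, 0, 0)

    def test_all_negative_prediction(self):
        y = np.array([1, 1, 0, 0])
        c = confusion(y, np.zeros(4, dtype=int))
        assert c.TP == 0 and c.FP == 0 and c.FN == 2 and c.TN == 2

    def test_random_labels_match_loop_oracle(self, rng):
        t = rng.integers(0, 2, 200)
        p = rng.integers(0, 2, 200)
        c = confusion(t, p)
        assert (c.TP, c.TN, c.FP, c.FN) == confusion_loop(t, p)
        assert c.total == 200

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.zeros(3), np.zeros(4))


class TestMetrics:
    def test_printed_case_study_counts(self):
        """Confusion counts reported for the 4X0P chain-D case study."""
        m = metrics(ConfusionCounts(TP=24, TN=559, FP=34, FN=8))
        assert m.SN == pytest.approx(24 / 32)
        assert m.Spec == pytest.approx(559 / 593)
        assert m.Pre == pytest.approx(24 / 58)
        assert m.ACC == pytest.approx(583 / 625)
        expected_mcc = (24 * 559 - 34 * 8) / math.sqrt(32 * 593 * 58 * 567)
        assert m.MCC == pytest.approx(expected_mcc)

    def test_perfect_balanced_prediction(self):
        m = metrics(ConfusionCounts(TP=50, TN=50, FP=0, FN=0))
        assert m.MCC == 1.0 and m.ACC == 1.0

    def test_zero_denominator_convention(self):
        m = metrics(ConfusionCounts(TP=0, TN=4, FP=0, FN=0))
        assert m.SN == 0.0 and m.Pre == 0.0 and m.MCC == 0.0

    def test_permuted_labels_center_mcc_at_zero(self, rng):
        y = np.array([1] * 30 + [0] * 170)
        pred = np.array([1] * 40 + [0] * 160)
        vals = []
        for _ in range(1000):
            vals.append(metrics(confusion(rng.permutation(y), pred)).MCC)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 1e-3

    def test_conservation_identity(self, rng):
        t = rng.integers(0, 2, 100)
        p = rng.integers(0, 2, 100)
        c = confusion(t, p)
        assert c.TP + c.FN == t.sum()
        m = metrics(c)
        assert m.ACC == pytest.approx((c.TP + c.TN) / 100)


class TestRocPr:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        auc, aupr, roc_pts, _ = roc_and_pr(np.array([0.1, 0.2, 0.8, 0.9]), y)
        assert auc == 1.0 and aupr == 1.0
        assert {"fpr", "tpr"} <= set(roc_pts.columns)

    def test_constant_scores_give_half(self):
        y = np.array([0, 1, 0, 1, 1])
        auc, _, _, _ = roc_and_pr(np.ones(5), y)
        assert auc == pytest.approx(0.5)

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(5):
            n = int(rng.integers(10, 60))
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            auc, _, _, _ = roc_and_pr(scores, labels)
            assert auc == pytest.approx(auc_pair_count(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_and_pr(np.array([0.1, 0.2]), np.array([1, 1]))


class TestSelectThreshold:
    def test_perfectly_separating_scores(self):
        y = np.array([0, 0, 0, 1, 1])
        scores = y.astype(float)
        for kind in ("sen_eq_spec", "fpr_target", "max_mcc"):
            T = select_threshold(scores, y, ThresholdStrategy(kind, 0.05))
            pred = (scores >= T).astype(int)
            m = metrics(confusion(y, pred))
            assert m.SN == 1.0 and m.Spec == 1.0

    def test_fpr_zero_excludes_all_negatives(self, rng):
        scores = rng.uniform(size=40)
        y = rng.integers(0, 2, 40)
        y[0], y[1] = 0, 1
        T = select_threshold(scores, y, ThresholdStrategy("fpr_target", 0.0))
        assert np.all(scores[y == 0] < T)

    def test_exhaustive_scan_oracle(self, rng):
        scores = rng.normal(size=100)
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        for kind, target in (("sen_eq_spec", 0.0), ("fpr_target", 0.05), ("max_mcc", 0.0)):
            T = select_threshold(scores, y, ThresholdStrategy(kind, target))
            # brute force over every candidate cut; ties prefer higher SN,
            # then the larger threshold
            best = None
            for cand in candidate_thresholds(scores):
                m = metrics(confusion(y, (scores >= cand).astype(int)))
                if kind == "sen_eq_spec":
                    val = abs(m.SN - m.Spec)
                elif kind == "fpr_target":
                    val = abs((1 - m.Spec) - target)
                else:
                    val = -m.MCC
                key = (val, -m.SN, -cand)
                if best is None or key < best[0]:
                    best = (key, cand)
            assert T == pytest.approx(best[1])

    def test_sen_eq_spec_gap_is_minimal(self, rng):
        scores = rng.normal(size=60)
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        T = select_threshold(scores, y, ThresholdStrategy("sen_eq_spec"))
        m0 = metrics(confusion(y, (scores >= T).astype(int)))
        for cand in candidate_thresholds(scores):
            m = metrics(confusion(y, (scores >= cand).astype(int)))
            assert abs(m0.SN - m0.Spec) <= abs(m.SN - m.Spec) + 1e-12

    def test_fixed_strategy_passthrough(self):
        T = select_threshold(np.array([0.4]), np.array([1]),
                             ThresholdStrategy("fixed", 0.718))
        assert T == 0.718

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            select_threshold(np.array([]), np.array([]), ThresholdStrategy("max_mcc"))


@pytest.fixture(scope="module")
def tiny_cv_corpus():
    return simulate(SimConfig(n_proteins=10, length_range=(40, 60),
                              effect_size=3.0, seed=11))


class TestCrossValidate:
    def test_partition_and_stratification(self, tiny_cv_corpus):
        ds = tiny_cv_corpus.to_dataset(11)
        res = cross_validate(ds, k=2, m=2, seed=0, split_by="residue",
                             strategy=ThresholdStrategy("max_mcc"))
        assert np.all(res.fold_assignment >= 0)  # every sample tested once
        for fold in (0, 1):
            mask = res.fold_assignment == fold
            ratio = ds.labels[mask].mean()
            assert ratio == pytest.approx(ds.labels.mean(), abs=0.02)

    def test_protein_grouping_keeps_chains_together(self, tiny_cv_corpus):
        ds = tiny_cv_corpus.to_dataset(11)
        res = cross_validate(ds, k=3, m=2, seed=0, split_by="protein",
                             strategy=ThresholdStrategy("max_mcc"))
        for pid in np.unique(ds.group_ids):
            folds = np.unique(res.fold_assignment[ds.group_ids == pid])
            assert len(folds) == 1

    def test_seed_determinism(self, tiny_cv_corpus):
        ds = tiny_cv_corpus.to_dataset(11)
        a = cross_validate(ds, k=2, m=2, seed=7, split_by="residue")
        b = cross_validate(ds, k=2, m=2, seed=7, split_by="residue")
        assert a.pooled.MCC == b.pooled.MCC
        np.testing.assert_array_equal(a.oof_scores, b.oof_scores)

    def test_k_exceeding_class_count_rejected(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.array([1] * 3 + [0] * 27)
        with pytest.raises(ValueError):
            cross_validate(LabeledDataset(X, y), k=5, m=1, split_by="residue")


class TestGridSearch:
    def test_single_cell_equals_cross_validate(self, tiny_cv_corpus):
        table = grid_search(tiny_cv_corpus, [11], [2], seed=3, k=2,
                            strategy=ThresholdStrategy("max_mcc"))
        assert table.shape[0] == 1
        direct = cross_validate(tiny_cv_corpus.to_dataset(11), k=2, m=2, seed=3,
                                strategy=ThresholdStrategy("max_mcc"))
        assert table.MCC.iloc[0] == pytest.approx(direct.pooled.MCC)

    def test_grid_shape(self):
        ws = list(range(7, 18, 2))
        ms = list(range(1, 30, 2))
        assert len(ws) * len(ms) == 6 * 15

    def test_narrow_signal_favors_small_windows(self):
        """Signal confined to +-2 residues: widening the window from 7 to 17
        dilutes the conserved block, so MCC must not improve (seed-averaged)."""
        diffs = []
        for seed in (0, 1, 2, 3):
            corpus = simulate(SimConfig(n_proteins=12, length_range=(60, 80),
                                        effect_size=3.0, seed=seed))
            table = grid_search(corpus, [7, 17], [5], seed=seed, k=3,
                                strategy=ThresholdStrategy("max_mcc"))
            by_w = table.set_index("w").MCC
            diffs.append(by_w[7] - by_w[17])
        assert np.mean(diffs) >= 0


def test_wilcoxon_wrapper_detects_shift(rng):
    a = rng.normal(0.0, 1.0, 40)
    b = rng.normal(2.0, 1.0, 40)
    _, p = wilcoxon_rank_sum(a, b)
    assert p < 1e-6
    _, p_same = wilcoxon_rank_sum(a, a)
    assert p_same == pytest.approx(1.0)
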