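import numpy as np
import pytest

import guidestack as gs
from guidestack.evaluation import (
    EvalReport,
    UndefinedMetricError,
    group_guides_for_loso,
    kfold_split,
    pr_auc,
    roc_auc,
    run_loso,
    single_split,
)
from guidestack.model import ModelConfig


def roc_auc_pairwise_oracle(labels, scores):
    """Brute-force Mann-Whitney: P(random positive outscores random
    negative), ties counted 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def average_precision_oracle(labels, scores):
    """Direct step-sum over score-descending tie blocks."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    n_pos = labels.sum()
    tp = fp = 0
    ap = 0.0
    for s in sorted(set(scores), reverse=True):
        block = labels[scores == s]
        d_tp = int(block.sum())
        tp += d_tp
        fp += int(len(block) - block.sum())
        precision = tp / (tp + fp)
        ap += (d_tp / n_pos) * precision
    return ap


def _random_instance(rng, n_max=30):
    n = int(rng.integers(4, n_max))
    labels = rng.integers(0, 2, size=n)
    if labels.sum() == 0:
        labels[0] = 1
    if labels.sum() == n:
        labels[-1] = 0
    # quantized scores force plenty of ties
    scores = np.round(rng.random(n), 1)
    return labels, scores


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 0], [0.9, 0.1]) == 1.0

    def test_all_ties_is_half(self):
        assert roc_auc([1, 0, 1, 0], [0.5] * 4) == 0.5

    def test_small_case_against_pairwise_oracle(self):
        labels = [1, 1, 0, 0, 0]
        scores = [0.8, 0.4, 0.6, 0.4, 0.1]
        assert roc_auc(labels, scores) == pytest.approx(
            roc_auc_pairwise_oracle(labels, scores), abs=1e-12
        )

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            labels, scores = _random_instance(rng)
            assert roc_auc(labels, scores) == pytest.approx(
                roc_auc_pairwise_oracle(labels, scores), abs=1e-12
            )

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([1, 1], [0.2, 0.3])

    def test_complement_symmetry_without_ties(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        scores = rng.permutation(np.linspace(0, 1, 50))  # tie-free
        assert roc_auc(labels, scores) + roc_auc(labels, -scores) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        labels, scores = _random_instance(rng)
        assert roc_auc(labels, scores) == pytest.approx(
            roc_auc(labels, np.exp(3 * scores)), abs=1e-12
        )


class TestPrAuc:
    def test_perfect_ranking(self):
        assert pr_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_equals_prevalence(self):
        labels = [1, 0, 0, 0, 1]
        assert pr_auc(labels, [0.3] * 5) == pytest.approx(2 / 5, abs=1e-12)

    def test_small_case_against_step_sum_oracle(self):
        labels = [1, 1, 0, 0, 1, 0]
        scores = [0.9, 0.6, 0.6, 0.4, 0.3, 0.1]
        assert pr_auc(labels, scores) == pytest.approx(
            average_precision_oracle(labels, scores), abs=1e-12
        )

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            labels, scores = _random_instance(rng)
            assert pr_auc(labels, scores) == pytest.approx(
                average_precision_oracle(labels, scores), abs=1e-12
            )

    def test_no_positives_undefined(self):
        with pytest.raises(UndefinedMetricError):
            pr_auc([0, 0], [0.2, 0.3])

    def test_raising_prevalence_raises_ap_at_fixed_roc(self):
        """Dropping negatives at fixed scores leaves ROC-AUC roughly alone
        but lifts average precision."""
        rng = np.random.default_rng(3)
        n = 4000
        labels = (rng.random(n) < 0.05).astype(int)
        labels[0] = 1
        scores = np.where(labels == 1, rng.normal(1.0, 1.0, n), rng.normal(0.0, 1.0, n))
        keep = (labels == 1) | (rng.random(n) < 0.25)
        full_ap = pr_auc(labels, scores)
        sub_ap = pr_auc(labels[keep], scores[keep])
        assert sub_ap > full_ap
        assert roc_auc(labels[keep], scores[keep]) == pytest.approx(
            roc_auc(labels, scores), abs=0.05
        )


class TestSplits:
    def test_single_split_sizes_and_stratification(self, small_dataset):
        train, val = single_split(small_dataset, 0.1, seed=0)
        assert len(val) == round(0.1 * len(small_dataset))
        assert len(train) + len(val) == len(small_dataset)
        overall = np.mean([p.label for p in small_dataset])
        val_frac = np.mean([p.label for p in val])
        assert abs(val_frac - overall) < 1.5 / len(val)

    def test_exact_stratification_small(self):
        pairs = [
            gs.GuideTargetPair(f"g{i}", "A" * 23, "A" * 22 + "C", int(i < 10))
            for i in range(100)
        ]
        _, val = single_split(pairs, 0.1, seed=1)
        assert sum(p.label for p in val) == 1

    def test_single_split_deterministic(self, small_dataset):
        s1 = single_split(small_dataset, 0.2, seed=5)
        s2 = single_split(small_dataset, 0.2, seed=5)
        assert s1 == s2

    def test_bad_fraction(self, small_dataset):
        with pytest.raises(ValueError):
            single_split(small_dataset, 1.5)

    def test_kfold_partition_and_stratification(self):
        pairs = [
            gs.GuideTargetPair(f"g{i}", "A" * 23, "A" * 22 + "C", int(i < 5))
            for i in range(10)
        ]
        folds = kfold_split(pairs, 5, seed=0)
        assert len(folds) == 5
        all_val = [p for _, val in folds for p in val]
        assert sorted(p.guide_id for p in all_val) == sorted(p.guide_id for p in pairs)
        for _, val in folds:
            assert sum(p.label for p in val) == 1

    def test_kfold_too_many_folds(self, toy_pairs):
        with pytest.raises(ValueError):
            kfold_split(toy_pairs, 10)


def _pairs_with_counts(counts: dict[str, int], n_neg: int = 2):
    """Build a dataset with the given positive count per guide."""
    pairs = []
    for gid, n_pos in counts.items():
        guide = "A" * 23
        for i in range(n_pos):
            # unique target per pair to avoid accidental duplicates
            t = list(guide)
            t[0] = "CGT"[i % 3]
            t[1] = "CGT"[(i // 3) % 3]
            t[2] = "CGT"[(i // 9) % 3]
            pairs.append(gs.GuideTargetPair(gid, guide, "".join(t), 1))
        for i in range(n_neg):
            t = list(guide)
            t[20] = "CG"[i % 2]
            pairs.append(gs.GuideTargetPair(gid, guide, "".join(t), 0))
    return pairs


class TestLosoGrouping:
    def test_guides_meeting_threshold_stay_single(self):
        pairs = _pairs_with_counts({"g1": 40, "g2": 35, "g3": 31}, n_neg=0)
        assignment = group_guides_for_loso(pairs, min_pos=30)
        assert assignment.groups == [["g3"], ["g2"], ["g1"]]
        assert assignment.positive_counts == [31, 35, 40]

    def test_small_guides_merge_ascending(self):
        pairs = _pairs_with_counts({"g1": 5, "g2": 10, "g3": 20, "g4": 40}, n_neg=0)
        assignment = group_guides_for_loso(pairs, min_pos=30)
        assert assignment.groups == [["g1", "g2", "g3"], ["g4"]]
        assert assignment.positive_counts == [35, 40]

    def test_trailing_shortfall_merges_backwards(self):
        # ascending order c(1), d(2), b(28), a(29): first group closes at
        # 31 positives; the trailing {a} holds 29 < 30 and merges back
        pairs = _pairs_with_counts({"a": 29, "b": 28, "c": 1, "d": 2}, n_neg=0)
        assignment = group_guides_for_loso(pairs, min_pos=30)
        assert assignment.groups == [["c", "d", "b", "a"]]
        assert assignment.positive_counts == [60]

    def test_degenerate_single_group_flagged(self):
        pairs = _pairs_with_counts({"g1": 12}, n_neg=1)
        assignment = group_guides_for_loso(pairs, min_pos=30)
        assert assignment.groups == [["g1"]]
        assert assignment.degenerate

    def test_partition_covers_every_guide(self, small_dataset):
        assignment = group_guides_for_loso(small_dataset, min_pos=30)
        seen = [g for grp in assignment.groups for g in grp]
        assert sorted(seen) == sorted({p.guide_id for p in small_dataset})
        assert len(seen) == len(set(seen))

    def test_every_group_meets_threshold(self, small_dataset):
        for min_pos in (5, 20, 40):
            assignment = group_guides_for_loso(small_dataset, min_pos=min_pos)
            if not assignment.degenerate:
                assert all(c >= min_pos for c in assignment.positive_counts)

    def test_zero_positives_rejected(self):
        pairs = _pairs_with_counts({"g1": 0}, n_neg=3)
        with pytest.raises(ValueError):
            group_guides_for_loso(pairs)


@pytest.fixture(scope="module")
def loso_result(small_dataset):
    cfg = ModelConfig(
        variant="static", embed_dim=8, lstm_units=4, dense_units=(8, 4),
        dropout=0.0, learning_rate=3e-3, batch_size=32, epochs=3, seed=0,
    )
    return run_loso(small_dataset, cfg, min_pos=20)


class TestRunLoso:
    def test_every_pair_scored_exactly_once(self, loso_result, small_dataset):
        n_scored = loso_result.global_report.n_pos + loso_result.global_report.n_neg
        assert n_scored == len(small_dataset)

    def test_round_count_matches_groups(self, loso_result):
        assert len(loso_result.per_group) == len(loso_result.assignment.groups)
        assert len(loso_result.assignment.groups) >= 2

    def test_reports_both_global_and_averages(self, loso_result):
        assert 0.0 <= loso_result.global_report.roc_auc <= 1.0
        assert 0.0 <= loso_result.mean_roc_auc <= 1.0
        assert 0.0 <= loso_result.mean_pr_auc <= 1.0


class TestEvalReport:
    def test_curve_shapes_and_counts(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        scores = rng.random(50)
        report = EvalReport.from_scores(labels, scores)
        assert report.n_pos + report.n_neg == 50
        assert report.roc_points.shape[1] == 2
        # ROC sweep is monotone in both coordinates
        assert np.all(np.diff(report.roc_points[:, 0]) >= 0)
        assert np.all(np.diff(report.roc_points[:, 1]) >= 0)

    def test_write_round_trip(self, tmp_path):
        report = EvalReport.from_scores([1, 0, 1, 0], [0.9, 0.2, 0.7, 0.4])
        report.write(tmp_path / "eval")
        text = (tmp_path / "eval.txt").read_text()
        assert "roc_auc: 1.0" in text
        curve = np.loadtxt(tmp_path / "eval_roc.csv", delimiter=",", skiprows=1)
        assert curve.shape[1] == 2
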