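"""Metrics, cutoff selection, grid sweep, and descriptor ablation."""

import numpy as np
import pytest

from nrpcm.dataset import SplitSpec
from nrpcm.evaluation import (
    EvaluationError,
    best_balanced_accuracy_cutoff,
    classification_metrics,
    restrict_features,
    roc_auc,
    run_grid,
    score_file_metrics,
)
from nrpcm.model import AugmentationConfig, RFConfig

from oracles import best_ba_scan, pairwise_auc


def random_labeled_scores(rng, n):
    labels = np.zeros(n, dtype=int)
    # guarantee both classes
    k = rng.integers(1, n)
    labels[:k] = 1
    rng.shuffle(labels)
    # duplicate-heavy scores exercise tie handling
    scores = rng.choice(np.round(rng.random(max(2, n // 2)), 3), size=n)
    return labels, scores


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_hand_counted_example(self):
        # 4 pos-neg pairs, 3 concordant: (0.9,0.8),(0.9,0.1),(0.7,0.1)
        assert roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == 0.75

    def test_all_ties_is_half(self):
        assert roc_auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            labels, scores = random_labeled_scores(rng, int(rng.integers(4, 51)))
            assert roc_auc(labels, scores) == pytest.approx(
                pairwise_auc(labels, scores), abs=1e-12
            )

    def test_complement_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            labels, scores = random_labeled_scores(rng, 30)
            total = roc_auc(labels, scores) + roc_auc(labels, 1 - scores)
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(EvaluationError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])


class TestClassificationMetrics:
    def test_all_correct(self):
        rep = classification_metrics([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1], 0.5)
        assert rep.accuracy == 1.0 and rep.fpr == 0.0
        assert rep.precision == 1.0 and rep.recall == 1.0 and rep.f1 == 1.0

    def test_hand_counted_confusion(self):
        # TP=1 FN=1 FP=1 TN=1 at cutoff 0.5
        rep = classification_metrics([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.2], 0.5)
        assert rep.accuracy == 0.5
        assert rep.precision == 0.5
        assert rep.recall == 0.5
        assert rep.fpr == 0.5
        assert rep.f1 == 0.5

    def test_strict_inequality_at_cutoff(self):
        # a score exactly at the cutoff is a negative call
        rep = classification_metrics([1, 0], [0.5, 0.1], 0.5)
        assert rep.recall == 0.0

    def test_recall_monotone_in_cutoff(self):
        rng = np.random.default_rng(3)
        labels, scores = random_labeled_scores(rng, 40)
        r1 = classification_metrics(labels, scores, 0.5).recall
        r2 = classification_metrics(labels, scores, 0.7).recall
        assert r2 <= r1

    def test_no_positive_calls_flagged_degenerate(self):
        rep = classification_metrics([1, 0], [0.1, 0.2], 0.9)
        assert rep.precision == 0.0
        assert "precision" in rep.degenerate

    def test_f1_is_harmonic_mean(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            labels, scores = random_labeled_scores(rng, 30)
            rep = classification_metrics(labels, scores, 0.5)
            if rep.precision + rep.recall > 0:
                want = 2 * rep.precision * rep.recall / (rep.precision + rep.recall)
                assert rep.f1 == pytest.approx(want, abs=1e-12)


class TestBestBalancedAccuracy:
    def test_separable_returns_smallest_perfect_cutoff(self):
        cutoff, ba = best_balanced_accuracy_cutoff([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert ba == 1.0
        assert cutoff == pytest.approx(0.5)  # midpoint of 0.2 and 0.8

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            labels, scores = random_labeled_scores(rng, int(rng.integers(4, 40)))
            got_c, got_ba = best_balanced_accuracy_cutoff(labels, scores)
            want_c, want_ba = best_ba_scan(list(labels), list(scores))
            assert got_ba == pytest.approx(want_ba, abs=1e-12)
            assert got_c == pytest.approx(want_c, abs=1e-12)

    def test_invariant_to_proportional_duplication(self):
        labels = [1, 0, 1, 0, 1, 0]
        scores = [0.9, 0.8, 0.7, 0.3, 0.6, 0.1]
        c1, ba1 = best_balanced_accuracy_cutoff(labels, scores)
        c2, ba2 = best_balanced_accuracy_cutoff(labels * 3, scores * 3)
        assert (c1, ba1) == (c2, ba2)

    def test_score_file_metrics_uses_best_ba(self):
        import pandas as pd

        df = pd.DataFrame({"label": [0, 0, 1, 1], "score": [0.1, 0.2, 0.8, 0.9]})
        rep = score_file_metrics(df)
        assert rep.accuracy == 1.0


class TestRestrictFeatures:
    def test_block_dimensions(self, examples, bundle):
        p = restrict_features(examples[:5], "P", len(bundle.panel))
        l = restrict_features(examples[:5], "L", len(bundle.panel))
        both = restrict_features(examples[:5], "P+L", len(bundle.panel))
        assert p[0].feature.shape == (30,)
        assert l[0].feature.shape == (187,)
        assert both[0].feature.shape == (217,)

    def test_blocks_are_complementary(self, examples, bundle):
        e = examples[0]
        p = restrict_features([e], "P", len(bundle.panel))[0]
        l = restrict_features([e], "L", len(bundle.panel))[0]
        assert np.array_equal(np.concatenate([p.feature, l.feature]), e.feature)

    def test_unknown_mode_rejected(self, examples, bundle):
        with pytest.raises(EvaluationError):
            restrict_features(examples[:2], "Q", len(bundle.panel))


class TestRunGrid:
    def test_small_grid_shape_and_best_cell(self, examples, bundle, manifest):
        result = run_grid(
            examples, bundle.panel, manifest,
            fractions=(0.70, 0.85), n_values=(1000, 1500),
            learner_cfg=RFConfig(n_trees=10, seed=0), seed=0,
        )
        assert len(result.reports) == 4 and not result.failures
        assert result.best in result.reports
        best_auc = result.reports[result.best].roc_auc
        assert all(r.roc_auc <= best_auc for r in result.reports.values())

    def test_single_cell_matches_direct_fit(self, examples, bundle, manifest):
        from nrpcm.dataset import features_labels, split
        from nrpcm.evaluation import evaluate_model
        from nrpcm.model import fit_rf

        result = run_grid(
            examples, bundle.panel, manifest,
            fractions=(0.85,), n_values=(1000,),
            learner_cfg=RFConfig(n_trees=10, seed=0), seed=0,
        )
        train, val = split(examples, SplitSpec(train_fraction=0.85, seed=0))
        model = fit_rf(
            train, RFConfig(n_trees=10, seed=0),
            AugmentationConfig(n_per_target=1000, sigma=0.1, seed=0),
            bundle.panel, manifest,
        )
        direct = evaluate_model(model, val)
        assert result.reports[(0.85, 1000)].roc_auc == direct.roc_auc

    def test_default_axes_span_81_cells(self):
        from nrpcm.evaluation import DEFAULT_FRACTIONS, DEFAULT_N_VALUES

        assert len(DEFAULT_FRACTIONS) * len(DEFAULT_N_VALUES) == 81

    def test_cell_failure_recorded_not_fatal(self, examples, bundle, manifest):
        # quota 200 per class is below some target's inactive count -> cell fails
        result = run_grid(
            examples, bundle.panel, manifest,
            fractions=(0.85,), n_values=(400, 1000),
            learner_cfg=RFConfig(n_trees=5, seed=0), seed=0,
        )
        assert (0.85, 400) in result.failures
        assert (0.85, 1000) in result.reports
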