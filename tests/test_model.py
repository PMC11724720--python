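"""Augmentation, random-forest fitting, tri-level calls, screening."""

import numpy as np
import pytest

from nrpcm.dataset import ACTIVE, INACTIVE, PCMExample, SplitSpec, features_labels, split
from nrpcm.model import (
    ActivityCall,
    AugmentationConfig,
    ModelError,
    PCMModel,
    RFConfig,
    augment,
    best_target_per_compound,
    fit_rf,
    positive_proportions,
    screen,
)


def toy_examples(n_active=10, n_inactive=90, target="T1", dim=6, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_active):
        out.append(PCMExample(rng.normal(1, 1, dim), ACTIVE, f"a{i}", target))
    for i in range(n_inactive):
        out.append(PCMExample(rng.normal(-1, 1, dim), INACTIVE, f"i{i}", target))
    return out


class TestAugment:
    def test_balances_to_half_quota_per_class(self):
        train = toy_examples(10, 90)
        out = augment(train, AugmentationConfig(n_per_target=1000, sigma=0.0, seed=0))
        labels = [e.label for e in out]
        assert labels.count(ACTIVE) == 500 and labels.count(INACTIVE) == 500

    def test_sigma_zero_synthetic_rows_equal_originals(self):
        train = toy_examples(10, 90)
        out = augment(train, AugmentationConfig(n_per_target=1000, sigma=0.0, seed=0))
        originals = {e.feature.tobytes() for e in train}
        for e in out:
            if e.origin == "oversampled":
                assert e.feature.tobytes() in originals

    def test_originals_kept_noise_free(self):
        train = toy_examples(10, 90)
        out = augment(train, AugmentationConfig(n_per_target=1000, sigma=0.5, seed=0))
        kept = [e for e in out if e.origin == "original"]
        assert len(kept) == len(train)
        for orig, k in zip(train, kept):
            assert np.array_equal(orig.feature, k.feature)

    def test_deterministic_under_seed(self):
        train = toy_examples(10, 90)
        cfg = AugmentationConfig(n_per_target=500, sigma=0.1, seed=7)
        a = augment(train, cfg)
        b = augment(train, cfg)
        assert all(np.array_equal(x.feature, y.feature) for x, y in zip(a, b))

    def test_per_target_totals(self):
        train = toy_examples(10, 90, "T1") + toy_examples(20, 80, "T2", seed=1)
        out = augment(train, AugmentationConfig(n_per_target=1000, sigma=0.1, seed=0))
        counts = {}
        for e in out:
            counts[e.target_id] = counts.get(e.target_id, 0) + 1
        assert counts == {"T1": 1000, "T2": 1000}

    def test_target_missing_a_class_errors(self):
        train = [e for e in toy_examples(10, 90) if e.label == INACTIVE]
        with pytest.raises(ModelError, match="T1"):
            augment(train, AugmentationConfig(n_per_target=1000, seed=0))

    def test_quota_below_existing_count_errors(self):
        train = toy_examples(10, 90)
        with pytest.raises(ModelError, match="quota"):
            augment(train, AugmentationConfig(n_per_target=100, seed=0))

    def test_five_targets_at_5000_gives_25000(self):
        train = []
        for t in range(5):
            train.extend(toy_examples(10, 40, f"T{t}", seed=t))
        out = augment(train, AugmentationConfig(n_per_target=5000, sigma=0.1, seed=0))
        assert len(out) == 25000


class TestActivityCall:
    @pytest.mark.parametrize(
        "score,level",
        [
            (0.777, "high"),    # docosapentaenoic-acid-like score
            (0.54, "medium"),   # lycopene-like score
            (0.105, "low"),     # butanedioic-acid-like score
            (0.7, "medium"),    # boundary: high requires strictly above 0.7
            (0.5, "low"),       # boundary: medium requires strictly above 0.5
            (0.0, "low"),
            (1.0, "high"),
        ],
    )
    def test_threshold_rule(self, score, level):
        assert ActivityCall.from_score(score).level == level

    def test_levels_partition_unit_interval(self):
        for s in np.linspace(0, 1, 101):
            call = ActivityCall.from_score(float(s))
            assert call.level in ("high", "medium", "low")

    def test_out_of_range_rejected(self):
        with pytest.raises(ModelError):
            ActivityCall.from_score(1.5)


@pytest.fixture(scope="module")
def small_model(bundle, manifest, examples):
    """A quick forest on a training split of the synthetic study."""
    train, _ = split(examples, SplitSpec(train_fraction=0.85, seed=0))
    return fit_rf(
        train,
        RFConfig(n_trees=30, seed=0),
        AugmentationConfig(n_per_target=1000, sigma=0.1, seed=0),
        bundle.panel,
        manifest,
    )


class TestFitPredict:
    def test_scores_are_probabilities(self, small_model, examples):
        X, _ = features_labels(examples)
        s = small_model.score_matrix(X)
        assert np.all((s >= 0) & (s <= 1))

    def test_separable_training_auc_is_one(self, bundle, manifest):
        from nrpcm.evaluation import roc_auc

        train = toy_examples(30, 30, dim=217, seed=3)
        model = fit_rf(
            train, RFConfig(n_trees=50, seed=0),
            AugmentationConfig(n_per_target=200, sigma=0.0, seed=0),
            bundle.panel, manifest,
        )
        X, y = features_labels(train)
        assert roc_auc(y, model.score_matrix(X)) == 1.0

    def test_same_seed_identical_predictions(self, bundle, manifest, examples):
        train, val = split(examples, SplitSpec(train_fraction=0.85, seed=0))
        kwargs = dict(
            cfg=RFConfig(n_trees=20, seed=5),
            aug=AugmentationConfig(n_per_target=1000, sigma=0.1, seed=5),
            panel=bundle.panel, manifest=manifest,
        )
        X, _ = features_labels(val)
        s1 = fit_rf(train, **kwargs).score_matrix(X)
        s2 = fit_rf(train, **kwargs).score_matrix(X)
        assert np.array_equal(s1, s2)

    def test_single_class_training_errors(self, bundle, manifest):
        train = toy_examples(10, 10)
        only_active = [e for e in train if e.label == ACTIVE]
        with pytest.raises(ModelError):
            fit_rf(
                only_active, RFConfig(n_trees=5, seed=0),
                AugmentationConfig(n_per_target=100, seed=0),
                bundle.panel, manifest,
            )

    def test_predict_single_pair(self, small_model, bundle):
        call = small_model.predict(bundle.compounds[0], bundle.panel.members[0])
        assert 0 <= call.score <= 1
        assert call.level in ("high", "medium", "low")

    def test_save_load_roundtrip(self, small_model, bundle, tmp_path):
        path = tmp_path / "model.joblib"
        small_model.save(path)
        loaded = PCMModel.load(path)
        table1 = small_model.predict_batch(bundle.compounds[:5], bundle.panel.members[:2])
        table2 = loaded.predict_batch(bundle.compounds[:5], bundle.panel.members[:2])
        assert np.array_equal(table1["score"], table2["score"])


class TestScreen:
    def test_cutoff_levels(self, small_model, bundle):
        compounds = bundle.compounds[:20]
        targets = [bundle.panel.member(t) for t in bundle.train_targets]
        normal = screen(small_model, compounds, targets, cutoff_level=1)
        strict = screen(small_model, compounds, targets, cutoff_level=2)
        assert (normal["score"] > 0.5).equals(normal["positive"])
        assert (strict["score"] > 0.7).equals(strict["positive"])
        assert strict["positive"].sum() <= normal["positive"].sum()

    def test_preserves_pair_order(self, small_model, bundle):
        compounds = bundle.compounds[:3]
        targets = [bundle.panel.member(t) for t in bundle.train_targets[:2]]
        table = screen(small_model, compounds, targets)
        expected = [(c.id, t.id) for c in compounds for t in targets]
        assert list(zip(table["compound_id"], table["target_id"])) == expected

    def test_argmax_matches_per_pair_predict(self, small_model, bundle):
        compounds = bundle.compounds[:10]
        targets = [bundle.panel.member(t) for t in bundle.train_targets]
        table = screen(small_model, compounds, targets)
        best = best_target_per_compound(table)
        for _, row in best.iterrows():
            comp = next(c for c in compounds if c.id == row["compound_id"])
            scores = {
                t.id: small_model.predict(comp, t).score for t in targets
            }
            assert row["best_score"] == max(scores.values())
            assert scores[row["best_target"]] == row["best_score"]

    def test_positive_proportions(self, small_model, bundle):
        compounds = bundle.compounds[:20]
        targets = [bundle.panel.member(t) for t in bundle.train_targets[:2]]
        table = screen(small_model, compounds, targets)
        props = positive_proportions(table)
        assert set(props.index) == {t.id for t in targets}
        assert ((props >= 0) & (props <= 1)).all()
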