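import numpy as np
import pytest

from histotriage.classifier import (
    MockClassifier,
    TileClassification,
    TrainConfig,
    TrainedClassifier,
    TrainingStore,
    apply_flip,
    augment,
    classify,
    mock_classify,
    record_correction,
    retrain_due,
    split_validation,
    tile_features,
    train,
)
from histotriage.hierarchy import CLASSES, DiagnosticClass
from histotriage.synthetic import generate_class_tile

from conftest import make_tile

D = DiagnosticClass


def class_tiles(per_class: int, size: int = 96, seed_base: int = 0):
    """(tile, true class) pairs, one texture tile per draw."""
    out = []
    for cls in CLASSES:
        for i in range(per_class):
            px = generate_class_tile(cls, size=size, seed=seed_base + 1000 * cls.rank + i)
            out.append((make_tile(px, slide_id=f"t{cls.rank}", row0=i, col0=0), cls))
    return out


class TestTileClassification:
    def test_probabilities_must_normalize(self):
        with pytest.raises(ValueError):
            TileClassification(
                "s", 0, 0, np.full(10, 0.2), label=D.adenocarcinoma, score=0.2
            )

    def test_label_score_must_match_argmax(self):
        p = np.zeros(10)
        p[0] = 1.0
        with pytest.raises(ValueError, match="inconsistent"):
            TileClassification("s", 0, 0, p, label=D.adenoma, score=1.0)
        ok = TileClassification.from_probabilities("s", 0, 0, p)
        assert ok.label is D.adenocarcinoma and ok.score == 1.0

    def test_classify_rejects_non_square_tile(self):
        t = make_tile(np.zeros((64, 32, 3), np.uint8))
        with pytest.raises(ValueError, match="square"):
            classify(t, MockClassifier())


class TestMockClassifier:
    def test_zero_error_recovers_every_class(self):
        tiles = class_tiles(per_class=20)
        mc = MockClassifier(error_rate=0.0)
        assert all(mc.classify(t).label is cls for t, cls in tiles)

    def test_full_error_never_emits_truth(self):
        tiles = class_tiles(per_class=5)
        mc = MockClassifier(error_rate=1.0, seed=3)
        assert all(mc.classify(t).label is not cls for t, cls in tiles)

    def test_error_rate_recovered_binomially(self):
        """Misclassified fraction over 1000 tiles within 3 binomial SEs of 0.2."""
        eps = 0.2
        tiles = class_tiles(per_class=100)
        mc = MockClassifier(error_rate=eps, seed=11)
        wrong = sum(mc.classify(t).label is not cls for t, cls in tiles)
        n = len(tiles)
        assert abs(wrong / n - eps) <= 3 * np.sqrt(eps * (1 - eps) / n)

    def test_deterministic_per_tile(self):
        t, cls = class_tiles(per_class=1)[3]
        a = mock_classify(t, error_rate=0.5, seed=7)
        b = mock_classify(t, error_rate=0.5, seed=7)
        assert a.label is b.label and np.array_equal(a.probabilities, b.probabilities)

    def test_scores_within_configured_range(self):
        tiles = class_tiles(per_class=3)
        mc = MockClassifier(score_range=(0.80, 0.99))
        assert all(0.80 <= mc.classify(t).score <= 0.99 for t, _ in tiles)

    def test_confusion_profile_directs_errors(self):
        tiles = [t for t, cls in class_tiles(per_class=10) if cls is D.adenoma]
        profile = {D.adenoma: {D.adenocarcinoma: 1.0}}
        mc = MockClassifier(error_rate=1.0, confusion_profile=profile, seed=1)
        assert all(mc.classify(t).label is D.adenocarcinoma for t in tiles)

    def test_probability_vector_sums_to_one(self):
        t, _ = class_tiles(per_class=1)[0]
        c = mock_classify(t)
        assert abs(c.probabilities.sum() - 1.0) < 1e-9


class TestSplitValidation:
    def _store(self, n):
        store = TrainingStore()
        for i in range(n):
            store.add(np.zeros((8, 8, 3), np.uint8), CLASSES[i % 10])
        return store

    @pytest.mark.parametrize("n,expected", [(100, 25), (4, 1)])
    def test_validation_size(self, n, expected):
        tr, val = split_validation(self._store(n), 0.25, seed=0)
        assert len(val) == expected
        assert len(tr) + len(val) == n
        assert not {id(e) for e in tr} & {id(e) for e in val}

    def test_reproducible_by_seed(self):
        store = self._store(40)
        a = split_validation(store, 0.25, seed=5)
        b = split_validation(store, 0.25, seed=5)
        assert [id(e) for e in a[0]] == [id(e) for e in b[0]]

    def test_bad_fraction_and_empty_store(self):
        with pytest.raises(ValueError):
            split_validation(self._store(10), 1.5, seed=0)
        with pytest.raises(ValueError):
            split_validation(TrainingStore(), 0.25, seed=0)


class TestAugment:
    def test_horizontal_flip_is_involution_and_maps_pixels(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, size=(16, 16, 3)).astype(np.uint8)
        flipped = apply_flip(img, 1)
        assert np.array_equal(apply_flip(flipped, 1), img)
        r, c = 3, 5
        assert np.array_equal(flipped[r, c], img[r, 16 - 1 - c])

    def test_vertical_flip_maps_pixels(self):
        img = np.arange(64, dtype=np.uint8).reshape(8, 8)[..., None].repeat(3, axis=2)
        flipped = apply_flip(img, 2)
        assert np.array_equal(flipped[0], img[7])

    def test_variant_frequencies_uniform(self):
        """Over 4000 seeded draws each flip variant occurs at 0.25 +/- 0.03."""
        img = np.arange(48, dtype=np.uint8).reshape(4, 4, 3)
        variants = [apply_flip(img, v) for v in range(4)]
        rng = np.random.default_rng(123)
        counts = np.zeros(4)
        for _ in range(4000):
            out = augment(img, rng)
            counts[[np.array_equal(out, v) for v in variants].index(True)] += 1
        assert (np.abs(counts / 4000 - 0.25) <= 0.03).all()

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            augment(np.zeros((4, 8, 3), np.uint8), np.random.default_rng(0))


class TestTrainingStore:
    def test_corrections_counted(self):
        store = TrainingStore()
        t = make_tile(np.zeros((8, 8, 3), np.uint8))
        record_correction(store, t, D.adenoma)
        assert len(store) == 1 and store.corrections_since_retrain == 1
        record_correction(store, t, D.inflammation)
        record_correction(store, t, D.adenoma)
        assert store.corrections_since_retrain == 3

    def test_retrain_due_threshold_boundary(self):
        store = TrainingStore()
        assert not retrain_due(store, 200)
        store.corrections_since_retrain = 199
        assert not retrain_due(store, 200)
        store.corrections_since_retrain = 200
        assert retrain_due(store, 200)

    def test_counter_resets_on_retrain_event(self):
        store = TrainingStore()
        store.corrections_since_retrain = 42
        store.mark_retrained()
        assert store.corrections_since_retrain == 0

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError):
            record_correction(TrainingStore(), make_tile(np.zeros((8, 8, 3), np.uint8)), "adenoma")


@pytest.fixture(scope="module")
def trained_model():
    """Train once on 30 tiles/class at reduced size; reused across tests."""
    store = TrainingStore()
    for cls in CLASSES:
        for i in range(30):
            store.add(generate_class_tile(cls, size=96, seed=1000 * cls.rank + i), cls)
    model, val_acc, epochs = train(store, TrainConfig(seed=1))
    return store, model, val_acc, epochs


class TestTrain:
    def test_validation_accuracy_and_convergence(self, trained_model):
        _, _, val_acc, epochs = trained_model
        assert val_acc >= 0.90
        assert epochs <= 50

    def test_per_class_recall_on_held_out_tiles(self, trained_model):
        _, model, _, _ = trained_model
        for cls in CLASSES:
            hits = 0
            for i in range(20):
                px = generate_class_tile(cls, size=96, seed=500_000 + 1000 * cls.rank + i)
                hits += model.classify(make_tile(px)).label is cls
            assert hits / 20 >= 0.85, cls

    def test_training_resets_correction_counter(self, trained_model):
        store, _, _, _ = trained_model
        assert store.corrections_since_retrain == 0

    def test_sanity_overfit_small_set(self):
        """Capacity check: 20 tiles, trained and evaluated on themselves."""
        store = TrainingStore()
        for cls in CLASSES[:2]:
            for i in range(10):
                store.add(generate_class_tile(cls, 96, seed=5000 + cls.rank * 100 + i), cls)
        model, _, _ = train(
            store,
            TrainConfig(seed=0, max_epochs=100, early_stopping_patience=100,
                        validation_fraction=0.2),
        )
        x = np.stack([tile_features(e.image) for e in store.entries])
        pred = model.mlp.predict(model.scaler.transform(x))
        truth = np.array([e.label.rank for e in store.entries])
        assert (pred == truth).all()

    def test_small_class_warns_but_is_retained(self):
        store = TrainingStore()
        for cls in CLASSES[:2]:
            for i in range(20):
                store.add(generate_class_tile(cls, 64, seed=cls.rank * 50 + i), cls)
        for i in range(4):  # an HP/SSL-style rare class
            store.add(generate_class_tile(D.hp_ssl, 64, seed=900 + i), D.hp_ssl)
        with pytest.warns(UserWarning, match="only 4 tiles"):
            model, _, _ = train(store, TrainConfig(seed=0, max_epochs=5))
        assert D.hp_ssl.rank in model.class_ranks

    def test_single_class_rejected(self):
        store = TrainingStore()
        for i in range(20):
            store.add(generate_class_tile(D.adenoma, 64, seed=i), D.adenoma)
        with pytest.raises(ValueError, match="2 classes"):
            train(store, TrainConfig(seed=0))

    def test_model_round_trips_through_file(self, trained_model, tmp_path):
        _, model, _, _ = trained_model
        path = tmp_path / "model.joblib"
        model.save(path)
        loaded = TrainedClassifier.load(path)
        px = generate_class_tile(D.adenoma, 96, seed=31337)
        t = make_tile(px)
        assert np.allclose(
            model.predict_proba_image(px), loaded.predict_proba_image(px)
        )
        assert classify(t, loaded).label is classify(t, model).label
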