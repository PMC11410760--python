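import numpy as np
import pytest

from pretextnet.sharp_unet import build_restorer
from pretextnet.transfer import (
    Classifier,
    ClassifierTrainConfig,
    build_classifier,
    fine_tune,
    predict_cohort,
    truncate_encoder,
)


@pytest.fixture
def restorer():
    return build_restorer((64, 64), width_multiplier=0.125, seed=4)


class TestTruncateEncoder:
    def test_feature_map_shape_at_64(self, restorer, rng):
        encoder = truncate_encoder(restorer)
        x = rng.random((2, 1, 64, 64)).astype(np.float32)
        bottom, _ = encoder.forward(x, train=False)
        assert bottom.shape == (2, 64, 4, 4)  # 4x4 spatial, 512/8 channels

    def test_matches_restorer_internal_activation(self, restorer, rng):
        encoder = truncate_encoder(restorer)
        x = rng.random((1, 1, 64, 64)).astype(np.float32)
        restorer.forward(x, train=False)
        bottom, _ = encoder.forward(x, train=False)
        assert np.array_equal(bottom, restorer._bottom_activation)

    def test_weights_copied_bit_exactly(self, restorer):
        encoder = truncate_encoder(restorer)
        src = restorer.encoder.named_params()
        for name, p in encoder.named_params().items():
            assert np.array_equal(p.value, src[name].value)

    def test_copy_is_independent(self, restorer):
        encoder = truncate_encoder(restorer)
        encoder.blocks[0][0][0].W.value += 1.0
        assert not np.array_equal(
            encoder.blocks[0][0][0].W.value, restorer.encoder.blocks[0][0][0].W.value
        )

    def test_rejects_non_restorer(self):
        with pytest.raises(ValueError):
            truncate_encoder(object())


class TestBuildClassifier:
    def test_softmax_rows_sum_to_one(self, restorer, rng):
        clf = build_classifier(truncate_encoder(restorer), seed=0)
        probs = clf.predict_proba(rng.random((4, 1, 64, 64)).astype(np.float32))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_purity(self, restorer, rng):
        clf = build_classifier(truncate_encoder(restorer), seed=0)
        x = rng.random((2, 1, 64, 64)).astype(np.float32)
        assert np.array_equal(clf.predict_proba(x), clf.predict_proba(x))

    def test_random_init_symmetry(self, restorer, rng):
        # expectation over head initializations is 0.5 by sign symmetry
        x = rng.random((32, 1, 32, 32)).astype(np.float32)
        small = build_restorer((32, 32), width_multiplier=0.0625, seed=7)
        means = []
        for head_seed in range(16):
            clf = build_classifier(truncate_encoder(small), seed=head_seed)
            means.append(clf.predict_proba(x)[:, 1].mean())
        assert np.mean(means) == pytest.approx(0.5, abs=0.1)

    def test_unknown_init_source_rejected(self, restorer):
        with pytest.raises(ValueError):
            build_classifier(truncate_encoder(restorer), init_source="imagenet")


class TestFineTune:
    def _small_classifier(self, seed=0):
        restorer = build_restorer((32, 32), width_multiplier=0.0625, seed=seed)
        return build_classifier(
            truncate_encoder(restorer), init_source="deblur_pretext", seed=seed
        )

    def test_smoke_two_epochs(self, tiny_cohort):
        clf = self._small_classifier()
        cfg = ClassifierTrainConfig(max_epochs=2, batch_size=8, seed=0)
        best, history = fine_tune(clf, tiny_cohort, cfg)
        assert len(history) == 2
        assert min(history.val_loss) == history.val_loss[history.best_epoch]

    def test_best_no_worse_than_final(self, tiny_cohort):
        clf = self._small_classifier(seed=1)
        cfg = ClassifierTrainConfig(max_epochs=3, batch_size=8, seed=1)
        _, history = fine_tune(clf, tiny_cohort, cfg)
        assert min(history.val_loss) <= history.val_loss[-1] + 1e-12

    def test_single_class_rejected(self, tiny_cohort):
        from pretextnet.phantom import Cohort

        recs = [r for r in tiny_cohort.records if not (r.split == "train" and r.label == 1)]
        ids = {r.image_id for r in recs}
        cohort = Cohort(
            recs,
            {k: v for k, v in tiny_cohort.images.items() if k in ids},
            {k: v for k, v in tiny_cohort.truth_boxes.items() if k in ids},
        )
        with pytest.raises(ValueError):
            fine_tune(self._small_classifier(), cohort, ClassifierTrainConfig(max_epochs=1))

    def test_pretext_init_loads_encoder_bit_exactly(self):
        restorer = build_restorer((32, 32), width_multiplier=0.0625, seed=9)
        clf = build_classifier(truncate_encoder(restorer), init_source="deblur_pretext")
        src = restorer.encoder.named_params()
        for name, p in clf.encoder.named_params().items():
            assert np.array_equal(p.value, src[name].value)


class TestPredictAndPersistence:
    def test_predict_cohort_columns(self, tiny_cohort):
        restorer = build_restorer((32, 32), width_multiplier=0.0625, seed=2)
        clf = build_classifier(truncate_encoder(restorer), seed=2)
        df = predict_cohort(clf, tiny_cohort, "val")
        assert list(df.columns) == [
            "image_id",
            "p_normal",
            "p_abnormal",
            "logit_normal",
            "logit_abnormal",
            "label",
        ]
        assert np.allclose(df["p_normal"] + df["p_abnormal"], 1.0)

    def test_classifier_checkpoint_round_trip(self, tmp_path, rng):
        restorer = build_restorer((32, 32), width_multiplier=0.0625, seed=3)
        clf = build_classifier(truncate_encoder(restorer), seed=3)
        x = rng.random((2, 1, 32, 32)).astype(np.float32)
        before = clf.predict_proba(x)
        clf.save(tmp_path / "clf.npz")
        loaded = Classifier.load(tmp_path / "clf.npz")
        assert np.array_equal(before, loaded.predict_proba(x))
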