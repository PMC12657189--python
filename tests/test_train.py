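"""Training-harness tests: modes, determinism, freezing, RCJ statistics."""

import numpy as np
import pytest

from acam.backbone import Adam, ConvBackbone
from acam.estimators import AcamContrastRegressor, AcamImageClassifier
from acam.phantoms import PhantomSpec, generate_arrays
from acam.train import (
    Stage1Config,
    TrainConfig,
    freeze_generator,
    rcj_augment,
    reference_backbone,
    train_classifier,
    train_stage1,
)
from acam._autograd import Tensor


class TestReferenceBackbone:
    def test_head_dimension(self):
        net = reference_backbone(10, 6)
        logits = net.forward(Tensor(np.random.default_rng(0).random((2, 10, 64, 64))))
        assert logits.data.shape == (2, 6)
        assert np.all(np.isfinite(logits.data))

    def test_parameter_budget(self):
        assert reference_backbone(10, 6).n_parameters() < 200_000

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            reference_backbone(0, 6)


class TestRcjAugment:
    def test_degenerate_range_is_identity(self, random_image):
        out = rcj_augment(random_image, np.random.default_rng(0), 1.0, 1.0)
        np.testing.assert_allclose(out, random_image, rtol=1e-12)

    def test_gain_distribution_mean(self):
        rng = np.random.default_rng(0)
        gains = [rng.uniform(1.0, 3.0) for _ in range(10_000)]
        assert np.mean(gains) == pytest.approx(2.0, abs=0.05)

    def test_mean_preserved(self, random_image):
        out = rcj_augment(random_image, np.random.default_rng(1))
        assert out.mean() == pytest.approx(random_image.mean(), abs=1e-5)


class TestStage1:
    def test_untrained_zero_net_predicts_midrange(self, tiny_dataset):
        _, _, degraded, manifest = tiny_dataset
        reg = AcamContrastRegressor(epochs=0, seed=0)
        from acam.nets import TextureNet

        net = TextureNet(n_views=10, seed=0)
        net.load_state_dict({k: np.zeros_like(v) for k, v in net.state_dict().items()})
        reg.net_ = net
        pred = reg.predict(degraded[:20])
        np.testing.assert_allclose(pred, 2.0, atol=1e-12)
        # so the untrained baseline error is mean |alpha* - 2|
        alpha = manifest.records["alpha_star"].to_numpy()[:20]
        assert np.abs(pred - alpha).mean() == pytest.approx(np.abs(alpha - 2).mean())

    def test_determinism(self, tiny_dataset):
        _, _, degraded, manifest = tiny_dataset
        cfg = Stage1Config(epochs=2)
        net1, hist1 = train_stage1(degraded, manifest, cfg, seed=3)
        net2, hist2 = train_stage1(degraded, manifest, cfg, seed=3)
        assert hist1 == hist2
        assert net1.checksum() == net2.checksum()

    def test_missing_alpha_star_rejected(self, tiny_dataset):
        _, _, degraded, manifest = tiny_dataset
        import copy

        broken = copy.deepcopy(manifest)
        broken.records = broken.records.drop(columns=["alpha_star"])
        with pytest.raises(ValueError):
            train_stage1(degraded, broken, Stage1Config(epochs=1), seed=0)


class TestFreezeContract:
    def test_frozen_net_untouched_by_optimizer(self, tiny_dataset):
        _, _, degraded, manifest = tiny_dataset
        net, _ = train_stage1(degraded, manifest, Stage1Config(epochs=1), seed=0)
        freeze_generator(net)
        before = net.checksum()
        cfg = TrainConfig(mode="acam_two_stage", epochs=2, batch_size=32, seed=0)
        bundle = train_classifier(degraded, manifest, cfg, acam_params=net)
        assert bundle.texture_net.checksum() == before
        assert net.checksum() == before

    def test_unfrozen_net_changes_under_training(self, tiny_dataset):
        _, _, degraded, manifest = tiny_dataset
        from acam.nets import TextureNet

        net = TextureNet(n_views=10, seed=0)
        before = net.checksum()
        cfg = TrainConfig(mode="acam", epochs=2, batch_size=32, seed=0)
        bundle = train_classifier(degraded, manifest, cfg, acam_params=net)
        # constructor argument untouched; the trained copy differs
        assert net.checksum() == before
        assert bundle.texture_net.checksum() != before

    def test_double_freeze_idempotent(self):
        from acam.nets import TextureNet

        net = TextureNet(seed=0)
        assert freeze_generator(freeze_generator(net)).frozen


class TestTrainClassifier:
    def test_overfit_probe_small_fixture(self):
        """Capacity sanity: the backbone memorizes 32 images."""
        spec = PhantomSpec(n_samples=32, image_size=32, seed=1)
        _, degraded, manifest = generate_arrays(spec)
        y = manifest.records["class"].to_numpy()
        clf = AcamImageClassifier(
            mode="plain", image_size=32, epochs=50, batch_size=8, lr=3e-3, seed=0
        ).fit(degraded, y)
        assert clf.score(degraded, y) >= 0.95

    def test_determinism_same_seed_same_history(self, tiny_dataset):
        _, _, degraded, manifest = tiny_dataset
        cfg = TrainConfig(mode="plain", epochs=2, batch_size=32, seed=5)
        h1 = train_classifier(degraded, manifest, cfg).history
        h2 = train_classifier(degraded, manifest, cfg).history
        assert h1 == h2

    def test_acam_mode_feeds_ten_channels(self, tiny_dataset):
        _, _, degraded, manifest = tiny_dataset
        cfg = TrainConfig(mode="acam", epochs=1, batch_size=32, seed=0)
        bundle = train_classifier(degraded, manifest, cfg)
        assert bundle.classifier.backbone_.in_channels == 10

    def test_mode_argument_mismatches_rejected(self, tiny_dataset):
        _, _, degraded, manifest = tiny_dataset
        from acam.nets import TextureNet

        with pytest.raises(ValueError):
            train_classifier(
                degraded, manifest, TrainConfig(mode="plain", epochs=1), TextureNet(seed=0)
            )
        with pytest.raises(ValueError):
            train_classifier(degraded, manifest, TrainConfig(mode="acam_two_stage", epochs=1))
        with pytest.raises(ValueError):
            TrainConfig(mode="spicy")

    def test_two_stage_requires_frozen_net(self, tiny_dataset):
        _, _, degraded, manifest = tiny_dataset
        from acam.nets import TextureNet

        clf = AcamImageClassifier(mode="acam_two_stage", contrast_net=TextureNet(seed=0), epochs=1)
        y = manifest.records["class"].to_numpy()
        with pytest.raises(ValueError):
            clf.fit(degraded, y)

    def test_rcj_mode_trains(self, tiny_dataset):
        _, _, degraded, manifest = tiny_dataset
        cfg = TrainConfig(mode="rcj", epochs=1, batch_size=32, seed=0)
        bundle = train_classifier(degraded, manifest, cfg)
        assert bundle.classifier.texture_net_ is None
        assert len(bundle.history) == 1


class TestEvaluateIntegration:
    def test_report_has_six_classes(self, tiny_dataset):
        from acam.metrics import evaluate

        _, _, degraded, manifest = tiny_dataset
        cfg = TrainConfig(mode="plain", epochs=1, batch_size=32, seed=0)
        bundle = train_classifier(degraded, manifest, cfg)
        report = evaluate(bundle, degraded, manifest, split="test")
        assert len(report.per_class) == 6
        assert report.weighted["recall"] == pytest.approx(report.accuracy)
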