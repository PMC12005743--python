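"""Model zoo: architectures, training procedure, probability contracts."""

import numpy as np
import pandas as pd
import pytest

from phospsych import nn
from phospsych.models import (
    Model,
    ModelSpec,
    TrainConfig,
    build_model,
    conv_depth,
    fit_pca_features,
    predict_probs,
    restrict_probs,
    train_model,
)


class TestBuildModel:
    def test_pixel_head_parameter_count(self):
        model = build_model(ModelSpec(arch="PIXEL", n_classes=16))
        assert model.head_param_count() == 128 * 128 * 16 + 16

    @pytest.mark.parametrize("arch", ["PIXEL", "CNN_SHALLOW", "ALEXNET_LIKE", "VGG_LIKE", "RESNET_LIKE"])
    def test_untrained_model_outputs_probabilities(self, arch, rng):
        model = build_model(ModelSpec(arch=arch, n_classes=4, instance_seed=1))
        imgs = rng.integers(0, 256, (3, 128, 128)).astype(np.uint8)
        probs = model.predict_proba(imgs)
        assert probs.shape == (3, 4)
        assert np.allclose(probs.sum(1), 1.0, atol=1e-6)
        assert (probs >= 0).all()

    def test_shallow_cnn_is_shallower_than_vgg(self):
        assert conv_depth("CNN_SHALLOW") < conv_depth("VGG_LIKE")

    def test_unknown_arch_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(arch="TRANSFORMER")

    def test_unknown_loss_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(loss="focal")


class TestPCAFeatures:
    def test_planar_data_fully_explained_by_two_components(self, rng):
        # images lying exactly in a 2-D affine subspace
        base = rng.integers(0, 200, (2, 16, 16)).astype(float)
        coeffs = rng.uniform(0, 1, (30, 2))
        imgs = (coeffs @ base.reshape(2, -1)).reshape(30, 16, 16)
        pca = fit_pca_features(imgs, 2)
        assert pca.explained_variance_ratio_.sum() == pytest.approx(1.0, abs=1e-9)

    def test_mean_image_maps_to_zero_scores(self, rng):
        imgs = rng.integers(0, 256, (20, 16, 16)).astype(np.uint8)
        pca = fit_pca_features(imgs, 5)
        mean_img = (imgs.astype(float) / 255.0).reshape(20, -1).mean(0)
        assert np.allclose(pca.transform(mean_img[None]), 0.0, atol=1e-9)

    def test_reconstruction_matches_svd_oracle(self, rng):
        """PCA reconstruction error at k=10 equals the truncated-SVD
        optimum computed independently."""
        imgs = rng.integers(0, 256, (50, 16, 16)).astype(np.uint8)
        x = imgs.reshape(50, -1).astype(float) / 255.0
        pca = fit_pca_features(imgs, 10)
        recon = pca.inverse_transform(pca.transform(x))
        err_pca = ((x - recon) ** 2).sum()

        xc = x - x.mean(0)
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        err_svd = (s[10:] ** 2).sum()
        assert err_pca == pytest.approx(err_svd, abs=1e-8)

    def test_excessive_k_rejected(self, rng):
        imgs = rng.integers(0, 256, (5, 8, 8)).astype(np.uint8)
        with pytest.raises(ValueError):
            fit_pca_features(imgs, 50)


class TestTraining:
    def test_overfits_two_classes_within_epoch_budget(self):
        """A shallow CNN on 2 well-separated classes reaches 100% training
        accuracy before the 30-epoch cap."""
        from phospsych import generate_dataset

        ds = generate_dataset(n_classes=2, train_per_class=20, seed=11)
        spec = ModelSpec(arch="CNN_SHALLOW", n_classes=2, instance_seed=0)
        _model, hist = train_model(spec, ds, TrainConfig(lr=1e-3))
        assert (hist["train_acc"] == 1.0).any()
        assert hist["epoch"].max() < 30

    def test_early_stop_after_patience_without_improvement(self, small_dataset):
        """With a zero learning rate the validation loss never improves
        after the first epoch, so training halts after exactly the
        early-stop patience."""
        spec = ModelSpec(arch="PIXEL", n_classes=4, instance_seed=0)
        cfg = TrainConfig(lr=0.0, min_lr=0.0, early_stop_patience=7)
        _model, hist = train_model(spec, small_dataset, cfg)
        assert len(hist) == 1 + 7  # best epoch + patience stalled epochs
        assert hist.attrs["stop_epoch"] == 7

    def test_same_seed_reproduces_weights_and_history(self, small_dataset):
        spec = ModelSpec(arch="PIXEL", n_classes=4, instance_seed=5)
        cfg = TrainConfig(max_epochs=3)
        m1, h1 = train_model(spec, small_dataset, cfg)
        m2, h2 = train_model(spec, small_dataset, cfg)
        for (p1, _), (p2, _) in zip(m1.net.params(), m2.net.params()):
            assert np.array_equal(p1, p2)
        pd.testing.assert_frame_equal(h1, h2)

    def test_patience_outside_specified_range_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(early_stop_patience=3)

    def test_finetune_mix_variant_trains(self, small_dataset):
        spec = ModelSpec(arch="PIXEL", n_classes=4, instance_seed=0)
        cfg = TrainConfig(max_epochs=2, finetune_mix="ngb_highest_piq")
        _model, hist = train_model(spec, small_dataset, cfg)
        assert len(hist) == 2

    def test_multimargin_loss_trains(self, small_dataset):
        spec = ModelSpec(arch="PIXEL", loss="mml", n_classes=4, instance_seed=0)
        _model, hist = train_model(spec, small_dataset, TrainConfig(max_epochs=3, lr=1e-3))
        assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]


class TestPredictions:
    def test_probabilities_sum_to_one(self, trained_cnn, small_dataset):
        model, _ = trained_cnn
        test = small_dataset.subset("test")
        rec = predict_probs(model, test.images)
        probs = rec[[c for c in rec.columns if c.startswith("prob_")]].to_numpy()
        assert np.allclose(probs.sum(1), 1.0, atol=1e-6)

    def test_duplicate_images_get_identical_probabilities(self, trained_cnn, small_dataset):
        model, _ = trained_cnn
        img = small_dataset.subset("test").images[0]
        rec = predict_probs(model, np.stack([img, img]))
        cols = [c for c in rec.columns if c.startswith("prob_")]
        assert np.array_equal(rec[cols].iloc[0].to_numpy(), rec[cols].iloc[1].to_numpy())

    def test_wrong_size_rejected(self, trained_cnn, rng):
        model, _ = trained_cnn
        with pytest.raises(ValueError):
            predict_probs(model, rng.integers(0, 256, (2, 64, 64)).astype(np.uint8))

    def test_high_resolution_accuracy_above_80_percent(self, trained_cnn, small_dataset):
        """After training, the shallow CNN recognizes the contrast-
        normalized high-resolution test faces nearly perfectly (well above
        the 80% the task demands at high resolution)."""
        from phospsych import histogram_equalize

        model, _ = trained_cnn
        test = small_dataset.subset("test")
        eq = np.stack([histogram_equalize(im) for im in test.images])
        acc = (model.predict_proba(eq).argmax(1) == test.labels).mean()
        assert acc > 0.8


class TestRestrictProbs:
    def test_renormalization_never_decreases_kept_probability(self, rng):
        probs = rng.dirichlet(np.ones(16), size=200)
        options = [2, 5, 11, 14]
        restricted = restrict_probs(probs, options)
        assert np.allclose(restricted.sum(1), 1.0)
        for j, cls in enumerate(options):
            assert (restricted[:, cls] >= probs[:, cls] - 1e-12).all()
        off = [c for c in range(16) if c not in options]
        assert (restricted[:, off] == 0).all()

    def test_no_mass_on_options_rejected(self):
        p = np.zeros(4)
        p[0] = 1.0
        with pytest.raises(ValueError):
            restrict_probs(p, [1, 2])


class TestEngineGradients:
    def test_conv_net_gradients_match_finite_differences(self, rng):
        net = nn.Sequential(
            [
                nn.Conv2d(3, 3, 2, 1),
                nn.MaxPool2d(2),
                nn.ReLU(),
                nn.BatchNorm2d(),
                nn.Flatten(),
                nn.Dense(4),
            ]
        )
        net.init_shapes(rng, (2, 12, 12))
        x = rng.normal(size=(5, 2, 12, 12))
        y = rng.integers(0, 4, 5)
        logits = net.forward(x, train=True)
        _, g = nn.cross_entropy(logits, y)
        net.backward(g)
        for p, grad in net.params():
            flat = p.ravel()
            for k in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                eps, orig = 1e-6, flat[k]
                flat[k] = orig + eps
                lp, _ = nn.cross_entropy(net.forward(x, train=True), y)
                flat[k] = orig - eps
                lm, _ = nn.cross_entropy(net.forward(x, train=True), y)
                flat[k] = orig
                num = (lp - lm) / (2 * eps)
                denom = max(1e-6, abs(num) + abs(grad.ravel()[k]))
                assert abs(num - grad.ravel()[k]) / denom < 1e-4

    def test_residual_block_gradients(self, rng):
        body = nn.Sequential([nn.Conv2d(4, 3, 1, 1), nn.ReLU(), nn.Conv2d(4, 3, 1, 1)])
        shortcut = nn.Sequential([nn.Conv2d(4, 1, 1, 0)])
        net = nn.Sequential(
            [nn.Conv2d(4, 3, 1, 1), nn.Residual(body, shortcut), nn.GlobalAvgPool(), nn.Dense(3)]
        )
        net.init_shapes(rng, (1, 8, 8))
        x = rng.normal(size=(4, 1, 8, 8))
        y = rng.integers(0, 3, 4)
        logits = net.forward(x, train=True)
        _, g = nn.cross_entropy(logits, y)
        net.backward(g)
        p, grad = net.params()[0]
        flat, gflat = p.ravel(), grad.ravel()
        k = 0
        eps, orig = 1e-6, flat[k]
        flat[k] = orig + eps
        lp, _ = nn.cross_entropy(net.forward(x, train=True), y)
        flat[k] = orig - eps
        lm, _ = nn.cross_entropy(net.forward(x, train=True), y)
        flat[k] = orig
        assert (lp - lm) / (2 * eps) == pytest.approx(gflat[k], rel=1e-4, abs=1e-8)

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        spec = ModelSpec(arch="CNN_SHALLOW", n_classes=4, instance_seed=2)
        model = Model(spec)
        imgs = rng.integers(0, 256, (2, 128, 128)).astype(np.uint8)
        before = model.predict_proba(imgs)
        model.net.save(tmp_path / "m.pkl", meta={"arch": spec.arch, "seed": 2})
        clone = Model(ModelSpec(arch="CNN_SHALLOW", n_classes=4, instance_seed=99))
        meta = clone.net.load(tmp_path / "m.pkl")
        assert meta["seed"] == 2
        assert np.allclose(clone.predict_proba(imgs), before)
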