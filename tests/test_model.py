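"""Dual-branch classifier: forward contract, training, prediction, search."""

import numpy as np
import pytest

import hsimargin
from hsimargin import (
    DatasetSpec,
    ModelConfig,
    PatchSample,
    TrainConfig,
    build_model,
    build_patch_dataset,
    forward_logit,
    generate_phantom,
    predict_pixelwise,
    train_model,
    vertical_half_split,
)
from hsimargin.evaluation import auc, roc_curve
from hsimargin.model import HyperparamSearchSpec, hyperparameter_search, load_model, save_model
from hsimargin.sampling import SampleArrays, SplitSpec, pixel_features
from .conftest import small_params


def _random_batch(n=7, seed=0):
    rng = np.random.default_rng(seed)
    return (
        rng.uniform(size=(n, 25, 25, 3)).astype(np.float32),
        rng.standard_normal((n, 120)).astype(np.float32),
    )


def _small_dataset(n_per_class=150, seed=3, noise_sd=0.05):
    phantom = generate_phantom(small_params(seed=seed, noise_sd=noise_sd))
    split = vertical_half_split(phantom.image, guard_band_px=12)
    spec = DatasetSpec(samples_per_class_per_lesion=n_per_class, seed=seed)
    return phantom, build_patch_dataset([phantom.image], split, spec)


class TestForwardContract:
    def test_zero_parameters_give_probability_half(self):
        model = build_model(seed=0)
        model.load_state_dict([np.zeros_like(p) for p in model.parameters])
        spatial, spectral = _random_batch()
        logits = model.forward(spatial, spectral)
        np.testing.assert_array_equal(logits, 0.0)
        sample = PatchSample(spatial[0], spectral[0], (0, 0), 1, "x")
        assert forward_logit(model, sample) == 0.0

    def test_seeded_initialization_is_deterministic(self):
        a = build_model(seed=42)
        b = build_model(seed=42)
        for pa, pb in zip(a.parameters, b.parameters):
            np.testing.assert_array_equal(pa, pb)
        c = build_model(seed=43)
        assert any(
            not np.array_equal(pa, pc) for pa, pc in zip(a.parameters, c.parameters)
        )

    def test_batch_of_seven_gives_seven_logits(self):
        model = build_model(seed=1)
        spatial, spectral = _random_batch(7)
        assert model.forward(spatial, spectral).shape == (7,)

    def test_batch_forward_equals_per_sample(self):
        model = build_model(seed=2)
        spatial, spectral = _random_batch(9, seed=5)
        batch = model.forward(spatial, spectral)
        singles = [
            model.forward(spatial[i : i + 1], spectral[i : i + 1])[0]
            for i in range(9)
        ]
        np.testing.assert_allclose(batch, singles, atol=1e-5)

    def test_probabilities_strictly_inside_unit_interval(self):
        model = build_model(seed=3)
        spatial, spectral = _random_batch(20)
        probs = model.predict_proba(spatial, spectral)
        assert np.all((probs > 0) & (probs < 1))

    def test_unsupported_backbone_rejected(self):
        with pytest.raises(ValueError, match="backbone"):
            ModelConfig(spatial_backbone="efficientnet-b0")

    def test_both_branches_off_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(use_spatial=False, use_spectral=False)


class TestTraining:
    def test_overfits_small_separable_batch(self):
        """A 64-sample batch of pure-window patches (centres far from the
        margin) must be driven to near-zero training loss."""
        from scipy import ndimage

        phantom = generate_phantom(
            small_params(seed=3, noise_sd=0.0, boundary_blur_px=0.0,
                         illum_amplitude=0.0)
        )
        tumour = phantom.image.mask.binary_tumour
        inside = ndimage.distance_transform_edt(tumour)
        outside = ndimage.distance_transform_edt(~tumour)
        rng = np.random.default_rng(0)

        def pick(depth_map, k):
            rr, cc = np.nonzero(depth_map >= 14)
            idx = rng.choice(rr.size, size=k, replace=False)
            return np.column_stack([rr[idx], cc[idx]])

        centres = np.vstack([pick(inside, 32), pick(outside, 32)])
        spatial, spectral = pixel_features(phantom.image, centres)
        sub = SampleArrays(
            spatial=spatial, spectral=spectral,
            labels=np.r_[np.ones(32, np.int8), np.zeros(32, np.int8)],
            centres=centres, lesion_ids=np.array(["p"] * 64, dtype=object),
        )
        model = build_model(seed=0)
        tc = TrainConfig(max_epochs=200, patience=200, learning_rate=3e-3,
                         batch_size=64)
        train_model(model, sub, sub, tc)
        assert model.training_log[-1]["train_loss"] < 0.05

    def test_early_stopping_rule(self):
        """Training stops within `patience` epochs of the best epoch."""
        _, ds = _small_dataset(n_per_class=60)
        model = build_model(seed=1)
        tc = TrainConfig(max_epochs=40, patience=2)
        train_model(model, ds.train, ds.validation, tc)
        n_epochs = len(model.training_log)
        assert model.best_epoch == int(
            np.argmin([rec["val_loss"] for rec in model.training_log])
        )
        if n_epochs < tc.max_epochs:  # early-stopped
            assert (n_epochs - 1) - model.best_epoch >= tc.patience

    def test_training_is_deterministic(self):
        _, ds = _small_dataset(n_per_class=30)
        tc = TrainConfig(max_epochs=3, patience=5)
        runs = []
        for _ in range(2):
            model = build_model(seed=4)
            train_model(model, ds.train, ds.validation, tc)
            runs.append(model.state_dict())
        for pa, pb in zip(*runs):
            np.testing.assert_array_equal(pa, pb)

    def test_single_class_training_rejected(self):
        _, ds = _small_dataset(n_per_class=20)
        only_pos = ds.train.labels == 1
        sub = SampleArrays(
            spatial=ds.train.spatial[only_pos], spectral=ds.train.spectral[only_pos],
            labels=ds.train.labels[only_pos], centres=ds.train.centres[only_pos],
            lesion_ids=ds.train.lesion_ids[only_pos],
        )
        with pytest.raises(ValueError, match="single class"):
            train_model(build_model(seed=0), sub, sub, TrainConfig())


class TestPredictPixelwise:
    def test_single_pixel_region_matches_forward(self):
        phantom, _ = _small_dataset(n_per_class=10)
        model = build_model(seed=0)
        region = np.zeros((100, 100), dtype=bool)
        region[40, 60] = True
        pm = predict_pixelwise(model, phantom.image, region)
        assert np.isfinite(pm[40, 60]) and np.isnan(pm[0, 0])
        spatial, spectral = pixel_features(phantom.image, np.array([[40, 60]]))
        sample = PatchSample(spatial[0], spectral[0], (40, 60), 0, "x")
        from hsimargin.nn import sigmoid

        assert pm[40, 60] == pytest.approx(
            sigmoid(np.array([forward_logit(model, sample)]))[0], abs=1e-5
        )

    def test_region_pixel_count_and_range(self):
        phantom, _ = _small_dataset(n_per_class=10)
        model = build_model(seed=1)
        region = np.zeros((100, 100), dtype=bool)
        region[:, 50:] = True  # right half of a 100-wide image
        pm = predict_pixelwise(model, phantom.image, region)
        vals = pm[region]
        assert vals.size == 100 * 50
        assert np.all((vals > 0) & (vals < 1))
        assert np.isnan(pm[~region]).all()


class TestAblation:
    def test_spectral_branch_carries_the_spectral_signal(self):
        """Classes differing spectrally are separated by the spectral branch
        alone; shuffling its input destroys the separation."""
        phantom, ds = _small_dataset(n_per_class=250, seed=6)
        model = build_model(ModelConfig(use_spatial=False), seed=0)
        tc = TrainConfig(max_epochs=12, patience=12)
        train_model(model, ds.train, ds.validation, tc)

        (stream,) = ds.test
        sub = np.arange(0, stream.centres.shape[0], 7)  # thin for speed
        centres, labels = stream.centres[sub], stream.labels[sub]
        _, spectral = pixel_features(phantom.image, centres)
        probs = model.predict_proba(None, spectral)
        assert auc(roc_curve(probs, labels)) >= 0.95

        rng = np.random.default_rng(0)
        shuffled = spectral[:, rng.permutation(spectral.shape[1])]
        # destroy band structure independently per sample
        for row in shuffled:
            rng.shuffle(row)
        probs_shuffled = model.predict_proba(None, shuffled)
        assert abs(auc(roc_curve(probs_shuffled, labels)) - 0.5) < abs(
            auc(roc_curve(probs, labels)) - 0.5
        )


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path):
        _, ds = _small_dataset(n_per_class=20)
        model = build_model(seed=0)
        train_model(model, ds.train, ds.validation, TrainConfig(max_epochs=2))
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        for pa, pb in zip(model.parameters, back.parameters):
            np.testing.assert_array_equal(pa, pb)
        assert back.best_epoch == model.best_epoch
        assert back.training_log == model.training_log
        spatial, spectral = _random_batch(4)
        np.testing.assert_allclose(
            back.forward(spatial, spectral), model.forward(spatial, spectral)
        )


class TestHyperparameterSearch:
    def _tiny(self):
        _, ds = _small_dataset(n_per_class=25)
        return ds

    def test_budget_one_returns_single_trial(self):
        ds = self._tiny()
        spec = HyperparamSearchSpec(
            space={"learning_rate": [1e-3, 3e-3]}, budget=1, seed=0
        )
        base_tc = TrainConfig(max_epochs=2)
        _, tc, table = hyperparameter_search(spec, ds.train, ds.validation,
                                             base_train_config=base_tc)
        assert len(table) == 1
        assert tc.learning_rate == table[0]["params"]["learning_rate"]

    def test_best_trial_is_argmin_and_seeded(self):
        ds = self._tiny()
        spec = HyperparamSearchSpec(
            space={"learning_rate": [1e-4, 1e-3], "head_hidden_dims": [(16,), (32,)]},
            budget=3, seed=7,
        )
        base_tc = TrainConfig(max_epochs=2)
        _, _, table_a = hyperparameter_search(spec, ds.train, ds.validation,
                                              base_train_config=base_tc)
        _, _, table_b = hyperparameter_search(spec, ds.train, ds.validation,
                                              base_train_config=base_tc)
        assert [t["params"] for t in table_a] == [t["params"] for t in table_b]
        best = min(t["val_loss"] for t in table_a)
        assert all(t["val_loss"] >= best for t in table_a)
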