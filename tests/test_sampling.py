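"""Patch extraction, band selection, normalization, splits, augmentation."""

import numpy as np
import pytest

from hsimargin import (
    AnnotationMask,
    AugmentationPolicy,
    DatasetSpec,
    LesionImage,
    PatchSample,
    SpectralCube,
    augment_patch,
    build_patch_dataset,
    extract_patch,
    loo_folds,
    make_wavelength_grid,
    select_bands,
    spectral_input,
    vertical_half_split,
)
from hsimargin.sampling import (
    PATCH_HALF,
    SplitSpec,
    mean_spectrum_map,
    pixel_features,
)


def _toy_image(height=30, width=60, n_bands=6, seed=0, lesion_id="toy"):
    rng = np.random.default_rng(seed)
    grid = make_wavelength_grid(n_bands, 400, 900)
    cube = SpectralCube(rng.uniform(0.1, 1.0, size=(height, width, n_bands)), grid)
    labels = np.zeros((height, width), dtype=np.uint8)
    labels[:, : width // 6] = 1  # tumour strip near the left edge
    labels[:, width // 2 + 2 : width // 2 + 8] = 1
    return LesionImage(cube=cube, mask=AnnotationMask(labels), lesion_id=lesion_id)


class TestVerticalHalfSplit:
    def test_sensor_resolution_split(self):
        img = _toy_image(height=30, width=1920)
        split = vertical_half_split(img, guard_band_px=0)
        assert split.train_cols["toy"] == (0, 960)
        assert split.test_cols["toy"] == (960, 1920)

    def test_odd_width_floor_rule(self):
        img = _toy_image(width=61)
        split = vertical_half_split(img, guard_band_px=0)
        # floor(61/2) = 30: train gets 0..29, test gets 30..60
        assert split.train_cols["toy"] == (0, 30)
        assert split.test_cols["toy"] == (30, 61)

    def test_too_narrow_image_rejected(self):
        with pytest.raises(ValueError, match="narrow"):
            vertical_half_split(_toy_image(width=40), guard_band_px=12)

    def test_guard_band_exclusion_matches_bruteforce(self):
        img = _toy_image(width=100)
        split = vertical_half_split(img, guard_band_px=12)
        mid = 50
        excluded = [
            c for c in range(100)
            if not (c < split.train_cols["toy"][1] or c >= split.test_cols["toy"][0])
        ]
        brute = [c for c in range(100) if mid - 12 <= c < mid + 12]
        assert excluded == brute == list(range(38, 62))


class TestLooFolds:
    def test_partition_property(self):
        cohort = [_toy_image(seed=i, lesion_id=f"l{i}") for i in range(4)]
        folds = loo_folds(cohort)
        assert len(folds) == 4
        tested = [list(f.test_cols) for f in folds]
        assert sorted(t for ts in tested for t in ts) == sorted(
            img.lesion_id for img in cohort
        )
        for f in folds:
            assert set(f.train_cols).isdisjoint(f.test_cols)
            assert len(f.train_cols) == 3

    def test_two_lesion_minimal_case(self):
        cohort = [_toy_image(seed=i, lesion_id=f"l{i}") for i in range(2)]
        folds = loo_folds(cohort)
        assert list(folds[0].test_cols) == ["l0"] and list(folds[0].train_cols) == ["l1"]
        assert list(folds[1].test_cols) == ["l1"] and list(folds[1].train_cols) == ["l0"]

    def test_duplicate_ids_rejected(self):
        cohort = [_toy_image(lesion_id="same"), _toy_image(seed=1, lesion_id="same")]
        with pytest.raises(ValueError, match="duplicate"):
            loo_folds(cohort)


class TestExtractPatch:
    def test_corner_patch_shape(self):
        img = _toy_image()
        patch = extract_patch(img.cube, (0, 0))
        assert patch.shape == (25, 25, 6)

    def test_interior_patch_is_subarray(self):
        img = _toy_image(height=40, width=60)
        patch = extract_patch(img.cube, (20, 30))
        np.testing.assert_array_equal(patch, img.cube.data[8:33, 18:43, :])

    def test_reflect_rule_column_minus1_is_column_1(self):
        img = _toy_image()
        patch = extract_patch(img.cube, (13, 0))
        # patch column 11 corresponds to image column -1 -> reflected to col 1
        np.testing.assert_array_equal(patch[:, 11, :], patch[:, 13, :])
        np.testing.assert_array_equal(patch[12, 12, :], img.cube.data[13, 0, :])

    def test_outside_centre_rejected(self):
        img = _toy_image()
        with pytest.raises(ValueError):
            extract_patch(img.cube, (-1, 5))


class TestSelectBands:
    def test_default_indices_on_default_grid(self, default_grid):
        slab = np.arange(120)[None, None, :] * np.ones((2, 2, 1))
        out = select_bands(slab, default_grid)
        np.testing.assert_array_equal(out[0, 0], [9, 46, 108])

    def test_degenerate_selection_warns(self, default_grid):
        slab = np.ones((2, 2, 120))
        with pytest.warns(UserWarning, match="duplicate"):
            out = select_bands(slab, default_grid, targets=[460, 460, 460])
        assert out.shape == (2, 2, 3)

    def test_permuted_targets_permute_channels(self, default_grid):
        slab = np.random.default_rng(0).uniform(size=(3, 3, 120))
        a = select_bands(slab, default_grid, targets=[487, 604, 795])
        b = select_bands(slab, default_grid, targets=[795, 487, 604])
        np.testing.assert_array_equal(a[..., [2, 0, 1]], b)


class TestSpectralInput:
    def test_constant_slab_returns_zeros(self):
        assert (spectral_input(np.full((25, 25, 10), 3.0)) == 0).all()

    def test_zscore_property_on_linear_spectrum(self):
        slab = np.linspace(0.1, 1.0, 10)[None, None, :] * np.ones((25, 25, 1))
        out = spectral_input(slab)
        assert out.mean() == pytest.approx(0, abs=1e-12)
        assert out.std() == pytest.approx(1, abs=1e-12)

    def test_matches_direct_recomputation(self):
        slab = np.random.default_rng(5).uniform(0.2, 1.0, size=(25, 25, 40))
        mean_spec = slab.mean(axis=(0, 1))
        expected = (mean_spec - mean_spec.mean()) / mean_spec.std()
        np.testing.assert_allclose(spectral_input(slab), expected, atol=1e-9)


class TestAugmentation:
    def _sample(self, seed=0):
        rng = np.random.default_rng(seed)
        return PatchSample(
            spatial=rng.uniform(size=(25, 25, 3)),
            spectral=rng.uniform(size=(120,)),
            centre=(5, 5),
            label=1,
            lesion_id="toy",
        )

    def test_double_horizontal_flip_is_identity(self):
        s = self._sample()
        flipped = np.ascontiguousarray(s.spatial[:, ::-1, :])
        np.testing.assert_array_equal(flipped[:, ::-1, :], s.spatial)

    def test_four_quarter_turns_are_identity(self):
        s = self._sample()
        out = s.spatial
        for _ in range(4):
            out = np.rot90(out, axes=(0, 1))
        np.testing.assert_array_equal(out, s.spatial)

    def test_label_and_spectral_invariant_over_many_draws(self):
        s = self._sample()
        policy = AugmentationPolicy()
        for seed in range(1000):
            out = augment_patch(s, policy, seed=seed)
            assert out.label == s.label
            assert out.spectral is s.spectral

    def test_deterministic_given_seed(self):
        s = self._sample()
        policy = AugmentationPolicy()
        a = augment_patch(s, policy, seed=123).spatial
        b = augment_patch(s, policy, seed=123).spatial
        np.testing.assert_array_equal(a, b)

    def test_spectral_input_invariant_under_augmentations(self):
        slab = np.random.default_rng(2).uniform(0.2, 1.0, size=(25, 25, 30))
        base = spectral_input(slab)
        for transform in (slab[:, ::-1], slab[::-1], np.rot90(slab, axes=(0, 1))):
            np.testing.assert_allclose(spectral_input(transform), base, atol=1e-12)

    def test_off_grid_rotation_rejected(self):
        with pytest.raises(ValueError):
            AugmentationPolicy(rotations=(45,))


class TestPixelFeatures:
    def test_agrees_with_per_pixel_operations(self):
        img = _toy_image(height=30, width=60, n_bands=8)
        targets = [500, 700, 850]
        centres = np.array([[0, 0], [15, 30], [29, 59], [13, 0]])
        spatial, spectral = pixel_features(img, centres, band_targets=targets)
        for k, (r, c) in enumerate(centres):
            patch = extract_patch(img.cube, (r, c))
            np.testing.assert_allclose(
                spatial[k], select_bands(patch, img.cube.grid, targets), atol=1e-6
            )
            np.testing.assert_allclose(
                spectral[k], spectral_input(patch), atol=1e-4
            )

    def test_mean_spectrum_map_matches_patch_mean(self):
        img = _toy_image(height=28, width=50, n_bands=5)
        m = mean_spectrum_map(img.cube)
        for r, c in [(0, 0), (14, 25), (27, 49)]:
            patch = extract_patch(img.cube, (r, c))
            np.testing.assert_allclose(m[r, c], patch.mean(axis=(0, 1)), atol=1e-10)


class TestBuildPatchDataset:
    def _dataset(self, spec=None, guard=0, width=50, height=10):
        img = _toy_image(height=height, width=width, n_bands=6)
        split = vertical_half_split(img, guard_band_px=guard)
        spec = spec or DatasetSpec(samples_per_class_per_lesion=None,
                                   validation_fraction=0.0, seed=0)
        return img, build_patch_dataset([img], split, spec)

    def test_test_stream_enumerates_every_test_pixel(self):
        img, ds = self._dataset(width=50, height=10)
        (stream,) = ds.test
        assert stream.centres.shape[0] == 10 * 25
        assert np.unique(stream.centres, axis=0).shape[0] == 250

    def test_same_seed_identical_order(self):
        spec = DatasetSpec(samples_per_class_per_lesion=30, seed=5)
        _, a = self._dataset(spec=spec)
        _, b = self._dataset(spec=spec)
        np.testing.assert_array_equal(a.train.centres, b.train.centres)
        np.testing.assert_array_equal(a.validation.centres, b.validation.centres)

    def test_stratified_count_contract(self):
        spec = DatasetSpec(samples_per_class_per_lesion=20,
                           validation_fraction=0.0, seed=1)
        _, ds = self._dataset(spec=spec, height=20, width=60)
        assert (ds.train.labels == 1).sum() == 20
        assert (ds.train.labels == 0).sum() == 20

    def test_missing_class_raises_with_lesion_name(self):
        img = _toy_image(lesion_id="allhealthy")
        img.mask.labels[:] = 0
        split = vertical_half_split(img, guard_band_px=0)
        with pytest.raises(ValueError, match="allhealthy"):
            build_patch_dataset([img], split, DatasetSpec(seed=0))

    def test_train_test_centres_disjoint(self):
        img, ds = self._dataset(width=60, height=12)
        train = {tuple(c) for c in ds.train.centres} | {
            tuple(c) for c in ds.validation.centres
        }
        test = {tuple(c) for c in ds.test[0].centres}
        assert not (train & test)

    def test_guard_band_prevents_any_column_contact(self):
        """With guard >= 12 no training patch reads any test-half column."""
        img, ds = self._dataset(guard=12, width=60, height=12)
        mid = 30
        touched = set()
        for r, c in ds.train.centres:
            touched.update(range(c - PATCH_HALF, c + PATCH_HALF + 1))
        assert max(touched) < mid

    def test_half_mean_mode_gives_constant_spectral_input(self):
        spec = DatasetSpec(samples_per_class_per_lesion=10, seed=0,
                           validation_fraction=0.0, spectral_mode="half_mean")
        _, ds = self._dataset(spec=spec, height=20, width=60)
        assert np.ptp(ds.train.spectral, axis=0).max() == 0
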