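"""Patch bookkeeping, training loop, reconstruction."""

import numpy as np
import pytest

from pamrestore.mtrdn import MTRDN
from pamrestore.train import (
    PatchSet,
    build_patch_set,
    extract_patches,
    load_patch_set,
    reconstruct,
    save_patch_set,
    stitch_patches,
    train_model,
)
from pamrestore.vesselness import make_ground_truth3

TINY = dict(n_blocks=2, convs_per_block=2, growth=4, base_channels=8)


class TestExtractPatches:
    @pytest.mark.parametrize("patch, expected", [(100, 4), (50, 16)])
    def test_tile_counts_on_200px_image(self, patch, expected):
        patches, origins = extract_patches(np.zeros((200, 200)), patch)
        assert len(patches) == expected == len(origins)

    def test_row_major_origins(self):
        _, origins = extract_patches(np.zeros((4, 4)), 2)
        assert origins == [(0, 0), (0, 2), (2, 0), (2, 2)]

    def test_remainder_shifts_last_tile_inward(self):
        img = np.arange(35.0).reshape(5, 7)
        patches, origins = extract_patches(img, 3, 3)
        assert (2, 4) in origins  # bottom/right tiles shifted to fit
        rows = {o[0] for o in origins}
        cols = {o[1] for o in origins}
        assert rows == {0, 2} and cols == {0, 3, 4}

    def test_patch_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            extract_patches(np.zeros((8, 8)), 16)


class TestStitchPatches:
    def test_round_trip_identity_on_exact_tiling(self, rng):
        img = rng.random((64, 64))
        patches, origins = extract_patches(img, 16)
        out = stitch_patches(patches, origins, img.shape)
        np.testing.assert_allclose(out, img)

    def test_overlap_averaging(self):
        patches = [np.zeros((4, 4)), np.ones((4, 4))]
        origins = [(0, 0), (0, 2)]
        out = stitch_patches(patches, origins, (4, 6))
        np.testing.assert_array_equal(out[:, :2], 0.0)
        np.testing.assert_array_equal(out[:, 2:4], 0.5)
        np.testing.assert_array_equal(out[:, 4:], 1.0)

    def test_scaled_origin_arithmetic(self, rng):
        # 16 low-res 50x50 tiles of a 200x200 image at scale 4 -> 800x800
        lr = rng.random((200, 200))
        _, origins = extract_patches(lr, 50)
        hr_patches = [rng.random((200, 200)) for _ in origins]
        out = stitch_patches(hr_patches, origins, (800, 800), scale=4)
        assert out.shape == (800, 800)
        # independently computed placement of the last tile
        r, c = origins[-1]
        np.testing.assert_allclose(out[r * 4 :, c * 4 :], hr_patches[-1])

    def test_uncovered_pixels_rejected(self):
        with pytest.raises(ValueError):
            stitch_patches([np.ones((2, 2))], [(0, 0)], (4, 4))


@pytest.fixture(scope="module")
def toy_patches(scene_batch):
    scenes, pairs = scene_batch
    gt3 = [make_ground_truth3(s.gt532) for s in scenes]
    triples = [(s.gt532, s.gt560, g) for s, g in zip(scenes, gt3)]
    return build_patch_set(pairs, triples, patch=16)


class TestBuildPatchSet:
    def test_aligned_lengths_and_sizes(self, toy_patches):
        ps = toy_patches
        assert len(ps) == 4 * 4  # four 32x32 inputs tiled into 16x16 patches
        assert ps.input1.shape[1:] == (16, 16)
        assert ps.gt3.shape[1:] == (32, 32)
        assert ps.scale == 2

    def test_patch_alignment_against_source(self, scene_batch, toy_patches):
        scenes, pairs = scene_batch
        np.testing.assert_array_equal(toy_patches.input1[0], pairs[0].input1[:16, :16])
        np.testing.assert_array_equal(toy_patches.gt1[0], scenes[0].gt532[:32, :32])

    def test_hdf5_round_trip(self, toy_patches, tmp_path):
        path = tmp_path / "patches.h5"
        save_patch_set(toy_patches, path)
        loaded = load_patch_set(path)
        np.testing.assert_array_equal(loaded.input1, toy_patches.input1)
        np.testing.assert_array_equal(loaded.gt3, toy_patches.gt3)
        assert loaded.scale == toy_patches.scale
        assert loaded.origins == toy_patches.origins


class TestTrainModel:
    def test_single_step_history(self, toy_patches):
        model = MTRDN(scale=2, **TINY, seed=0)
        state = train_model(toy_patches, model, steps=1, batch=2, seed=0)
        assert len(state.loss_history) == 1
        assert np.isfinite(state.loss_history[0][1])

    def test_loss_decreases_on_toy_set(self, toy_patches):
        model = MTRDN(scale=2, **TINY, seed=1)
        state = train_model(toy_patches, model, steps=120, batch=4, seed=1)
        losses = [l for _, l in state.loss_history]
        assert np.mean(losses[-20:]) < np.mean(losses[:20])

    def test_same_seed_same_history(self, toy_patches):
        s1 = train_model(toy_patches, MTRDN(scale=2, **TINY, seed=2), steps=5, batch=2, seed=3)
        s2 = train_model(toy_patches, MTRDN(scale=2, **TINY, seed=2), steps=5, batch=2, seed=3)
        assert s1.loss_history == s2.loss_history

    def test_empty_patch_set_rejected(self):
        with pytest.raises(ValueError):
            train_model(
                PatchSet(
                    input1=np.zeros((0, 8, 8)),
                    input2=np.zeros((0, 8, 8)),
                    gt1=np.zeros((0, 8, 8)),
                    gt2=np.zeros((0, 8, 8)),
                    gt3=np.zeros((0, 8, 8)),
                    patch_size_lr=8,
                    scale=1,
                ),
                MTRDN(scale=1, **TINY),
            )


@pytest.fixture(scope="module")
def model():
    return MTRDN(scale=2, **TINY, seed=4)


class TestReconstruct:
    def test_shape_contract_with_overlap(self, model, rng):
        i1, i2 = rng.random((32, 32)), rng.random((32, 32))
        r1, r2, r3 = reconstruct(model, i1, i2, patch=16, stride=8)
        assert r1.shape == r2.shape == r3.shape == (64, 64)

    def test_whole_image_patch_equals_single_forward(self, model, rng):
        i1, i2 = rng.random((16, 16)), rng.random((16, 16))
        recons = reconstruct(model, i1, i2)  # patch = whole image
        direct = model.forward(i1, i2)
        for r, d in zip(recons, direct):
            np.testing.assert_allclose(r, d, atol=1e-6)

    def test_seam_error_is_bounded_and_reported(self, model, rng):
        i1, i2 = rng.random((32, 32)), rng.random((32, 32))
        tiled = reconstruct(model, i1, i2, patch=16)
        overlapped = reconstruct(model, i1, i2, patch=16, stride=8)
        seam = np.abs(tiled[2] - overlapped[2]).max()
        assert np.isfinite(seam)  # measured, not asserted zero: tiling context differs
        assert seam < 0.5
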