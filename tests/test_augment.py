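"""CTIA operator invariants: identity limits, label closure, joint geometry."""

import numpy as np
import pytest

from ctseg.augment import (
    AugmentPolicy,
    DEFAULT_WINDOW_TABLE,
    IntensityWindowTable,
    augment_batch,
    cwvrs,
    gaussian_noise,
    random_patch,
    random_rotate,
    slice_interpolate,
    slice_skip,
)
from ctseg.preprocess import SliceStack


def make_stack(n=6, side=16, seed=0):
    rng = np.random.default_rng(seed)
    slices = rng.normal(50.0, 30.0, size=(n, side, side))
    labels = np.zeros((n, side, side), dtype=np.int64)
    labels[:, 4:10, 4:10] = 1
    labels[:, 6:8, 6:8] = 2
    return SliceStack(slices=slices, label_slices=labels)


class _ForcedRng:
    """Minimal rng stub whose uniform() always returns the upper bound."""

    def uniform(self, lo, hi):
        return hi

    def random(self):
        return 0.0


@pytest.mark.parametrize(
    "op",
    [
        lambda s, rng: cwvrs(s, DEFAULT_WINDOW_TABLE, 0.0, 0.0, rng),
        lambda s, rng: slice_skip(s, 0, rng),
        lambda s, rng: slice_interpolate(s, 0, rng),
        lambda s, rng: gaussian_noise(s, 0.0, rng),
        lambda s, rng: random_rotate(s, 0.0, rng),
        lambda s, rng: random_patch(s, s.slices.shape[1], rng),
    ],
    ids=["cwvrs", "skip", "interpolate", "noise", "rotate", "patch"],
)
def test_zero_magnitude_is_identity(op, rng):
    stack = make_stack()
    out = op(stack, rng)
    assert np.array_equal(out.slices, stack.slices)
    assert np.array_equal(out.label_slices, stack.label_slices)


class TestCWVRS:
    def test_forced_pure_shift_moves_in_window_voxels_exactly(self):
        ramp = np.tile(np.linspace(0.0, 100.0, 101), (2, 16, 1))[:, :, :16]
        stack = SliceStack(slices=ramp, label_slices=np.zeros_like(ramp, dtype=np.int64))
        table = IntensityWindowTable((("w", 0.0, 100.0),))
        out = cwvrs(stack, table, max_shift_hu=10.0, max_scale_delta=0.0, rng=_ForcedRng())
        inside = (ramp >= 0) & (ramp <= 100)
        assert np.allclose(out.slices[inside], ramp[inside] + 10.0)

    def test_out_of_window_voxels_bit_identical(self, rng):
        stack = make_stack()
        stack.slices[0, 0, 0] = -500.0
        table = IntensityWindowTable((("w", 0.0, 100.0),))
        out = cwvrs(stack, table, 20.0, 0.1, rng)
        outside = (stack.slices < 0.0) | (stack.slices > 100.0)
        assert np.array_equal(out.slices[outside], stack.slices[outside])
        assert out.slices[0, 0, 0] == -500.0

    def test_labels_untouched(self, rng):
        stack = make_stack()
        out = cwvrs(stack, DEFAULT_WINDOW_TABLE, 20.0, 0.1, rng)
        assert np.array_equal(out.label_slices, stack.label_slices)

    def test_rescaled_table_matches_zscore(self):
        from ctseg.preprocess import NormStats

        table = IntensityWindowTable((("w", -150.0, 250.0),))
        scaled = table.rescaled(NormStats(mean=50.0, std=100.0))
        assert scaled.windows[0][1] == pytest.approx((-150.0 - 50.0) / 100.0)
        assert scaled.windows[0][2] == pytest.approx((250.0 - 50.0) / 100.0)


class TestSliceSkip:
    def test_removes_nonadjacent_interior_slices(self, rng):
        for _ in range(100):
            stack = make_stack(n=8)
            out = slice_skip(stack, 3, rng)
            kept = out.source_indices.astype(int)
            removed = sorted(set(range(8)) - set(kept))
            assert 1 <= len(removed) <= 3
            assert 0 not in removed and 7 not in removed
            assert all(b - a > 1 for a, b in zip(removed, removed[1:]))
            assert np.all(np.diff(kept) > 0)

    def test_images_and_labels_drop_same_indices(self, rng):
        stack = make_stack(n=8)
        stack.label_slices = (np.arange(8)[:, None, None] * np.ones((1, 16, 16))).astype(int)
        stack.slices = np.asarray(stack.label_slices, dtype=float) * 10.0
        for _ in range(100):
            out = slice_skip(stack, 3, rng)
            assert np.array_equal(out.slices, out.label_slices * 10.0)

    def test_repad_restores_fixed_count(self, rng):
        stack = make_stack(n=8)
        out = slice_skip(stack, 3, rng, pad_to=8)
        assert out.n_slices == 8

    def test_too_short_stack_passes_through(self, rng):
        stack = make_stack(n=2)
        out = slice_skip(stack, 3, rng)
        assert np.array_equal(out.slices, stack.slices)


class TestSliceInterpolate:
    def test_inserted_slice_is_midpoint_of_constant_parents(self, rng):
        slices = np.stack([np.zeros((8, 8)), np.full((8, 8), 2.0)])
        labels = np.stack([np.zeros((8, 8), dtype=np.int64), np.ones((8, 8), dtype=np.int64)])
        stack = SliceStack(slices=slices, label_slices=labels)
        out = slice_interpolate(stack, 1, rng)
        assert out.n_slices == 3
        assert np.allclose(out.slices[1], 1.0)
        assert np.array_equal(out.label_slices[1], labels[0]) or np.array_equal(
            out.label_slices[1], labels[1])
        assert out.source_indices[1] == pytest.approx(0.5)

    def test_inserted_label_equals_one_parent(self, rng):
        stack = make_stack(n=5)
        for _ in range(50):
            out = slice_interpolate(stack, 2, rng)
            assert set(np.unique(out.label_slices)) <= set(np.unique(stack.label_slices))


class TestNoise:
    def test_moments_of_seeded_draw(self):
        stack = SliceStack(slices=np.zeros((1, 128, 128)),
                           label_slices=np.zeros((1, 128, 128), dtype=np.int64))
        out = gaussian_noise(stack, 5.0, np.random.default_rng(7))
        diff = out.slices - stack.slices
        assert abs(diff.std() - 5.0) < 0.2
        assert abs(diff.mean()) < 3 * 5.0 / np.sqrt(diff.size)

    def test_negative_sigma_rejected(self, rng):
        with pytest.raises(ValueError):
            gaussian_noise(make_stack(), -1.0, rng)


class TestRotate:
    def test_label_set_never_grows(self, rng):
        stack = make_stack()
        for _ in range(20):
            out = random_rotate(stack, 16.0, rng)
            assert set(np.unique(out.label_slices)) <= {0, 1, 2}

    def test_centered_disk_area_preserved(self):
        side = 64
        yy, xx = np.ogrid[:side, :side]
        disk = ((yy - 31.5) ** 2 + (xx - 31.5) ** 2 <= 20**2)
        labels = disk.astype(np.int64)[None]
        stack = SliceStack(slices=labels.astype(float) * 100.0, label_slices=labels)
        area = disk.sum()
        out = random_rotate(stack, 16.0, np.random.default_rng(3))
        assert abs(out.label_slices.sum() - area) < 0.02 * area

    def test_angle_shared_across_slices(self):
        base = np.zeros((16, 16))
        base[2:6, 2:6] = 1.0
        stack = SliceStack(slices=np.stack([base, base]),
                           label_slices=np.zeros((2, 16, 16), dtype=np.int64))
        out = random_rotate(stack, 16.0, np.random.default_rng(5))
        assert np.array_equal(out.slices[0], out.slices[1])


class TestPatch:
    def test_crop_of_coordinate_ramp_matches_index_oracle(self):
        side = 16
        ramp = (np.arange(side)[:, None] * side + np.arange(side)[None, :]).astype(float)
        stack = SliceStack(slices=np.stack([ramp] * 3),
                           label_slices=np.zeros((3, side, side), dtype=np.int64))
        rng = np.random.default_rng(9)
        out = random_patch(stack, 8, rng)
        r0 = int(out.slices[0, 0, 0] // side)
        c0 = int(out.slices[0, 0, 0] % side)
        assert np.array_equal(out.slices[0], ramp[r0:r0 + 8, c0:c0 + 8])

    def test_image_and_label_share_offset(self, rng):
        stack = make_stack()
        marker = np.zeros_like(stack.label_slices)
        marker[:, ::2, ::3] = 1
        stack.label_slices = marker
        stack.slices = marker.astype(float)
        out = random_patch(stack, 8, rng)
        assert np.array_equal(out.slices, out.label_slices.astype(float))

    def test_oversized_patch_rejected(self, rng):
        with pytest.raises(ValueError):
            random_patch(make_stack(side=16), 32, rng)


class TestBatchPolicy:
    def test_p_zero_returns_untouched(self, rng):
        batch = [make_stack(seed=i) for i in range(3)]
        out = augment_batch(batch, AugmentPolicy.disabled(), rng)
        for a, b in zip(batch, out):
            assert np.array_equal(a.slices, b.slices)

    def test_all_identity_parameters_give_voxel_identical_batch(self, rng):
        policy = AugmentPolicy(
            p_augment=1.0, p_cwvrs=1.0, max_rotation_deg=0.0, noise_sigma=0.0,
            skip_max_removed=0, interp_max_inserted=0, patch_size=None,
            cwvrs_max_shift=0.0, cwvrs_max_scale_delta=0.0,
        )
        batch = [make_stack(seed=i) for i in range(3)]
        out = augment_batch(batch, policy, rng)
        for a, b in zip(batch, out):
            assert np.array_equal(a.slices, b.slices)
            assert np.array_equal(a.label_slices, b.label_slices)

    def test_gating_frequency_close_to_policy(self):
        # 2000-trial check here; the 10k version runs in the acceptance suite
        policy = AugmentPolicy(p_augment=0.9, noise_sigma=1.0, max_rotation_deg=0.0,
                               skip_max_removed=0, interp_max_inserted=0, p_cwvrs=0.0)
        rng = np.random.default_rng(0)
        tiny = SliceStack(slices=np.zeros((1, 2, 2)),
                          label_slices=np.zeros((1, 2, 2), dtype=np.int64))
        hits = sum(
            not np.array_equal(augment_batch([tiny], policy, rng)[0].slices, tiny.slices)
            for _ in range(2000)
        )
        assert hits / 2000 == pytest.approx(0.9, abs=0.025)

    def test_dims_defaults_follow_protocol(self):
        assert AugmentPolicy.for_dims(2).p_augment == 0.9
        assert AugmentPolicy.for_dims(3).p_augment == 0.8
        assert AugmentPolicy.for_dims(2).p_cwvrs == 0.2
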