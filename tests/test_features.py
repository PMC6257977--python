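import numpy as np
import pytest

import pairscreen as ps
from pairscreen.features import downscale_mean


class TestBuildSchedule:
    @pytest.mark.parametrize(
        "b0,b,expected",
        [
            (16, 0.5, (16, 8, 4, 2)),
            (16, 0.125, (16, 2)),
            (128, 0.125, (128, 16, 2)),
            (2, 0.5, (2,)),
            (10, 0.5, (10, 5, 2)),  # fractional 2.5 floored
        ],
    )
    def test_bin_hierarchies(self, b0, b, expected):
        sched = ps.build_schedule(b0, 0.5, b)
        assert sched.bins_per_level == expected
        assert sched.n_features == sum(expected)

    def test_last_level_at_least_two(self):
        for b0 in (2, 3, 16, 100, 128):
            for b in (0.125, 0.25, 0.5):
                bins = ps.build_schedule(b0, 0.5, b).bins_per_level
                assert bins[-1] >= 2
                assert bins[-1] * b < 2  # the next level would be invalid

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            ps.build_schedule(1, 0.5, 0.5)


class TestDownscale:
    def test_integer_factor_is_block_mean(self):
        rng = np.random.default_rng(0)
        img = rng.random((8, 12))
        out = downscale_mean(img, 0.5)
        expected = img.reshape(4, 2, 6, 2).mean(axis=(1, 3))
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_mass_preserving(self):
        rng = np.random.default_rng(1)
        img = rng.random((9, 7))
        out = downscale_mean(img, 1 / 3)
        assert out.shape == (3, 2)
        # area-weighted averaging preserves the overall mean over covered area
        assert out.min() >= img.min() - 1e-12 and out.max() <= img.max() + 1e-12


class TestFrameFeatures:
    def test_toy_frame_matches_hand_counted_histograms(self):
        """4×4 frame, b0=4, b=1/2, r=1/2, all-pixels mode, hand enumeration.

        Level 1 (4 bins over [0,255]): values {0×3, 50×3, 100×3, 150×3,
        200×2, 250×2} → counts [6, 3, 3, 4].  Level 2: 2×2 block means
        [125, 75, 75, 175] → 2-bin counts [3, 1].
        """
        frame = np.array(
            [
                [0, 50, 100, 150],
                [200, 250, 0, 50],
                [100, 150, 200, 250],
                [0, 50, 100, 150],
            ],
            dtype=np.uint8,
        )
        sched = ps.build_schedule(4, 0.5, 0.5)
        vec = ps.frame_features(frame, sched, mask_mode="all_pixels")
        np.testing.assert_array_equal(vec, [6, 3, 3, 4, 3, 1])

    def test_constant_foreground_is_delta_histogram(self, background_model):
        frame = np.full((8, 8), 200, dtype=np.uint8)
        sched = ps.build_schedule(2, 0.5, 0.125)  # single level, 2 bins
        vec = ps.frame_features(
            frame, sched, mask_mode="foreground_normalized", model=background_model
        )
        np.testing.assert_array_equal(vec, [0.0, 1.0])

    def test_all_background_frame_warns_and_zeroes(self, background_model):
        frame = np.full((8, 8), 100, dtype=np.uint8)
        sched = ps.build_schedule(4, 0.5, 0.5)
        with pytest.warns(RuntimeWarning, match="empty foreground"):
            vec = ps.frame_features(
                frame, sched, mask_mode="foreground_normalized", model=background_model
            )
        np.testing.assert_array_equal(vec, np.zeros(sched.n_features))

    def test_normalized_blocks_sum_to_one(self, control_plate, background_model):
        sched = ps.build_schedule(16, 0.5, 0.5)
        frame = control_plate.datastore["c00"][2]
        vec = ps.frame_features(
            frame, sched, mask_mode="foreground_normalized", model=background_model
        )
        offset = 0
        for nbins in sched.bins_per_level:
            assert vec[offset : offset + nbins].sum() == pytest.approx(1.0, abs=1e-9)
            offset += nbins

    def test_all_pixels_mode_conserves_mass(self, control_plate):
        sched = ps.build_schedule(16, 0.5, 0.5)
        frame = control_plate.datastore["c00"][0]
        vec = ps.frame_features(frame, sched, mask_mode="all_pixels")
        assert vec[:16].sum() == frame.size

    def test_normalized_features_invariant_to_blob_duplication(self, background_model):
        """Doubling the foreground at fixed texture leaves normalized
        histograms unchanged (confluence independence)."""
        texture = np.arange(120, 250, 10, dtype=np.uint8).reshape(1, 13)
        one = np.full((16, 32), 100, dtype=np.uint8)
        one[2:3, 2:15] = texture
        two = one.copy()
        two[10:11, 10:23] = texture
        sched = ps.build_schedule(16, 1.0, 0.5)  # full resolution levels only
        v1 = ps.frame_features(one, sched, "foreground_normalized", background_model)
        v2 = ps.frame_features(two, sched, "foreground_normalized", background_model)
        np.testing.assert_allclose(v1, v2, atol=1e-12)

    def test_float_frames_need_explicit_range(self):
        with pytest.raises(ValueError, match="value_range"):
            ps.frame_features(np.zeros((4, 4)), ps.build_schedule(4), "all_pixels")


class TestExtractTEM:
    def test_column_count_matches_post_treatment_frames(self, control_plate, background_model, small_spec):
        sched = ps.build_schedule(16, 0.5, 0.5)
        movie = control_plate.datastore["c01"]
        tem = ps.extract_tem(
            movie, sched, model=background_model,
            frame_range=(small_spec.n_untreated, small_spec.n_frames), well="c01",
        )
        assert tem.values.shape == (30, small_spec.n_frames - small_spec.n_untreated)
        assert tem.values.shape[0] == 16 + 8 + 4 + 2

    def test_worker_count_invariance(self, control_plate, background_model):
        sched = ps.build_schedule(16, 0.5, 0.5)
        store = {w: control_plate.datastore[w] for w in list(control_plate.datastore)[:6]}
        ref = ps.extract_plate_tem(store, sched, model=background_model, frame_range=(2, 6))
        for workers in (2, 4):
            alt = ps.extract_plate_tem(
                store, sched, model=background_model, frame_range=(2, 6), workers=workers
            )
            for w in store:
                np.testing.assert_array_equal(ref[w].values, alt[w].values)

    def test_missing_frames_reported_by_well_and_time(self, control_plate, background_model):
        store = {w: list(control_plate.datastore[w]) for w in list(control_plate.datastore)[:3]}
        short = sorted(store)[1]
        store[short] = store[short][:4]
        with pytest.raises(ValueError) as err:
            ps.extract_plate_tem(
                store, ps.build_schedule(16, 0.5, 0.5),
                model=background_model, frame_range=(0, 6),
            )
        assert short in str(err.value) and "5" in str(err.value)

    def test_window_slices_columns(self, control_plate, background_model):
        sched = ps.build_schedule(16, 0.5, 0.5)
        tem = ps.extract_tem(
            control_plate.datastore["c02"], sched, model=background_model,
            frame_range=(2, 6), well="c02",
        )
        sub = tem.window(2)
        np.testing.assert_array_equal(sub.values, tem.values[:, 2:])
        assert sub.times == tem.times[2:]
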