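import numpy as np
import pytest
from oracles import dense_convolve, gaussian_kernel_formula

from gazesal import saliency as sal
from gazesal.kernels import gaussian_kernel2d, log_kernel
from gazesal.patches import PatchSequence


def uniform_patch(value=0.5, side=16):
    return np.full((side, side, 3), value)


def blob_patch(side=16, cx=None, cy=None, sigma=2.0, amp=0.5, background=0.2):
    cx = side // 2 if cx is None else cx
    cy = side // 2 if cy is None else cy
    yy, xx = np.mgrid[:side, :side]
    g = amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
    return np.clip(background + g[:, :, None] * np.ones(3), 0, 1)


def make_seq(frames, valid=None):
    frames = np.asarray(frames, dtype=np.float32)
    T = frames.shape[0]
    return PatchSequence(
        patches=frames,
        valid=np.ones(T, bool) if valid is None else np.asarray(valid, bool),
        clip_id="c",
        participant_id="p",
    )


class TestDecomposeChannels:
    def test_uniform_patch_flat_channels(self):
        maps = sal.decompose_channels(uniform_patch())
        np.testing.assert_allclose(maps.orientation, 0.0, atol=1e-9)
        np.testing.assert_allclose(maps.texture, 0.0, atol=1e-9)
        assert np.ptp(maps.red_green) < 1e-12  # constant
        assert np.ptp(maps.yellow_blue) < 1e-12

    def test_static_pair_zero_flow(self):
        p = blob_patch()
        maps = sal.decompose_channels(p, p)
        np.testing.assert_allclose(maps.flow_mag, 0.0, atol=1e-9)

    def test_first_frame_zero_flow(self):
        maps = sal.decompose_channels(blob_patch(), None)
        assert np.all(maps.flow_mag == 0.0)

    def test_moving_blob_flow_about_one(self):
        prev = blob_patch(side=32, cx=15, cy=16, sigma=2.5)
        curr = blob_patch(side=32, cx=16, cy=16, sigma=2.5)
        maps = sal.decompose_channels(curr, prev)
        blob = prev[:, :, 0] > 0.3
        assert np.mean(maps.flow_mag[blob]) == pytest.approx(1.0, abs=0.4)

    def test_luminance_is_lm_sum(self):
        patch = uniform_patch(1.0)
        maps = sal.decompose_channels(patch)
        expected = sal.RGB_TO_LMS[0].sum() + sal.RGB_TO_LMS[1].sum()
        np.testing.assert_allclose(maps.luminance, expected, rtol=1e-10)

    def test_opponent_channels_sign(self):
        red = np.zeros((8, 8, 3))
        red[:, :, 0] = 1.0
        cfg = sal.SaliencyConfig(linearize_rgb=False)
        maps = sal.decompose_channels(red, config=cfg)
        assert np.all(maps.red_green > 0)  # L > M for pure red
        blue = np.zeros((8, 8, 3))
        blue[:, :, 2] = 1.0
        maps_b = sal.decompose_channels(blue, config=cfg)
        assert np.all(maps_b.yellow_blue < 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sal.decompose_channels(uniform_patch(side=16), uniform_patch(side=12))

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError):
            sal.decompose_channels(np.zeros((8, 8)))


class TestBuildPyramid:
    def test_75px_level_sizes(self):
        pyr = sal.build_pyramid(np.zeros((75, 75)))
        assert [p.shape[0] for p in pyr] == [75, 38, 19, 10]

    def test_four_levels(self):
        assert len(sal.build_pyramid(np.zeros((16, 16)))) == 4

    def test_constant_preserved(self):
        pyr = sal.build_pyramid(np.full((16, 16), 0.7))
        for level in pyr:
            np.testing.assert_allclose(level, 0.7, rtol=1e-12)

    def test_impulse_matches_dense_oracle(self, rng):
        # level 1 equals blur-then-decimate computed by dense convolution
        img = np.zeros((16, 16))
        img[7, 8] = 1.0
        pyr = sal.build_pyramid(img, blur_sigma=1.0)
        want = dense_convolve(img, gaussian_kernel_formula(1.0))[::2, ::2]
        np.testing.assert_allclose(pyr[1], want, rtol=1e-8, atol=1e-14)

    def test_random_map_levels_match_oracle(self, rng):
        img = rng.random((12, 12))
        pyr = sal.build_pyramid(img, blur_sigma=1.0)
        cur = img
        for level in pyr[1:]:
            cur = dense_convolve(cur, gaussian_kernel_formula(1.0))[::2, ::2]
            np.testing.assert_allclose(level, cur, rtol=1e-8, atol=1e-14)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            sal.build_pyramid(np.zeros((6, 6)))


class TestCenterSurround:
    def test_constant_map_zeroed(self):
        out = sal.center_surround_activate([np.full((12, 12), 2.5)])
        np.testing.assert_allclose(out[0], 0.0, atol=1e-9)

    def test_five_passes_match_dense_oracle(self, rng):
        cfg = sal.DEFAULT_CONFIG
        img = rng.random((14, 14))
        want = img
        lk = log_kernel(cfg.activation_log_sigma)
        gk = gaussian_kernel_formula(cfg.activation_blur_sigma)
        for _ in range(cfg.activation_passes):
            want = np.maximum(dense_convolve(want, lk), 0.0)
            want = dense_convolve(want, gk)
        got = sal.center_surround_activate([img], cfg)[0]
        np.testing.assert_allclose(got, want, rtol=1e-8, atol=1e-14)

    def test_blob_peak_at_center(self):
        img = blob_patch(side=16, sigma=1.5, amp=1.0, background=0.0)[:, :, 0]
        out = sal.center_surround_activate([img])[0]
        peak = np.unravel_index(np.argmax(out), out.shape)
        assert abs(peak[0] - 8) <= 1 and abs(peak[1] - 8) <= 1


def activated_stacks(patch, prev=None, config=sal.DEFAULT_CONFIG):
    maps = sal.decompose_channels(patch, prev, config)
    return {
        name: sal.center_surround_activate(
            sal.build_pyramid(m, config.pyramid_levels, config.pyramid_blur_sigma), config
        )
        for name, m in maps.as_dict().items()
    }


class TestNormalize:
    def test_equal_channels_equal_factors(self, rng):
        m = rng.random((12, 12))
        stack = sal.center_surround_activate(sal.build_pyramid(m))
        stacks = {name: [lv.copy() for lv in stack] for name in sal.CHANNELS}
        buf = sal.TemporalBuffer()
        _, factors, raw, _ = sal.normalize_stacks(stacks, buf)
        assert np.ptp(factors) < 1e-12
        np.testing.assert_allclose(factors, raw)  # empty buffer: blended == raw

    def test_identical_frames_fixed_point(self):
        patch = blob_patch()
        buf = sal.TemporalBuffer()
        f1 = sal.process_frame(patch, None, buf)
        f2 = sal.process_frame(patch, patch, buf)
        f3 = sal.process_frame(patch, patch, buf)
        np.testing.assert_allclose(f2.norm_factors, f1.norm_factors, rtol=1e-10)
        np.testing.assert_allclose(f3.norm_factors, f1.norm_factors, rtol=1e-10)

    def test_doubling_doubles_raw_factor(self, rng):
        m = rng.random((12, 12)) + 0.1
        stack = [m, m / 2]
        doubled = [2 * lv for lv in stack]
        f1 = sal._raw_factor(stack, 0.9)
        f2 = sal._raw_factor(doubled, 0.9)
        assert f2 == pytest.approx(2 * f1, rel=1e-12)

    def test_zero_channel_flagged_and_untouched(self):
        stacks = activated_stacks(uniform_patch())
        buf = sal.TemporalBuffer()
        scaled, factors, _, zero_channels = sal.normalize_stacks(stacks, buf)
        assert "flow_mag" in zero_channels
        idx = sal.CHANNELS.index("flow_mag")
        assert factors[idx] == 0.0
        np.testing.assert_array_equal(scaled["flow_mag"][0], stacks["flow_mag"][0])


class TestFuse:
    def test_all_zero_stacks_constant_logistic_floor(self):
        cfg = sal.DEFAULT_CONFIG
        stacks = {name: [np.zeros((12, 12)), np.zeros((6, 6))] for name in sal.CHANNELS}
        final, current = sal.fuse_saliency(stacks, sal.TemporalBuffer(), cfg)
        expected = 1.0 / (1.0 + np.exp(cfg.logistic_gain * cfg.logistic_midpoint))
        np.testing.assert_allclose(final, expected, rtol=1e-12)
        np.testing.assert_allclose(current, 0.0)

    def test_output_in_unit_interval(self, rng):
        stacks = {
            name: [rng.normal(size=(12, 12)) * 10, rng.normal(size=(6, 6)) * 10]
            for name in sal.CHANNELS
        }
        final, _ = sal.fuse_saliency(stacks, sal.TemporalBuffer())
        assert np.all((final >= 0) & (final <= 1))

    def test_static_sequence_reaches_fixed_point(self):
        # with per-frame maps stored in the buffer, frame 3 of a static
        # sequence reproduces frame 1 exactly (weights sum to one)
        patch = blob_patch()
        buf = sal.TemporalBuffer()
        f1 = sal.process_frame(patch, None, buf)
        f2 = sal.process_frame(patch, patch, buf)
        f3 = sal.process_frame(patch, patch, buf)
        np.testing.assert_allclose(f3.final_map, f1.final_map, rtol=1e-10)
        np.testing.assert_allclose(f2.final_map, f1.final_map, rtol=1e-10)

    def test_transient_event_decays_by_half(self):
        # factor contribution of a single bright event halves per frame
        # and leaves the buffer after two frames
        zero = np.zeros((16, 16, 3))
        event = blob_patch(amp=0.8)
        buf = sal.TemporalBuffer()
        sal.process_frame(zero, None, buf)
        f_event = sal.process_frame(event, zero, buf)
        f_after1 = sal.process_frame(zero, event, buf)
        f_after2 = sal.process_frame(zero, zero, buf)
        f_after3 = sal.process_frame(zero, zero, buf)
        idx = sal.CHANNELS.index("luminance")
        e = f_event.norm_factors[idx]
        assert f_after1.norm_factors[idx] <= 0.5 * e + 1e-12
        assert f_after2.norm_factors[idx] <= 0.5 * f_after1.norm_factors[idx] + 1e-12
        assert f_after3.norm_factors[idx] == 0.0


class TestSaliencyIndex:
    def test_constant_map(self):
        assert sal.saliency_index(np.full((10, 10), 0.37)) == pytest.approx(0.37)

    def test_half_zeros_half_ones(self):
        m = np.zeros((10, 10))
        m[5:] = 1.0
        assert sal.saliency_index(m) == pytest.approx(0.5)

    def test_region_matches_hand_sum(self):
        m = np.array([[0.1, 0.2, 0.3], [0.4, 0.5, 0.6], [0.7, 0.8, 0.9]])
        # hand-summed oracle: (0.1+...+0.9)/9 = 4.5/9
        assert sal.saliency_index(m, np.ones((3, 3), bool)) == pytest.approx(4.5 / 9)
        # 2x2 sub-region rows 1:3 x cols 1:3: (0.5+0.6+0.8+0.9)/4
        assert sal.saliency_index(m, (slice(1, 3), slice(1, 3))) == pytest.approx(2.8 / 4)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sal.saliency_index(np.ones((4, 4)), np.zeros((4, 4), bool))


class TestRunSequence:
    def test_feature_vector_length(self, rng):
        frames = rng.random((20, 16, 16, 3))
        feats = sal.run_saliency_sequence(make_seq(frames))
        vec = sal.features_to_vector(feats)
        assert vec.shape == (20 * 6,)
        assert sal.features_to_matrix(feats).shape == (20, 6)

    def test_all_invalid_zero_features(self):
        frames = np.zeros((5, 16, 16, 3))
        feats = sal.run_saliency_sequence(make_seq(frames, valid=[False] * 5))
        for f in feats:
            np.testing.assert_array_equal(f.norm_factors, 0.0)
            assert len(f.zero_channels) == 6

    def test_deterministic_rerun(self, rng):
        frames = rng.random((6, 16, 16, 3))
        a = sal.run_saliency_sequence(make_seq(frames))
        b = sal.run_saliency_sequence(make_seq(frames))
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.norm_factors, fb.norm_factors)
            np.testing.assert_array_equal(fa.final_map, fb.final_map)

    def test_outputs_finite_and_bounded(self, rng):
        frames = rng.random((8, 16, 16, 3))
        feats = sal.run_saliency_sequence(make_seq(frames, valid=[True, False] * 4))
        for f in feats:
            assert np.all(np.isfinite(f.norm_factors))
            assert np.all((f.final_map >= 0) & (f.final_map <= 1))
            assert 0.0 <= f.saliency_index <= 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            sal.run_saliency_sequence(make_seq(np.zeros((0, 16, 16, 3))))

    def test_moving_blob_more_salient_than_static_uniform(self):
        T, side = 8, 16
        moving = np.stack(
            [blob_patch(side=side, cx=4 + t, cy=8, amp=0.7) for t in range(T)]
        )
        static = np.stack([uniform_patch(0.5, side)] * T)
        idx_moving = np.mean(
            [f.saliency_index for f in sal.run_saliency_sequence(make_seq(moving))]
        )
        idx_static = np.mean(
            [f.saliency_index for f in sal.run_saliency_sequence(make_seq(static))]
        )
        assert idx_moving > idx_static

    def test_batched_path_matches_public_ops(self, rng):
        # process_frame's channel-batched pyramid/activation equals the
        # composition of the public per-channel operations
        patch = rng.random((16, 16, 3))
        prev = rng.random((16, 16, 3))
        maps = sal.decompose_channels(patch, prev)
        fast = sal._batched_stacks(maps, sal.DEFAULT_CONFIG)
        slow = activated_stacks(patch, prev)
        for name in sal.CHANNELS:
            for a, b in zip(fast[name], slow[name]):
                np.testing.assert_allclose(a, b, rtol=1e-10, atol=1e-13)
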