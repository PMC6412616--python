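"""Blush pipeline stages against brute-force oracles and invariants."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qube import (BlushOptions, ContentError, FrameSequence, KernelSpec,
                  RoiPolygon, RoiTrack, compute_blush_curve,
                  estimate_panning_offsets, frame_blush_value, invert_contrast,
                  median_filter_background, qube_score, subtract_background)
from qube.angio_io import BlushCurve, rasterize_roi


def _seq(frames, rate=12.5):
    return FrameSequence(frames=np.asarray(frames, dtype=np.float64),
                         frame_rate_hz=rate)


# ---------------------------------------------------------------------------
# invert_contrast
# ---------------------------------------------------------------------------

class TestInvert:
    def test_constant_sequence_maps_to_zero(self):
        out = invert_contrast(_seq(np.full((3, 8, 8), 7.0)))
        assert np.all(out.frames == 0)

    def test_involution_up_to_global_max(self, rng):
        """Double inversion restores the frames up to the shared offset:
        exactly when the sequence minimum is 0, else shifted by it."""
        frames = rng.random((4, 10, 10)) * 100
        frames[2, 3, 3] = 0.0  # pin the minimum so involution is exact
        seq = _seq(frames)
        twice = invert_contrast(invert_contrast(seq))
        np.testing.assert_allclose(twice.frames, seq.frames)
        lifted = _seq(frames + 10)
        np.testing.assert_allclose(
            invert_contrast(invert_contrast(lifted)).frames, frames)

    def test_elementwise_definition(self, rng):
        frames = rng.random((3, 6, 6)) * 100
        frames[0, 0, 0], frames[1, 2, 3] = 0.0, 100.0
        out = invert_contrast(_seq(frames))
        np.testing.assert_allclose(out.frames, 100.0 - frames)
        assert out.frames[0, 0, 0] == 100.0  # darkest pixel -> max density


# ---------------------------------------------------------------------------
# median_filter_background
# ---------------------------------------------------------------------------

def brute_force_median(frame, k):
    """Window-by-window oracle: edge-replicated pad, explicit sort, order
    statistic at rank side^2 // 2, window centered at floor(side/2)."""
    lo = k // 2
    padded = np.pad(frame, ((lo, k - 1 - lo), (lo, k - 1 - lo)), mode="edge")
    out = np.empty_like(np.asarray(frame, dtype=float))
    for r in range(frame.shape[0]):
        for c in range(frame.shape[1]):
            win = np.sort(padded[r:r + k, c:c + k], axis=None)
            out[r, c] = win[k * k // 2]
    return out


class TestMedianFilter:
    @pytest.mark.parametrize("kernel", [3, 5, 20])
    @pytest.mark.parametrize("integer_valued", [False, True])
    def test_matches_window_oracle(self, rng, kernel, integer_valued):
        frame = rng.random((32, 32)) * 200
        if integer_valued:
            frame = np.floor(frame)  # exercises the histogram fast path
        out = median_filter_background(frame, KernelSpec(kernel))
        np.testing.assert_array_equal(out, brute_force_median(frame, kernel))

    def test_constant_frame_unchanged(self):
        out = median_filter_background(np.full((20, 20), 3.5), KernelSpec(7))
        assert np.all(out == 3.5)

    def test_single_bright_pixel_removed(self):
        frame = np.zeros((9, 9))
        frame[4, 4] = 100.0
        assert np.all(median_filter_background(frame, KernelSpec(3)) == 0)

    def test_monotone_ramp_fixed_in_interior(self):
        frame = np.tile(np.arange(12.0), (12, 1))
        out = median_filter_background(frame, KernelSpec(3))
        np.testing.assert_array_equal(out[1:-1, 1:-1], frame[1:-1, 1:-1])

    def test_output_within_input_range(self, rng):
        frame = rng.normal(50, 30, (25, 25)).clip(0)
        for k in (4, 9):
            out = median_filter_background(frame, KernelSpec(k))
            assert out.min() >= frame.min() and out.max() <= frame.max()

    def test_kernel_larger_than_frame_rejected(self):
        with pytest.raises(ContentError):
            median_filter_background(np.zeros((10, 10)), KernelSpec(11))

    def test_kernel_side_below_three_rejected(self):
        with pytest.raises(ContentError):
            KernelSpec(2)


# ---------------------------------------------------------------------------
# subtract_background
# ---------------------------------------------------------------------------

class TestSubtract:
    def test_identical_inputs_zero_residual(self, rng):
        f = rng.random((12, 12))
        assert np.all(subtract_background(f, f) == 0)

    def test_constant_offset_preserved(self, rng):
        b = rng.random((12, 12))
        np.testing.assert_allclose(subtract_background(b + 5, b), 5.0)

    def test_negative_residual_clipped(self):
        out = subtract_background(np.zeros((4, 4)), np.ones((4, 4)))
        assert np.all(out == 0)

    def test_dim_mismatch_rejected(self):
        with pytest.raises(ContentError):
            subtract_background(np.zeros((4, 4)), np.zeros((5, 4)))

    def test_kernel_must_exceed_blob_scale(self):
        """The large-structure-removal mechanism: a median kernel smaller
        than the blush scale swallows the blush into the background."""
        rr, cc = np.meshgrid(np.arange(128), np.arange(128), indexing="ij")
        sigma = 8.0
        blob = 100 * np.exp(-((rr - 64) ** 2 + (cc - 64) ** 2) / (2 * sigma ** 2))
        frame = 50 + blob
        peaks = {}
        for k in (9, 35):
            res = subtract_background(frame,
                                      median_filter_background(frame, KernelSpec(k)))
            peaks[k] = res.max() / 100
        assert peaks[35] >= 0.75      # large kernel preserves the blob
        assert peaks[9] <= 0.5        # small kernel swallows most of it
        assert peaks[9] < peaks[35]

    def test_residual_amplitude_nondecreasing_in_kernel(self):
        rr, cc = np.meshgrid(np.arange(128), np.arange(128), indexing="ij")
        sigma = 8.0
        frame = 50 + 100 * np.exp(-((rr - 64) ** 2 + (cc - 64) ** 2) / (2 * sigma ** 2))
        amps = [subtract_background(
            frame, median_filter_background(frame, KernelSpec(k))).max()
            for k in (8, 16, 32)]  # kernel = sigma, 2 sigma, 4 sigma
        assert amps[0] <= amps[1] <= amps[2]


# ---------------------------------------------------------------------------
# frame_blush_value
# ---------------------------------------------------------------------------

def _opts(**kw):
    base = dict(smoothing_side_px=1, panning_correction=False)
    base.update(kw)
    return BlushOptions(**base)


class TestFrameBlushValue:
    def test_constant_residual_returns_constant(self):
        mask = np.ones((10, 10), dtype=bool)
        assert frame_blush_value(np.full((10, 10), 4.2), mask, _opts()) == pytest.approx(4.2)

    def test_top_k_rule_worked_examples(self):
        residual = np.zeros((10, 10))
        residual.flat[:5] = 10.0      # 5 bright px in a 100 px mask
        mask = np.ones((10, 10), dtype=bool)
        v1 = frame_blush_value(residual, mask,
                               _opts(top_fraction=0.05, min_top_pixels=5))
        assert v1 == pytest.approx(10.0)   # k = 5 -> the five 10s
        v2 = frame_blush_value(residual, mask,
                               _opts(top_fraction=0.10, min_top_pixels=5))
        assert v2 == pytest.approx(5.0)    # k = 10 -> five 10s + five 0s

    def test_matches_sort_and_average_oracle(self, rng):
        residual = rng.random((20, 20)) * 30
        mask = rng.random((20, 20)) > 0.4
        opts = _opts(top_fraction=0.07, min_top_pixels=3)
        area = mask.sum()
        k = max(3, math.ceil(0.07 * area))
        expected = np.sort(residual[mask])[::-1][:k].mean()
        assert frame_blush_value(residual, mask, opts) == pytest.approx(expected)

    def test_smoothing_is_mean_filter(self, rng):
        import scipy.ndimage
        residual = rng.random((15, 15)) * 10
        mask = np.zeros((15, 15), dtype=bool)
        mask[7, 7] = True
        got = frame_blush_value(residual, mask, BlushOptions(
            smoothing_side_px=3, min_top_pixels=1, top_fraction=0.01,
            panning_correction=False))
        want = scipy.ndimage.uniform_filter(residual, 3, mode="nearest")[7, 7]
        assert got == pytest.approx(want)

    def test_empty_mask_rejected(self):
        with pytest.raises(ContentError):
            frame_blush_value(np.zeros((5, 5)), np.zeros((5, 5), dtype=bool))


# ---------------------------------------------------------------------------
# estimate_panning_offsets
# ---------------------------------------------------------------------------

def _structured_frame(rng, dims=(96, 96)):
    """Smooth random texture with content away from the borders."""
    import scipy.ndimage
    f = scipy.ndimage.gaussian_filter(rng.random(dims), 3)
    window = np.zeros(dims)
    window[20:-20, 20:-20] = 1.0
    return 100 * f * scipy.ndimage.gaussian_filter(window, 6)


class TestPanning:
    def test_identical_frames_zero_offsets(self):
        seq = _seq(np.tile(np.arange(40.0), (3, 40, 1)))
        assert estimate_panning_offsets(seq, radius_px=5) == [(0, 0)] * 3

    @pytest.mark.parametrize("shift", [(3, -2), (0, 7), (-6, -6), (10, 1)])
    def test_exact_integer_shift_recovered(self, rng, shift):
        ref = _structured_frame(rng)
        moved = np.roll(ref, shift, axis=(0, 1))
        seq = _seq(np.stack([ref, moved]))
        assert estimate_panning_offsets(seq, radius_px=12)[1] == shift

    def test_pure_noise_stays_in_search_box(self, rng):
        seq = _seq(rng.random((4, 48, 48)))
        for dr, dc in estimate_panning_offsets(seq, radius_px=6):
            assert abs(dr) <= 6 and abs(dc) <= 6

    def test_constant_frames_tie_break_to_origin(self):
        seq = _seq(np.full((3, 32, 32), 9.0))
        assert estimate_panning_offsets(seq, radius_px=4) == [(0, 0)] * 3

    def test_excessive_radius_rejected(self):
        seq = _seq(np.zeros((2, 30, 30)))
        with pytest.raises(ContentError):
            estimate_panning_offsets(seq, radius_px=15)


# ---------------------------------------------------------------------------
# qube_score
# ---------------------------------------------------------------------------

def brute_force_score(values):
    v = list(values)
    a = max((v[j] - v[i] for i in range(len(v)) for j in range(i + 1, len(v))),
            default=0.0)
    b = max((v[i] - v[j] for i in range(len(v)) for j in range(i + 1, len(v))),
            default=0.0)
    return max(a, 0.0), max(b, 0.0)


finite_curves = st.lists(
    st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=2,
    max_size=30)


class TestQubeScore:
    @pytest.mark.parametrize("values, expected", [
        ([5, 5, 5], (0, 0)),
        ([10, 15, 12, 8, 11], (5, 7)),
        ([0, 1, 2, 3], (3, 0)),
        ([3, 2, 1, 0], (0, 3)),
    ])
    def test_worked_examples(self, values, expected):
        res = qube_score(BlushCurve(values))
        assert (res.max_increase_a, res.max_decrease_b) == expected
        assert res.score == sum(expected)

    @settings(max_examples=60, derandomize=True)
    @given(values=finite_curves)
    def test_matches_all_pairs_oracle(self, values):
        res = qube_score(BlushCurve(values))
        a, b = brute_force_score(values)
        assert res.max_increase_a == pytest.approx(a, abs=1e-9)
        assert res.max_decrease_b == pytest.approx(b, abs=1e-9)
        assert res.score == pytest.approx(a + b, abs=1e-9)

    @settings(max_examples=40, derandomize=True)
    @given(values=finite_curves,
           shift=st.floats(-1e5, 1e5, allow_nan=False),
           scale=st.floats(0.01, 100, allow_nan=False))
    def test_shift_invariant_and_scale_linear(self, values, shift, scale):
        v = np.asarray(values)
        base = qube_score(BlushCurve(v))
        shifted = qube_score(BlushCurve(v + shift))
        assert shifted.score == pytest.approx(base.score, rel=1e-9, abs=1e-6)
        scaled = qube_score(BlushCurve(v * scale))
        assert scaled.score == pytest.approx(base.score * scale,
                                             rel=1e-9, abs=1e-6)

    @settings(max_examples=40, derandomize=True)
    @given(values=finite_curves)
    def test_reversal_swaps_a_and_b(self, values):
        fwd = qube_score(BlushCurve(values))
        rev = qube_score(BlushCurve(values[::-1]))
        assert rev.max_increase_a == pytest.approx(fwd.max_decrease_b, abs=1e-9)
        assert rev.max_decrease_b == pytest.approx(fwd.max_increase_a, abs=1e-9)
        assert rev.score == pytest.approx(fwd.score, abs=1e-9)

    def test_score_bounded_by_twice_range(self, rng):
        v = rng.random(25) * 40
        res = qube_score(BlushCurve(v))
        rng_v = v.max() - v.min()
        assert 0 <= res.max_increase_a <= rng_v
        assert 0 <= res.max_decrease_b <= rng_v
        assert res.score <= 2 * rng_v

    def test_single_point_rejected(self):
        with pytest.raises(ContentError):
            qube_score(BlushCurve([1.0]))


# ---------------------------------------------------------------------------
# compute_blush_curve
# ---------------------------------------------------------------------------

class TestComputeBlushCurve:
    def test_constant_sequence_gives_zero_curve(self):
        seq = _seq(np.full((4, 64, 64), 50.0))
        roi = RoiPolygon([[20, 20], [20, 44], [44, 44], [44, 20]])
        curve, offsets = compute_blush_curve(seq, roi,
                                             BlushOptions(kernel=KernelSpec(9)))
        assert np.all(curve.values == 0)
        assert offsets == [(0, 0)] * 4
        assert qube_score(curve).score == 0

    def test_track_equal_to_fixed_roi_matches(self, small_scene):
        seq, gt = small_scene
        roi = gt.roi_reference
        opts = BlushOptions(panning_correction=False)
        fixed, _ = compute_blush_curve(seq, roi, opts)
        track = RoiTrack([roi] * seq.n_frames)
        tracked, _ = compute_blush_curve(seq, track, opts)
        np.testing.assert_array_equal(fixed.values, tracked.values)

    def test_cropped_pipeline_equals_whole_frame_pipeline(self, small_scene):
        """The ROI-neighbourhood crop is an exact optimization, not an
        approximation: it must reproduce the stage-by-stage full-frame
        pipeline bit for bit."""
        seq, gt = small_scene
        opts = BlushOptions(panning_correction=False)
        curve, _ = compute_blush_curve(seq, gt.roi_reference, opts)
        inv = invert_contrast(seq)
        mask = rasterize_roi(gt.roi_reference, seq.dims)
        for i in range(0, seq.n_frames, 5):
            bg = median_filter_background(inv.frames[i], opts.kernel)
            residual = subtract_background(inv.frames[i], bg)
            assert curve.values[i] == pytest.approx(
                frame_blush_value(residual, mask, opts), abs=1e-9)

    def test_roi_outside_frame_names_frame(self, small_scene):
        seq, _ = small_scene
        roi = RoiPolygon([[200, 200], [200, 220], [220, 220], [220, 200]])
        with pytest.raises(ContentError, match="frame 0"):
            compute_blush_curve(seq, roi, BlushOptions(panning_correction=False))

    def test_track_length_mismatch_rejected(self, small_scene):
        seq, gt = small_scene
        track = RoiTrack([gt.roi_reference] * (seq.n_frames - 1))
        with pytest.raises(ContentError, match="track length"):
            compute_blush_curve(seq, track)
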