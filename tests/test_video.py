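"""Segmentation, stabilization, area/mobility extraction, onset detection."""

import numpy as np
import pytest

from larvaquant.video import (FrameStack, OnsetNotDetectedError,
                              SegmentationMask, detect_stimulus_onset,
                              extract_area, extract_mobility, segment_larva,
                              stabilize)


def _stack_from_masks(masks, fg=200, bg=10, dt=1 / 30):
    frames = np.where(masks, fg, bg).astype(np.uint8)
    return FrameStack(frames=frames, frame_interval=dt)


class TestSegmentation:
    def test_area_within_2pct_of_truth(self, quiet_larva):
        spec, stack, truth = quiet_larva
        mask = segment_larva(stack)
        area = mask.masks.reshape(len(stack), -1).sum(axis=1)
        assert np.all(np.abs(area - truth.true_area) / truth.true_area < 0.02)
        assert not mask.empty.any()

    def test_all_background_aborts(self):
        rng = np.random.default_rng(0)
        frames = rng.normal(20, 3, (10, 64, 64)).clip(0, 255).astype(np.uint8)
        stack = FrameStack(frames=frames, frame_interval=1 / 30)
        with pytest.raises(RuntimeError, match="empty foreground"):
            segment_larva(stack, threshold_method="fixed:100")

    def test_single_empty_frame_flagged(self):
        frames = np.full((10, 64, 64), 10, dtype=np.uint8)
        frames[:, 20:40, 20:36] = 200
        frames[4] = 10  # larva leaves the field of view for one frame
        stack = FrameStack(frames=frames, frame_interval=1 / 30)
        mask = segment_larva(stack, threshold_method="fixed:100")
        assert mask.empty[4] and not mask.empty[[0, 1, 2, 3, 5]].any()
        assert mask.valid[3] and not mask.valid[4]

    def test_speck_removed_single_component(self):
        # larva blob plus a 4-px speck; fixed threshold isolates the logic
        frames = np.full((3, 64, 64), 10, dtype=np.uint8)
        frames[:, 20:40, 20:36] = 200
        frames[:, 5:7, 5:7] = 200
        stack = FrameStack(frames=frames, frame_interval=1 / 30)
        mask = segment_larva(stack, threshold_method="fixed:100", min_blob_px=20)
        from scipy import ndimage as ndi

        for m in mask.masks:
            assert ndi.label(m)[1] == 1
            assert not m[5, 5]

    def test_morphology_log_records_recipe(self, quiet_larva):
        _, stack, _ = quiet_larva
        mask = segment_larva(stack)
        assert mask.morphology_log[0].startswith("threshold:huang")
        assert any("erode" in s for s in mask.morphology_log)
        assert any("dilate" in s for s in mask.morphology_log)


class TestStabilize:
    def test_stationary_is_identity(self, stationary_larva):
        _, stack, _ = stationary_larva
        mask = segment_larva(stack)
        out_stack, out_mask = stabilize(mask, stack)
        assert np.array_equal(out_stack.frames, stack.frames)
        assert np.array_equal(out_mask.masks, mask.masks)

    def test_translating_larva_centroid_constant(self):
        # rigid 2 px/frame rightward drift of a synthetic blob
        masks = np.zeros((10, 64, 96), dtype=bool)
        for i in range(10):
            masks[i, 20:36, 10 + 2 * i:30 + 2 * i] = True
        stack = _stack_from_masks(masks)
        seg = SegmentationMask(masks=masks, method_tag="fixed")
        _, stab = stabilize(seg, stack)
        cents = np.array([np.argwhere(m).mean(axis=0) for m in stab.masks])
        assert np.all(np.abs(cents - cents[0]) <= 1.0)

    def test_idempotent(self, contracting_larva):
        _, stack, _ = contracting_larva
        mask = segment_larva(stack)
        s1, m1 = stabilize(mask, stack)
        s2, m2 = stabilize(m1, s1)
        assert np.array_equal(s1.frames, s2.frames)
        assert np.array_equal(m1.masks, m2.masks)

    def test_area_translation_invariant(self, contracting_larva):
        _, stack, _ = contracting_larva
        mask = segment_larva(stack)
        _, stab = stabilize(mask, stack)
        a0 = extract_area(mask, stack.frame_interval)
        a1 = extract_area(stab, stack.frame_interval)
        assert np.array_equal(a0.area, a1.area)


class TestAreaTrace:
    def test_square_counts_pixels(self):
        masks = np.zeros((2, 128, 128), dtype=bool)
        masks[:, 10:110, 10:110] = True
        seg = SegmentationMask(masks=masks, method_tag="fixed")
        trace = extract_area(seg, 1 / 30)
        assert np.all(trace.area == 10000)

    def test_flagged_frame_carries_previous_value(self):
        masks = np.zeros((4, 32, 32), dtype=bool)
        masks[[0, 1, 3], 5:15, 5:15] = True
        seg = SegmentationMask(masks=masks, method_tag="fixed",
                               empty=np.array([False, False, True, False]))
        trace = extract_area(seg, 1 / 30)
        assert trace.area[2] == trace.area[1]
        assert not trace.valid[2] and trace.valid[1]

    def test_too_many_fills_abort(self):
        masks = np.zeros((10, 32, 32), dtype=bool)
        masks[0, 5:15, 5:15] = True
        empty = np.ones(10, dtype=bool)
        empty[0] = False
        seg = SegmentationMask(masks=masks, method_tag="fixed", empty=empty)
        with pytest.raises(RuntimeError, match="consecutive invalid"):
            extract_area(seg, 1 / 30)


class TestMobility:
    def test_identical_masks_zero(self):
        masks = np.zeros((5, 32, 32), dtype=bool)
        masks[:, 8:24, 8:24] = True
        seg = SegmentationMask(masks=masks, method_tag="fixed")
        mob = extract_mobility(seg, 1 / 30)
        assert np.all(mob.raw_mobility[1:] == 0)
        assert not mob.valid[0]

    def test_rigid_shift_scores_leading_edge(self):
        # 16x20 rectangle shifted 1 px rightward: 16 newly occupied pixels
        masks = np.zeros((4, 32, 48), dtype=bool)
        for i in range(4):
            masks[i, 8:24, 10 + i:30 + i] = True
        seg = SegmentationMask(masks=masks, method_tag="fixed")
        mob = extract_mobility(seg, 1 / 30)
        assert np.all(mob.raw_mobility[1:] == 16)

    def test_pure_shrink_scores_zero_one_sided(self):
        masks = np.zeros((3, 32, 32), dtype=bool)
        masks[0, 4:28, 4:28] = True
        masks[1, 8:24, 8:24] = True
        masks[2, 10:22, 10:22] = True
        seg = SegmentationMask(masks=masks, method_tag="fixed")
        mob = extract_mobility(seg, 1 / 30)
        assert np.all(mob.raw_mobility[1:] == 0)
        sym = extract_mobility(seg, 1 / 30, symmetric=True)
        assert np.all(sym.raw_mobility[1:] > 0)


class TestOnsetDetection:
    def _stack(self, step_frame=None, step=0.15, n=200, noise=2.0):
        rng = np.random.default_rng(1)
        frames = np.full((n, 32, 32), 100.0)
        if step_frame is not None:
            frames[step_frame:] *= 1 + step
        frames += rng.normal(0, noise, frames.shape)
        return FrameStack(frames=np.clip(frames, 0, 255).astype(np.uint8),
                          frame_interval=1 / 30)

    def test_brightness_step_found(self):
        onset = detect_stimulus_onset(self._stack(step_frame=120))
        assert abs(onset - 120) <= 1

    def test_constant_stack_raises(self):
        with pytest.raises(OnsetNotDetectedError):
            detect_stimulus_onset(self._stack(step_frame=None))

    def test_subthreshold_step_not_detected(self):
        # mean-brightness jump of ~0.5 pre-onset SD stays undetected at 3 SD
        stack = self._stack(step_frame=None, noise=2.0)
        sd = stack.frames.reshape(len(stack), -1).mean(axis=1)[:100].std()
        sub = stack.frames.astype(float)
        sub[120:] += 0.5 * sd
        stack2 = FrameStack(frames=np.clip(sub, 0, 255).astype(np.uint8),
                            frame_interval=1 / 30)
        with pytest.raises(OnsetNotDetectedError):
            detect_stimulus_onset(stack2, jump_sd=3.0)
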