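"""Behavior-video quantification: segmentation, stabilization, area, mobility.

The processing recipe mirrors the standard FIJI macro approach for dark-field
larval video: automatic threshold -> erode -> remove small outlier blobs ->
dilate -> keep the single largest connected component; translate every frame
so the body centroid sits at a fixed reference, then read out per-frame
silhouette area and frame-to-frame mobility (newly occupied pixels) from the
stabilized mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

from ._thresholds import resolve_threshold

__all__ = [
    "FrameStack",
    "SegmentationMask",
    "AreaTrace",
    "MobilityTrace",
    "OnsetNotDetectedError",
    "segment_larva",
    "stabilize",
    "extract_area",
    "extract_mobility",
    "detect_stimulus_onset",
]

MAX_CONSECUTIVE_FILLS = 5


def _remove_outliers(fg: np.ndarray, min_blob_px: int) -> np.ndarray:
    """Symmetric despeckle: drop small components, fill small enclosed holes."""
    lab, nlab = ndi.label(fg)
    if nlab:
        sizes = np.bincount(lab.ravel())[1:]
        fg = np.isin(lab, np.flatnonzero(sizes >= min_blob_px) + 1)
    holes = ndi.binary_fill_holes(fg) & ~fg
    hlab, hn = ndi.label(holes)
    if hn:
        hsizes = np.bincount(hlab.ravel())[1:]
        fg = fg | np.isin(hlab, np.flatnonzero(hsizes < min_blob_px) + 1)
    return fg


class OnsetNotDetectedError(RuntimeError):
    """Raised when no stimulus-onset brightness jump is found."""


@dataclass
class FrameStack:
    """An ordered grayscale recording with a fixed frame interval (seconds)."""

    frames: np.ndarray           # (n, H, W)
    frame_interval: float
    origin: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or len(self.frames) < 2:
            raise ValueError("FrameStack needs >= 2 same-shape 2-D frames")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.frames)) * self.frame_interval


@dataclass
class SegmentationMask:
    """Per-frame boolean foreground masks plus per-frame quality flags."""

    masks: np.ndarray            # (n, H, W) bool
    method_tag: str
    morphology_log: list[str] = field(default_factory=list)
    empty: np.ndarray = None     # frames where no foreground survived
    multi: np.ndarray = None     # frames where >1 component survived (largest kept)

    def __post_init__(self) -> None:
        n = len(self.masks)
        if self.empty is None:
            self.empty = np.zeros(n, dtype=bool)
        if self.multi is None:
            self.multi = np.zeros(n, dtype=bool)

    @property
    def valid(self) -> np.ndarray:
        return ~self.empty

    def __len__(self) -> int:
        return len(self.masks)


@dataclass
class AreaTrace:
    """Per-frame silhouette area in pixels^2; invalid frames are flag-filled."""

    t: np.ndarray
    area: np.ndarray
    valid: np.ndarray

    @property
    def frame_interval(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class MobilityTrace:
    """Per-frame count of newly occupied pixels; frame 0 is undefined."""

    t: np.ndarray
    raw_mobility: np.ndarray
    valid: np.ndarray

    @property
    def frame_interval(self) -> float:
        return float(self.t[1] - self.t[0])


def segment_larva(
    stack: FrameStack,
    threshold_method: str = "huang",
    min_blob_px: int = 20,
    selem_radius: int = 2,
    max_empty_fraction: float = 0.10,
) -> SegmentationMask:
    """Threshold and clean every frame, keeping one component per frame.

    Per frame: auto-threshold (``huang``, ``moments`` or ``fixed:<v>``) ->
    outlier removal -> binary erosion (disk of ``selem_radius``) -> outlier
    removal -> dilation with the same element. Outlier removal mirrors
    ImageJ's median-style "Remove Outliers", which is symmetric: bright
    outliers (foreground components smaller than ``min_blob_px``) are
    deleted and dark outliers (enclosed background holes smaller than
    ``min_blob_px``) are filled; running it before erosion keeps pepper
    noise from being blown up into large holes. If several components
    survive, the largest is kept and the frame flagged ``multi``; if none
    survives the frame is flagged ``empty``. More than
    ``max_empty_fraction`` empty frames aborts with a diagnostic.
    """
    selem = disk(selem_radius)
    n = len(stack)
    masks = np.zeros(stack.frames.shape, dtype=bool)
    empty = np.zeros(n, dtype=bool)
    multi = np.zeros(n, dtype=bool)

    for i, frame in enumerate(stack.frames):
        try:
            thr = resolve_threshold(frame, threshold_method)
        except ValueError:  # constant frame
            empty[i] = True
            continue
        fg = frame > thr
        fg = _remove_outliers(fg, min_blob_px)
        fg = ndi.binary_erosion(fg, structure=selem)
        fg = _remove_outliers(fg, min_blob_px)
        if not fg.any():
            empty[i] = True
            continue
        fg = ndi.binary_dilation(fg, structure=selem)
        lab, nlab = ndi.label(fg)
        if nlab > 1:
            multi[i] = True
            sizes = np.bincount(lab.ravel())[1:]
            fg = lab == (int(np.argmax(sizes)) + 1)
        masks[i] = fg

    if empty.mean() > max_empty_fraction:
        raise RuntimeError(
            f"segmentation failed: {int(empty.sum())}/{n} frames "
            f"({100 * empty.mean():.0f}%) have empty foreground "
            f"(threshold={threshold_method}, min_blob_px={min_blob_px})"
        )
    log = [f"threshold:{threshold_method}", f"erode:disk{selem_radius}",
           f"remove_outliers:specks+holes<{min_blob_px}px",
           f"dilate:disk{selem_radius}", "keep_largest"]
    return SegmentationMask(masks=masks, method_tag=threshold_method,
                            morphology_log=log, empty=empty, multi=multi)


def _centroid(mask: np.ndarray) -> np.ndarray:
    idx = np.argwhere(mask)
    return idx.mean(axis=0)


def _shift_int(arr: np.ndarray, dy: int, dx: int, fill=0) -> np.ndarray:
    out = np.full_like(arr, fill)
    h, w = arr.shape
    ys = slice(max(dy, 0), min(h, h + dy))
    xs = slice(max(dx, 0), min(w, w + dx))
    yo = slice(max(-dy, 0), min(h, h - dy))
    xo = slice(max(-dx, 0), min(w, w - dx))
    out[ys, xs] = arr[yo, xo]
    return out


def stabilize(
    mask: SegmentationMask, stack: FrameStack
) -> tuple[FrameStack, SegmentationMask]:
    """Translate each frame so the body centroid matches the first frame's.

    Offsets are integer-rounded pure shifts with zero fill; flagged (empty)
    frames reuse the previous frame's offset and keep their flags.
    """
    n = len(mask)
    first_valid = int(np.argmax(mask.valid))
    if not mask.valid.any():
        raise RuntimeError("cannot stabilize: no valid frames")
    ref = _centroid(mask.masks[first_valid])

    new_frames = np.empty_like(stack.frames)
    new_masks = np.zeros_like(mask.masks)
    offset = np.zeros(2, dtype=int)
    for i in range(n):
        if mask.valid[i]:
            c = _centroid(mask.masks[i])
            offset = np.rint(ref - c).astype(int)
        dy, dx = int(offset[0]), int(offset[1])
        new_frames[i] = _shift_int(stack.frames[i], dy, dx)
        new_masks[i] = _shift_int(mask.masks[i], dy, dx)

    out_stack = FrameStack(frames=new_frames, frame_interval=stack.frame_interval,
                           origin=stack.origin + " [stabilized]")
    out_mask = SegmentationMask(
        masks=new_masks, method_tag=mask.method_tag,
        morphology_log=mask.morphology_log + ["stabilize:translate"],
        empty=mask.empty.copy(), multi=mask.multi.copy())
    return out_stack, out_mask


def extract_area(mask: SegmentationMask, frame_interval: float) -> AreaTrace:
    """Foreground pixel count per frame; invalid frames carry the last value."""
    n = len(mask)
    area = mask.masks.reshape(n, -1).sum(axis=1).astype(float)
    valid = mask.valid.copy()
    run = 0
    last = None
    for i in range(n):
        if valid[i]:
            last = area[i]
            run = 0
        else:
            run += 1
            if run > MAX_CONSECUTIVE_FILLS:
                raise RuntimeError(
                    f"more than {MAX_CONSECUTIVE_FILLS} consecutive invalid frames "
                    f"at frame {i}; recording unscorable")
            if last is not None:
                area[i] = last
    # leading invalid frames take the first valid value (still flagged)
    if not valid[0] and valid.any():
        area[: int(np.argmax(valid))] = area[int(np.argmax(valid))]
    t = np.arange(n) * frame_interval
    return AreaTrace(t=t, area=area, valid=valid)


def extract_mobility(
    mask: SegmentationMask, frame_interval: float, symmetric: bool = False
) -> MobilityTrace:
    """Newly occupied pixels per frame on a stabilized mask stack.

    The default counts pixels foreground in frame N but not in N-1 (the
    one-sided set difference); ``symmetric=True`` counts the symmetric
    difference instead. Frame 0 is undefined and flagged invalid, as is any
    frame whose own or preceding mask is flagged.
    """
    n = len(mask)
    cur = mask.masks[1:]
    prev = mask.masks[:-1]
    if symmetric:
        diff = np.logical_xor(cur, prev)
    else:
        diff = cur & ~prev
    raw = np.concatenate([[0], diff.reshape(n - 1, -1).sum(axis=1)]).astype(float)
    valid = mask.valid.copy()
    valid[1:] &= mask.valid[:-1]
    valid[0] = False
    t = np.arange(n) * frame_interval
    return MobilityTrace(t=t, raw_mobility=raw, valid=valid)


def detect_stimulus_onset(
    stack: FrameStack,
    jump_sd: float = 3.0,
    min_pre_frames: int = 20,
    sustain_frames: int = 3,
) -> int:
    """First frame whose mean brightness jumps > jump_sd pre-onset SDs.

    The pre-onset mean/SD are computed over all frames before the candidate
    (expanding window, >= ``min_pre_frames``); the deviation must persist for
    ``sustain_frames`` consecutive frames.
    """
    if len(stack) < min_pre_frames + sustain_frames:
        raise ValueError(f"need >= {min_pre_frames} pre-onset frames")
    means = stack.frames.reshape(len(stack), -1).mean(axis=1)
    for i in range(min_pre_frames, len(stack) - sustain_frames + 1):
        base = means[:i]
        mu, sd = base.mean(), base.std()
        if sd == 0:
            sd = np.finfo(float).tiny
        window = means[i : i + sustain_frames]
        if np.all(np.abs(window - mu) > jump_sd * sd):
            return i
    raise OnsetNotDetectedError("no onset detected")
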