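"""ΔF/F analysis of fluorescence time series (GCaMP / jRCaMP recordings).

ΔF/F = 100 * (F - mean F over a prestimulus window) / (that mean), per
sample. Responses are summarised per stimulation epoch (max, time of max,
trapezoidal AUC over the epoch plus a short tail) and grouped spatially for
the muscle analyses: anterior (T1-A1) / central (A2-A5) / posterior (A6-A8)
body segments, and dorsal / lateral-transverse / ventral muscle groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .behavior import PercentTrace

__all__ = [
    "FluorTrace",
    "EpochSet",
    "EpochResponse",
    "dff",
    "epoch_stats",
    "group_segments",
    "group_muscles",
    "SEGMENT_GROUPS",
    "MUSCLE_GROUPS",
]

SEGMENT_GROUPS = {
    "anterior": ("T1", "T2", "T3", "A1"),
    "central": ("A2", "A3", "A4", "A5"),
    "posterior": ("A6", "A7", "A8"),
}

# Spatial muscle groups by standard larval body-wall muscle numbering:
# dorsal longitudinal + dorsal oblique, lateral transverse, and ventral
# longitudinal + ventral oblique. Override via the `groups` argument.
MUSCLE_GROUPS = {
    "DL/DO": (1, 2, 3, 4, 9, 10, 5, 11, 19, 20),
    "LT": (8, 21, 22, 23, 24),
    "VL/VO": (6, 7, 12, 13, 14, 15, 16, 17, 28, 30),
}


@dataclass
class FluorTrace:
    """A raw fluorescence trace for one ROI (segment, muscle, or neuron)."""

    t: np.ndarray
    F: np.ndarray
    roi_label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.t.shape != self.F.shape or self.t.ndim != 1:
            raise ValueError("t and F must be matching 1-D arrays")
        if (np.diff(self.t) <= 0).any():
            raise ValueError("timestamps must be strictly increasing")
        if (self.F < 0).any():
            raise ValueError("fluorescence must be non-negative")


@dataclass
class EpochSet:
    """Ordered stimulation epochs plus the prestimulus-window length (s)."""

    epochs: Sequence[tuple[float, float, str]]  # (onset_s, offset_s, label)
    prestimulus_s: float = 15.0

    def __post_init__(self) -> None:
        eps = []
        for k, e in enumerate(self.epochs):
            onset, offset = float(e[0]), float(e[1])
            label = e[2] if len(e) > 2 else f"epoch_{k + 1}"
            if offset <= onset:
                raise ValueError(f"epoch {label}: offset must follow onset")
            if eps and onset < eps[-1][1]:
                raise ValueError(f"epoch {label} overlaps the previous epoch")
            eps.append((onset, offset, label))
        self.epochs = eps

    @property
    def first_onset(self) -> float:
        return self.epochs[0][0]


@dataclass
class EpochResponse:
    epoch_label: str
    max_dff: float       # percent
    time_of_max: float   # s, absolute trace time
    auc: float           # percent * s


def dff(trace: FluorTrace, epochs: EpochSet) -> PercentTrace:
    """Per-sample ΔF/F in percent, baselined to the prestimulus window.

    The window is the ``epochs.prestimulus_s`` seconds immediately before the
    first epoch onset; it must hold at least 5 samples with positive mean.
    """
    t0 = epochs.first_onset
    sel = (trace.t >= t0 - epochs.prestimulus_s) & (trace.t < t0)
    if sel.sum() < 5:
        raise ValueError(
            f"ROI {trace.roi_label!r}: prestimulus window holds fewer than 5 samples")
    base = float(trace.F[sel].mean())
    if base <= 0:
        raise ValueError(f"ROI {trace.roi_label!r}: non-positive prestimulus baseline")
    pct = 100.0 * (trace.F - base) / base
    return PercentTrace(t=trace.t.copy(), pct=pct,
                        valid=np.ones_like(trace.t, dtype=bool))


def smooth_trace(trace: PercentTrace, window_samples: int) -> PercentTrace:
    """Centered moving average; a light low-pass before peak amplitude reads.

    The raw max of a noisy trace is a biased amplitude estimator (it rides
    the upper envelope of the noise); averaging over ~1 s of samples makes
    the bias negligible relative to trial-to-trial SEM while leaving the
    slow response shape intact.
    """
    if window_samples <= 1:
        return trace
    kernel = np.ones(window_samples) / window_samples
    sm = np.convolve(trace.pct, kernel, mode="same")
    return PercentTrace(t=trace.t.copy(), pct=sm, valid=trace.valid.copy())


def epoch_stats(
    dff_trace: PercentTrace,
    epochs: EpochSet,
    tail_s: float = 5.0,
    smooth_samples: int = 1,
) -> list[EpochResponse]:
    """Max ΔF/F, time of max and trapezoidal AUC per epoch.

    The search window is [onset, offset + tail_s], letting off-peaking
    responses that outlast the stimulus be captured. ``smooth_samples`` > 1
    applies :func:`smooth_trace` before the max is read (the default leaves
    the trace untouched, so the reported max is the exact sample max).
    Epochs lying outside the sampled trace are skipped with a warning.
    """
    dff_trace = smooth_trace(dff_trace, smooth_samples)
    out = []
    for onset, offset, label in epochs.epochs:
        sel = (dff_trace.t >= onset) & (dff_trace.t <= offset + tail_s)
        if not sel.any() or onset > dff_trace.t[-1]:
            warnings.warn(f"epoch {label!r} lies outside the trace; skipped")
            continue
        tt, vv = dff_trace.t[sel], dff_trace.pct[sel]
        imax = int(np.argmax(vv))
        out.append(EpochResponse(
            epoch_label=label,
            max_dff=float(vv[imax]),
            time_of_max=float(tt[imax]),
            auc=float(np.trapezoid(vv, tt)),
        ))
    return out


_VALID_SEGMENTS = {f"T{i}" for i in range(1, 4)} | {f"A{i}" for i in range(1, 9)}


def _grouped_summary(
    responses: Mapping, groups: Mapping[str, tuple]
) -> pd.DataFrame:
    rows = []
    for gname, members in groups.items():
        rs = [responses[m] for m in members if m in responses]
        if rs:
            rows.append((gname,
                         float(np.mean([r.max_dff for r in rs])),
                         float(np.mean([r.time_of_max for r in rs])),
                         len(rs)))
        else:
            rows.append((gname, np.nan, np.nan, 0))
    return pd.DataFrame(rows, columns=["group", "mean_max_dff",
                                       "mean_time_of_max", "n"])


def group_segments(responses: Mapping[str, EpochResponse]) -> pd.DataFrame:
    """Anterior/central/posterior means of max ΔF/F and time-to-max.

    ``responses`` maps segment labels (T1..T3, A1..A8) to their
    EpochResponse; unknown labels are rejected. Missing segments simply
    reduce the group's n.
    """
    unknown = set(responses) - _VALID_SEGMENTS
    if unknown:
        raise ValueError(f"unknown segment labels: {sorted(unknown)}")
    return _grouped_summary(responses, SEGMENT_GROUPS)


def group_muscles(
    responses: Mapping[int, EpochResponse],
    groups: Mapping[str, tuple] = MUSCLE_GROUPS,
) -> pd.DataFrame:
    """Spatial muscle-group means (DL/DO, LT, VL/VO by default)."""
    known = {m for members in groups.values() for m in members}
    unknown = set(responses) - known
    if unknown:
        raise ValueError(f"muscle ids not in any spatial group: {sorted(unknown)}")
    return _grouped_summary(responses, groups)
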