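"""CaMPARI photoconversion quantification.

CaMPARI integrates neural activity: under photoconverting light, high
intracellular Ca2+ converts the green fluorophore to red, so post-hoc
activity is read as the ratio of area-normalised (mean per pixel) red to
green fluorescence over a region of interest. Two readouts are provided:
soma ratios from automatically detected cell bodies, and Sholl intensity
profiles — the same ratio measured in overlapping 5-px-wide annuli stepped
1 px at a time away from the soma, restricted to the neuron's own mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import disk

from ._thresholds import threshold_moments

__all__ = [
    "TwoChannelImage",
    "SomaROI",
    "ShollProfile",
    "find_somata",
    "ratio_at_roi",
    "sholl_intensity",
]


@dataclass
class TwoChannelImage:
    """Registered red/green channel pair (same shape, non-negative)."""

    red: np.ndarray
    green: np.ndarray
    pixel_size: float | None = None  # µm per pixel, optional

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red, dtype=float)
        self.green = np.asarray(self.green, dtype=float)
        if self.red.shape != self.green.shape or self.red.ndim != 2:
            raise ValueError("red and green must be same-shape 2-D arrays")
        if (self.red < 0).any() or (self.green < 0).any():
            raise ValueError("intensities must be non-negative")


@dataclass
class SomaROI:
    mask: np.ndarray          # boolean pixel set
    centroid: tuple[float, float]
    area: int
    provenance: str = "auto"  # auto | manual
    label: int = 0


@dataclass
class ShollProfile:
    """F_red/F_green per overlapping annulus away from the soma centroid."""

    radius: np.ndarray        # inner radii, 1-px steps
    ratio: np.ndarray         # NaN where the annulus is missing
    n_pixels: np.ndarray
    annulus_width: int = 5

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.ratio)


def find_somata(
    image: TwoChannelImage,
    min_area: int = 30,
    max_area: int = 5000,
    selem_radius: int = 3,
) -> list[SomaROI]:
    """Detect cell bodies on the green channel.

    Moments-threshold the green channel, erode with a disk (stripping thin
    dendrites), drop components whose eroded area falls outside
    [min_area, max_area], dilate back with the same element; each surviving
    component becomes a SomaROI. An empty result is returned with a warning
    rather than an error, leaving the manual-ROI path open.
    """
    green = image.green
    if np.ptp(green) == 0:
        warnings.warn("green channel is constant; no somata found")
        return []
    thr = threshold_moments(green)
    fg = green > thr
    selem = disk(selem_radius)
    fg = ndi.binary_erosion(fg, structure=selem)
    lab, nlab = ndi.label(fg)
    if nlab:
        sizes = np.bincount(lab.ravel())[1:]
        keep = np.flatnonzero((sizes >= min_area) & (sizes <= max_area)) + 1
        fg = np.isin(lab, keep)
    fg = ndi.binary_dilation(fg, structure=selem)
    lab, nlab = ndi.label(fg)
    rois = []
    for k in range(1, nlab + 1):
        m = lab == k
        cy, cx = np.argwhere(m).mean(axis=0)
        rois.append(SomaROI(mask=m, centroid=(float(cy), float(cx)),
                            area=int(m.sum()), provenance="auto", label=k))
    if not rois:
        warnings.warn("no somata detected; consider manual ROI entry")
    return rois


def ratio_at_roi(image: TwoChannelImage, roi: SomaROI) -> float:
    """Area-normalised F_red / F_green over the ROI (mean red / mean green)."""
    if roi.area == 0:
        raise ValueError(f"ROI {roi.label} is empty")
    g = float(image.green[roi.mask].mean())
    if g <= 0:
        raise ZeroDivisionError(f"ROI {roi.label}: mean green intensity is zero")
    return float(image.red[roi.mask].mean()) / g


def sholl_intensity(
    image: TwoChannelImage,
    neuron_mask: np.ndarray,
    center: tuple[float, float],
    annulus_width: int = 5,
    step: int = 1,
    min_pixels: int = 5,
) -> ShollProfile:
    """Radial F_red/F_green profile in overlapping annuli around the soma.

    For each radius r = 1, 1+step, ... the annulus is the set of neuron-mask
    pixels whose Euclidean distance from ``center`` lies in [r, r + width).
    Annuli holding fewer than ``min_pixels`` mask pixels are reported as
    missing (NaN ratio).
    """
    neuron_mask = np.asarray(neuron_mask, dtype=bool)
    cy, cx = center
    iy, ix = int(round(cy)), int(round(cx))
    if not (0 <= iy < neuron_mask.shape[0] and 0 <= ix < neuron_mask.shape[1]
            and neuron_mask[iy, ix]):
        raise ValueError("Sholl center lies outside the neuron mask")
    yy, xx = np.mgrid[0:neuron_mask.shape[0], 0:neuron_mask.shape[1]]
    rad = np.hypot(yy - cy, xx - cx)
    max_r = int(np.ceil(rad[neuron_mask].max()))
    radii = np.arange(1, max_r + 1, step)
    ratio = np.full(len(radii), np.nan)
    npix = np.zeros(len(radii), dtype=int)
    for k, r0 in enumerate(radii):
        ann = neuron_mask & (rad >= r0) & (rad < r0 + annulus_width)
        npix[k] = int(ann.sum())
        if npix[k] >= min_pixels:
            g = image.green[ann].mean()
            if g > 0:
                ratio[k] = image.red[ann].mean() / g
    return ShollProfile(radius=radii, ratio=ratio, n_pixels=npix,
                        annulus_width=annulus_width)


def roi_table(image: TwoChannelImage, rois: list[SomaROI]) -> pd.DataFrame:
    """Tidy per-ROI table: id, centroid, area, mean intensities, ratio."""
    rows = []
    for roi in rois:
        f_red = float(image.red[roi.mask].mean())
        f_green = float(image.green[roi.mask].mean())
        rows.append((roi.label, roi.centroid[1], roi.centroid[0], roi.area,
                     f_red, f_green, f_red / f_green if f_green > 0 else np.nan))
    return pd.DataFrame(rows, columns=["roi_id", "x", "y", "area",
                                       "f_red", "f_green", "ratio"])
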