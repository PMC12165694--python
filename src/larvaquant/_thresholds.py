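"""Automatic gray-level thresholds in the ImageJ "Auto Threshold" family.

Only the two methods the pipeline needs are implemented: Huang's fuzzy-entropy
minimisation (used for whole-larva segmentation) and Tsai's moment-preserving
method, known in ImageJ as "Moments" (used for soma detection on the green
channel). Both operate on a 256-bin histogram of an 8-bit-scaled image and
return the threshold as a gray level in the input image's own scale; pixels
strictly above the returned value are foreground.
"""

from __future__ import annotations

import numpy as np

__all__ = ["threshold_huang", "threshold_moments", "resolve_threshold"]

_NBINS = 256


def _histogram(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """256-bin histogram plus bin centers spanning the image's value range."""
    img = np.asarray(image, dtype=np.float64).ravel()
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        raise ValueError("image is constant; no threshold exists")
    hist, edges = np.histogram(img, bins=_NBINS, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    return hist.astype(np.float64), centers


def threshold_huang(image: np.ndarray) -> float:
    """Huang & Wang fuzzy-thresholding by minimum Shannon fuzziness.

    For each candidate threshold the image is split into two classes; each
    pixel's membership to its class is ``1 / (1 + |g - mu_class| / C)`` with
    ``C`` the gray-level range, and the threshold minimising the total fuzzy
    entropy ``-mu*ln(mu) - (1-mu)*ln(1-mu)`` is returned.
    """
    hist, centers = _histogram(image)
    nz = np.nonzero(hist)[0]
    first, last = nz[0], nz[-1]
    crange = centers[last] - centers[first]

    w = np.cumsum(hist)
    s = np.cumsum(hist * centers)
    total_w, total_s = w[-1], s[-1]

    # class means for every candidate threshold t (foreground = bins > t)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = s / w
        mu1 = (total_s - s) / (total_w - w)

    ts = np.arange(first, last)  # candidate split points
    bins = centers[np.newaxis, :]
    m0 = mu0[ts, np.newaxis]
    m1 = mu1[ts, np.newaxis]
    below = bins <= centers[ts, np.newaxis]
    mu = np.where(below, 1.0 / (1.0 + np.abs(bins - m0) / crange),
                  1.0 / (1.0 + np.abs(bins - m1) / crange))
    # Shannon fuzziness; mu is in (0.5, 1] so (1-mu) can be 0
    with np.errstate(invalid="ignore", divide="ignore"):
        ent = -mu * np.log(mu) - (1.0 - mu) * np.log(1.0 - mu)
    ent = np.nan_to_num(ent, nan=0.0)
    scores = (ent * hist[np.newaxis, :]).sum(axis=1)
    return float(centers[ts[int(np.argmin(scores))]])


def threshold_moments(image: np.ndarray) -> float:
    """Tsai moment-preserving threshold (ImageJ "Moments").

    Chooses the threshold so that a two-level image with the same first three
    gray-level moments as the input assigns the same pixel fraction to the
    dark class.
    """
    hist, centers = _histogram(image)
    p = hist / hist.sum()
    # raw moments on the bin index scale (scale cancels in the fraction)
    idx = np.arange(_NBINS, dtype=np.float64)
    m1 = float((p * idx).sum())
    m2 = float((p * idx**2).sum())
    m3 = float((p * idx**3).sum())

    cd = m2 - m1 * m1
    if cd <= 0:
        raise ValueError("degenerate histogram; moments method undefined")
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (-m3 + m2 * m1) / cd
    disc = c1 * c1 - 4.0 * c0
    disc = max(disc, 0.0)
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 == z0:
        raise ValueError("degenerate histogram; moments method undefined")
    pd = (z1 - m1) / (z1 - z0)  # target fraction of pixels in the dark class

    cum = np.cumsum(p)
    t = int(np.searchsorted(cum, pd))
    t = min(t, _NBINS - 1)
    return float(centers[t])


def resolve_threshold(image: np.ndarray, method: str) -> float:
    """Dispatch a threshold-method label: ``huang``, ``moments``, ``fixed:<v>``."""
    if method == "huang":
        return threshold_huang(image)
    if method == "moments":
        return threshold_moments(image)
    if method.startswith("fixed:"):
        return float(method.split(":", 1)[1])
    raise ValueError(
        f"unknown threshold method {method!r}; expected 'huang', 'moments' or 'fixed:<value>'"
    )
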