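"""Synthetic inputs with closed-form ground truth for every pipeline stage.

Four generators emulate the four kinds of raw data the quantification pipeline
consumes:

* :func:`render_larva_video` — a crawling, contracting larval silhouette on a
  dark-field background, for the behavior-video pipeline. The larva is a
  capsule (rectangle with semicircular caps) bent along a circular arc, so its
  true area is closed-form: ``A = 2*w*L + pi*w**2`` for half-width ``w`` and
  straight-section length ``L``. Contraction episodes scale the area by a
  scheduled fractional change with linear 0.2 s on/off ramps.
* :func:`render_campari_image` — a two-channel (red/green) neuron image with a
  disk soma and capsule dendrites, red/green levels given as functions of
  distance from the soma center, for CaMPARI ratiometry and Sholl profiling.
* :func:`simulate_trace` — a fluorescence time series with box-rise /
  exponential-decay responses in scheduled stimulation epochs and geometric
  habituation across epochs, for ΔF/F analysis.
* :func:`simulate_phenotypes` — a genotypes × metrics percent-change matrix
  drawn from isotropic Gaussian clusters, for the embedding/clustering stage.

All generators are deterministic given their spec (which embeds a seed), and
each returns a ground-truth object recording what downstream modules should
recover.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .video import FrameStack

__all__ = [
    "Episode",
    "LarvaSimSpec",
    "LarvaGroundTruth",
    "render_larva_video",
    "NeuronSimSpec",
    "NeuronGroundTruth",
    "render_campari_image",
    "TraceSimSpec",
    "TraceGroundTruth",
    "simulate_trace",
    "PhenotypeSimSpec",
    "PHENOTYPE_METRICS",
    "simulate_phenotypes",
]

RAMP_S = 0.2  # linear contraction on/off ramp


# --------------------------------------------------------------------------
# Behavior video
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Episode:
    """One scheduled contraction (or expansion) episode.

    The fractional area change ramps linearly from 0 to ``frac_change`` over
    the first 0.2 s, holds, and ramps back to 0 over 0.2 s after ``end_s``.
    """

    start_s: float
    end_s: float
    frac_change: float

    def fraction_at(self, t: float) -> float:
        if t <= self.start_s or t >= self.end_s + RAMP_S:
            return 0.0
        rise = min(1.0, (t - self.start_s) / RAMP_S)
        fall = min(1.0, (self.end_s + RAMP_S - t) / RAMP_S)
        return self.frac_change * min(rise, fall)


@dataclass
class LarvaSimSpec:
    """Parameters of one synthetic larva recording.

    Gray levels are on an 8-bit scale. The capsule's total length is
    ``aspect_ratio`` times its width; ``bend_amplitude`` is the peak total
    bending angle (radians) of a sinusoidally oscillating body bend, which
    changes shape (hence mobility after stabilisation) without changing area.
    Motion and bending halt inside ``freeze_schedule`` windows.
    """

    image_size: tuple[int, int] = (128, 128)
    frame_rate: float = 30.0
    n_frames: int = 300
    baseline_area: float = 1500.0
    contraction_schedule: Sequence[Episode] = field(default_factory=tuple)
    crawl_speed: float = 0.5
    turn_rate: float = 0.02
    noise_sd: float = 3.0
    background_level: float = 20.0
    foreground_level: float = 150.0
    seed: int = 0
    aspect_ratio: float = 5.0
    bend_amplitude: float = 0.5
    bend_period_s: float = 1.5
    freeze_schedule: Sequence[tuple[float, float]] = field(default_factory=tuple)
    texture_sd: float = 8.0       # smooth illumination mottle on the body
    texture_scale_px: float = 2.0

    def __post_init__(self) -> None:
        self.contraction_schedule = tuple(
            e if isinstance(e, Episode) else Episode(*e) for e in self.contraction_schedule
        )
        self.freeze_schedule = tuple(tuple(w) for w in self.freeze_schedule)
        self.validate()

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def validate(self) -> None:
        if self.n_frames < 2 or self.frame_rate <= 0:
            raise ValueError("need >= 2 frames and a positive frame rate")
        if abs(self.foreground_level - self.background_level) < 5 * self.noise_sd:
            raise ValueError("foreground/background separation must be >= 5x noise_sd")
        prev_end = -np.inf
        for ep in self.contraction_schedule:
            if not -1.0 < ep.frac_change < 1.0:
                raise ValueError(f"episode {ep}: fractional change must lie in (-1, 1)")
            if ep.end_s <= ep.start_s:
                raise ValueError(f"episode {ep}: end must follow start")
            if ep.start_s < 0 or ep.end_s + RAMP_S > self.duration_s:
                raise ValueError(
                    f"episode {ep} falls outside the {self.duration_s:.2f} s recording"
                )
            if ep.start_s < prev_end + RAMP_S:
                raise ValueError(f"episode {ep} overlaps the previous episode")
            prev_end = ep.end_s


@dataclass
class LarvaGroundTruth:
    """Per-frame analytic truth for a rendered larva video."""

    t: np.ndarray
    true_area: np.ndarray          # pixels^2, from the capsule's closed form
    true_frac_change: np.ndarray   # scheduled fractional area change per frame
    true_centroid: np.ndarray      # (n_frames, 2) row/col body center
    schedule: tuple[Episode, ...]


def _capsule_dims(area: float, aspect_ratio: float) -> tuple[float, float]:
    """Half-width w and straight length L with 2wL + pi w^2 = area."""
    if aspect_ratio <= 1.0:
        raise ValueError("aspect_ratio must exceed 1")
    w = np.sqrt(area / (4.0 * (aspect_ratio - 1.0) + np.pi))
    length = 2.0 * w * (aspect_ratio - 1.0)
    return float(w), float(length)


def _centerline(center: np.ndarray, heading: float, length: float,
                bend: float, n_pts: int = 13) -> np.ndarray:
    """Sample a constant-curvature arc of given arc length, centered on `center`.

    `bend` is the total turning angle along the body; bend -> 0 degenerates to
    a straight segment. Arc length is preserved so area is bend-invariant.
    """
    s = np.linspace(-length / 2.0, length / 2.0, n_pts)
    if abs(bend) < 1e-6:
        pts = np.stack([np.zeros_like(s), s], axis=1)
    else:
        r = length / bend
        ang = s / r
        pts = np.stack([r * (1.0 - np.cos(ang)), r * np.sin(ang)], axis=1)
        pts -= pts.mean(axis=0)
    rot = np.array([[np.cos(heading), -np.sin(heading)],
                    [np.sin(heading), np.cos(heading)]])
    return pts @ rot.T + center


def _dist_to_polyline(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Min distance from each point (N,2) to a polyline (M,2), vectorised."""
    a = poly[:-1]                       # (S,2)
    d = poly[1:] - a                    # (S,2)
    len2 = (d * d).sum(axis=1)          # (S,)
    diff = points[:, None, :] - a[None, :, :]          # (N,S,2)
    tproj = (diff * d[None, :, :]).sum(axis=2) / len2  # (N,S)
    tproj = np.clip(tproj, 0.0, 1.0)
    closest = a[None, :, :] + tproj[:, :, None] * d[None, :, :]
    dist2 = ((points[:, None, :] - closest) ** 2).sum(axis=2)
    return np.sqrt(dist2.min(axis=1))


def render_larva_video(spec: LarvaSimSpec) -> tuple[FrameStack, LarvaGroundTruth]:
    """Render a contracting, crawling capsule larva; return frames + truth."""
    rng = np.random.default_rng(spec.seed)
    h, wd = spec.image_size
    yy, xx = np.mgrid[0:h, 0:wd]
    pts = np.stack([yy.ravel(), xx.ravel()], axis=1).astype(np.float64)

    w0, l0 = _capsule_dims(spec.baseline_area, spec.aspect_ratio)
    body_len = l0 + 2.0 * w0
    margin = body_len / 2.0 + 3.0
    if 2 * margin >= min(h, wd):
        raise ValueError("image too small for the requested larva size")

    center = np.array([h / 2.0, wd / 2.0])
    heading = rng.uniform(0, 2 * np.pi)
    bend_phase = rng.uniform(0, 2 * np.pi)

    # static bright mottle sampled by the moving body: widens the foreground
    # gray-level mode (as real cuticle/gut texture does) while keeping its
    # lower edge sharp at foreground_level, which keeps auto-thresholds from
    # shaving body pixels
    if spec.texture_sd > 0:
        from scipy.ndimage import gaussian_filter

        tex = gaussian_filter(rng.normal(0.0, 1.0, (h, wd)), spec.texture_scale_px)
        tex = np.abs(tex) * (spec.texture_sd / tex.std())
    else:
        tex = np.zeros((h, wd))

    dt = 1.0 / spec.frame_rate
    t = np.arange(spec.n_frames) * dt
    frames = np.empty((spec.n_frames, h, wd), dtype=np.uint8)
    true_area = np.empty(spec.n_frames)
    true_frac = np.empty(spec.n_frames)
    true_centroid = np.empty((spec.n_frames, 2))
    sim_time = 0.0  # advances only while not frozen, so frozen frames repeat

    for i in range(spec.n_frames):
        ti = t[i]
        frozen = any(a <= ti < b for a, b in spec.freeze_schedule)
        frac = sum(ep.fraction_at(ti) for ep in spec.contraction_schedule)
        scale = np.sqrt(1.0 + frac)
        w, length = w0 * scale, l0 * scale

        bend = spec.bend_amplitude * np.sin(
            2 * np.pi * sim_time / spec.bend_period_s + bend_phase)
        poly = _centerline(center, heading, length, bend)
        # distances only inside the body's bounding box, for speed
        pad = w + 1.5
        r0 = max(0, int(poly[:, 0].min() - pad))
        r1 = min(h, int(np.ceil(poly[:, 0].max() + pad)) + 1)
        c0 = max(0, int(poly[:, 1].min() - pad))
        c1 = min(wd, int(np.ceil(poly[:, 1].max() + pad)) + 1)
        sub = pts.reshape(h, wd, 2)[r0:r1, c0:c1].reshape(-1, 2)
        dist = _dist_to_polyline(sub, poly)
        mask = np.zeros((h, wd), dtype=bool)
        mask[r0:r1, c0:c1] = (dist <= w).reshape(r1 - r0, c1 - c0)

        img = np.full((h, wd), spec.background_level, dtype=np.float64)
        img[mask] = spec.foreground_level + tex[mask]
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=img.shape)
        frames[i] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

        true_area[i] = 2.0 * w * length + np.pi * w * w
        true_frac[i] = frac
        true_centroid[i] = center

        if not frozen:
            heading += rng.normal(0.0, spec.turn_rate)
            step = spec.crawl_speed * np.array([np.sin(heading), np.cos(heading)])
            nxt = center + step
            # reflect off the walls so the body never leaves the frame
            for ax, size in ((0, h), (1, wd)):
                if nxt[ax] < margin or nxt[ax] > size - margin:
                    heading += np.pi / 2.0
                    nxt = center
                    break
            center = nxt
            sim_time += dt

    stack = FrameStack(frames=frames, frame_interval=dt, origin="synthetic larva video")
    truth = LarvaGroundTruth(t=t, true_area=true_area, true_frac_change=true_frac,
                             true_centroid=true_centroid,
                             schedule=tuple(spec.contraction_schedule))
    return stack, truth


# --------------------------------------------------------------------------
# CaMPARI two-channel neuron image
# --------------------------------------------------------------------------

LevelMap = Callable[[np.ndarray], np.ndarray]  # radius (px) -> gray level


@dataclass
class NeuronSimSpec:
    """A disk soma with straight capsule dendrites on a dark background.

    ``red_level_map`` / ``green_level_map`` give channel intensity as a
    function of Euclidean distance from the soma center, evaluated on neuron
    pixels only; the background sits at ``background_level`` in both channels.
    """

    image_size: tuple[int, int] = (128, 128)
    soma_center: tuple[float, float] = (64.0, 64.0)
    soma_radius: float = 10.0
    dendrite_segments: Sequence[tuple[tuple[float, float], tuple[float, float], float]] = \
        field(default_factory=tuple)  # (start_rc, end_rc, width_px)
    red_level_map: LevelMap = lambda r: np.full_like(r, 100.0)
    green_level_map: LevelMap = lambda r: np.full_like(r, 100.0)
    background_level: float = 5.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size
        cy, cx = self.soma_center
        if not (self.soma_radius <= cy <= h - self.soma_radius
                and self.soma_radius <= cx <= w - self.soma_radius):
            raise ValueError("soma must lie fully inside the image")


@dataclass
class NeuronGroundTruth:
    soma_mask: np.ndarray
    neuron_mask: np.ndarray
    radius: np.ndarray        # annulus inner radii, 1-px steps
    true_ratio: np.ndarray    # noise-free annulus-averaged red/green
    centroid: tuple[float, float]


def render_campari_image(
    spec: NeuronSimSpec, annulus_width: int = 5
) -> tuple["TwoChannelImage", NeuronGroundTruth]:
    """Render red/green channels plus the analytic Sholl ratio curve.

    The ground-truth curve is the noise-free red/green annulus average on the
    same pixel grid, i.e. exactly what an ideal Sholl measurement recovers.
    """
    from .campari import TwoChannelImage  # local import to avoid a cycle

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = spec.soma_center
    rad = np.hypot(yy - cy, xx - cx)

    soma_mask = rad <= spec.soma_radius
    neuron_mask = soma_mask.copy()
    if spec.dendrite_segments:
        pts = np.stack([yy.ravel(), xx.ravel()], axis=1).astype(np.float64)
        for (a, b, width) in spec.dendrite_segments:
            poly = np.array([a, b], dtype=np.float64)
            d = _dist_to_polyline(pts, poly).reshape(h, w)
            neuron_mask |= d <= width / 2.0

    red = np.full((h, w), spec.background_level, dtype=np.float64)
    green = red.copy()
    red[neuron_mask] = spec.red_level_map(rad[neuron_mask])
    green[neuron_mask] = spec.green_level_map(rad[neuron_mask])
    clean_red, clean_green = red.copy(), green.copy()
    if spec.noise_sd > 0:
        red += rng.normal(0.0, spec.noise_sd, red.shape)
        green += rng.normal(0.0, spec.noise_sd, green.shape)
    red = np.clip(red, 0.0, None)
    green = np.clip(green, 0.0, None)

    max_r = int(np.ceil(rad[neuron_mask].max()))
    radii = np.arange(1, max_r + 1)
    true_ratio = np.full(len(radii), np.nan)
    for k, r0 in enumerate(radii):
        ann = neuron_mask & (rad >= r0) & (rad < r0 + annulus_width)
        if ann.sum() >= 5:
            true_ratio[k] = clean_red[ann].mean() / clean_green[ann].mean()

    img = TwoChannelImage(red=red, green=green)
    truth = NeuronGroundTruth(soma_mask=soma_mask, neuron_mask=neuron_mask,
                              radius=radii, true_ratio=true_ratio,
                              centroid=(cy, cx))
    return img, truth


# --------------------------------------------------------------------------
# Fluorescence trace
# --------------------------------------------------------------------------

@dataclass
class TraceSimSpec:
    """Habitating fluorescence responses to repeated stimulation epochs.

    Within epoch k (1-based) the response kernel steps to 1 at onset and
    decays as exp(-(t - offset)/decay_tau) after offset; its amplitude is
    ``response_amplitude * habituation_factor**(k-1)``. Matches a paradigm of
    repeated 15 s optogenetic activations separated by 30 s dark rests.

    The multiplicative noise is a smooth Gaussian process with marginal SD
    ``noise_sd`` and correlation time ``noise_tau_s``, emulating the slow
    fluctuations (focus drift, motion, hemolymph movement) that dominate
    ROI-averaged in-vivo recordings; per-frame shot noise on a ROI mean is
    comparatively negligible. ``noise_tau_s = 0`` gives white noise.
    """

    frame_interval: float = 0.3072
    prestimulus_s: float = 15.0
    epochs: Sequence[tuple[float, float]] = ((30.0, 15.0), (75.0, 15.0), (120.0, 15.0))
    response_amplitude: float = 1.0
    decay_tau: float = 3.0
    habituation_factor: float = 0.5
    noise_sd: float = 0.02
    noise_tau_s: float = 2.0
    baseline_F: float = 100.0
    total_s: float = 165.0
    seed: int = 0

    def validate(self) -> None:
        if self.baseline_F <= 0:
            raise ValueError("baseline_F must be positive")
        if not 0 < self.habituation_factor <= 1:
            raise ValueError("habituation_factor must lie in (0, 1]")
        prev_end = -np.inf
        for onset, dur in self.epochs:
            if onset < prev_end:
                raise ValueError("epochs must be ordered and non-overlapping")
            prev_end = onset + dur
        if self.epochs and self.epochs[0][0] < self.prestimulus_s:
            raise ValueError("first epoch onset precedes the prestimulus window")


@dataclass
class TraceGroundTruth:
    t: np.ndarray
    true_dff: np.ndarray            # percent
    epoch_max_dff: np.ndarray       # percent, one per epoch


def simulate_trace(spec: TraceSimSpec) -> tuple["FluorTrace", TraceGroundTruth]:
    from .fluor import FluorTrace

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.total_s, spec.frame_interval)
    kernel = np.zeros_like(t)
    epoch_max = np.zeros(len(spec.epochs))
    for k, (onset, dur) in enumerate(spec.epochs):
        amp = spec.response_amplitude * spec.habituation_factor**k
        active = (t >= onset) & (t <= onset + dur)
        tail = t > onset + dur
        contrib = np.zeros_like(t)
        contrib[active] = amp
        contrib[tail] = amp * np.exp(-(t[tail] - onset - dur) / spec.decay_tau)
        kernel += contrib
        epoch_max[k] = 100.0 * amp

    clean = spec.baseline_F * (1.0 + kernel)
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, 1.0, t.shape)
        if spec.noise_tau_s > 0:
            from scipy.ndimage import gaussian_filter1d

            noise = gaussian_filter1d(noise, spec.noise_tau_s / spec.frame_interval,
                                      mode="reflect")
        noise *= spec.noise_sd / noise.std()
    else:
        noise = 0.0
    f = np.clip(clean * (1.0 + noise), 0.0, None)
    trace = FluorTrace(t=t, F=f, roi_label="synthetic")
    truth = TraceGroundTruth(t=t, true_dff=100.0 * kernel, epoch_max_dff=epoch_max)
    return trace, truth


# --------------------------------------------------------------------------
# Phenotype matrix
# --------------------------------------------------------------------------

PHENOTYPE_METRICS = (
    "coact_peak_pct_ct",
    "coact_cumulative_pct_ct",
    "coact_avg_area_change",
    "coact_ct_duration",
    "silence_cumulative_pct_ct",
    "silence_avg_area_change",
    "silence_ct_duration",
)


@dataclass
class PhenotypeSimSpec:
    """Gaussian-cluster genotype phenotypes in percent-change-from-control units.

    Genotype i is assigned to cluster ``i % k`` (round-robin) and its row is
    drawn from an isotropic Gaussian around that cluster's center.
    """

    n_genotypes: int = 20
    cluster_centers: Sequence[Sequence[float]] = field(default_factory=tuple)
    within_cluster_sd: float = 5.0
    metric_names: Sequence[str] = PHENOTYPE_METRICS
    seed: int = 0

    def validate(self) -> None:
        centers = np.asarray(self.cluster_centers, dtype=float)
        if centers.ndim != 2 or centers.shape[1] != len(self.metric_names):
            raise ValueError("each cluster center needs one value per metric")
        if len(np.unique(centers, axis=0)) != len(centers):
            raise ValueError("cluster centers must be distinct")
        if self.n_genotypes < len(centers):
            raise ValueError("need at least one genotype per cluster")
        if len(self.metric_names) != 7:
            raise ValueError("the phenotype matrix has exactly seven metrics")


def simulate_phenotypes(spec: PhenotypeSimSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Return (matrix, true_labels); labels are 0-based cluster assignments."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    centers = np.asarray(spec.cluster_centers, dtype=float)
    k = len(centers)
    labels = np.arange(spec.n_genotypes) % k
    rows = centers[labels] + rng.normal(
        0.0, spec.within_cluster_sd, size=(spec.n_genotypes, centers.shape[1]))
    index = [f"genotype_{i:02d}" for i in range(spec.n_genotypes)]
    matrix = pd.DataFrame(rows, index=index, columns=list(spec.metric_names))
    return matrix, labels


def spec_to_dict(spec) -> dict:
    """JSON-serialisable view of any sim spec (for ground-truth sidecars)."""
    return dataclasses.asdict(spec)
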