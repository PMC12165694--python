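"""Behavioral readouts from area and mobility traces.

The central readout is the contraction (CT) response: a sustained reduction
in projected body area, scored as any run of frames at or below a percent
threshold (default -10%, relative to a pre-stimulus baseline mean) lasting at
least a minimum duration (default 0.5 s). From CT events the module derives
per-animal metrics (CT duration, CT magnitude, responder status), population
curves (instantaneous / cumulative / peak %CT), mobility-based immobility
metrics, and the per-genotype statistical battery: Fisher's exact with
Benjamini-Hochberg for responder fractions, Kruskal-Wallis with the two-stage
Benjamini-Krieger-Yekutieli FDR step-up for durations, and one-way ANOVA with
Holm-Šídák for magnitudes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .video import AreaTrace, MobilityTrace

__all__ = [
    "BaselineWindow",
    "PercentTrace",
    "CTEvent",
    "CTEventSet",
    "AnimalMetrics",
    "PopulationCurves",
    "area_change_pct",
    "mobility_change_pct",
    "detect_ct",
    "summarize_animal",
    "population_curves",
    "mobility_metrics",
    "group_statistics",
]

CT_THRESHOLD_PCT = -10.0
CT_MIN_DURATION_S = 0.5
IMMOBILITY_THRESHOLD_PCT = -25.0


@dataclass(frozen=True)
class BaselineWindow:
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("baseline window must have positive length")


@dataclass
class PercentTrace:
    """Per-frame percent change relative to a baseline-window mean."""

    t: np.ndarray
    pct: np.ndarray
    valid: np.ndarray

    @property
    def frame_interval(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass(frozen=True)
class CTEvent:
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class CTEventSet:
    events: list[CTEvent]
    ct_threshold: float = CT_THRESHOLD_PCT
    min_duration: float = CT_MIN_DURATION_S

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class AnimalMetrics:
    ct_duration: float = np.nan       # s at or below threshold within stimulus
    ct_magnitude: float = np.nan      # mean % area change over the stimulus
    responded: bool = False
    mobility_change: float = np.nan   # mean % mobility change over the stimulus
    immobility_duration: float = np.nan
    immobile: bool = False
    unscorable: bool = False


@dataclass
class PopulationCurves:
    t: np.ndarray
    instantaneous_pct_ct: np.ndarray
    cumulative_pct_ct: np.ndarray
    peak_pct_ct: float


def _baseline_mean(t, values, valid, baseline: BaselineWindow, what: str) -> float:
    sel = (t >= baseline.start_s) & (t < baseline.end_s) & valid
    if sel.sum() < 5:
        raise ValueError(f"baseline window holds fewer than 5 valid {what} frames")
    return float(values[sel].mean())


def area_change_pct(trace: AreaTrace, baseline: BaselineWindow) -> PercentTrace:
    """Percent area change: 100 * (area_N - mean baseline area) / mean baseline area."""
    base = _baseline_mean(trace.t, trace.area, trace.valid, baseline, "area")
    if base <= 0:
        raise ValueError("baseline mean area is zero; percent change undefined")
    pct = 100.0 * (trace.area - base) / base
    return PercentTrace(t=trace.t.copy(), pct=pct, valid=trace.valid.copy())


def mobility_change_pct(mob: MobilityTrace, baseline: BaselineWindow) -> PercentTrace:
    """Percent mobility change relative to the baseline-window mean mobility."""
    base = _baseline_mean(mob.t, mob.raw_mobility, mob.valid, baseline, "mobility")
    if base <= 0:
        raise ZeroDivisionError("baseline mean mobility is zero")
    pct = 100.0 * (mob.raw_mobility - base) / base
    return PercentTrace(t=mob.t.copy(), pct=pct, valid=mob.valid.copy())


def min_run_frames(min_duration: float, frame_interval: float) -> int:
    """'At least d consecutive seconds' as a frame count: ceil(d * frame rate)."""
    return max(1, math.ceil(round(min_duration / frame_interval, 9)))


def detect_ct(
    pct: PercentTrace,
    threshold: float = CT_THRESHOLD_PCT,
    min_duration: float = CT_MIN_DURATION_S,
    window: tuple[float, float] | None = None,
) -> CTEventSet:
    """Maximal runs of frames at or below ``threshold`` inside ``window``.

    The comparison is inclusive (<=). A run of n frames spans n frame
    intervals, so its duration is n / frame_rate; runs shorter than
    ceil(min_duration * frame_rate) frames are discarded. Event times are
    reported at frame resolution: an event starts at its first sub-threshold
    frame's time and lasts n_frames * frame_interval.
    """
    dt = pct.frame_interval
    if window is None:
        window = (float(pct.t[0]), float(pct.t[-1]) + dt)
    sel = (pct.t >= window[0]) & (pct.t < window[1])
    t = pct.t[sel]
    below = pct.pct[sel] <= threshold
    need = min_run_frames(min_duration, dt)

    events: list[CTEvent] = []
    i, n = 0, len(below)
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            run = j - i + 1
            if run >= need:
                events.append(CTEvent(start_s=float(t[i]),
                                      end_s=float(t[i]) + run * dt))
            i = j + 1
        else:
            i += 1
    return CTEventSet(events=events, ct_threshold=threshold, min_duration=min_duration)


def summarize_animal(
    pct: PercentTrace, events: CTEventSet, stimulus: tuple[float, float]
) -> AnimalMetrics:
    """CT duration (event time within the stimulus), magnitude, responder flag."""
    s0, s1 = stimulus
    dur = sum(max(0.0, min(e.end_s, s1) - max(e.start_s, s0)) for e in events.events)
    in_stim = (pct.t >= s0) & (pct.t < s1)
    mag = float(pct.pct[in_stim].mean()) if in_stim.any() else np.nan
    responded = any(min(e.end_s, s1) > max(e.start_s, s0) for e in events.events)
    return AnimalMetrics(ct_duration=dur, ct_magnitude=mag, responded=responded)


def population_curves(
    animals: list[PercentTrace],
    threshold: float = CT_THRESHOLD_PCT,
    min_duration: float = CT_MIN_DURATION_S,
    window: tuple[float, float] = (5.0, 10.0),
) -> PopulationCurves:
    """Instantaneous, cumulative and peak %CT across a cohort.

    Traces are resampled (previous-sample hold) onto the coarsest frame grid.
    The cumulative curve counts animals whose first qualifying event has
    started by t; the instantaneous curve counts animals at or below the
    threshold at t; the peak is the instantaneous maximum inside the window.
    """
    if not animals:
        raise ValueError("need at least one animal")
    dt = max(a.frame_interval for a in animals)
    t = np.arange(window[0], window[1], dt)

    inst = np.zeros((len(animals), len(t)))
    first_onset = np.full(len(animals), np.inf)
    for i, a in enumerate(animals):
        idx = np.clip(np.searchsorted(a.t, t, side="right") - 1, 0, len(a.t) - 1)
        inst[i] = a.pct[idx] <= threshold
        ev = detect_ct(a, threshold=threshold, min_duration=min_duration, window=window)
        if ev.events:
            first_onset[i] = ev.events[0].start_s
    instantaneous = 100.0 * inst.mean(axis=0)
    cumulative = 100.0 * (first_onset[:, None] <= t[None, :]).mean(axis=0)
    return PopulationCurves(t=t, instantaneous_pct_ct=instantaneous,
                            cumulative_pct_ct=cumulative,
                            peak_pct_ct=float(instantaneous.max()))


def mobility_metrics(
    mob: MobilityTrace,
    baseline: BaselineWindow,
    stimulus: tuple[float, float],
    immobility_threshold: float = IMMOBILITY_THRESHOLD_PCT,
) -> AnimalMetrics:
    """Mean % mobility change, immobility flag and immobility duration.

    An animal is immobile if its mean mobility change over the stimulus is at
    or below the threshold (default -25%); immobility duration is the time
    spent at or below the threshold frame-by-frame. Per-frame new-pixel
    counts are noisy, so the animal-level flag uses the stimulus average —
    an any-frame rule would label nearly every animal immobile. Zero
    baseline mobility makes the animal unscorable (flag, not an error).
    """
    try:
        pct = mobility_change_pct(mob, baseline)
    except ZeroDivisionError:
        return AnimalMetrics(unscorable=True)
    s0, s1 = stimulus
    in_stim = (pct.t >= s0) & (pct.t < s1) & pct.valid
    if not in_stim.any():
        return AnimalMetrics(unscorable=True)
    dt = pct.frame_interval
    below = pct.pct[in_stim] <= immobility_threshold
    mean_change = float(pct.pct[in_stim].mean())
    return AnimalMetrics(
        mobility_change=mean_change,
        immobile=mean_change <= immobility_threshold,
        immobility_duration=float(below.sum()) * dt,
    )


def _pairwise_vs_control(groups: dict[str, np.ndarray], control: str, test):
    rows = []
    for g, vals in groups.items():
        if g == control:
            continue
        rows.append((g, test(vals, groups[control])))
    return rows


def group_statistics(
    metrics_by_genotype: pd.DataFrame, control_labels: list[str]
) -> pd.DataFrame:
    """Per-genotype test battery against each named control.

    ``metrics_by_genotype`` is tidy per-animal data with columns
    ``genotype``, ``responded``, ``ct_duration``, ``ct_magnitude``. For each
    control: responder counts -> Fisher's exact (two-sided) with
    Benjamini-Hochberg across genotypes; durations -> pairwise
    Kruskal-Wallis with the two-stage Benjamini-Krieger-Yekutieli FDR
    step-up; magnitudes -> pairwise ANOVA-style t tests (pooled variance)
    with Holm-Šídák. Groups with n < 2 are excluded from the parametric
    comparison with a warning. Returns a tidy table with columns
    (metric, control, genotype, test, raw_p, adj_p, n).
    """
    df = metrics_by_genotype
    required = {"genotype", "responded", "ct_duration", "ct_magnitude"}
    if not required.issubset(df.columns):
        raise ValueError(f"metrics table must have columns {sorted(required)}")
    genotypes = list(dict.fromkeys(df["genotype"]))
    for c in control_labels:
        if c not in genotypes:
            raise ValueError(f"control group {c!r} not present")

    out = []
    for control in control_labels:
        ctrl = df[df["genotype"] == control]
        # --- responder fractions: Fisher + BH -------------------------------
        rows = []
        for g in genotypes:
            if g == control:
                continue
            sub = df[df["genotype"] == g]
            table = [
                [int(sub["responded"].sum()), int((~sub["responded"].astype(bool)).sum())],
                [int(ctrl["responded"].sum()), int((~ctrl["responded"].astype(bool)).sum())],
            ]
            _, p = stats.fisher_exact(table, alternative="two-sided")
            rows.append((g, p, len(sub)))
        if rows:
            adj = multipletests([r[1] for r in rows], method="fdr_bh")[1]
            out += [("pct_ct_response", control, g, "fisher_exact_bh", p, a, n)
                    for (g, p, n), a in zip(rows, adj)]

        # --- durations: Kruskal-Wallis + two-stage BKY FDR ------------------
        rows = []
        for g in genotypes:
            if g == control:
                continue
            sub = df[df["genotype"] == g]["ct_duration"].to_numpy(float)
            cv = ctrl["ct_duration"].to_numpy(float)
            if len(np.unique(np.concatenate([sub, cv]))) < 2:
                p = 1.0
            else:
                _, p = stats.kruskal(sub, cv)
            rows.append((g, p, len(sub)))
        if rows:
            adj = multipletests([r[1] for r in rows], method="fdr_tsbky")[1]
            out += [("ct_duration", control, g, "kruskal_wallis_bky", p, a, n)
                    for (g, p, n), a in zip(rows, adj)]

        # --- magnitudes: ANOVA-family pairwise t + Holm-Šídák ---------------
        rows = []
        for g in genotypes:
            if g == control:
                continue
            sub = df[df["genotype"] == g]["ct_magnitude"].dropna().to_numpy(float)
            if len(sub) < 2:
                warnings.warn(f"group {g!r} has n < 2; excluded from ANOVA comparisons")
                continue
            cv = ctrl["ct_magnitude"].dropna().to_numpy(float)
            _, p = stats.ttest_ind(sub, cv, equal_var=True)
            rows.append((g, float(p), len(sub)))
        if rows:
            adj = multipletests([r[1] for r in rows], method="holm-sidak")[1]
            out += [("ct_magnitude", control, g, "anova_holm_sidak", p, a, n)
                    for (g, p, n), a in zip(rows, adj)]

    return pd.DataFrame(
        out, columns=["metric", "control", "genotype", "test", "raw_p", "adj_p", "n"]
    )
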