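"""End-to-end pipelines composing the quantification stages.

Two pipelines mirror the two experimental arms: the behavior pipeline
(video -> segmentation -> stabilization -> area & mobility -> CT scoring ->
population curves and statistics) and the imaging pipeline (CaMPARI soma
ratios and Sholl profiles; ΔF/F epoch analysis of fluorescence traces).
Both are deterministic given the config (which embeds the seed) and stamp
every output bundle with the config hash.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, campari, fluor, io, video
from .config import RunConfig, derive_seed
from .synthetic import LarvaSimSpec, render_larva_video

__all__ = ["BehaviorBundle", "ImagingBundle",
           "quantify_larva", "run_behavior_pipeline", "run_imaging_pipeline",
           "demo_larva_specs"]


@dataclass
class BehaviorBundle:
    per_animal: pd.DataFrame
    curves: behavior.PopulationCurves
    statistics: pd.DataFrame | None
    pct_traces: list[behavior.PercentTrace]
    config_hash: str


@dataclass
class ImagingBundle:
    roi_table: pd.DataFrame | None
    sholl: campari.ShollProfile | None
    epoch_responses: list[fluor.EpochResponse] = field(default_factory=list)
    config_hash: str = ""


def quantify_larva(
    stack: video.FrameStack, config: RunConfig
) -> tuple[behavior.PercentTrace, behavior.AnimalMetrics, behavior.AnimalMetrics]:
    """One animal through segmentation, stabilization, area and mobility scoring.

    Returns the percent-area trace, the CT metrics and the mobility metrics.
    """
    vc, bc = config.video, config.behavior
    mask = video.segment_larva(stack, threshold_method=vc.threshold_method,
                               min_blob_px=vc.min_blob_px,
                               selem_radius=vc.selem_radius)
    _, stab_mask = video.stabilize(mask, stack)
    area = video.extract_area(stab_mask, stack.frame_interval)
    mob = video.extract_mobility(stab_mask, stack.frame_interval)

    baseline = behavior.BaselineWindow(*bc.baseline)
    pct = behavior.area_change_pct(area, baseline)
    events = behavior.detect_ct(pct, threshold=bc.ct_threshold,
                                min_duration=bc.ct_min_duration,
                                window=bc.stimulus)
    ct = behavior.summarize_animal(pct, events, bc.stimulus)
    mobm = behavior.mobility_metrics(mob, baseline, bc.stimulus,
                                     immobility_threshold=bc.immobility_threshold)
    return pct, ct, mobm


def run_behavior_pipeline(
    config: RunConfig,
    inputs,
    genotypes: list[str] | None = None,
    control_labels: list[str] | None = None,
    out_dir=None,
) -> BehaviorBundle:
    """Run the full behavior pipeline over a cohort.

    ``inputs`` is a list of FrameStacks or LarvaSimSpecs (specs are rendered
    with per-animal seeds derived from the config seed). Optional genotype
    labels (one per animal) enable the per-genotype statistics table.
    """
    if not inputs:
        raise ValueError("no inputs: provide FrameStacks or LarvaSimSpecs")
    stacks = []
    for i, item in enumerate(inputs):
        if isinstance(item, LarvaSimSpec):
            spec = dataclasses.replace(
                item, seed=derive_seed(config.seed, f"larva:{i}:{item.seed}"))
            stk, _ = render_larva_video(spec)
        else:
            stk = item
        stacks.append(stk)

    rows, pct_traces = [], []
    for i, stk in enumerate(stacks):
        pct, ct, mobm = quantify_larva(stk, config)
        pct_traces.append(pct)
        rows.append({
            "animal": i,
            "genotype": genotypes[i] if genotypes else "all",
            "responded": ct.responded,
            "ct_duration": ct.ct_duration,
            "ct_magnitude": ct.ct_magnitude,
            "mobility_change": mobm.mobility_change,
            "immobility_duration": mobm.immobility_duration,
            "immobile": mobm.immobile,
            "unscorable_mobility": mobm.unscorable,
        })
    per_animal = pd.DataFrame(rows)

    bc = config.behavior
    curves = behavior.population_curves(
        pct_traces, threshold=bc.ct_threshold,
        min_duration=bc.ct_min_duration, window=bc.stimulus)

    statistics = None
    if control_labels:
        statistics = behavior.group_statistics(per_animal, control_labels)

    bundle = BehaviorBundle(per_animal=per_animal, curves=curves,
                            statistics=statistics, pct_traces=pct_traces,
                            config_hash=config.config_hash())
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_animal.to_csv(out / "per_animal_metrics.csv", index=False)
        pd.DataFrame({
            "t_s": curves.t,
            "instantaneous_pct_ct": curves.instantaneous_pct_ct,
            "cumulative_pct_ct": curves.cumulative_pct_ct,
        }).to_csv(out / "population_curves.csv", index=False)
        if statistics is not None:
            statistics.to_csv(out / "statistics.csv", index=False)
        io.write_manifest(out / "manifest.json", config,
                          {"n_animals": len(stacks),
                           "peak_pct_ct": curves.peak_pct_ct})
    return bundle


def run_imaging_pipeline(
    config: RunConfig,
    image: campari.TwoChannelImage | None = None,
    neuron_mask=None,
    traces: list[fluor.FluorTrace] | None = None,
    epochs: fluor.EpochSet | None = None,
    out_dir=None,
) -> ImagingBundle:
    """CaMPARI ratiometry (somata + Sholl) and ΔF/F epoch analysis."""
    cc, fc = config.campari, config.fluor
    roi_table = sholl = None
    if image is not None:
        rois = campari.find_somata(image, min_area=cc.min_soma_area,
                                   max_area=cc.max_soma_area,
                                   selem_radius=cc.selem_radius)
        roi_table = campari.roi_table(image, rois)
        if neuron_mask is not None and rois:
            sholl = campari.sholl_intensity(
                image, neuron_mask, rois[0].centroid,
                annulus_width=cc.annulus_width, step=cc.step)

    responses: list[fluor.EpochResponse] = []
    if traces:
        if epochs is None:
            raise ValueError("epoch definitions are required with traces")
        for tr in traces:
            d = fluor.dff(tr, epochs)
            responses.extend(fluor.epoch_stats(d, epochs, tail_s=fc.tail_s))

    bundle = ImagingBundle(roi_table=roi_table, sholl=sholl,
                           epoch_responses=responses,
                           config_hash=config.config_hash())
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if roi_table is not None:
            roi_table.to_csv(out / "roi_table.csv", index=False)
        if sholl is not None:
            pd.DataFrame({"radius_px": sholl.radius, "ratio": sholl.ratio,
                          "n_pixels": sholl.n_pixels}).to_csv(
                out / "sholl_profile.csv", index=False)
        if responses:
            pd.DataFrame([dataclasses.asdict(r) for r in responses]).to_csv(
                out / "epoch_responses.csv", index=False)
        io.write_manifest(out / "manifest.json", config, {})
    return bundle


def demo_larva_specs(n: int = 12, responder_fraction: float = 0.5,
                     seed: int = 0) -> tuple[list[LarvaSimSpec], list[bool]]:
    """A small demo cohort: half the animals carry a scheduled contraction."""
    n_resp = int(round(n * responder_fraction))
    specs, truth = [], []
    for i in range(n):
        responds = i < n_resp
        schedule = [(6.0, 8.5, -0.25)] if responds else []
        specs.append(LarvaSimSpec(n_frames=300, frame_rate=30.0,
                                  contraction_schedule=schedule, seed=seed + i))
        truth.append(responds)
    return specs, truth
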