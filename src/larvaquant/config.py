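"""Validated run configuration with paper-default parameters.

All defaults match the assay definitions: CT threshold -10%, minimum CT
duration 0.5 s, immobility threshold -25%, 5 s baseline / 5 s stimulus
optogenetic paradigm, 5-px Sholl annuli at 1-px steps, 15 s prestimulus
window, Euclidean/complete clustering cut at k = 5. Unknown keys are
rejected. A single top-level seed fans out to stable per-stage seeds so
stages can be re-run independently yet reproducibly.
"""

from __future__ import annotations

import hashlib
import json

import yaml
from pydantic import BaseModel, ConfigDict

__all__ = ["RunConfig", "load_config", "derive_seed"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class VideoConfig(_Strict):
    threshold_method: str = "huang"
    min_blob_px: int = 20
    selem_radius: int = 2
    frame_rate: float = 30.0


class BehaviorConfig(_Strict):
    ct_threshold: float = -10.0
    ct_min_duration: float = 0.5
    immobility_threshold: float = -25.0
    baseline: tuple[float, float] = (0.0, 5.0)
    stimulus: tuple[float, float] = (5.0, 10.0)


class CampariConfig(_Strict):
    annulus_width: int = 5
    step: int = 1
    selem_radius: int = 3
    min_soma_area: int = 30
    max_soma_area: int = 5000


class FluorConfig(_Strict):
    prestimulus_s: float = 15.0
    tail_s: float = 5.0


class ClusterConfig(_Strict):
    k: int = 5
    perplexity: float = 5.0
    linkage: str = "complete"
    metric: str = "euclidean"
    standardize: bool = True


class RunConfig(_Strict):
    seed: int = 0
    video: VideoConfig = VideoConfig()
    behavior: BehaviorConfig = BehaviorConfig()
    campari: CampariConfig = CampariConfig()
    fluor: FluorConfig = FluorConfig()
    cluster: ClusterConfig = ClusterConfig()

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from the run seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
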