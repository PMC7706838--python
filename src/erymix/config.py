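"""Pipeline configuration: one YAML file drives an end-to-end run.

A master seed is the only source of randomness; each stochastic stage gets
a child seed derived from it through a fixed counter-based spawn scheme
(numpy SeedSequence with a per-stage spawn key), so adding a stage never
perturbs the randomness of earlier stages.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .ruler import RulerSettings
from .simulate import SynthConfig

__all__ = ["PipelineConfig", "child_seed", "STAGE_SEED_KEYS"]

#: fixed counter per stochastic stage; append-only, never renumber
STAGE_SEED_KEYS = {
    "simulate": 0,
    "impute": 1,
    "anova": 2,
    "any20": 3,
    "ratios": 4,
    "controls": 5,
}


def child_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31) from the master seed."""
    key = STAGE_SEED_KEYS[stage]
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(key,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Everything a reproducible end-to-end run needs."""

    # input: either a synthetic-data config or a matrix TSV path
    synth: SynthConfig | None = field(default_factory=SynthConfig)
    matrix_path: str | None = None
    stages: tuple[str, ...] | None = None  # required when matrix_path is set
    curated_lists: dict[str, str] = field(default_factory=dict)  # name -> file
    histone_list: str | None = None

    # preprocessing
    min_fraction_per_stage: float = 0.75
    n_stages_required: int = 1
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    n_permutations: int = 250
    s0: float = 0.1
    n_clusters: int = 6

    # panels
    q_threshold: float = 0.01
    per_cluster: int = 3
    any20_size: int = 20

    # deconvolution benchmark
    signature_replicates: tuple[int, ...] = (2, 4)
    mixture_replicates: tuple[int, ...] = (1, 3)
    n_mixtures: int = 500
    retain_fraction: float = 0.90

    ruler: RulerSettings = field(default_factory=RulerSettings)
    seed: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.signature_replicates) & set(self.mixture_replicates)
        if overlap:
            raise ValueError(
                f"signature and mixture replicates overlap: {sorted(overlap)}"
            )
        if self.matrix_path is None and self.synth is None:
            raise ValueError("provide either a synthetic config or a matrix path")
        if self.matrix_path is not None and self.stages is None:
            raise ValueError("stage order must accompany an external matrix")

    def seed_for(self, stage: str) -> int:
        return child_seed(self.seed, stage)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if raw.get("synth") is not None:
            synth = dict(raw["synth"])
            for key in ("stages", "archetype_weights"):
                if key in synth and synth[key] is not None:
                    synth[key] = tuple(synth[key])
            if "marker_spec" in synth and synth["marker_spec"] is not None:
                synth["marker_spec"] = tuple(tuple(m) for m in synth["marker_spec"])
            raw["synth"] = SynthConfig(**synth)
        if raw.get("ruler") is not None and not isinstance(raw["ruler"], RulerSettings):
            raw["ruler"] = RulerSettings(**raw["ruler"])
        for key in ("stages", "signature_replicates", "mixture_replicates"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _plain(obj):
    """Recursively convert tuples/numpy scalars for clean YAML output."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
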