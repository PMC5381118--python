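"""Run configuration: a validated YAML schema with every protocol constant named.

Defaults carry the study conditions — 30-s PRTS steps, 300-s warm-up,
75/105/135 steps·min⁻¹ cadence levels, 0.01-Hz low-pass, 0.008-Hz harmonic
ceiling, 3.5 ml·min⁻¹·kg⁻¹ per MET — so nothing physiological is hard-coded
in pipeline code.  Unknown keys are rejected.
"""

from __future__ import annotations

import hashlib

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PRTSConfig(_Strict):
    degree: int = 3
    step_s: float = 30.0
    base_cadence: float = 105.0
    delta: float = 30.0
    warmup_s: float = 300.0


class FilterConfig(_Strict):
    cutoff_hz: float = 0.01
    order: int = 4


class ForestConfig(_Strict):
    n_trees: int = 100
    min_leaf: int = 5
    mtry: int | None = None  # None -> ceil(p/3)
    train_stride: int = 1    # keep every k-th training row (1-Hz rows are autocorrelated)


class DynamicsConfig(_Strict):
    f_max_hz: float = 0.008
    include_first: bool = True


class MetsConfig(_Strict):
    ml_per_met: float = 3.5


class SimConfig(_Strict):
    n_participants: int = 16
    tau_min_s: float = 20.0
    tau_max_s: float = 60.0
    noise_scale: float = 1.0
    breath_sampling: bool = True


class RunConfig(_Strict):
    seed: int = 7
    prts: PRTSConfig = Field(default_factory=PRTSConfig)
    filter: FilterConfig = Field(default_factory=FilterConfig)
    forest: ForestConfig = Field(default_factory=ForestConfig)
    dynamics: DynamicsConfig = Field(default_factory=DynamicsConfig)
    mets: MetsConfig = Field(default_factory=MetsConfig)
    sim: SimConfig = Field(default_factory=SimConfig)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML run configuration; missing file fields default."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data = {**data, **overrides}
    return RunConfig.model_validate(data)
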