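"""Run configuration: one YAML file drives the whole pipeline.

Unknown keys are rejected (every offending key reported at once, via
pydantic's aggregated validation) and each run writes a manifest echoing
the fully resolved configuration, so any artifact is reproducible from
its manifest alone.

Randomness: every stage derives its own stream from the single top-level
seed as ``SeedSequence([seed, crc32(stage_name)])``.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = ["RunConfig", "ConfigError", "load_config"]

STAGES = ("simulate", "score", "classify", "expression", "synergy", "report")


class ConfigError(ValueError):
    pass


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortBlock(_Block):
    n_cases: int = 33
    responder_fraction: float = 0.576
    ki67_mean_responder: float = 16.0
    ki67_mean_nonresponder: float = 26.0
    ki67_sd: float = 8.0
    rel_ki67_final_responder_range: tuple[float, float] = (0.0, 50.0)
    rel_ki67_final_nonresponder_range: tuple[float, float] = (70.0, 180.0)
    casp3_induction_fold_responder: float = 6.0
    timepoints: tuple[float, ...] = (0.0, 24.0, 48.0, 72.0)
    noise_cv: float = 0.05


class ExpressionBlock(_Block):
    n_targets: int = 92
    reference_genes: tuple[str, ...] = ("ACTB", "TBP", "HMBS")
    base_ct: float = 26.0
    base_ct_spread: float = 3.0
    ct_sd: float = 0.25
    effect_genes: dict[str, float] = Field(default_factory=lambda: {"BIRC5": 2.0})
    duplicate_wells: int = 2
    efficiency: float = 2.0
    max_missing_fraction: float = 0.5


class PlateBlock(_Block):
    doses_a: tuple[float, ...] | None = None
    doses_b: tuple[float, ...] | None = None
    hill_ec50_a: float = 0.0063
    hill_ec50_b: float = 0.063
    hill_slope_a: float = 1.0
    hill_slope_b: float = 1.0
    interaction: str = "synergistic"
    interaction_strength: float = 1.0
    f_neg_mean: float = 10000.0
    f_pos_mean: float = 1000.0
    replicate_wells: int = 2
    control_wells: int = 12
    noise_sd: float = 180.0


class ClassifyBlock(_Block):
    final_time: float | None = None  # None = latest shared timepoint
    denominator: str = "vehicle"  # "vehicle" (same-time control) or "t0" (baseline only)
    welch: bool = False


class SynergyBlock(_Block):
    delta: float = 0.0
    plot: bool = False


class RunConfig(_Block):
    seed: int = 0
    outdir: str = "exvivopharm_run"
    stages: tuple[str, ...] = STAGES
    use_clinical_fixture: bool = True
    cohort: CohortBlock = Field(default_factory=CohortBlock)
    expression: ExpressionBlock = Field(default_factory=ExpressionBlock)
    plate: PlateBlock = Field(default_factory=PlateBlock)
    classify: ClassifyBlock = Field(default_factory=ClassifyBlock)
    synergy: SynergyBlock = Field(default_factory=SynergyBlock)

    def model_post_init(self, _ctx) -> None:
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ConfigError(f"unknown stages {bad}; valid: {list(STAGES)}")


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config (or defaults) and apply flat overrides."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        node = data
        *parents, leaf = key.split(".")
        for part in parents:
            node = node.setdefault(part, {})
        node[leaf] = value
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        problems = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration: {problems}") from exc
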