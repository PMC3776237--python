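"""Run configuration: a single validated YAML file drives the pipeline.

Every method default is a named knob here: 500 kb flank, minimum haplotype
count 4, 90% concordance threshold, 1% window-growth plateau, 20 phaser
iterations, exclusion at 2 Mendelian conflicts.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator


class SimSection(BaseModel):
    """Simulator settings (mirrors :class:`msimpute.sim.SimConfig`)."""

    n_breeds: int = 6
    n_ancestral_haplotypes: int = 12
    fraction_shared: float = 0.25
    region_snps: int = 60
    window_snps: int = 30
    recomb_rate: float = 0.01
    ms_mutation_rate: float = 0.001
    ms_error_rate: float = 0.01
    rounding_error_rate: float = 0.005
    dropout_rate: float = 0.0
    n_founders: int = 60
    n_trios: int = 30
    markers: list[str] = Field(default_factory=lambda: ["MS1", "MS2"])


class RunConfig(BaseModel):
    """Validated configuration for the end-to-end pipeline."""

    out_dir: Path = Path("msimpute_out")
    seed: int = 0

    # marker map inputs (empty when simulating)
    snp_map: Path | None = None
    ms_map: Path | None = None

    flank_bp: int = 500_000
    taxon: str = "BT"
    window_sizes: list[int] = Field(default_factory=lambda: [20, 40, 50, 60])
    min_count: float = 4
    concordance: float = 0.90
    plateau_tol: float = 0.01

    phaser_iterations: int = 20
    phaser_restarts: int = 5

    backoff_floor: int = 20
    backoff_step: int = 10
    allow_ambiguous: bool = False

    tolerance_bp: int = 0
    exclude_at: int = 2

    simulate: SimSection = Field(default_factory=SimSection)
    holdout_fraction: float = 0.5

    @field_validator("taxon")
    @classmethod
    def _check_taxon(cls, v: str) -> str:
        if v not in ("BT", "BT+BI"):
            raise ValueError("taxon must be 'BT' or 'BT+BI'")
        return v

    @field_validator("window_sizes")
    @classmethod
    def _check_sizes(cls, v: list[int]) -> list[int]:
        if len(v) < 2 or any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("window_sizes must be >=2 strictly increasing values")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                yaml.safe_load(self.model_dump_json()), fh, sort_keys=True
            )
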