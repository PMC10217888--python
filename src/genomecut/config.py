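"""Run configuration shared by the pipeline and the CLI.

A flat set of tunables with the package defaults; YAML config files are
merged under explicit CLI flags, unknown keys are rejected, and every run
echoes its resolved configuration (plus a hash of it) into the output so a
result can always be traced back to the knobs that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .constructs import ConstructConfig, PrimerConfig


@dataclass
class RunConfig:
    # randomness
    seed: int = 0
    # synthetic genome (used when no input genome is given)
    n_genes: int = 250
    gc: float = 0.5
    region_size_targets: list[int] = field(
        default_factory=lambda: [12000, 15000, 11000, 18000, 13000, 16000, 14000]
    )
    # region finding
    min_region_bp: int = 10_000
    strict_over: bool = True
    span: str = "gene-extent"
    delete_beneficial: bool = False
    feature_type: str = "gene"
    # guide design
    pam: str = "TTN"
    spacer_len: int = 22
    guides_per_region: int = 2
    gc_min: float = 0.3
    gc_max: float = 0.7
    # construct design
    arm_bp: int = 1000
    tail_len: int = 20
    max_amplicon: int = 5000
    inner_offset: int = 300
    internal_product: int = 800
    outer_offset: int = 1200
    # planning
    start_marker: str = "Km"
    order: str = "input"
    n_steps: int = 7
    payload_flank_bp: int = 200
    # expression
    fc_threshold: float = 2.0
    alpha: float = 0.05
    pseudo_fpkm: float = 1.0
    segregated_below: float = 0.05
    failed_above: float = 0.5
    depth: int = 1_000_000
    dispersion: float = 0.1
    n_reps: int = 3

    def construct_config(self) -> ConstructConfig:
        return ConstructConfig(
            arm_bp=self.arm_bp,
            tail_len=self.tail_len,
            pam=self.pam,
            spacer_len=self.spacer_len,
            guides_per_region=self.guides_per_region,
            gc_range=(self.gc_min, self.gc_max),
            primers=PrimerConfig(max_amplicon=self.max_amplicon),
            inner_offset=self.inner_offset,
            internal_product=self.internal_product,
            outer_offset=self.outer_offset,
        )

    def breakers(self) -> frozenset[str]:
        base = {"essential", "unknown"}
        if not self.delete_beneficial:
            base.add("beneficial")
        return frozenset(base)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path: str, overrides: dict | None = None) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        data.update({k: v for k, v in (overrides or {}).items() if v is not None})
        return cls.from_mapping(data)


__all__ = ["RunConfig"]
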