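"""Pipeline configuration: every tunable threshold in one place.

All constants that drive the mining pipeline live here with their
defaults — the two greedy identity tiers, the tree-dissection depth, the
consensus/homogeneity thresholds, the neighborhood and directon geometry,
the precursor candidate rules, and the association reporting thresholds.
The effective configuration is serialized verbatim into every run
manifest, and a flat YAML-compatible key-value file round-trips through
``PipelineConfig.from_yaml`` / ``to_yaml``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # homolog clustering
    tier1_identity: float = 0.9
    tier2_identity: float = 0.5
    depth_cutoff: float = -math.log(0.01) / 2  # ~2.303, from the 0.01 ratio
    identity_kernel: str = "quick"
    # consensus and alignment filtering
    h_consensus: float = 0.5
    filter_max_gap: float = 0.5
    filter_min_homog: float = 0.1
    # gap model (BLAST-style affine defaults)
    gap_open: int = 11
    gap_extend: int = 1
    score_floor: float = 1.0
    # neighborhoods and directons
    neighborhood_window: int = 10
    directon_gap: int = 100
    # precursor candidate rules
    candidate_max_rank: int = 2
    max_precursor_length: int = 150
    length_majority: float = 0.5
    leader_window: int = 30
    hydrophobic_set: str = "ACFILMVWY"
    small_set: str = "GASCE"
    require_gly: bool = False
    reference_identity: float = 0.5
    reference_coverage: float = 0.5
    # association reporting
    assoc_min_loci: int = 20
    assoc_min_wfreq: float = 0.01
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "tier1_identity",
            "tier2_identity",
            "h_consensus",
            "filter_max_gap",
            "filter_min_homog",
            "length_majority",
            "reference_identity",
            "reference_coverage",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth_cutoff < 0:
            raise ValueError("depth_cutoff must be non-negative")
        if self.assoc_min_wfreq < 0 or self.assoc_min_wfreq > 1:
            raise ValueError("assoc_min_wfreq must be in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)
        )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
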