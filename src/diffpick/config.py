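"""Run configuration: a flat, schema-validated key/value structure.

Loadable from YAML; every CLI flag overrides its config key. Defaults encode
the pipeline's documented parameter choices (k=31 assembly / k=21 bait
mapping, matched-k-mer fractions 0.5 for DS reads and 0.3 for chimera-rich
baits, 100x subsampling target).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    seed: int = 0
    assembly_k: int = 31
    bait_k: int = 21
    min_kmer_count: int = 2
    tip_max_len: int | None = None  # None -> 2k
    min_frac_ds: float = 0.5
    min_frac_bait: float = 0.3
    min_bait_reads: int = 1
    genome_size_estimate: int = 100_000
    target_cov: float = 100.0
    trim_platform_b: bool = True
    trim_q: int = 20
    trim_window_frac: float = 0.1
    trim_min_length: int = 20

    def __post_init__(self) -> None:
        if self.assembly_k % 2 == 0 or not 15 <= self.assembly_k <= 31:
            raise ValueError("assembly_k must be odd and in [15, 31]")
        if self.bait_k % 2 == 0 or not 15 <= self.bait_k <= 31:
            raise ValueError("bait_k must be odd and in [15, 31]")
        for name in ("min_frac_ds", "min_frac_bait", "trim_window_frac"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.min_kmer_count < 1 or self.min_bait_reads < 1:
            raise ValueError("min_kmer_count and min_bait_reads must be >= 1")
        if self.genome_size_estimate <= 0 or self.target_cov <= 0:
            raise ValueError("genome_size_estimate and target_cov must be positive")
        if self.trim_q < 0 or self.trim_min_length < 1:
            raise ValueError("trim_q must be >= 0 and trim_min_length >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config file; unknown keys are rejected, overrides win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
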