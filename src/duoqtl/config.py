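"""Pipeline configuration: one flat, strictly validated parameter set.

Defaults are the analysis defaults used throughout the package: 50-SNP
bins, 20x minimum phasing depth, a 0.9 phase-consistency rule, 0.75/1.25
dosage cuts, 1,000 permutations and alpha 0.05. Unknown keys are rejected
so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # simulation scale
    n_chrom: int = 5
    chrom_len: int = 2_000_000
    het_density: float = 5e-4
    n_lines: int = 343
    deep_n: int = 122
    recomb_per_chrom: float = 1.5
    indel_rate: float = 2.5
    indel_min_size: int = 250_000
    indel_max_size: int = 750_000
    p_deletion: float = 0.665
    low_depth: float = 0.5
    deep_depth: float = 30.0
    error_rate: float = 0.005
    cov_bin_size: int = 50_000
    mean_bin_cov: float = 250.0
    # analysis parameters
    bin_size: int = 50
    depth_min: int = 20
    consistency: float = 0.9
    min_concordance: float = 0.9
    max_switches: int = 5
    low_cut: float = 0.75
    high_cut: float = 1.25
    min_run: int = 2
    n_perm: int = 1000
    alpha: float = 0.05
    min_n: int = 20
    min_minor: int = 5
    min_group: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.n_chrom >= 1, "n_chrom >= 1"),
            (self.chrom_len >= 10**5, "chrom_len >= 1e5"),
            (self.het_density > 0, "het_density > 0"),
            (self.n_lines >= 1, "n_lines >= 1"),
            (1 <= self.deep_n <= self.n_lines, "1 <= deep_n <= n_lines"),
            (0 <= self.p_deletion <= 1, "p_deletion in [0, 1]"),
            (self.bin_size >= 1, "bin_size >= 1"),
            (self.depth_min >= 1, "depth_min >= 1"),
            (0 < self.consistency <= 1, "consistency in (0, 1]"),
            (self.low_cut < self.high_cut, "low_cut < high_cut"),
            (self.min_run >= 1, "min_run >= 1"),
            (self.n_perm >= 1, "n_perm >= 1"),
            (0 < self.alpha < 1, "alpha in (0, 1)"),
            (0 <= self.error_rate < 0.25, "error_rate in [0, 0.25)"),
        ]
        bad = [msg for ok, msg in checks if not ok]
        if bad:
            raise ValueError("invalid configuration: " + "; ".join(bad))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text
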