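"""Pipeline configuration.

All tunable thresholds of the discovery pipeline live in one flat dataclass so
that a run is fully described by (inputs, config, seed).  The defaults encode
the published screen: candidate hits are kept when the E-value is below 0.01,
at most the top three hits per query are considered, and a precursor must be
shorter than 300 amino acids to pass screening.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates its contract."""


@dataclass
class PipelineConfig:
    # homology mining
    e_threshold: float = 0.01
    top_k: int = 3
    matrix: str = "BLOSUM62"
    gap_open: int = 11      # cost of a gap of length 1
    gap_extend: int = 1     # additional cost per further gapped residue
    karlin_lambda: float = 0.267   # gapped BLOSUM62 Karlin-Altschul constants
    karlin_k: float = 0.041
    min_segment_len: int = 6       # skip inter-stop segments shorter than this

    # precursor screening
    max_precursor_len: int = 300

    # prohormone cleavage rules
    accept_kr: bool = True
    accept_rr: bool = True
    accept_rk: bool = False
    accept_kk: bool = False
    accept_mono_r: bool = True
    accept_multibasic: bool = True
    reject_site_before_pro: bool = True
    # ignore -4/-6/-8 basics that sit inside an accepted site or the signal
    # peptide (they are removed before the monobasic context exists)
    mono_ignore_consumed_basics: bool = True

    # post-translational modifications
    amidation: bool = True
    pyroglu_gln: bool = True
    pyroglu_glu: bool = False
    sulfation_window: int = 5
    acidic_min: int = 2

    # reporting
    dedupe_peptides: bool = False

    seed: int = 0

    def __post_init__(self) -> None:
        if self.e_threshold <= 0:
            raise ConfigError("e_threshold must be > 0")
        if self.top_k < 1:
            raise ConfigError("top_k must be >= 1")
        if self.max_precursor_len < 1:
            raise ConfigError("max_precursor_len must be >= 1")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ConfigError("gap penalties must be non-negative costs")
        if self.sulfation_window < 0 or self.acidic_min < 0:
            raise ConfigError("sulfation parameters must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
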