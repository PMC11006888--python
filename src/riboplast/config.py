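"""Pipeline configuration: a single YAML/JSON mapping, validated strictly.

Unknown keys are rejected (typo safety) and every numeric parameter is range
checked before any work starts. CLI flags override config-file keys; the
effective merged configuration is written to the run manifest.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError
from .io import DEFAULT_LENGTH_MAX, DEFAULT_LENGTH_MIN
from .pausing import DEFAULT_TUNNEL_LEN_CODONS, PeakParams
from .quantify import DEFAULT_MIN_READS, RATIO_MODES
from .simulate import P_SITE_OFFSET_NT


@dataclasses.dataclass
class PipelineConfig:
    """Everything a pipeline run depends on, in one validated object."""

    # paths
    genome: str | None = None
    gff: str | None = None
    sample_sheet: str | None = None
    outdir: str = "riboplast_out"
    # filters
    length_min: int = DEFAULT_LENGTH_MIN
    length_max: int = DEFAULT_LENGTH_MAX
    min_reads: int = DEFAULT_MIN_READS
    # offsets
    psite_offset: int = P_SITE_OFFSET_NT
    profile_offset: int = P_SITE_OFFSET_NT
    # peak parameters
    smooth_codons: int = 3
    min_prominence_frac: float = 0.25
    min_sep_codons: int = 9
    top_k: int = 6
    match_window: int = 1
    # ratios / tunnel
    ratio_mode: str = "mean_ref"
    tunnel_len_codons: int = DEFAULT_TUNNEL_LEN_CODONS
    # simulation / reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.length_min <= self.length_max):
            raise ConfigError(
                f"length filter invalid: need 1 <= length_min <= length_max, "
                f"got [{self.length_min}, {self.length_max}]"
            )
        if self.min_reads < 0:
            raise ConfigError("min_reads must be >= 0")
        if self.psite_offset < 0 or self.profile_offset < 0:
            raise ConfigError("offsets must be >= 0")
        if self.ratio_mode not in RATIO_MODES:
            raise ConfigError(f"ratio_mode must be one of {RATIO_MODES}")
        if self.tunnel_len_codons < 0:
            raise ConfigError("tunnel_len_codons must be >= 0")
        # delegates peak-parameter range checks
        self.peak_params()

    def peak_params(self) -> PeakParams:
        return PeakParams(
            smooth_codons=self.smooth_codons,
            min_prominence_frac=self.min_prominence_frac,
            min_sep_codons=self.min_sep_codons,
            top_k=self.top_k,
            match_window_codons=self.match_window,
        )

    @classmethod
    def field_names(cls) -> set[str]:
        return {f.name for f in dataclasses.fields(cls)}

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "PipelineConfig":
        unknown = set(mapping) - cls.field_names()
        if unknown:
            raise ConfigError(
                f"unknown config key(s): {sorted(unknown)}; "
                f"valid keys: {sorted(cls.field_names())}"
            )
        return cls(**mapping)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)  # YAML is a superset of JSON
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_mapping(data)

    def merged(self, overrides: Mapping[str, Any]) -> "PipelineConfig":
        """New config with non-None overrides applied (CLI flags win)."""
        data = dataclasses.asdict(self)
        for key, value in overrides.items():
            if value is not None:
                if key not in data:
                    raise ConfigError(f"unknown override key {key!r}")
                data[key] = value
        return PipelineConfig(**data)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
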