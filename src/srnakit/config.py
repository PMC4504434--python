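"""Pipeline configuration: every stage threshold in one TOML-backed object.

The defaults mirror the parameter set of the plant small-RNA workbench this
pipeline reproduces: 16-30 nt reads, at most 16 genome hits, 100-nt folding
flanks, 60-nt minimum hairpin, <=4 duplex mismatches, <=1 asymmetric bulge
of <=2 nt, |MFEI| >= 0.85, randfold p <= 0.1, 21-nt phase with an 11-cycle
search window, and a 3.0 target-penalty threshold.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class PreprocessConfig:
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"  # TruSeq small-RNA 3' adapter
    min_overlap: int = 7
    quality_floor: int = 13          # bases below this Phred score are "low quality"
    max_low_quality: int = 6         # reject reads with more than this many
    min_length: int = 16
    max_length: int = 30
    keep_untrimmed: bool = False     # discard reads with no detectable adapter


@dataclass
class MappingConfig:
    max_hits: int = 16


@dataclass
class MirnaConfig:
    flank: int = 100
    min_hairpin: int = 60
    max_duplex_mismatches: int = 4
    max_bulge_count: int = 1
    max_bulge_size: int = 2
    min_abs_mfei: float = 0.85
    enable_mfei: bool = True
    randfold_shuffles: int = 99
    randfold_cutoff: float = 0.1
    enable_randfold: bool = True
    min_abundance: int = 1
    max_ref_mismatches: int = 3      # known/conserved classification
    family_mismatches: int = 2       # single-linkage family clustering
    novel_prefix: str = "sbi"


@dataclass
class ExpressionConfig:
    alpha: float = 0.05              # Figure-legend threshold; 0.01 also in use
    min_tpm: float = 1.0
    min_abs_log2fc: float = 1.0


@dataclass
class PhasingConfig:
    phase: int = 21
    cycles: int = 11
    min_abundance: int = 2
    p_threshold: float = 1e-4
    tas_pad: int = 10                # pads the 231-nt register window to 251 bp


@dataclass
class TargetConfig:
    max_score: float = 3.0
    seed_start: int = 2              # penalties doubled in positions 2..13
    seed_end: int = 13
    wobble_penalty: float = 0.5
    mismatch_penalty: float = 1.0
    central_start: int = 9           # central mismatch -> translational inhibition
    central_end: int = 11


@dataclass
class PathsConfig:
    genome: str = ""
    libraries: list[str] = field(default_factory=list)
    contaminants: str = ""
    same_species_ref: str = ""
    other_species_ref: str = ""
    transcripts: str = ""
    out_dir: str = "run_out"


_SECTIONS = {
    "preprocess": PreprocessConfig,
    "mapping": MappingConfig,
    "mirna": MirnaConfig,
    "expression": ExpressionConfig,
    "phasing": PhasingConfig,
    "targets": TargetConfig,
    "paths": PathsConfig,
}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    mapping: MappingConfig = field(default_factory=MappingConfig)
    mirna: MirnaConfig = field(default_factory=MirnaConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    phasing: PhasingConfig = field(default_factory=PhasingConfig)
    targets: TargetConfig = field(default_factory=TargetConfig)
    paths: PathsConfig = field(default_factory=PathsConfig)

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls()
        for key, value in raw.items():
            if key == "seed":
                cfg.seed = int(value)
            elif key in _SECTIONS:
                section_cls = _SECTIONS[key]
                known = {f.name for f in dataclasses.fields(section_cls)}
                unknown = set(value) - known
                if unknown:
                    raise ConfigError(
                        f"unknown key(s) in [{key}]: {sorted(unknown)}"
                    )
                setattr(cfg, key, section_cls(**value))
            else:
                raise ConfigError(f"unknown config section or key: {key!r}")
        return cfg

    def to_toml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(self.dumps())

    def dumps(self) -> str:
        lines = [f"seed = {self.seed}", ""]
        for name in _SECTIONS:
            lines.append(f"[{name}]")
            for f in dataclasses.fields(getattr(self, name)):
                lines.append(f"{f.name} = {_fmt(getattr(getattr(self, name), f.name))}")
            lines.append("")
        return "\n".join(lines)


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        return '"' + value.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(value, list):
        return "[" + ", ".join(_fmt(v) for v in value) + "]"
    raise ConfigError(f"cannot serialise {type(value).__name__} to TOML")
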