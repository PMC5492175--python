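"""Pipeline configuration: schema, defaults and validation.

``validate_config`` resolves defaults and collects *every* violated
constraint rather than stopping at the first, so a bad config is fixable in
one pass.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .annotation import DEFAULT_EXCLUSION_CLASSES


class ConfigError(ValueError):
    """Raised with the full list of configuration problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors))


class SampleConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    barcode: str
    group: str
    role: Literal["protein", "reference", "background"]
    model: Literal["tss_peaked", "body", "uniform", "junction"] = "uniform"
    n_molecules: int = Field(default=8000, gt=0)
    spliced_fraction: float = Field(default=0.25, ge=0.0, le=1.0)
    weight_overrides: dict[str, float] = Field(default_factory=dict)
    dup_geom_p: float = Field(default=0.55, gt=0.0, le=1.0)
    background_fraction: float = Field(default=0.02, ge=0.0, le=1.0)
    low_complexity_fraction: float = Field(default=0.005, ge=0.0, le=1.0)


class GenomeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    chrom_lengths: dict[str, int] = Field(
        default_factory=lambda: {"chrI": 60_000, "chrII": 45_000}
    )
    class_counts: Optional[dict[str, int]] = None
    gap_range: tuple[int, int] = (80, 300)


class PathsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    genome: Optional[str] = None
    annotation: Optional[str] = None
    fastq: Optional[str] = None
    alignments: dict[str, str] = Field(default_factory=dict)


class ParamsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    tag_length: int = Field(default=3, ge=1)
    barcode_mismatch: int = Field(default=0, ge=0)
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    max_uncalled: int = Field(default=3, ge=0)
    quality_threshold: int = Field(default=30, ge=0)
    min_length: int = Field(default=17, ge=1)
    min_overlap: int = Field(default=3, ge=1)
    lowcomp_before_collapse: bool = True
    min_overhang: int = Field(default=3, ge=1)
    pseudocount: float = 5.0
    cv_max: float = Field(default=0.5, gt=0)
    rpkm_min: float = Field(default=30.0, ge=0)
    exclusion_classes: list[str] = Field(
        default_factory=lambda: list(DEFAULT_EXCLUSION_CLASSES)
    )
    tss_window: tuple[int, int] = (-100, 1500)
    pa_window: tuple[int, int] = (-1500, 100)
    flank: int = Field(default=100, ge=0)
    metagene_classes: list[str] = Field(default_factory=lambda: ["mRNA"])
    match_classes: list[str] = Field(default_factory=lambda: ["mRNA", "SUT", "CUT"])
    match_tolerance: float = Field(default=0.05, gt=0)
    match_window: int = Field(default=300, gt=0)


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    samples: list[SampleConfig]
    simulate: Optional[GenomeConfig] = None
    paths: PathsConfig = Field(default_factory=PathsConfig)
    params: ParamsConfig = Field(default_factory=ParamsConfig)

    def groups(self, role: str | None = None) -> dict[str, list[SampleConfig]]:
        out: dict[str, list[SampleConfig]] = {}
        for s in self.samples:
            if role is None or s.role == role:
                out.setdefault(s.group, []).append(s)
        return out

    @property
    def reference_group(self) -> str:
        return next(iter(self.groups("reference")))


def _cross_checks(cfg: PipelineConfig) -> list[str]:
    errors: list[str] = []
    names = [s.name for s in cfg.samples]
    if len(set(names)) != len(names):
        errors.append("sample names must be unique")
    barcodes = [s.barcode for s in cfg.samples]
    if len(set(barcodes)) != len(barcodes):
        errors.append("sample barcodes must be distinct")
    if len({len(b) for b in barcodes}) > 1:
        errors.append("sample barcodes must be equal length")
    for s in cfg.samples:
        if set(s.barcode) - set("ACGT"):
            errors.append(f"barcode for sample {s.name} contains non-ACGT characters")
    ref_groups = cfg.groups("reference")
    if cfg.groups("protein") and len(ref_groups) != 1:
        errors.append(
            f"enrichment needs exactly one reference-role group, found {len(ref_groups)}"
        )
    if cfg.params.pseudocount <= 0:
        errors.append("pseudocount must be > 0")
    if cfg.simulate is None:
        for key in ("genome", "annotation", "fastq"):
            if getattr(cfg.paths, key) is None:
                errors.append(f"missing required path: paths.{key} (no simulate section)")
        for s in cfg.samples:
            if s.name not in cfg.paths.alignments:
                errors.append(f"missing alignments path for sample {s.name}")
    declared = [p for p in (cfg.paths.genome, cfg.paths.annotation, cfg.paths.fastq) if p]
    declared += list(cfg.paths.alignments.values())
    if len(set(declared)) != len(declared):
        errors.append("referenced paths must be distinct")
    return errors


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Parse + validate a config (YAML path or dict); collect all errors."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = source
    errors: list[str] = []
    try:
        cfg = PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"])
            errors.append(f"{loc}: {err['msg']}")
        raise ConfigError(errors) from None
    errors = _cross_checks(cfg)
    if errors:
        raise ConfigError(errors)
    return cfg
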