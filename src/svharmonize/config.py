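"""Pipeline configuration: every stage threshold with its published default.

Configs are strict pydantic models (unknown keys are rejected before any
stage runs) and round-trip losslessly through YAML/JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .strandseq import SegmentationParams
from .synthetic import CallerProfile


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GenomeConfig(_Strict):
    n_chroms: int = 2
    chrom_length: int = 2_500_000
    tr_density: float = 0.05
    snv_spacing_mean: float = 1200.0


class InversionSimConfig(_Strict):
    n: int = 12
    size_min: int = 10_000
    size_max: int = 200_000
    hom_fraction: float = 0.33
    complex_fraction: float = 0.30


class CompositeConfig(_Strict):
    read_density: float = 50.0  # reads per kb, both haplotypes pooled
    orientation_error: float = 0.02
    haplotag_rate: float = 0.12


class SVSimConfig(_Strict):
    n: int = 250
    size_min: int = 50
    size_max: int = 10_000
    ins_fraction: float = 0.4
    hom_fraction: float = 0.33


class CallerProfileConfig(_Strict):
    name: str
    sensitivity: float = 1.0
    fp_rate: float = 0.0
    breakpoint_jitter_sd: float = 0.0
    length_bias: float = 1.0
    detectable_types: list[str] = Field(default_factory=lambda: ["DEL", "INS", "DUP", "INV"])

    def to_profile(self) -> CallerProfile:
        return CallerProfile(
            self.name, self.sensitivity, self.fp_rate, self.breakpoint_jitter_sd,
            self.length_bias, tuple(self.detectable_types),
        )


def _default_il_callers() -> list[CallerProfileConfig]:
    # three short-read algorithm families: split-read, paired-end, read-depth
    return [
        CallerProfileConfig(name="srcall", sensitivity=0.70, fp_rate=1.0,
                            breakpoint_jitter_sd=5.0, detectable_types=["DEL", "INS"]),
        CallerProfileConfig(name="pecall", sensitivity=0.65, fp_rate=2.0,
                            breakpoint_jitter_sd=30.0, detectable_types=["DEL", "INS"]),
        CallerProfileConfig(name="rdcall", sensitivity=0.50, fp_rate=3.0,
                            breakpoint_jitter_sd=150.0, detectable_types=["DEL"]),
    ]


def _default_inv_platforms() -> list[CallerProfileConfig]:
    return [
        CallerProfileConfig(name="IL", sensitivity=0.6, fp_rate=0.05,
                            breakpoint_jitter_sd=50.0, detectable_types=["INV"]),
        CallerProfileConfig(name="PB", sensitivity=0.7, fp_rate=0.05,
                            breakpoint_jitter_sd=10.0, detectable_types=["INV"]),
        CallerProfileConfig(name="liWGS", sensitivity=0.5, fp_rate=0.05,
                            breakpoint_jitter_sd=500.0, detectable_types=["INV"]),
        CallerProfileConfig(name="BNG", sensitivity=0.3, fp_rate=0.02,
                            breakpoint_jitter_sd=2000.0, detectable_types=["INV"]),
    ]


def _default_pb_methods() -> list[CallerProfileConfig]:
    return [
        CallerProfileConfig(name="phased_sv", sensitivity=0.95, fp_rate=0.3,
                            breakpoint_jitter_sd=5.0, detectable_types=["DEL", "INS"]),
        CallerProfileConfig(name="mspac", sensitivity=0.90, fp_rate=0.5,
                            breakpoint_jitter_sd=30.0, detectable_types=["DEL", "INS"]),
    ]


class EvidenceConfig(_Strict):
    support_mean_true: float = 20.0
    support_mean_false: float = 1.0
    bng_rel_error_sd: float = 0.05
    base_depth: float = 40.0
    bng_fraction: float = 0.6


class SegmentationConfig(_Strict):
    window_reads: int = 250
    window_step: int = 50
    nonref_trigger: float = 0.15
    background: float = 0.02
    min_genotype_reads: int = 50
    min_phased_reads: int = 10
    hap_lo: float = 0.25
    hap_hi: float = 0.75
    reject_alpha: float | None = None
    refine_window: int = 25
    refine_trigger: float = 0.25

    def to_params(self) -> SegmentationParams:
        return SegmentationParams(**self.model_dump())


class ThresholdConfig(_Strict):
    ro_min: float = 0.5
    regenotype_min_reads: int = 25
    tr_max: float = 0.9
    ci_min_matches: int = 30
    ci_default_halfwidth: int = 500
    qc_max_len: int = 1_000_000
    pbrc_validate_min_support: int = 5  # cluster validation: > 4 supporting reads
    pbrc_unify_min: int = 3  # unified-callset inclusion: PBRC > 3
    f_max: float = 0.1
    depth_max_min_cov: float = 30.0
    il_max_depth: float = 25.0
    mspac_min_dist: int = 10_000
    ro_hap_non_tr: float = 0.10
    ro_hap_tr: float = 0.50
    tr_max_cluster: int = 5


class PipelineConfig(_Strict):
    seed: int = 1
    genome: GenomeConfig = Field(default_factory=GenomeConfig)
    inversions: InversionSimConfig = Field(default_factory=InversionSimConfig)
    composite: CompositeConfig = Field(default_factory=CompositeConfig)
    svs: SVSimConfig = Field(default_factory=SVSimConfig)
    il_callers: list[CallerProfileConfig] = Field(default_factory=_default_il_callers)
    inv_platforms: list[CallerProfileConfig] = Field(default_factory=_default_inv_platforms)
    pb_methods: list[CallerProfileConfig] = Field(default_factory=_default_pb_methods)
    evidence: EvidenceConfig = Field(default_factory=EvidenceConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    thresholds: ThresholdConfig = Field(default_factory=ThresholdConfig)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)
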