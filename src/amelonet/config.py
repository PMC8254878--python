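"""Pipeline-wide configuration.

All thresholds of the filtration cascade, the co-expression network, the
sub-network extraction and the GO enrichment live in one dataclass so a run
is fully described by a single object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict


@dataclass
class PipelineConfig:
    """Thresholds and knobs for the whole analysis.

    Quality control (somatic calling)
    ---------------------------------
    qc_p_max : Fisher-test p-value must be strictly below this (default 0.05).
    qc_depth_min : minimum read depth required in *both* tissues (10).
    qc_normal_alt_max : maximum alt-supporting reads tolerated in normal (1).
    qc_tumor_alt_min : minimum alt-supporting reads required in tumor (3).
    qc_normal_vaf_max : maximum variant allele fraction in normal (0.03).
    qc_tumor_vaf_min : minimum variant allele fraction in tumor (0.05).

    Annotation filters
    ------------------
    rare_freq_max : a variant is rare iff every East-Asian population
        frequency is strictly below this (0.005); missing = never observed.
    cadd_min : CADD-phred score counted as damaging when >= this (30).
    severe_tool_min : number of predictors (CADD, SIFT, PolyPhen-2) that must
        call a missense variant damaging for it to be severe (2).

    Co-expression network
    ---------------------
    soft_power : soft-threshold exponent for the unsigned adjacency (12).
    tom_edge_min : TOM threshold for sub-network edges (0.15).
    cut_height : static cut height on the 1 - TOM dendrogram (0.4).
    min_module_size : clusters smaller than this become "grey" (30).

    GO enrichment
    -------------
    go_min_genes : terms with fewer annotated genes are not tested (10).
    go_fdr_max : BH-adjusted significance threshold (0.05).

    fisher_alternative : "greater" (tumor alt-enrichment, default) or
        "two-sided".
    rng_seed : seed for every stochastic step.
    """

    qc_p_max: float = 0.05
    qc_depth_min: int = 10
    qc_normal_alt_max: int = 1
    qc_tumor_alt_min: int = 3
    qc_normal_vaf_max: float = 0.03
    qc_tumor_vaf_min: float = 0.05
    rare_freq_max: float = 0.005
    cadd_min: float = 30.0
    severe_tool_min: int = 2
    soft_power: int = 12
    tom_edge_min: float = 0.15
    cut_height: float = 0.4
    min_module_size: int = 30
    go_min_genes: int = 10
    go_fdr_max: float = 0.05
    fisher_alternative: str = "greater"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "qc_p_max": self.qc_p_max,
            "qc_normal_vaf_max": self.qc_normal_vaf_max,
            "qc_tumor_vaf_min": self.qc_tumor_vaf_min,
            "rare_freq_max": self.rare_freq_max,
            "tom_edge_min": self.tom_edge_min,
            "cut_height": self.cut_height,
            "go_fdr_max": self.go_fdr_max,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        ints = {
            "qc_depth_min": self.qc_depth_min,
            "qc_normal_alt_max": self.qc_normal_alt_max,
            "qc_tumor_alt_min": self.qc_tumor_alt_min,
            "severe_tool_min": self.severe_tool_min,
            "soft_power": self.soft_power,
            "min_module_size": self.min_module_size,
            "go_min_genes": self.go_min_genes,
        }
        for name, value in ints.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if self.fisher_alternative not in ("greater", "two-sided"):
            raise ValueError(
                "fisher_alternative must be 'greater' or 'two-sided'"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
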