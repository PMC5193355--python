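"""Pipeline configuration: thresholds, windows, radii and field mappings.

All parameters carry the defaults of the analysis this package
operationalizes (quality >= 20, depth < 100, either-strand alt support > 3,
1-49 bp; 1 kb flanking windows, 2 bp splice window; 5 cM peak radius, 5 Mb
GWAS radius, Fisher alpha 0.05) and can be overridden from a YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import yaml

from .errors import ConfigError
from .evidence import DEFAULT_TRAIT_LABELS
from .variants import CallQualityThresholds

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    thresholds: CallQualityThresholds = field(default_factory=CallQualityThresholds)
    upstream_window: int = 1000
    downstream_window: Optional[int] = None  # None -> same as upstream
    splice_window: int = 2
    peak_radius_cM: float = 5.0
    gwas_radius_bp: int = 5_000_000
    enrichment_alpha: float = 0.05
    trait_labels: tuple = tuple(sorted(DEFAULT_TRAIT_LABELS))
    strand_field: str = "DP4"  # DP4-style INFO field name mapping

    def __post_init__(self):
        if self.peak_radius_cM <= 0 or self.gwas_radius_bp <= 0:
            raise ConfigError("radii must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(open(path)) or {}
        known = {f.name for f in fields(cls)}
        thr_kwargs = raw.pop("thresholds", {}) or {}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "trait_labels" in raw:
            raw["trait_labels"] = tuple(raw["trait_labels"])
        return cls(thresholds=CallQualityThresholds(**thr_kwargs), **raw)

    def to_dict(self) -> dict:
        return {
            "thresholds": vars(self.thresholds).copy()
            if hasattr(self.thresholds, "__dict__")
            else {
                "min_quality": self.thresholds.min_quality,
                "max_depth": self.thresholds.max_depth,
                "min_strand_alt_support": self.thresholds.min_strand_alt_support,
                "min_length": self.thresholds.min_length,
                "max_length": self.thresholds.max_length,
            },
            "upstream_window": self.upstream_window,
            "downstream_window": self.downstream_window,
            "splice_window": self.splice_window,
            "peak_radius_cM": self.peak_radius_cM,
            "gwas_radius_bp": self.gwas_radius_bp,
            "enrichment_alpha": self.enrichment_alpha,
            "trait_labels": list(self.trait_labels),
            "strand_field": self.strand_field,
        }
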