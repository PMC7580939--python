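"""Pipeline configuration: the analysis thresholds and file paths.

Defaults are the cutoffs used throughout the analysis: DEG filter
(BH-adjusted p <= 0.05, |log2FC| >= 2, baseMean >= 10, prefilter counts
>= 10 in >= 5 samples), enrichment FDR <= 0.1, gene-significance and
module-membership p <= 0.05, cluster-difference FDR <= 0.05, stability
selection frequency 0.6 with PFER 2, and module-merge correlation 0.30.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import yaml

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Out-of-range or malformed configuration value."""


# (name, default, low, high) -- inclusive validity range
_THRESHOLDS = [
    ("deg_padj", 0.05, 0.0, 1.0),
    ("deg_abs_l2fc", 2.0, 0.0, float("inf")),
    ("deg_basemean", 10.0, 0.0, float("inf")),
    ("prefilter_count", 10, 0, float("inf")),
    ("prefilter_samples", 5, 0, float("inf")),
    ("gsea_fdr", 0.1, 0.0, 1.0),
    ("gs_p", 0.05, 0.0, 1.0),
    ("mm_p", 0.05, 0.0, 1.0),
    ("cluster_fdr", 0.05, 0.0, 1.0),
    ("stab_freq", 0.6, 0.5, 1.0),
    ("stab_pfer", 2.0, 0.0, float("inf")),
    ("merge_cor", 0.30, 0.0, 1.0),
]


@dataclass
class PipelineConfig:
    seed: int = 0
    deg_padj: float = 0.05
    deg_abs_l2fc: float = 2.0
    deg_basemean: float = 10.0
    prefilter_count: int = 10
    prefilter_samples: int = 5
    gsea_fdr: float = 0.1
    gs_p: float = 0.05
    mm_p: float = 0.05
    cluster_fdr: float = 0.05
    stab_freq: float = 0.6
    stab_pfer: float = 2.0
    merge_cor: float = 0.30
    soft_power: int | str = "auto"  # integer or "auto"
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, _default, lo, hi in _THRESHOLDS:
            val = getattr(self, name)
            if not lo <= val <= hi:
                raise ConfigError(
                    f"threshold {name!r} = {val} outside valid range [{lo}, {hi}]"
                )
        if self.soft_power != "auto":
            if not isinstance(self.soft_power, int) or self.soft_power < 1:
                raise ConfigError(
                    f"soft_power must be a positive integer or 'auto', "
                    f"got {self.soft_power!r}"
                )
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigError(f"seed must be a non-negative integer, got {self.seed!r}")


def load_config(path: str | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config, applying defaults for absent keys.

    Unknown keys raise; the full effective configuration is logged.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError(f"config file {path} is not a mapping")
            data.update(loaded)
    data.update(overrides)
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    log.info("effective config: %s", cfg)
    return cfg
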