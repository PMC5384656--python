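"""Run configuration: documented keys, defaults, and YAML loading.

The configuration is a flat key-value file (YAML).  Every analysis threshold
the pipeline applies is represented here so a run is auditable: the preterm
gestational-age cutoff (37 weeks), the CADD deleteriousness cutoff (phred
20, strict), the CNVR coverage threshold (0.8), the replication-timing
window (1000 bp) and the extreme-load fraction (0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # analysis thresholds
    preterm_cutoff: float = 37.0  # weeks; preterm iff GA < cutoff
    cadd_cutoff: float = 20.0  # phred; deleterious iff CADD > cutoff
    coverage_threshold: float = 0.8  # shared iff covered fraction >= threshold
    timing_window: int = 1000  # bp, centered at the mutation locus
    top_load_fraction: float = 0.05  # extreme-load subset size
    normalization: str = "zscore"  # 'zscore' or 'minmax' across stages
    seed: int = 0
    # input paths (None = stage skipped by the pipeline)
    trios: str | None = None
    mutations: str | None = None
    genes: str | None = None
    expression: str | None = None
    terms: str | None = None
    query_bed: str | None = None
    reference_bed: str | None = None
    gene_regions_bed: str | None = None
    timing_track: str | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.coverage_threshold <= 1:
            raise ValueError(
                f"coverage_threshold must be in (0, 1], got {self.coverage_threshold}"
            )
        if not 0 < self.top_load_fraction < 1:
            raise ValueError(
                f"top_load_fraction must be in (0, 1), got {self.top_load_fraction}"
            )
        if self.cadd_cutoff < 0:
            raise ValueError(f"cadd_cutoff must be >= 0, got {self.cadd_cutoff}")
        if self.timing_window <= 0 or self.timing_window % 2:
            raise ValueError(
                f"timing_window must be a positive even integer, got {self.timing_window}"
            )
        if not 20 < self.preterm_cutoff < 45:
            raise ValueError(f"implausible preterm_cutoff {self.preterm_cutoff}")
        if self.normalization not in ("zscore", "minmax"):
            raise ValueError(f"normalization must be 'zscore' or 'minmax'")


VALID_KEYS = tuple(f.name for f in fields(RunConfig))


def load_config(path=None, **overrides) -> RunConfig:
    """Load a flat YAML config; unknown keys raise an error listing valid ones.

    An empty (or absent) file yields all defaults.  Keyword overrides are
    applied after the file.
    """
    data: dict = {}
    if path is not None:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        data.update(loaded)
    data.update(overrides)
    unknown = sorted(set(data) - set(VALID_KEYS))
    if unknown:
        raise ValueError(
            f"unknown config key(s): {', '.join(unknown)}; "
            f"valid keys: {', '.join(VALID_KEYS)}"
        )
    return RunConfig(**data)
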