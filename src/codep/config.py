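"""Run configuration: every fixed analysis constant in one validated object."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, with their defaults.

    alpha: FDR level for every significance call (q < alpha).
    essential_threshold / strong_kill_threshold: gene-effect cutoffs for
        "essential" and "strong cytotoxic" calls (strict <).
    dup_max_range: duplicate AUC entries spanning more than this are removed.
    coverage_min_frac: drugs measured in fewer than this fraction of lines
        are excluded.
    min_events: minimum events per group for a survival stratification.
    k_min/k_max: percentile range of the Kaplan-Meier scan.
    min_pairs: minimum jointly observed values for any Spearman test.
    min_set_size/max_set_size: gene-set size window for enrichment.
    n_perm: gene-label permutations for the enrichment null.
    """

    seed: int = 0
    alpha: float = 0.1
    essential_threshold: float = -0.5
    strong_kill_threshold: float = -1.0
    dup_max_range: float = 0.2
    coverage_min_frac: float = 0.7
    min_events: int = 10
    k_min: int = 10
    k_max: int = 50
    min_pairs: int = 20
    min_set_size: int = 5
    max_set_size: int = 500
    n_perm: int = 1000
    scan_mode: str = "tails"
    fdr_scope: str = "per-scan"
    outdir: str = "codep_out"
    inputs: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.alpha <= 1):
            raise ValueError(f"alpha={self.alpha} out of range (0, 1]")
        if not (0 <= self.dup_max_range <= 1):
            raise ValueError(f"dup_max_range={self.dup_max_range} out of range [0, 1]")
        if not (0 <= self.coverage_min_frac <= 1):
            raise ValueError(f"coverage_min_frac={self.coverage_min_frac} out of range [0, 1]")
        if self.min_events < 0:
            raise ValueError("min_events must be >= 0")
        if not (10 <= self.k_min <= self.k_max <= 90):
            raise ValueError(f"percentile range {self.k_min}..{self.k_max} invalid")
        if self.min_pairs < 3:
            raise ValueError("min_pairs must be >= 3")
        if not (0 < self.min_set_size <= self.max_set_size):
            raise ValueError("gene-set size window invalid")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.scan_mode not in ("tails", "single-cut"):
            raise ValueError(f"unknown scan_mode {self.scan_mode!r}")
        if self.fdr_scope not in ("per-scan", "global"):
            raise ValueError(f"unknown fdr_scope {self.fdr_scope!r}")


def load_config(path) -> RunConfig:
    """Load a YAML config; missing keys take defaults, unknown keys error."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {', '.join(unknown)}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
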