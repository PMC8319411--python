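"""Pipeline configuration, YAML-serializable, mirrored by CLI flags."""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

from .network import KeystoneThresholds

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the end-to-end analysis.

    ``rmt_fallback_threshold`` is used when the RMT scan accepts no
    threshold on the grid (the scan outcome is always logged); set it to
    None to make such runs fail instead.
    """

    min_rel_abundance: float = 1e-4
    rmt_lo: float = 0.30
    rmt_hi: float = 0.99
    rmt_step: float = 0.01
    rmt_fallback_threshold: float | None = 0.70
    threshold: float | None = None  # fixed cutoff; skips the RMT scan
    fdr_alpha: float = 0.05
    degree_min: float = 6.0
    weighted_degree_min: float = 6.0
    closeness_min: float = 0.14
    betweenness_max: float = 0.05
    transitivity_min: float = 0.09
    anosim_permutations: int = 999
    cpcoa_permutations: int = 999
    positive_only: bool = False
    pooled_sites: bool = False
    global_scaling: bool = False  # scale MF over both sites jointly
    mf_excluded_variables: tuple[str, ...] = ("pH",)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_rel_abundance < 1:
            raise ValueError("min_rel_abundance must lie in (0, 1)")
        if not 0 < self.rmt_lo < self.rmt_hi < 1:
            raise ValueError("need 0 < rmt_lo < rmt_hi < 1")
        if self.rmt_step <= 0:
            raise ValueError("rmt_step must be positive")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must lie in (0, 1)")

    def keystone_thresholds(self) -> KeystoneThresholds:
        return KeystoneThresholds(
            degree_min=self.degree_min,
            weighted_degree_min=self.weighted_degree_min,
            closeness_min=self.closeness_min,
            betweenness_max=self.betweenness_max,
            transitivity_min=self.transitivity_min,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "mf_excluded_variables" in data:
            data["mf_excluded_variables"] = tuple(data["mf_excluded_variables"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["mf_excluded_variables"] = list(data["mf_excluded_variables"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})
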