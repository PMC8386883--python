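"""Run configuration for the subtyping pipeline (YAML-backed)."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, so that a manifest + seed reproduces it.

    Defaults: embedding width 8 shared across omics, MineClus k explored
    over 2-10 with a data-driven w grid, covariate
    filter at within-variable FDR < 1e-5, clinical significance at FDR-adjusted
    p < 0.05, enrichment at per-level FDR < 0.10, and a minimum small-subtype
    silhouette of 0.10.
    """

    omics_paths: dict = field(default_factory=dict)  # omic name -> TSV path
    clinical_path: str = ""
    schema_path: str = ""
    annotations_paths: dict = field(default_factory=dict)  # omic name -> GMT
    output_dir: str = "omsubtype_run"

    embedding_method: str = "pca"  # or "autoencoder"
    embedding_dim: int | None = 8  # None -> elbow over candidate_dims
    candidate_dims: list = field(default_factory=lambda: list(range(2, 17, 2)))
    ae_epochs: int = 300
    ae_learning_rate: float = 1e-3

    w_grid: list | None = None  # None -> deciles of per-dim |differences|
    k_range: list = field(default_factory=lambda: list(range(2, 11)))
    min_small_silhouette: float = 0.10
    beta: float = 0.25
    alpha: float = 0.10

    filter_fdr: float = 1e-5
    clinical_fdr: float = 0.05
    enrichment_fdr: float = 0.10

    stratify_by: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("filter_fdr", self.filter_fdr),
            ("clinical_fdr", self.clinical_fdr),
            ("enrichment_fdr", self.enrichment_fdr),
        ):
            if not 0 < value < 1:
                raise ValueError(f"{name} must lie in (0,1), got {value}")
        if self.embedding_method not in ("autoencoder", "pca"):
            raise ValueError(f"unknown embedding method {self.embedding_method!r}")
        self.k_range = sorted(int(k) for k in self.k_range)
        if self.k_range and not (1 <= self.k_range[0] and self.k_range[-1] <= 10):
            raise ValueError(f"k range must lie within [1,10], got {self.k_range}")
        if self.seed is None:
            raise ValueError("a random seed must be set; unseeded runs are refused")
        self.seed = int(self.seed)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)
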