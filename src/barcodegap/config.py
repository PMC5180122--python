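"""Run configuration: analysis thresholds and input locations.

Clade-forming distance thresholds are per locus (defaults: COI 3%, 16S
1%, i.e. proportions 0.03 / 0.01 — inside the empirical separation
between intra-clade divergence, typically under 1%, and inter-clade
divergence, typically 6% and above for COI).  min_support 0.95 matches
the usual significance cut for Bayesian posterior probabilities;
ratio_k = 10 is the 10x rule of thumb.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

__all__ = ["Thresholds", "RunConfig", "load_thresholds"]


@dataclass(frozen=True)
class Thresholds:
    clustering: dict = field(
        default_factory=lambda: {"COI": 0.03, "16S": 0.01}
    )
    linkage: str = "single"
    min_support: float = 0.95
    ratio_k: float = 10.0

    def __post_init__(self) -> None:
        for locus, t in self.clustering.items():
            if t <= 0:
                raise ValueError(f"{locus} clustering threshold must be positive")
        if not 0.0 <= self.min_support <= 1.0:
            raise ValueError("min_support must lie in [0, 1]")
        if self.ratio_k <= 0:
            raise ValueError("ratio_k must be positive")


def load_thresholds(path: str | Path | None) -> Thresholds:
    """Thresholds from a YAML file; missing keys keep their defaults."""
    if path is None:
        return Thresholds()
    data = yaml.safe_load(Path(path).read_text()) or {}
    base = Thresholds()
    clustering = dict(base.clustering)
    clustering.update(
        {str(k): float(v) for k, v in (data.get("clustering") or {}).items()}
    )
    return Thresholds(
        clustering=clustering,
        linkage=data.get("linkage", base.linkage),
        min_support=float(data.get("min_support", base.min_support)),
        ratio_k=float(data.get("ratio_k", base.ratio_k)),
    )


@dataclass
class RunConfig:
    coi_path: Path | None = None
    s16_path: Path | None = None
    metadata_path: Path | None = None
    tree_paths: dict = field(default_factory=dict)  # locus -> Newick path
    thresholds: Thresholds = field(default_factory=Thresholds)
    outdir: Path = Path("barcodegap-out")
    seed: int = 0

    def with_thresholds(self, **kwargs) -> "RunConfig":
        return replace(self, thresholds=replace(self.thresholds, **kwargs))
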