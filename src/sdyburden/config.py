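"""Analysis configuration.

Every threshold used anywhere in the pipeline lives here with its
published default, so a run can be re-parameterised from a single YAML
file: the reference rarity cutoff for burden ratios (MAF <= 0.005), the
cohort rare-variant cutoff (< 0.001), the suspicious-VUS M-CAP cutoff
(> 0.025), the damage-score threshold (>= 0.69), the allele-frequency
bin edges, the resampling depth B, and the number of ancestry PCs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["AnalysisConfig", "load_config"]


@dataclass
class AnalysisConfig:
    #: MAF cutoff (inclusive) for reference rare-variant counts feeding
    #: the per-gene burden ratio.
    universe_maf_threshold: float = 0.005
    #: cohort rarity cutoff (strict <) for burden and VUS analyses.
    rare_af_threshold: float = 0.001
    #: strict > cutoff marking a suspicious VUS.
    mcap_threshold: float = 0.025
    #: damage-score threshold (inclusive >=) defining a damaged call.
    gem_threshold: float = 0.69
    #: allele-frequency bin edges (upper edges; final bin closed).
    bin_edges: tuple[float, ...] = (0.001, 0.01, 0.1, 0.25, 0.5)
    #: resampling depth for the enrichment null.
    n_resamples: int = 100_000
    #: ancestry PCs used as regression covariates.
    n_pcs: int = 6
    #: multiple-testing adjustment: "fdr_bh" or "bonferroni".
    adjust_method: str = "fdr_bh"
    #: relative tolerance for burden-matched control sampling.
    match_rel_tolerance: float = 0.10
    #: attempt budget for burden-matched control sampling.
    match_max_attempts: int = 100_000
    #: genes generally associated with recessive inheritance, for
    #: flagging heterozygous P/LP hits as likely incidental.
    recessive_genes: tuple[str, ...] = ("QARS", "CLN8", "PPT1", "CSTB", "FKRP")
    #: use ancestry-specific instead of global allele frequency.
    use_ancestry_af: bool = False
    #: restrict the VUS table to missense-only consequences.
    vus_missense_only: bool = False
    #: input paths (set via YAML for CLI runs).
    inputs: dict = field(default_factory=dict)
    #: synthetic-study generator overrides (see SimulationConfig).
    simulation: dict = field(default_factory=dict)

    def validate(self) -> "AnalysisConfig":
        edges = tuple(float(e) for e in self.bin_edges)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError(f"bin edges must be strictly increasing: {edges}")
        if not all(0.0 < e <= 1.0 for e in edges):
            raise ValueError(f"bin edges must lie in (0, 1]: {edges}")
        for name in ("universe_maf_threshold", "rare_af_threshold", "mcap_threshold"):
            value = getattr(self, name)
            if not (0.0 < value < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {value}")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be positive")
        if self.adjust_method not in ("fdr_bh", "bonferroni"):
            raise ValueError(f"unknown adjust_method {self.adjust_method!r}")
        return self

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["bin_edges"] = list(self.bin_edges)
        out["recessive_genes"] = list(self.recessive_genes)
        return out


def load_config(path: Optional[str | Path]) -> AnalysisConfig:
    """Load YAML over the published defaults; None yields pure defaults."""
    if path is None:
        return AnalysisConfig().validate()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "bin_edges" in raw:
        raw["bin_edges"] = tuple(raw["bin_edges"])
    if "recessive_genes" in raw:
        raw["recessive_genes"] = tuple(raw["recessive_genes"])
    return AnalysisConfig(**raw).validate()
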