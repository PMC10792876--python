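"""Synthetic study generator.

Builds a complete self-contained study — gene universe, gene panels,
cohort manifest, per-sample variant tables, and per-(sample, gene)
damage scores — with the statistical structure the downstream analyses
assume, and with plantable effect sizes:

* ``enrichment_effect`` multiplies the per-(sample, gene) damage
  probability for case-arm panel genes (1.0 = null);
* ``age_effect_slope`` couples case age at death to the sample's count
  of rare (af below threshold) panel variants (0 = null).

The control arm exactly matches the case arm's size and its joint sex x
ancestry-cluster composition.  Ancestry PCs are the latent cluster
coordinates plus Gaussian noise (not re-derived by SVD — the damage
model and regressions only need coordinates with cluster structure).
Ages are generated for cases only; the control arm stands in for a
living reference cohort without ages.

Transcript lengths are drawn log-normally and per-gene rare-variant
rates from a gamma distribution, so the derived burden ratio is
heterogeneous across genes and burden-matched sampling is non-trivial.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import CohortManifest, DamageCallSet, GenePanel, GeneUniverse
from . import io as sio

logger = logging.getLogger(__name__)

__all__ = [
    "PanelSpec",
    "SimulationConfig",
    "SimulatedStudy",
    "gen_universe",
    "gen_panels",
    "gen_cohort_and_variants",
    "simulate_study",
    "write_fixture_bundle",
    "load_fixture_bundle",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PanelSpec:
    """One synthetic gene panel: size and optional overlap with another."""

    name: str
    size: int
    overlap_with: Optional[str] = None
    overlap_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"panel size must be positive: {self}")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError(f"overlap_fraction must lie in [0, 1]: {self}")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study.

    Defaults reproduce the study conditions of the motivating cohort:
    a 18,876-gene universe, 211 cases and 211 matched controls, and the
    four published panel sizes (191/118/82/143, the smaller epilepsy and
    cardiac panels overlapping the larger ones).  Effects default to the
    null (enrichment_effect = 1, age_effect_slope = 0).
    """

    n_genes: int = 18_876
    n_cases: int = 211
    n_controls: int = 211
    panel_specs: tuple[PanelSpec, ...] = (
        PanelSpec("epilepsy", 191),
        PanelSpec("cmar1", 118),
        PanelSpec("eiee_omim", 82, overlap_with="epilepsy", overlap_fraction=0.8),
        PanelSpec("cmar2", 143, overlap_with="cmar1", overlap_fraction=0.5),
    )
    #: transcript-length log-normal parameters (log-bases).
    length_log_mean: float = 7.8
    length_log_sd: float = 0.6
    #: per-gene reference rare-variant rate: gamma with this shape and
    #: mean (variants per transcript base), giving heterogeneous burden
    #: ratios across genes.
    burden_shape: float = 2.0
    burden_mean_rate: float = 0.05
    #: expected nonsynonymous cohort variants per sample per gene.
    baseline_variant_rate: float = 0.02
    #: expected synonymous variants per sample per gene (exercises the
    #: consequence filter; otherwise inert).
    synonymous_variant_rate: float = 0.01
    #: multiplicative excess of damaged case-arm panel-gene calls.
    enrichment_effect: float = 1.0
    #: change in mean age at death (years) per rare panel variant.
    age_effect_slope: float = 0.0
    age_intercept: float = 5.0
    age_noise_sd: float = 4.0
    #: null probability a (sample, gene) damage call reaches threshold.
    damaged_fraction: float = 0.002
    damage_threshold: float = 0.69
    #: mixture weights over the five analysis frequency bins.
    frequency_mixture: tuple[float, ...] = (0.50, 0.20, 0.15, 0.10, 0.05)
    bin_edges: tuple[float, ...] = (0.001, 0.01, 0.1, 0.25, 0.5)
    #: rarity cutoff coupling variants to the age effect.
    rare_af_threshold: float = 0.001
    #: ancestry model: latent clusters, their weights, separation and
    #: per-coordinate noise; PCs beyond the first two are pure noise.
    n_clusters: int = 3
    cluster_weights: tuple[float, ...] = (0.45, 0.30, 0.25)
    cluster_separation: float = 5.0
    pc_noise_sd: float = 1.0
    n_pcs: int = 6
    male_fraction: float = 0.61
    #: panel whose genes carry the planted effects; None = all panels.
    effect_panel: Optional[str] = None
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("cohort sizes must be positive")
        if self.enrichment_effect < 0:
            raise ValueError("enrichment_effect must be >= 0")
        for name in ("damaged_fraction", "male_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.length_log_sd <= 0 or self.burden_shape <= 0 or self.burden_mean_rate <= 0:
            raise ValueError("degenerate universe distribution parameters")
        mix = np.asarray(self.frequency_mixture, dtype=float)
        if len(mix) != len(self.bin_edges) or (mix < 0).any() or mix.sum() <= 0:
            raise ValueError("frequency_mixture must be non-negative, one weight per bin")
        if len(self.cluster_weights) != self.n_clusters:
            raise ValueError("cluster_weights must have n_clusters entries")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        raw = dict(raw)
        raw["panel_specs"] = tuple(
            PanelSpec(**p) if isinstance(p, dict) else p
            for p in raw.get("panel_specs", ())
        )
        for key in ("frequency_mixture", "bin_edges", "cluster_weights"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw).validate()


def gen_universe(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> GeneUniverse:
    """Synthetic gene universe with heterogeneous burden ratios."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_genes
    width = max(6, len(str(n)))
    symbols = [f"G{i:0{width}d}" for i in range(n)]
    lengths = np.maximum(
        np.rint(rng.lognormal(config.length_log_mean, config.length_log_sd, n)), 300
    ).astype(int)
    rates = rng.gamma(
        config.burden_shape, config.burden_mean_rate / config.burden_shape, n
    )
    counts = rng.poisson(lengths * rates)
    return GeneUniverse(
        pd.DataFrame(
            {
                "symbol": symbols,
                "transcript_length": lengths,
                "ref_rare_count": counts,
            }
        )
    )


def gen_panels(
    config: SimulationConfig,
    universe: GeneUniverse,
    rng: Optional[np.random.Generator] = None,
) -> list[GenePanel]:
    """Draw the configured panels from the universe, honouring overlaps."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    symbols = np.asarray(universe.symbols)
    panels: dict[str, GenePanel] = {}
    for spec in config.panel_specs:
        chosen: set[str] = set()
        if spec.overlap_with is not None:
            if spec.overlap_with not in panels:
                raise ValueError(
                    f"panel {spec.name!r} overlaps undefined panel "
                    f"{spec.overlap_with!r} (order panel_specs accordingly)"
                )
            source = sorted(panels[spec.overlap_with].genes)
            n_overlap = min(round(spec.overlap_fraction * spec.size), len(source))
            chosen.update(rng.choice(source, size=n_overlap, replace=False))
        pool = np.setdiff1d(symbols, np.array(sorted(chosen), dtype=object))
        if spec.overlap_with is not None:
            # keep the overlap exact: the remainder avoids the source panel
            pool = np.setdiff1d(
                pool, np.array(sorted(panels[spec.overlap_with].genes), dtype=object)
            )
        n_rest = spec.size - len(chosen)
        if n_rest > len(pool):
            raise ValueError(f"universe too small for panel {spec.name!r}")
        chosen.update(rng.choice(pool, size=n_rest, replace=False))
        panels[spec.name] = GenePanel(name=spec.name, genes=frozenset(chosen))
    return list(panels.values())


def _cluster_centers(config: SimulationConfig) -> np.ndarray:
    """Latent cluster coordinates: spread on a circle in the PC1-2 plane."""
    centers = np.zeros((config.n_clusters, config.n_pcs))
    angles = 2 * np.pi * np.arange(config.n_clusters) / max(config.n_clusters, 1)
    centers[:, 0] = config.cluster_separation * np.cos(angles)
    if config.n_pcs > 1:
        centers[:, 1] = config.cluster_separation * np.sin(angles)
    return centers


def _gen_manifest_skeleton(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Cases plus controls matched on joint sex x cluster composition."""
    n_cases, n_controls = config.n_cases, config.n_controls
    sex_case = np.where(rng.random(n_cases) < config.male_fraction, "male", "female")
    weights = np.asarray(config.cluster_weights, dtype=float)
    weights = weights / weights.sum()
    cluster_case = rng.choice(config.n_clusters, size=n_cases, p=weights)

    # controls replicate the case arm's joint composition; unequal sizes
    # resample the case composition with replacement
    if n_controls == n_cases:
        order = rng.permutation(n_cases)
    else:
        order = rng.integers(0, n_cases, size=n_controls)
    sex_control = sex_case[order]
    cluster_control = cluster_case[order]

    centers = _cluster_centers(config)
    rows = []
    for arm, sexes, clusters in (
        ("case", sex_case, cluster_case),
        ("control", sex_control, cluster_control),
    ):
        prefix = "SDY" if arm == "case" else "CTL"
        pcs = centers[clusters] + rng.normal(
            0.0, config.pc_noise_sd, size=(len(sexes), config.n_pcs)
        )
        for i in range(len(sexes)):
            row = {
                "sample_id": f"{prefix}{i:05d}",
                "arm": arm,
                "sex": sexes[i],
                "cluster": int(clusters[i]),
                "cause_category": "unavailable",
                "age_at_death": np.nan,
                "exclusion_reasons": "",
            }
            for j in range(config.n_pcs):
                row[f"pc{j + 1}"] = pcs[i, j]
            rows.append(row)
    return pd.DataFrame(rows)


def _draw_afs(
    config: SimulationConfig, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Allele frequencies from the bin mixture, log-uniform within bins."""
    weights = np.asarray(config.frequency_mixture, dtype=float)
    weights = weights / weights.sum()
    edges = (1e-6,) + tuple(config.bin_edges)
    which = rng.choice(len(weights), size=size, p=weights)
    lo = np.log(np.asarray(edges[:-1]))[which]
    hi = np.log(np.asarray(edges[1:]))[which]
    return np.exp(lo + rng.random(size) * (hi - lo))


def _gen_variant_frame(
    config: SimulationConfig,
    universe: GeneUniverse,
    sample_ids: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Poisson variant tables for all samples, nonsynonymous + synonymous."""
    n_samples = len(sample_ids)
    n_genes = len(universe)
    symbols = np.asarray(universe.symbols)
    parts = []
    for consequence, rate in (
        ("nonsynonymous", config.baseline_variant_rate),
        ("synonymous", config.synonymous_variant_rate),
    ):
        if rate <= 0:
            continue
        total = rng.poisson(rate * n_samples * n_genes)
        if total == 0:
            continue
        sample_idx = rng.integers(0, n_samples, size=total)
        gene_idx = rng.integers(0, n_genes, size=total)
        afs = _draw_afs(config, total, rng)
        ref_idx = rng.integers(0, 4, size=total)
        ref = _BASES[ref_idx]
        alt = _BASES[(ref_idx + rng.integers(1, 4, size=total)) % 4]  # always != ref
        clinvar = rng.choice(
            ["absent", "VUS", "B", "LB", "LP", "P"],
            size=total,
            p=[0.88, 0.06, 0.03, 0.02, 0.005, 0.005],
        )
        acmg = rng.choice(
            ["unclassified", "VUS", "B", "LB", "LP", "P"],
            size=total,
            p=[0.88, 0.06, 0.03, 0.02, 0.005, 0.005],
        )
        mcap = rng.beta(0.6, 4.0, size=total)
        mcap_missing = rng.random(total) < 0.2
        mcap = np.where(
            (consequence == "nonsynonymous") & ~mcap_missing, mcap, np.nan
        )
        parts.append(
            pd.DataFrame(
                {
                    "sample_id": sample_ids[sample_idx],
                    "gene": symbols[gene_idx],
                    "contig": (gene_idx % 22 + 1).astype(str),
                    "position": gene_idx * 10_000 + rng.integers(1, 10_000, size=total),
                    "ref": ref,
                    "alt": alt,
                    "consequence_class": consequence,
                    "aa_change": None,
                    "af_global": afs,
                    "af_ancestry": np.nan,
                    "clinvar_class": clinvar,
                    "acmg_class": acmg,
                    "mcap_score": mcap,
                    "zygosity": np.where(rng.random(total) < 0.03, "hom", "het"),
                }
            )
        )
    if not parts:
        from .datatypes import VARIANT_COLUMNS

        return pd.DataFrame(columns=VARIANT_COLUMNS)
    frame = pd.concat(parts, ignore_index=True)
    return frame.sort_values(["sample_id", "contig", "position"]).reset_index(drop=True)


def _effect_genes(config: SimulationConfig, panels: Sequence[GenePanel]) -> set[str]:
    if config.effect_panel is None:
        out: set[str] = set()
        for p in panels:
            out |= p.genes
        return out
    for p in panels:
        if p.name == config.effect_panel:
            return set(p.genes)
    raise ValueError(f"effect_panel {config.effect_panel!r} not among panels")


def _gen_damage(
    config: SimulationConfig,
    universe: GeneUniverse,
    panels: Sequence[GenePanel],
    manifest: pd.DataFrame,
    rng: np.random.Generator,
) -> DamageCallSet:
    """Sparse per-(sample, gene) damage scores.

    Case-arm effect genes are damaged at ``damaged_fraction x
    enrichment_effect`` (clipped at 1), everything else at the base
    rate.  Damaged pairs score threshold + Exponential; an equal number
    of random sub-threshold pairs exercises the cutoff.
    """
    symbols = np.asarray(universe.symbols)
    effect = _effect_genes(config, panels)
    effect_mask = np.isin(symbols, sorted(effect))
    base = config.damaged_fraction
    boosted = min(base * config.enrichment_effect, 1.0)

    rows_s: list[np.ndarray] = []
    rows_g: list[np.ndarray] = []
    for arm in ("case", "control"):
        ids = manifest.loc[manifest["arm"] == arm, "sample_id"].to_numpy()
        if len(ids) == 0:
            continue
        probs = np.where(
            effect_mask, boosted if arm == "case" else base, base
        )
        hit = rng.random((len(ids), len(symbols))) < probs[None, :]
        s_idx, g_idx = np.nonzero(hit)
        rows_s.append(ids[s_idx])
        rows_g.append(symbols[g_idx])
    sample_col = np.concatenate(rows_s) if rows_s else np.array([], dtype=object)
    gene_col = np.concatenate(rows_g) if rows_g else np.array([], dtype=object)
    n_damaged = len(sample_col)
    scores = config.damage_threshold + rng.exponential(0.5, size=n_damaged)

    # sub-threshold background calls
    all_ids = manifest["sample_id"].to_numpy()
    n_sub = n_damaged
    sub_samples = all_ids[rng.integers(0, len(all_ids), size=n_sub)]
    sub_genes = symbols[rng.integers(0, len(symbols), size=n_sub)]
    sub_scores = rng.random(n_sub) * config.damage_threshold * 0.999

    frame = pd.DataFrame(
        {
            "sample_id": np.concatenate([sample_col, sub_samples]),
            "gene": np.concatenate([gene_col, sub_genes]),
            "score": np.concatenate([scores, sub_scores]),
        }
    )
    frame = frame.sort_values(["sample_id", "gene"]).reset_index(drop=True)
    return DamageCallSet(frame, threshold=config.damage_threshold)


def gen_cohort_and_variants(
    config: SimulationConfig,
    universe: GeneUniverse,
    panels: Sequence[GenePanel],
    rng: Optional[np.random.Generator] = None,
) -> tuple[CohortManifest, pd.DataFrame, DamageCallSet]:
    """Manifest, variant table and damage calls with planted effects."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    skeleton = _gen_manifest_skeleton(config, rng)
    variants = _gen_variant_frame(
        config, universe, skeleton["sample_id"].to_numpy(), rng
    )

    effect = _effect_genes(config, panels)
    rare_panel = variants[
        (variants["consequence_class"] == "nonsynonymous")
        & variants["gene"].isin(effect)
        & (variants["af_global"] < config.rare_af_threshold)
    ]
    rare_counts = rare_panel.groupby("sample_id").size()

    case_mask = skeleton["arm"] == "case"
    case_ids = skeleton.loc[case_mask, "sample_id"]
    burden = rare_counts.reindex(case_ids, fill_value=0).to_numpy()
    raw_age = (
        config.age_intercept
        + config.age_effect_slope * burden
        + rng.normal(0.0, config.age_noise_sd, size=len(case_ids))
    )
    truncated = raw_age < 0
    if truncated.mean() > 0.5:
        warnings.warn(
            f"age model truncates {truncated.mean():.0%} of cases at 0; "
            "the planted effect is too large for the intercept/noise",
            stacklevel=2,
        )
    skeleton.loc[case_mask, "age_at_death"] = np.maximum(raw_age, 0.0)
    skeleton.loc[case_mask, "cause_category"] = rng.choice(
        ["unexplained", "cardiac", "SUDEP", "other", "unavailable"],
        size=int(case_mask.sum()),
        p=[0.45, 0.12, 0.05, 0.10, 0.28],
    )

    damage = _gen_damage(config, universe, panels, skeleton, rng)
    return CohortManifest(skeleton), variants, damage


@dataclass
class SimulatedStudy:
    """Everything one synthetic study run produced."""

    config: SimulationConfig
    universe: GeneUniverse
    panels: list[GenePanel]
    manifest: CohortManifest
    variants: pd.DataFrame
    damage: DamageCallSet


def simulate_study(
    config: Optional[SimulationConfig] = None, seed: Optional[int] = None
) -> SimulatedStudy:
    """One deterministic end-to-end study draw.

    ``seed`` overrides ``config.seed`` when given; all stages share a
    single generator chain, so equal (config, seed) means equal output.
    """
    config = config if config is not None else SimulationConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    config.validate()
    rng = np.random.default_rng(config.seed)
    universe = gen_universe(config, rng)
    panels = gen_panels(config, universe, rng)
    manifest, variants, damage = gen_cohort_and_variants(config, universe, panels, rng)
    return SimulatedStudy(
        config=config,
        universe=universe,
        panels=panels,
        manifest=manifest,
        variants=variants,
        damage=damage,
    )


_BUNDLE_FILES = {
    "universe": "universe.tsv",
    "manifest": "manifest.tsv",
    "variants": "variants.tsv",
    "damage": "damage_scores.tsv",
}


def write_fixture_bundle(
    study: SimulatedStudy, out_dir: str | Path, force: bool = False
) -> dict:
    """Write the study as a self-describing TSV bundle plus JSON sidecar."""
    out_dir = Path(out_dir)
    sidecar = out_dir / "bundle.json"
    if sidecar.exists() and not force:
        raise FileExistsError(
            f"bundle already exists at {out_dir} (use force to overwrite)"
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "panels").mkdir(exist_ok=True)
    sio.write_universe(study.universe, out_dir / _BUNDLE_FILES["universe"])
    sio.write_manifest(study.manifest, out_dir / _BUNDLE_FILES["manifest"])
    sio.write_variants(study.variants, out_dir / _BUNDLE_FILES["variants"], "tsv")
    sio.write_damage_scores(study.damage, out_dir / _BUNDLE_FILES["damage"])
    panel_files = {}
    for panel in study.panels:
        path = out_dir / "panels" / f"{panel.name}.txt"
        sio.write_panel(panel, path)
        panel_files[panel.name] = str(path.relative_to(out_dir))
    manifest = {
        "config": study.config.to_dict(),
        "seed": study.config.seed,
        "files": dict(_BUNDLE_FILES),
        "panels": panel_files,
    }
    sidecar.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("wrote fixture bundle to %s", out_dir)
    return manifest


def load_fixture_bundle(bundle_dir: str | Path) -> SimulatedStudy:
    """Reload a bundle into the same in-memory objects."""
    bundle_dir = Path(bundle_dir)
    sidecar = bundle_dir / "bundle.json"
    if not sidecar.exists():
        raise FileNotFoundError(f"bundle sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    config = SimulationConfig.from_dict(meta["config"])
    for key, rel in meta["files"].items():
        if not (bundle_dir / rel).exists():
            raise FileNotFoundError(f"bundle missing {key} file: {bundle_dir / rel}")
    for name, rel in meta["panels"].items():
        if not (bundle_dir / rel).exists():
            raise FileNotFoundError(f"bundle missing panel file: {bundle_dir / rel}")
    universe = sio.read_universe(bundle_dir / meta["files"]["universe"])
    manifest = sio.read_manifest(bundle_dir / meta["files"]["manifest"])
    variants = sio.read_variants(bundle_dir / meta["files"]["variants"], "tsv")
    variants.raise_if_errors()
    from .datatypes import variants_to_frame

    damage = sio.read_damage_scores(
        bundle_dir / meta["files"]["damage"], threshold=config.damage_threshold
    )
    panels = [
        sio.read_panel(bundle_dir / rel, name=name)
        for name, rel in sorted(meta["panels"].items())
    ]
    return SimulatedStudy(
        config=config,
        universe=universe,
        panels=panels,
        manifest=manifest,
        variants=variants_to_frame(variants.records),
        damage=damage,
    )
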