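"""Core data containers shared by every analysis stage.

The pipeline operates on five kinds of object:

* :class:`GeneUniverse` — the background set of genes with per-gene
  largest-transcript length and reference rare-variant count, from which
  the per-gene burden ratio is derived.
* :class:`GenePanel` — a named set of gene symbols (an epilepsy or
  cardiomyopathy/arrhythmia panel, a housekeeping list, a matched list).
* :class:`VariantRecord` / variant frames — one annotated, sample-level,
  biallelic variant call.
* :class:`CohortManifest` — per-decedent metadata: arm, age at death,
  sex, cause-of-death category, ancestry principal components, and
  enrollment/exclusion flags.
* :class:`DamageCallSet` — per-(sample, gene) damage scores (log10
  Bayes-factor style) with a configurable "damaged" threshold.

Tabular objects wrap a :class:`pandas.DataFrame` so that vectorised
analysis code can reach the raw frame while invariants are enforced at
construction time.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VALID_CLINVAR",
    "VALID_ACMG",
    "VARIANT_COLUMNS",
    "VariantRecord",
    "variants_to_frame",
    "frame_to_variants",
    "as_variant_frame",
    "GeneUniverse",
    "GenePanel",
    "CohortManifest",
    "ExclusionResult",
    "apply_cohort_exclusions",
    "DamageCallSet",
]

VALID_CLINVAR = frozenset({"P", "LP", "VUS", "LB", "B", "absent"})
VALID_ACMG = frozenset({"P", "LP", "VUS", "LB", "B", "unclassified"})
VALID_ZYGOSITY = frozenset({"het", "hom"})

#: Canonical column order of the variant TSV dialect.
VARIANT_COLUMNS = [
    "sample_id",
    "gene",
    "contig",
    "position",
    "ref",
    "alt",
    "consequence_class",
    "aa_change",
    "af_global",
    "af_ancestry",
    "clinvar_class",
    "acmg_class",
    "mcap_score",
    "zygosity",
]


@dataclass(frozen=True)
class VariantRecord:
    """One sample-level, biallelic, annotated variant call.

    Coordinates are 1-based (VCF convention).  ``af_global`` is the
    analysis allele frequency; ``af_ancestry`` is retained but unused by
    the default analyses.  ``mcap_score`` may be missing (``None``).
    """

    sample_id: str
    gene: str
    contig: str
    position: int
    ref: str
    alt: str
    consequence_class: str
    af_global: float
    aa_change: Optional[str] = None
    af_ancestry: Optional[float] = None
    clinvar_class: str = "absent"
    acmg_class: str = "unclassified"
    mcap_score: Optional[float] = None
    zygosity: str = "het"

    def __post_init__(self) -> None:
        if not (0.0 <= self.af_global <= 1.0):
            raise ValueError(
                f"af_global must lie in [0, 1], got {self.af_global!r}"
            )
        if self.af_ancestry is not None and not (0.0 <= self.af_ancestry <= 1.0):
            raise ValueError(
                f"af_ancestry must lie in [0, 1], got {self.af_ancestry!r}"
            )
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ, got {self.ref!r}")
        if self.clinvar_class not in VALID_CLINVAR:
            raise ValueError(f"unknown clinvar_class {self.clinvar_class!r}")
        if self.acmg_class not in VALID_ACMG:
            raise ValueError(f"unknown acmg_class {self.acmg_class!r}")
        if self.zygosity not in VALID_ZYGOSITY:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")


def variants_to_frame(records: Iterable[VariantRecord]) -> pd.DataFrame:
    """Convert records to the canonical variant frame (may be empty)."""
    rows = [dataclasses.asdict(r) for r in records]
    if not rows:
        return pd.DataFrame(columns=VARIANT_COLUMNS)
    return pd.DataFrame(rows)[VARIANT_COLUMNS]


def frame_to_variants(frame: pd.DataFrame) -> list[VariantRecord]:
    """Convert a canonical variant frame back into records."""
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            VariantRecord(
                sample_id=str(row.sample_id),
                gene=str(row.gene),
                contig=str(row.contig),
                position=int(row.position),
                ref=str(row.ref),
                alt=str(row.alt),
                consequence_class=str(row.consequence_class),
                aa_change=_opt_str(row.aa_change),
                af_global=float(row.af_global),
                af_ancestry=_opt_float(row.af_ancestry),
                clinvar_class=_cat(row.clinvar_class, "absent"),
                acmg_class=_cat(row.acmg_class, "unclassified"),
                mcap_score=_opt_float(row.mcap_score),
                zygosity=str(row.zygosity),
            )
        )
    return records


def as_variant_frame(variants) -> pd.DataFrame:
    """Accept either a canonical frame or an iterable of records."""
    if isinstance(variants, pd.DataFrame):
        missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
        if missing:
            raise ValueError(f"variant frame missing columns: {missing}")
        return variants
    return variants_to_frame(variants)


def _opt_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return str(value)


def _opt_float(value) -> Optional[float]:
    if value is None or value == "" or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


def _cat(value, default: str) -> str:
    out = _opt_str(value)
    return default if out is None else out


class GeneUniverse:
    """Background gene set with transcript lengths and rare-variant counts.

    Each gene carries the length (bases) of its largest coding transcript
    and the number of reference-population rare variants (MAF at or below
    the rarity threshold, 0.005 by default upstream) observed in that
    transcript.  The derived burden ratio ``ref_rare_count /
    transcript_length`` drives burden-matched control-gene sampling.
    """

    COLUMNS = ["symbol", "transcript_length", "ref_rare_count"]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"universe table missing columns: {missing}")
        frame = frame[self.COLUMNS].copy()
        frame["symbol"] = frame["symbol"].astype(str)
        frame["transcript_length"] = frame["transcript_length"].astype(int)
        frame["ref_rare_count"] = frame["ref_rare_count"].astype(int)
        if len(frame) < 2:
            raise ValueError("universe must contain at least 2 genes")
        if frame["symbol"].duplicated().any():
            dupes = frame.loc[frame["symbol"].duplicated(), "symbol"].tolist()
            raise ValueError(f"duplicate gene symbols in universe: {dupes[:5]}")
        if (frame["transcript_length"] < 1).any():
            raise ValueError("transcript_length must be >= 1 for every gene")
        if (frame["ref_rare_count"] < 0).any():
            raise ValueError("ref_rare_count must be >= 0 for every gene")
        self._frame = frame.reset_index(drop=True)

    @classmethod
    def from_entries(
        cls, entries: Iterable[tuple[str, int, int]]
    ) -> "GeneUniverse":
        return cls(pd.DataFrame(entries, columns=cls.COLUMNS))

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def symbols(self) -> pd.Index:
        return pd.Index(self._frame["symbol"])

    def __len__(self) -> int:
        return len(self._frame)

    def __contains__(self, symbol: str) -> bool:
        return symbol in set(self._frame["symbol"])

    def burden_ratios(self) -> pd.Series:
        """Per-gene burden ratio, indexed by symbol."""
        ratios = (
            self._frame["ref_rare_count"] / self._frame["transcript_length"]
        )
        ratios.index = self._frame["symbol"]
        ratios.name = "burden_ratio"
        return ratios


@dataclass(frozen=True)
class GenePanel:
    """A named gene list (test panel, housekeeping list, matched list)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene panel {self.name!r} is empty")
        object.__setattr__(self, "genes", frozenset(str(g) for g in self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def missing_from(self, universe: GeneUniverse) -> set[str]:
        """Symbols absent from the universe (reported, never dropped)."""
        return set(self.genes) - set(universe.symbols)


EXCLUSION_REASONS = ("failed_inclusion", "failed_sequencing")


class CohortManifest:
    """Per-decedent cohort metadata.

    Required columns: ``sample_id``, ``arm`` (case/control).  Optional:
    ``age_at_death`` (years; cases only — controls, drawn from a living
    reference cohort, have none), ``sex``, ``cause_category``,
    ``exclusion_reasons`` (semicolon-separated), and ancestry PC columns
    ``pc1``, ``pc2``, ...
    """

    def __init__(self, frame: pd.DataFrame):
        for col in ("sample_id", "arm"):
            if col not in frame.columns:
                raise ValueError(f"manifest missing required column {col!r}")
        frame = frame.copy()
        frame["sample_id"] = frame["sample_id"].astype(str)
        if frame["sample_id"].duplicated().any():
            dupes = frame.loc[frame["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample_ids: {dupes.tolist()[:5]}")
        bad_arm = set(frame["arm"]) - {"case", "control"}
        if bad_arm:
            raise ValueError(f"unknown arm labels: {sorted(bad_arm)}")
        if "exclusion_reasons" not in frame.columns:
            frame["exclusion_reasons"] = ""
        frame["exclusion_reasons"] = frame["exclusion_reasons"].fillna("")
        self._frame = frame.reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def __len__(self) -> int:
        return len(self._frame)

    @property
    def sample_ids(self) -> list[str]:
        return self._frame["sample_id"].tolist()

    def arm_samples(self, arm: str) -> list[str]:
        if arm not in ("case", "control"):
            raise ValueError(f"unknown arm {arm!r}")
        mask = self._frame["arm"] == arm
        return self._frame.loc[mask, "sample_id"].tolist()

    @property
    def cases(self) -> list[str]:
        return self.arm_samples("case")

    @property
    def controls(self) -> list[str]:
        return self.arm_samples("control")

    def ages(self) -> pd.Series:
        """Age at death for case samples, indexed by sample_id."""
        if "age_at_death" not in self._frame.columns:
            raise ValueError("manifest has no age_at_death column")
        cases = self._frame[self._frame["arm"] == "case"]
        ages = cases.set_index("sample_id")["age_at_death"].astype(float)
        ages.name = "age_at_death"
        return ages

    def pcs(self, k: int = 6) -> pd.DataFrame:
        """Ancestry PC matrix (samples x k), case samples by default use.

        Raises when fewer than ``k`` PC columns are present, since a
        regression asking for k covariates cannot silently get fewer.
        """
        cols = [f"pc{i}" for i in range(1, k + 1)]
        missing = [c for c in cols if c not in self._frame.columns]
        if missing:
            raise ValueError(
                f"manifest lacks ancestry PC columns {missing}; "
                f"{k} components requested"
            )
        out = self._frame.set_index("sample_id")[cols].astype(float)
        return out

    def summary(self) -> dict:
        """Cohort demographic arithmetic for the case arm.

        Reports the detailed-phenotype fraction (cause category known,
        i.e. not 'unavailable') and the sex split, as raw counts plus
        percentages rounded to the nearest integer.
        """
        cases = self._frame[self._frame["arm"] == "case"]
        n = len(cases)
        if n == 0:
            raise ValueError("manifest has no case samples to summarise")
        out: dict = {"n_cases": n}
        if "cause_category" in cases.columns:
            detailed = int((cases["cause_category"] != "unavailable").sum())
            out["n_detailed_phenotype"] = detailed
            out["pct_detailed_phenotype"] = round(100.0 * detailed / n)
        if "sex" in cases.columns:
            n_female = int((cases["sex"] == "female").sum())
            n_male = int((cases["sex"] == "male").sum())
            out["n_female"] = n_female
            out["n_male"] = n_male
            out["pct_female"] = round(100.0 * n_female / n)
            out["pct_male"] = round(100.0 * n_male / n)
        return out


@dataclass
class ExclusionResult:
    """Outcome of applying enrollment exclusions to a manifest."""

    manifest: CohortManifest
    n_enrolled: int
    n_retained: int
    n_excluded: int
    reason_counts: dict[str, int] = field(default_factory=dict)


def _split_reasons(cell: str) -> set[str]:
    return {r.strip() for r in str(cell).split(";") if r.strip()}


def apply_cohort_exclusions(manifest: CohortManifest) -> ExclusionResult:
    """Drop samples carrying any exclusion flag; account per reason.

    A sample flagged for more than one reason is excluded once but listed
    under every reason it carries, so per-reason counts may sum to more
    than the number of excluded samples.
    """
    frame = manifest.frame
    reasons = frame["exclusion_reasons"].map(_split_reasons)
    excluded_mask = reasons.map(bool)
    counts: Counter = Counter()
    for rset in reasons[excluded_mask]:
        counts.update(rset)
    retained = frame[~excluded_mask].copy()
    return ExclusionResult(
        manifest=CohortManifest(retained),
        n_enrolled=len(frame),
        n_retained=len(retained),
        n_excluded=int(excluded_mask.sum()),
        reason_counts=dict(counts),
    )


class DamageCallSet:
    """Per-(sample, gene) damage scores with a damaged/not threshold.

    Scores are log10 Bayes-factor style and non-negative; a pair is
    "damaged" when its score reaches the threshold (0.69 by default,
    the published operating point of the upstream AI prioritiser).
    Pairs absent from the table implicitly score 0.  Duplicate
    (sample, gene) rows are aggregated to their maximum at construction.
    """

    COLUMNS = ["sample_id", "gene", "score"]

    def __init__(self, frame: pd.DataFrame, threshold: float = 0.69):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"damage table missing columns: {missing}")
        frame = frame[self.COLUMNS].copy()
        frame["sample_id"] = frame["sample_id"].astype(str)
        frame["gene"] = frame["gene"].astype(str)
        frame["score"] = frame["score"].astype(float)
        if (frame["score"] < 0).any():
            raise ValueError("damage scores must be non-negative")
        # one entry per (sample, gene): keep the strongest call
        frame = (
            frame.groupby(["sample_id", "gene"], as_index=False)["score"].max()
        )
        self._frame = frame
        self.threshold = float(threshold)

    @property
    def frame(self) -> pd.DataFrame:
        out = self._frame.copy()
        out["damaged"] = out["score"] >= self.threshold
        return out

    def __len__(self) -> int:
        return len(self._frame)

    def gene_max_scores(self, samples: Sequence[str]) -> pd.Series:
        """Max score per gene over the given samples (arm aggregation)."""
        wanted = self._frame[self._frame["sample_id"].isin(set(samples))]
        return wanted.groupby("gene")["score"].max()

    def damaged_genes(
        self, samples: Sequence[str], threshold: Optional[float] = None
    ) -> set[str]:
        """Genes whose arm-level max score reaches the threshold."""
        thr = self.threshold if threshold is None else float(threshold)
        per_gene = self.gene_max_scores(samples)
        return set(per_gene.index[per_gene >= thr])
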