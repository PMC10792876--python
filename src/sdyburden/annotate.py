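"""Deterministic variant filtering and classification.

Covers nonsynonymous selection, allele-frequency binning, the
suspicious-VUS rule, panel intersection, and per-decedent summarisation
of pathogenic / likely pathogenic (P/LP) findings.

Bin-edge convention: every internal edge is strict (``af < edge`` falls
below it), the final bin is closed at its upper edge, and frequencies
above the last edge map to an overflow label excluded from analysis by
default.  The cohort rarity threshold used by the burden and VUS
analyses is ``af < 0.001``, i.e. the lowest bin.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import GenePanel, VariantRecord, as_variant_frame

logger = logging.getLogger(__name__)

__all__ = [
    "FrequencyBins",
    "filter_nonsynonymous",
    "assign_bin",
    "flag_suspicious_vus",
    "suspicious_vus_mask",
    "intersect_panel",
    "PlpSummary",
    "summarize_plp",
]

OVERFLOW_LABEL = ">0.5"

#: ClinVar / ACMG classes that disqualify a variant from VUS status.
_CLASSIFIED = frozenset({"P", "LP", "B", "LB"})


@dataclass(frozen=True)
class FrequencyBins:
    """Ordered allele-frequency bins.

    ``edges`` are the upper edges; the implicit lower edge of the first
    bin is 0.  Default edges reproduce the five analysis bins
    [<0.001, 0.001–0.01, 0.01–0.1, 0.1–0.25, 0.25–0.5].
    """

    edges: tuple[float, ...] = (0.001, 0.01, 0.1, 0.25, 0.5)

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        if len(edges) < 1:
            raise ValueError("at least one bin edge required")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError(f"edges must be strictly increasing: {edges}")
        if not all(0.0 < e <= 1.0 for e in edges):
            raise ValueError(f"edges must lie in (0, 1]: {edges}")
        object.__setattr__(self, "edges", edges)

    @property
    def labels(self) -> list[str]:
        labels = [f"<{self.edges[0]:g}"]
        for lo, hi in zip(self.edges, self.edges[1:]):
            labels.append(f"{lo:g}–{hi:g}")
        return labels

    def __len__(self) -> int:
        return len(self.edges)

    def assign(self, af: float) -> str:
        """Bin label for one frequency (overflow label above last edge)."""
        return assign_bin(af, self)

    def assign_many(self, af: Sequence[float]) -> pd.Series:
        """Vectorised bin assignment."""
        af = np.asarray(af, dtype=float)
        if (af < 0).any() or (af > 1).any():
            raise ValueError("allele frequencies must lie in [0, 1]")
        # index = number of internal edges <= af; final bin closed.
        idx = np.searchsorted(self.edges[:-1], af, side="right")
        labels = np.asarray(self.labels + [OVERFLOW_LABEL], dtype=object)
        idx = np.where(af > self.edges[-1], len(self.edges), idx)
        return pd.Series(labels[idx])


def assign_bin(af: float, bins: Optional[FrequencyBins] = None) -> str:
    """Assign one allele frequency to its bin label.

    Half-open convention [lower, upper) at internal edges; the final bin
    is closed at its upper edge; af above the last edge returns the
    overflow label.
    """
    bins = bins or FrequencyBins()
    if not (0.0 <= af <= 1.0):
        raise ValueError(f"allele frequency must lie in [0, 1], got {af}")
    if af > bins.edges[-1]:
        return OVERFLOW_LABEL
    idx = bisect.bisect_right(bins.edges[:-1], af)
    return bins.labels[idx]


def filter_nonsynonymous(variants) -> pd.DataFrame:
    """Keep only nonsynonymous records; fail on missing consequences."""
    frame = as_variant_frame(variants)
    missing = frame["consequence_class"].isna() | (
        frame["consequence_class"].astype(str).str.strip() == ""
    )
    if missing.any():
        offenders = frame.loc[missing, ["sample_id", "gene", "contig", "position"]]
        raise ValueError(
            "records with missing consequence_class: "
            + "; ".join(
                f"{r.sample_id}:{r.gene}@{r.contig}:{r.position}"
                for r in offenders.head(10).itertuples()
            )
        )
    kept = frame[frame["consequence_class"] == "nonsynonymous"].reset_index(drop=True)
    logger.info("nonsynonymous filter: %d of %d records retained", len(kept), len(frame))
    if kept.empty and len(frame):
        logger.warning("no nonsynonymous records among %d inputs", len(frame))
    return kept


def _vus_conditions(
    frame: pd.DataFrame, af_threshold: float, mcap_threshold: float
) -> tuple[pd.Series, pd.Series]:
    """(rare unclassified VUS mask, suspicious sub-mask)."""
    nonsyn = frame["consequence_class"] == "nonsynonymous"
    rare = frame["af_global"].astype(float) < af_threshold
    unclassified = ~frame["clinvar_class"].isin(_CLASSIFIED)
    vus = nonsyn & rare & unclassified
    mcap = pd.to_numeric(frame["mcap_score"], errors="coerce")
    n_missing = int((vus & mcap.isna()).sum())
    if n_missing:
        logger.info("%d VUS without M-CAP score treated as not suspicious", n_missing)
    suspicious = vus & (mcap > mcap_threshold).fillna(False)
    return vus, suspicious


def flag_suspicious_vus(
    variant: VariantRecord,
    af_threshold: float = 0.001,
    mcap_threshold: float = 0.025,
) -> bool:
    """True iff the record is a rare, unclassified, suspicious VUS.

    Requires: nonsynonymous, af_global < af_threshold, ClinVar class not
    in {P, LP, B, LB}, and M-CAP strictly above mcap_threshold.  A
    missing M-CAP score is never suspicious.
    """
    if variant.consequence_class != "nonsynonymous":
        return False
    if not variant.af_global < af_threshold:
        return False
    if variant.clinvar_class in _CLASSIFIED:
        return False
    if variant.mcap_score is None:
        return False
    return variant.mcap_score > mcap_threshold


def suspicious_vus_mask(
    variants, af_threshold: float = 0.001, mcap_threshold: float = 0.025
) -> pd.Series:
    """Vectorised suspicious-VUS flags for a variant frame."""
    frame = as_variant_frame(variants)
    _, suspicious = _vus_conditions(frame, af_threshold, mcap_threshold)
    return suspicious


def intersect_panel(variants, panel: GenePanel) -> pd.DataFrame:
    """Records whose gene belongs to the panel."""
    frame = as_variant_frame(variants)
    return frame[frame["gene"].isin(panel.genes)].reset_index(drop=True)


@dataclass
class PlpSummary:
    """Per-decedent summary of P/LP findings.

    ``per_variant`` has one row per admitted variant row with panel
    memberships and the recessive-gene incidental flag; ``recurrence``
    counts distinct decedents per (gene, aa_change).
    """

    per_variant: pd.DataFrame
    recurrence: pd.DataFrame
    n_decedents: int
    decedents: list[str] = field(default_factory=list)

    def recurrence_count(self, gene: str, aa_change: str) -> int:
        hit = self.recurrence[
            (self.recurrence["gene"] == gene)
            & (self.recurrence["aa_change"] == aa_change)
        ]
        return 0 if hit.empty else int(hit["n_decedents"].iloc[0])


def summarize_plp(
    variants,
    panels: Sequence[GenePanel],
    recessive_genes: Iterable[str] = ("QARS", "CLN8", "PPT1", "CSTB", "FKRP"),
) -> PlpSummary:
    """Summarise pathogenic / likely pathogenic variants per decedent.

    A record is admitted when either its ACMG or its ClinVar class is
    P or LP.  Recurrence counts distinct decedents, never variant rows,
    so duplicated rows cannot inflate it.  Heterozygous hits in genes
    generally associated with recessive inheritance are flagged as
    likely incidental but retained.
    """
    frame = as_variant_frame(variants)
    plp = frame[
        frame["acmg_class"].isin(("P", "LP")) | frame["clinvar_class"].isin(("P", "LP"))
    ].copy()
    recessive = set(recessive_genes)
    if plp.empty:
        empty = plp.assign(panel_memberships="", recessive_incidental=False)
        return PlpSummary(
            per_variant=empty,
            recurrence=pd.DataFrame(columns=["gene", "aa_change", "n_decedents"]),
            n_decedents=0,
        )
    plp["panel_memberships"] = plp["gene"].map(
        lambda g: ",".join(sorted(p.name for p in panels if g in p.genes))
    )
    plp["recessive_incidental"] = plp["gene"].isin(recessive) & (
        plp["zygosity"] == "het"
    )
    # distinct variant rows only, so duplicated inputs do not double-count
    plp = plp.drop_duplicates(subset=["sample_id", "gene", "contig", "position", "alt"])
    recurrence = (
        plp.groupby(["gene", "aa_change"], dropna=False)["sample_id"]
        .nunique()
        .reset_index(name="n_decedents")
        .sort_values(["n_decedents", "gene"], ascending=[False, True])
        .reset_index(drop=True)
    )
    decedents = sorted(plp["sample_id"].unique())
    return PlpSummary(
        per_variant=plp.reset_index(drop=True),
        recurrence=recurrence,
        n_decedents=len(decedents),
        decedents=decedents,
    )
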