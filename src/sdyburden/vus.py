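"""Observed-versus-expected rare VUS counts per gene in a panel.

A variant of uncertain significance (VUS) here is a rare
(af < 0.001) nonsynonymous cohort variant not reported pathogenic or
benign in ClinVar.  Expected per-gene counts follow a multinomial model:
each gene's probability is its share of the reference-population variant
count over the gene set, scaled by the cohort's total observed count, so
that expected totals match observed totals exactly.  Genes are ranked by
observed-minus-expected excess, ties broken by suspicious-VUS count
(M-CAP above threshold) and then symbol for determinism.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import _vus_conditions
from .datatypes import GenePanel, GeneUniverse, as_variant_frame

logger = logging.getLogger(__name__)

__all__ = [
    "gene_probabilities",
    "expected_counts",
    "rank_genes",
    "build_vus_table",
]


def gene_probabilities(reference_counts: pd.Series) -> pd.Series:
    """Per-gene multinomial probabilities from reference variant counts."""
    counts = reference_counts.astype(float)
    if (counts < 0).any():
        raise ValueError("reference counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("reference counts sum to zero; no model possible")
    probs = counts / total
    probs.name = "probability"
    return probs


def expected_counts(probabilities: pd.Series, cohort_total_observed: int) -> pd.Series:
    """Expected per-gene counts: p_g x total observed."""
    probs = probabilities.astype(float)
    if cohort_total_observed < 0:
        raise ValueError("total observed count must be non-negative")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {probs.sum():.6g}, not 1")
    expected = probs * float(cohort_total_observed)
    expected.name = "expected"
    return expected


def rank_genes(table: pd.DataFrame, tie_tolerance: float = 0.0) -> pd.DataFrame:
    """Order genes by descending excess, breaking ties deterministically.

    Rows whose excess values differ by at most ``tie_tolerance``
    (default: exact equality) form a tie group ordered by descending
    suspicious count, then lexical symbol.
    """
    for col in ("symbol", "excess", "suspicious"):
        if col not in table.columns:
            raise ValueError(f"ranking requires column {col!r}")
    out = table.sort_values(
        ["excess", "suspicious", "symbol"], ascending=[False, False, True]
    ).reset_index(drop=True)
    if tie_tolerance > 0.0 and len(out) > 1:
        # cluster consecutive rows within tolerance of the group leader,
        # then reorder each cluster by the tie-break keys
        groups = np.zeros(len(out), dtype=int)
        leader = out["excess"].iloc[0]
        gid = 0
        for i in range(1, len(out)):
            if abs(out["excess"].iloc[i] - leader) > tie_tolerance:
                gid += 1
                leader = out["excess"].iloc[i]
            groups[i] = gid
        out = (
            out.assign(_group=groups)
            .sort_values(
                ["_group", "suspicious", "symbol"], ascending=[True, False, True]
            )
            .drop(columns="_group")
            .reset_index(drop=True)
        )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def build_vus_table(
    variants,
    panel: GenePanel,
    universe: GeneUniverse,
    reference_counts: Optional[pd.Series] = None,
    af_threshold: float = 0.001,
    mcap_threshold: float = 0.025,
    tie_tolerance: float = 0.0,
    missense_only: bool = False,
) -> pd.DataFrame:
    """Full VUS table for a panel: observed, suspicious, expected, rank.

    ``reference_counts`` defaults to the universe's per-gene reference
    rare-variant counts restricted to the panel.  Every panel gene gets
    a row, including genes with zero observed VUS.  With
    ``missense_only`` the observed filter narrows from nonsynonymous to
    records whose protein-level annotation marks a substitution.
    """
    frame = as_variant_frame(variants)
    in_panel = frame[frame["gene"].isin(panel.genes)].copy()
    vus_mask, suspicious_mask = _vus_conditions(in_panel, af_threshold, mcap_threshold)
    if missense_only:
        missense = in_panel["aa_change"].notna() & ~in_panel["aa_change"].astype(
            str
        ).str.contains("fs|X|del|ins", regex=True, na=False)
        vus_mask &= missense
        suspicious_mask &= missense
    genes = sorted(panel.genes)
    observed = (
        in_panel.loc[vus_mask].groupby("gene").size().reindex(genes, fill_value=0)
    )
    suspicious = (
        in_panel.loc[suspicious_mask]
        .groupby("gene")
        .size()
        .reindex(genes, fill_value=0)
    )
    if reference_counts is None:
        missing = panel.missing_from(universe)
        if missing:
            raise ValueError(
                f"panel genes outside the universe: {sorted(missing)[:5]}"
            )
        ref = universe.frame.set_index("symbol")["ref_rare_count"].reindex(genes)
    else:
        ref = reference_counts.reindex(genes)
        if ref.isna().any():
            absent = ref.index[ref.isna()].tolist()
            raise ValueError(f"no reference count for genes: {absent[:5]}")
    probs = gene_probabilities(ref)
    expected = expected_counts(probs, int(observed.sum()))
    table = pd.DataFrame(
        {
            "symbol": genes,
            "observed": observed.to_numpy(),
            "suspicious": suspicious.to_numpy(),
            "reference_count": ref.to_numpy(),
            "expected": expected.to_numpy(),
        }
    )
    table["excess"] = table["observed"] - table["expected"]
    return rank_genes(table, tie_tolerance=tie_tolerance)
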