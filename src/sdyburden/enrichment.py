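"""Resampling-based damaged-gene enrichment between cases and controls.

The statistic for a gene list of size N in one cohort arm is the number
of its genes carrying at least one damaging call (per-(sample, gene)
damage score at or above threshold, aggregated over the arm's samples by
maximum).  Its null distribution is built by drawing B random gene sets
of size N uniformly without replacement from the background universe and
intersecting each with the arm's damaged gene set; the observed count is
converted to an upper-tail, add-one-corrected empirical p-value and a
Z-score against the null mean and SD.  Case and control arms are
additionally compared directly with a two-sided Fisher exact test on
damaged / not-damaged gene counts, and empirical p-values across gene
lists are adjusted by Benjamini–Hochberg FDR.

Both the per-arm empirical p-values and the Fisher case–control p-value
are always reported: the two answer different questions (absolute excess
over random gene sets vs. differential burden between arms), and the
adjusted empirical p-values are the headline quantities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import CohortManifest, DamageCallSet, GenePanel, GeneUniverse

logger = logging.getLogger(__name__)

__all__ = [
    "NullDistribution",
    "EnrichmentResult",
    "damaged_gene_count",
    "resample_null",
    "empirical_p",
    "fisher_case_control",
    "fdr_adjust",
    "zscore",
    "run_enrichment",
    "results_to_frame",
]

# chunk size cap for the B x |universe| random-key matrix (elements)
_MAX_CHUNK_ELEMENTS = 20_000_000


@dataclass
class NullDistribution:
    """Resampled null for a damaged-gene count."""

    draws: np.ndarray
    n_draws: int
    list_size: int
    universe_size: int
    seed: Optional[int]

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=np.int64)
        if len(self.draws) != self.n_draws:
            raise ValueError("draw count does not match n_draws")
        if (self.draws < 0).any() or (self.draws > self.list_size).any():
            raise ValueError("null draws must lie in [0, list_size]")

    @property
    def mean(self) -> float:
        return float(self.draws.mean())

    @property
    def sd(self) -> float:
        return float(self.draws.std(ddof=0))

    def histogram(self) -> pd.DataFrame:
        """Count per observed value, for plotting the null."""
        values, counts = np.unique(self.draws, return_counts=True)
        return pd.DataFrame({"damaged_genes": values, "n_draws": counts})


def damaged_gene_count(
    calls: DamageCallSet,
    gene_list: frozenset | set | GenePanel,
    samples: Sequence[str],
    threshold: Optional[float] = None,
) -> int:
    """Genes of the list damaged in at least one of the given samples."""
    genes = gene_list.genes if isinstance(gene_list, GenePanel) else set(gene_list)
    if not genes:
        raise ValueError("gene list is empty")
    damaged = calls.damaged_genes(samples, threshold=threshold)
    return len(genes & damaged)


def resample_null(
    universe_symbols: Sequence[str],
    list_size: int,
    damaged_genes: set[str],
    n_draws: int = 100_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> NullDistribution:
    """Null damaged-gene counts for random gene sets of a given size.

    Each draw is a uniform sample of ``list_size`` genes without
    replacement from the universe; draws are independent.  The count is
    the overlap of the drawn set with the damaged gene set.
    """
    symbols = list(universe_symbols)
    universe_size = len(symbols)
    if list_size > universe_size:
        raise ValueError(
            f"list_size {list_size} exceeds universe size {universe_size}"
        )
    if list_size < 1:
        raise ValueError("list_size must be positive")
    rng = rng if rng is not None else np.random.default_rng(seed)
    membership = np.fromiter(
        (s in damaged_genes for s in symbols), dtype=bool, count=universe_size
    )
    counts = np.empty(n_draws, dtype=np.int64)
    chunk = max(1, _MAX_CHUNK_ELEMENTS // universe_size)
    done = 0
    while done < n_draws:
        b = min(chunk, n_draws - done)
        # random-key trick: the list_size smallest keys per row form a
        # uniform without-replacement sample
        keys = rng.random((b, universe_size))
        picks = np.argpartition(keys, list_size - 1, axis=1)[:, :list_size]
        counts[done : done + b] = membership[picks].sum(axis=1)
        done += b
    return NullDistribution(
        draws=counts,
        n_draws=n_draws,
        list_size=list_size,
        universe_size=universe_size,
        seed=seed,
    )


def empirical_p(observed: int, null: NullDistribution) -> float:
    """Upper-tail add-one empirical p: (1 + #{draws >= obs}) / (B + 1)."""
    if null.n_draws < 1:
        raise ValueError("null distribution is empty")
    exceed = int((null.draws >= observed).sum())
    return (1 + exceed) / (null.n_draws + 1)


def fisher_case_control(
    case_damaged: int, control_damaged: int, list_size: int
) -> float:
    """Two-sided Fisher exact p for damaged/not x case/control counts."""
    cells = [
        [case_damaged, control_damaged],
        [list_size - case_damaged, list_size - control_damaged],
    ]
    if any(v < 0 for row in cells for v in row):
        raise ValueError(f"negative cell in 2x2 table: {cells}")
    _, p = stats.fisher_exact(cells, alternative="two-sided")
    return float(p)


def fdr_adjust(pvals: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Benjamini–Hochberg (or Bonferroni) adjusted p-values, same order."""
    arr = np.asarray(list(pvals), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one p-value")
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(arr, method=method)
    return q


def zscore(observed: int, null: NullDistribution) -> float:
    """(observed - null mean) / null SD; NaN when the null SD is zero."""
    sd = null.sd
    if sd == 0.0:
        logger.warning("null SD is zero; Z-score undefined")
        return float("nan")
    return (observed - null.mean) / sd


@dataclass
class EnrichmentResult:
    """All statistics for one gene list."""

    panel: str
    list_size: int
    case_damaged: int
    control_damaged: int
    null_mean_case: float
    null_sd_case: float
    null_mean_control: float
    null_sd_control: float
    empirical_p_case: float
    empirical_p_control: float
    fisher_p: float
    fdr_q: float  # BH-adjusted case-arm empirical p across panels
    z_case: float
    z_control: float
    n_draws: int
    seed: Optional[int]


def run_enrichment(
    gene_lists: Sequence[GenePanel],
    universe: GeneUniverse,
    calls: DamageCallSet,
    manifest: CohortManifest,
    n_draws: int = 100_000,
    seed: Optional[int] = None,
    adjust_method: str = "fdr_bh",
    keep_nulls: bool = False,
):
    """Full enrichment stage over a set of gene lists.

    Any gene list can be supplied — test panels, housekeeping lists,
    burden-matched controls — and all are evaluated identically.  The
    FDR adjustment runs across the supplied lists' case-arm empirical
    p-values.

    Returns a list of :class:`EnrichmentResult` (plus a dict of the
    per-(panel, arm) nulls when ``keep_nulls``).
    """
    if not gene_lists:
        raise ValueError("no gene lists supplied")
    for panel in gene_lists:
        missing = panel.missing_from(universe)
        if missing:
            raise ValueError(
                f"panel {panel.name!r} has genes outside the universe: "
                f"{sorted(missing)[:5]}"
            )
    rng = np.random.default_rng(seed)
    symbols = list(universe.symbols)
    arms = {
        "case": manifest.cases,
        "control": manifest.controls,
    }
    damaged_by_arm = {
        arm: calls.damaged_genes(samples) & set(symbols)
        for arm, samples in arms.items()
    }
    results: list[EnrichmentResult] = []
    nulls: dict[tuple[str, str], NullDistribution] = {}
    for panel in gene_lists:
        n = len(panel)
        obs = {
            arm: len(panel.genes & damaged_by_arm[arm]) for arm in arms
        }
        null_by_arm = {}
        for arm in arms:
            null = resample_null(
                symbols, n, damaged_by_arm[arm], n_draws=n_draws, rng=rng, seed=seed
            )
            null_by_arm[arm] = null
            if keep_nulls:
                nulls[(panel.name, arm)] = null
        results.append(
            EnrichmentResult(
                panel=panel.name,
                list_size=n,
                case_damaged=obs["case"],
                control_damaged=obs["control"],
                null_mean_case=null_by_arm["case"].mean,
                null_sd_case=null_by_arm["case"].sd,
                null_mean_control=null_by_arm["control"].mean,
                null_sd_control=null_by_arm["control"].sd,
                empirical_p_case=empirical_p(obs["case"], null_by_arm["case"]),
                empirical_p_control=empirical_p(
                    obs["control"], null_by_arm["control"]
                ),
                fisher_p=fisher_case_control(obs["case"], obs["control"], n),
                fdr_q=float("nan"),
                z_case=zscore(obs["case"], null_by_arm["case"]),
                z_control=zscore(obs["control"], null_by_arm["control"]),
                n_draws=n_draws,
                seed=seed,
            )
        )
    qvals = fdr_adjust([r.empirical_p_case for r in results], method=adjust_method)
    for r, q in zip(results, qvals):
        r.fdr_q = float(q)
    if keep_nulls:
        return results, nulls
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results, one row per gene list."""
    import dataclasses

    return pd.DataFrame([dataclasses.asdict(r) for r in results])
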