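"""Frequency-binned variant burden versus age at death.

Per-decedent counts of nonsynonymous panel-gene variants are tabulated
across allele-frequency bins; each bin's count is regressed against age
at death by ordinary least squares with ancestry PCs 1..k as covariates.
Raw two-sided slope p-values are adjusted across the bins, an
extreme-value sensitivity refit drops the carriers of the minimum and
maximum rare-bin burden, and subgroup burdens are compared with a
two-sided Wilcoxon rank-sum test (exhaustive enumeration at small n).
Controls carry no age, so this stage operates on cases only.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .annotate import FrequencyBins
from .datatypes import GenePanel, as_variant_frame
from .enrichment import fdr_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "AgeModelFit",
    "SubgroupComparison",
    "burden_matrix",
    "fit_age_model",
    "adjust_across_bins",
    "sensitivity_extremes",
    "compare_subgroups",
    "fits_to_frame",
]


def burden_matrix(
    variants,
    panel: GenePanel,
    bins: Optional[FrequencyBins] = None,
    samples: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-(decedent, bin) counts of nonsynonymous panel-gene variants.

    ``variants`` must already be nonsynonymous-filtered; the panel
    intersection happens here.  Samples with zero panel variants appear
    as all-zero rows.  Frequencies above the last bin edge are excluded
    from the matrix.  A variant belonging to a sample outside
    ``samples`` is an error, not a silent drop.
    """
    bins = bins or FrequencyBins()
    frame = as_variant_frame(variants)
    if samples is None:
        samples = sorted(frame["sample_id"].unique())
    else:
        samples = list(samples)
        unknown = set(frame["sample_id"]) - set(samples)
        if unknown:
            raise ValueError(
                f"variants carry sample ids absent from the manifest: "
                f"{sorted(unknown)[:5]}"
            )
    in_panel = frame[frame["gene"].isin(panel.genes)].copy()
    labels = bins.labels
    if in_panel.empty:
        return pd.DataFrame(
            0, index=pd.Index(samples, name="sample_id"), columns=labels
        )
    in_panel["bin"] = bins.assign_many(in_panel["af_global"].to_numpy()).to_numpy()
    in_panel = in_panel[in_panel["bin"].isin(labels)]
    counts = (
        in_panel.groupby(["sample_id", "bin"]).size().unstack(fill_value=0)
    )
    counts = counts.reindex(index=samples, columns=labels, fill_value=0)
    counts.index.name = "sample_id"
    return counts.astype(int)


@dataclass
class AgeModelFit:
    """One OLS fit of age at death on a burden column plus ancestry PCs."""

    bin: str
    slope: float
    stderr: float
    p_raw: float
    p_adjusted: Optional[float]
    n: int
    n_pcs: int
    extreme_excluded: bool = False
    n_excluded: int = 0


def fit_age_model(
    age: pd.Series,
    burden: pd.Series,
    pcs: pd.DataFrame,
    bin_label: str = "",
) -> AgeModelFit:
    """OLS of age ~ intercept + burden + PCs, two-sided slope t-test.

    Complete cases only (listwise deletion, count logged).  Refuses a
    zero-variance response or a rank-deficient design.
    """
    data = pd.concat(
        [age.rename("age"), burden.rename("burden"), pcs], axis=1, join="inner"
    )
    n_before = len(data)
    data = data.dropna()
    n = len(data)
    if n < n_before:
        logger.info("listwise deletion removed %d of %d samples", n_before - n, n_before)
    k_cov = 1 + pcs.shape[1]
    if n <= k_cov + 2:
        raise ValueError(
            f"only {n} complete cases for {k_cov} covariates; refusing to fit"
        )
    y = data["age"].to_numpy(dtype=float)
    if np.ptp(y) == 0.0:
        raise ValueError("age at death has zero variance; fit refused")
    X = sm.add_constant(data[["burden"] + list(pcs.columns)], has_constant="add")
    constant = [
        c for c in X.columns if c != "const" and np.ptp(X[c].to_numpy()) == 0.0
    ]
    if constant:
        raise ValueError(
            f"zero-variance covariate column(s) {constant}; fit refused"
        )
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise ValueError(
            f"design matrix rank {rank} < {X.shape[1]} columns; most "
            f"collinear pair: {worst}"
        )
    fit = sm.OLS(y, X).fit()
    return AgeModelFit(
        bin=bin_label,
        slope=float(fit.params["burden"]),
        stderr=float(fit.bse["burden"]),
        p_raw=float(fit.pvalues["burden"]),
        p_adjusted=None,
        n=n,
        n_pcs=pcs.shape[1],
    )


def adjust_across_bins(
    fits: Sequence[AgeModelFit], method: str = "fdr_bh"
) -> list[AgeModelFit]:
    """Adjust raw slope p-values across the frequency bins."""
    q = fdr_adjust([f.p_raw for f in fits], method=method)
    return [replace(f, p_adjusted=float(qi)) for f, qi in zip(fits, q)]


def sensitivity_extremes(
    age: pd.Series,
    burden: pd.Series,
    pcs: pd.DataFrame,
    bin_label: str = "",
    trim_rule: str = "minmax",
) -> tuple[AgeModelFit, AgeModelFit]:
    """Refit with the carriers of extreme burden values excluded.

    ``minmax`` (default) drops every carrier of the minimum and of the
    maximum burden value; ``percentile`` drops carriers outside the
    2.5–97.5 percentile range.  Returns (full fit, trimmed fit); both
    are always reported so the exclusion is transparent.
    """
    full = fit_age_model(age, burden, pcs, bin_label=bin_label)
    common = burden.index.intersection(age.dropna().index)
    b = burden.loc[common]
    if trim_rule == "minmax":
        keep = (b != b.min()) & (b != b.max())
    elif trim_rule == "percentile":
        lo, hi = np.percentile(b.to_numpy(dtype=float), [2.5, 97.5])
        keep = (b >= lo) & (b <= hi)
    else:
        raise ValueError(f"unknown trim_rule {trim_rule!r}")
    kept = b.index[keep]
    n_excluded = len(common) - len(kept)
    k_cov = 1 + pcs.shape[1]
    if len(kept) <= k_cov + 2:
        raise ValueError(
            f"extreme-value trimming leaves {len(kept)} samples for "
            f"{k_cov} covariates; refusing to fit"
        )
    trimmed = fit_age_model(
        age.loc[age.index.intersection(kept)], b.loc[kept], pcs, bin_label=bin_label
    )
    trimmed = replace(trimmed, extreme_excluded=True, n_excluded=n_excluded)
    return full, trimmed


@dataclass
class SubgroupComparison:
    """Two-sided rank-sum comparison of burden between subgroups."""

    p_value: float
    statistic: float
    method: str  # "exact" or "normal"
    n_a: int
    n_b: int


def _rank_sum_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exhaustive two-sided rank-sum test over all group assignments.

    Uses midranks for ties; p is the fraction of assignments whose
    rank-sum deviates from its mean by at least as much as observed.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    observed = ranks[:n_a].sum()
    expected = n_a * (len(pooled) + 1) / 2.0
    obs_dev = abs(observed - expected)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        w = ranks[list(combo)].sum()
        if abs(w - expected) >= obs_dev - 1e-12:
            count += 1
    return observed, count / total


def compare_subgroups(
    burden: pd.Series,
    group_a: Sequence[str],
    group_b: Sequence[str],
    exact_max_n: int = 10,
) -> SubgroupComparison:
    """Wilcoxon rank-sum burden comparison between two sample groups.

    Exhaustive enumeration when both groups have at most ``exact_max_n``
    members, tie-corrected normal approximation otherwise; the method
    used is reported.
    """
    set_a, set_b = set(group_a), set(group_b)
    if not set_a or not set_b:
        raise ValueError("both subgroups must be non-empty")
    overlap = set_a & set_b
    if overlap:
        raise ValueError(f"subgroups overlap: {sorted(overlap)[:5]}")
    missing = (set_a | set_b) - set(burden.index)
    if missing:
        raise ValueError(f"samples without burden values: {sorted(missing)[:5]}")
    a = burden.loc[sorted(set_a)].to_numpy(dtype=float)
    b = burden.loc[sorted(set_b)].to_numpy(dtype=float)
    if len(a) <= exact_max_n and len(b) <= exact_max_n:
        statistic, p = _rank_sum_exact(a, b)
        method = "exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        statistic, p = float(res.statistic), float(res.pvalue)
        method = "normal"
    return SubgroupComparison(
        p_value=float(min(p, 1.0)),
        statistic=float(statistic),
        method=method,
        n_a=len(a),
        n_b=len(b),
    )


def fits_to_frame(fits: Sequence[AgeModelFit]) -> pd.DataFrame:
    import dataclasses

    return pd.DataFrame([dataclasses.asdict(f) for f in fits])
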