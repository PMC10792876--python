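"""Ancestry principal components from a genotype dosage matrix.

Samples-by-variants allele dosages (0/1/2, missing allowed) are
standardised per variant and decomposed by SVD; the top-k left singular
vectors scaled by their singular values are the PC coordinates used as
regression covariates downstream.

Numerical conventions, all fixed for reproducibility:

* per-variant centering at twice the observed allele frequency 2p;
* scaling by sqrt(2p(1-p)) (population-genetics standard) or by the
  observed standard deviation (``scaling="unit"``);
* missing dosages mean-imputed (0 after centering);
* monomorphic variants dropped with a log entry;
* sign convention: the largest-magnitude variant loading of each
  component is made positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["GenotypeMatrix", "PcCoordinates", "compute_pcs", "read_dosage_tsv"]


@dataclass
class GenotypeMatrix:
    """Samples x variants allele dosages; NaN marks missing."""

    dosages: np.ndarray
    sample_ids: list[str]
    variant_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosage matrix must be 2-D (samples x variants)")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.variant_ids) != m:
            raise ValueError(f"{len(self.variant_ids)} variant ids for {m} columns")
        with np.errstate(invalid="ignore"):
            bad = np.logical_or(self.dosages < 0, self.dosages > 2)
        if np.any(bad[~np.isnan(self.dosages)]):
            raise ValueError("dosages must lie in [0, 2] or be missing")

    @property
    def missingness(self) -> np.ndarray:
        """Per-variant fraction of missing dosages."""
        return np.isnan(self.dosages).mean(axis=0)


@dataclass
class PcCoordinates:
    """Top-k PC scores with explained-variance fractions."""

    coords: np.ndarray  # samples x k
    explained_variance_ratio: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        evr = np.asarray(self.explained_variance_ratio, dtype=float)
        if np.any(np.diff(evr) > 1e-12):
            raise ValueError("explained-variance fractions must be non-increasing")
        if evr.sum() > 1 + 1e-9:
            raise ValueError("explained-variance fractions sum above 1")

    def frame(self) -> pd.DataFrame:
        k = self.coords.shape[1]
        return pd.DataFrame(
            self.coords,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"pc{i}" for i in range(1, k + 1)],
        )


def compute_pcs(
    genotypes: GenotypeMatrix, k: int = 6, scaling: str = "af"
) -> PcCoordinates:
    """Top-k ancestry PCs of a dosage matrix via SVD.

    Parameters
    ----------
    genotypes
        Samples x variants dosage matrix.
    k
        Number of components; requires at least k+1 samples and a
        post-filter matrix of rank >= k.
    scaling
        "af" for sqrt(2p(1-p)) scaling with p the observed allele
        frequency, "unit" for observed-SD scaling.
    """
    X = genotypes.dosages
    n, m = X.shape
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for k={k}, have {n}")
    if scaling not in ("af", "unit"):
        raise ValueError(f"unknown scaling {scaling!r}")

    col_mean = np.nanmean(X, axis=0)
    p = col_mean / 2.0
    if scaling == "af":
        scale = np.sqrt(2.0 * p * (1.0 - p))
    else:
        scale = np.nanstd(X, axis=0)
    keep = scale > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d monomorphic variant(s) before SVD", n_dropped)
    if not keep.any():
        raise ValueError("no polymorphic variants remain after filtering (rank 0)")
    Z = (X[:, keep] - col_mean[keep]) / scale[keep]
    Z = np.where(np.isnan(Z), 0.0, Z)  # mean imputation after centering

    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    tol = max(Z.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    if k > rank:
        raise ValueError(f"requested k={k} exceeds matrix rank {rank}")

    # fixed sign: largest-magnitude loading of each component positive
    for j in range(k):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0

    coords = U[:, :k] * s[:k]
    evr = (s**2) / (s**2).sum()
    return PcCoordinates(
        coords=coords,
        explained_variance_ratio=evr[:k],
        sample_ids=list(genotypes.sample_ids),
    )


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    """Read a samples x variants dosage TSV (first column = sample id)."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix(
        dosages=table.to_numpy(dtype=float),
        sample_ids=[str(s) for s in table.index],
        variant_ids=[str(v) for v in table.columns],
    )
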