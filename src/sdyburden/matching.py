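"""Burden-matched control gene lists.

Every gene carries a burden ratio — its reference rare-variant count per
base of largest coding transcript.  A matched control list for a test
panel is a random gene set of equal size, drawn from the universe with
the panel excluded, whose burden-ratio mean and standard deviation fall
within a relative tolerance of the panel's.  Matching is by rejection
sampling (the simplest procedure consistent with "randomly sampling"),
with an optional greedy swap refinement for tolerances too tight for
rejection alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import GenePanel, GeneUniverse

logger = logging.getLogger(__name__)

__all__ = [
    "BurdenProfile",
    "MatchedControlList",
    "MatchingError",
    "burden_ratio",
    "burden_profile",
    "sample_matched_controls",
]


def burden_ratio(transcript_length: int, ref_rare_count: int) -> float:
    """Rare variants per base of the largest coding transcript."""
    if transcript_length < 1:
        raise ValueError(f"transcript_length must be >= 1, got {transcript_length}")
    if ref_rare_count < 0:
        raise ValueError(f"ref_rare_count must be >= 0, got {ref_rare_count}")
    return ref_rare_count / transcript_length


@dataclass
class BurdenProfile:
    """Burden ratios of a gene list, with list-level mean and SD."""

    ratios: pd.Series  # indexed by symbol
    mean: float
    sd: float

    @classmethod
    def from_ratios(cls, ratios: pd.Series) -> "BurdenProfile":
        values = ratios.to_numpy(dtype=float)
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        return cls(ratios=ratios, mean=float(values.mean()), sd=sd)


def burden_profile(universe: GeneUniverse, genes=None) -> BurdenProfile:
    """Burden profile of a gene list (or of the whole universe)."""
    ratios = universe.burden_ratios()
    if genes is not None:
        genes = set(genes)
        missing = genes - set(ratios.index)
        if missing:
            raise ValueError(f"genes absent from universe: {sorted(missing)[:5]}")
        ratios = ratios.loc[sorted(genes)]
    return BurdenProfile.from_ratios(ratios)


@dataclass
class MatchedControlList:
    """A burden-matched random gene list and its bookkeeping."""

    name: str
    genes: frozenset[str]
    target_mean: float
    target_sd: float
    achieved_mean: float
    achieved_sd: float
    rel_tolerance: float
    attempts: int
    seed: Optional[int]


class MatchingError(RuntimeError):
    """Raised when no candidate met tolerance within the attempt budget."""

    def __init__(self, message: str, best: Optional[MatchedControlList] = None):
        super().__init__(message)
        self.best = best


def _within(achieved: float, target: float, rel_tol: float) -> bool:
    if target == 0.0:
        return abs(achieved) <= 1e-12
    return abs(achieved - target) <= rel_tol * abs(target)


def _deviation(achieved_mean, achieved_sd, target_mean, target_sd) -> float:
    dm = abs(achieved_mean - target_mean) / (abs(target_mean) or 1.0)
    ds = abs(achieved_sd - target_sd) / (abs(target_sd) or 1.0)
    return max(dm, ds)


def sample_matched_controls(
    target: GenePanel,
    universe: GeneUniverse,
    rel_tolerance: float = 0.10,
    max_attempts: int = 100_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    refine: bool = False,
) -> MatchedControlList:
    """Draw a burden-matched control gene list for a target panel.

    Uniform random gene sets of size ``|target|`` are drawn from the
    universe with the target excluded until both the burden-ratio mean
    and SD fall within ``rel_tolerance`` (relative) of the target's.
    With ``refine=True``, a failed budget falls back to greedy swaps
    from the best rejected candidate.

    Raises
    ------
    MatchingError
        After ``max_attempts`` failed draws (and failed refinement, if
        requested); carries the best candidate and its deviations.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    target_profile = burden_profile(universe, target.genes)
    ratios = universe.burden_ratios()
    pool = ratios.drop(labels=[g for g in target.genes if g in ratios.index])
    n = len(target.genes)
    if len(pool) < n:
        raise ValueError(
            f"universe minus target has {len(pool)} genes; need {n}"
        )
    pool_values = pool.to_numpy(dtype=float)
    pool_symbols = pool.index.to_numpy()

    batch = min(1024, max_attempts)
    attempts = 0
    best: Optional[tuple[float, np.ndarray, float, float]] = None
    while attempts < max_attempts:
        this_batch = min(batch, max_attempts - attempts)
        # one uniform-without-replacement draw per row via random keys
        keys = rng.random((this_batch, len(pool_values)))
        picks = np.argpartition(keys, n - 1, axis=1)[:, :n]
        values = pool_values[picks]
        means = values.mean(axis=1)
        sds = values.std(axis=1, ddof=1) if n > 1 else np.zeros(this_batch)
        for j in range(this_batch):
            attempts += 1
            ok_mean = _within(means[j], target_profile.mean, rel_tolerance)
            ok_sd = _within(sds[j], target_profile.sd, rel_tolerance)
            dev = _deviation(means[j], sds[j], target_profile.mean, target_profile.sd)
            if best is None or dev < best[0]:
                best = (dev, picks[j].copy(), float(means[j]), float(sds[j]))
            if ok_mean and ok_sd:
                genes = frozenset(pool_symbols[picks[j]])
                logger.info(
                    "matched list for %s after %d attempt(s): mean %.4g vs %.4g, "
                    "sd %.4g vs %.4g",
                    target.name, attempts, means[j], target_profile.mean,
                    sds[j], target_profile.sd,
                )
                return MatchedControlList(
                    name=f"{target.name}_matched",
                    genes=genes,
                    target_mean=target_profile.mean,
                    target_sd=target_profile.sd,
                    achieved_mean=float(means[j]),
                    achieved_sd=float(sds[j]),
                    rel_tolerance=rel_tolerance,
                    attempts=attempts,
                    seed=seed,
                )

    assert best is not None
    if refine:
        refined = _greedy_refine(
            best[1], pool_values, pool_symbols, target_profile, rel_tolerance, rng
        )
        if refined is not None:
            idx, mean, sd, extra = refined
            return MatchedControlList(
                name=f"{target.name}_matched",
                genes=frozenset(pool_symbols[idx]),
                target_mean=target_profile.mean,
                target_sd=target_profile.sd,
                achieved_mean=mean,
                achieved_sd=sd,
                rel_tolerance=rel_tolerance,
                attempts=attempts + extra,
                seed=seed,
            )

    best_list = MatchedControlList(
        name=f"{target.name}_matched",
        genes=frozenset(pool_symbols[best[1]]),
        target_mean=target_profile.mean,
        target_sd=target_profile.sd,
        achieved_mean=best[2],
        achieved_sd=best[3],
        rel_tolerance=rel_tolerance,
        attempts=attempts,
        seed=seed,
    )
    raise MatchingError(
        f"no matched list for {target.name!r} within tolerance "
        f"{rel_tolerance:.3g} after {attempts} attempts; best candidate "
        f"mean {best[2]:.4g} (target {target_profile.mean:.4g}), "
        f"sd {best[3]:.4g} (target {target_profile.sd:.4g})",
        best=best_list,
    )


def _greedy_refine(
    idx: np.ndarray,
    pool_values: np.ndarray,
    pool_symbols: np.ndarray,
    target: BurdenProfile,
    rel_tolerance: float,
    rng: np.random.Generator,
    max_swaps: int = 2000,
):
    """Greedy single-gene swaps reducing the worst relative deviation."""
    idx = idx.copy()
    chosen = set(idx.tolist())
    swaps = 0
    for _ in range(max_swaps):
        values = pool_values[idx]
        mean = float(values.mean())
        sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
        if _within(mean, target.mean, rel_tolerance) and _within(
            sd, target.sd, rel_tolerance
        ):
            return idx, mean, sd, swaps
        current = _deviation(mean, sd, target.mean, target.sd)
        out_pos = rng.integers(len(idx))
        candidates = rng.integers(len(pool_values), size=32)
        improved = False
        for cand in candidates:
            if cand in chosen:
                continue
            trial = idx.copy()
            trial[out_pos] = cand
            tv = pool_values[trial]
            tm = float(tv.mean())
            ts = float(tv.std(ddof=1)) if len(tv) > 1 else 0.0
            if _deviation(tm, ts, target.mean, target.sd) < current:
                chosen.discard(int(idx[out_pos]))
                chosen.add(int(cand))
                idx = trial
                improved = True
                swaps += 1
                break
        if not improved:
            swaps += 1
    return None
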