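"""Rarefaction and alpha-diversity estimation.

Chao1 (bias-corrected), Shannon entropy (natural log by default),
Good's coverage and sample-based accumulation curves; rarefaction is
subsampling without replacement to a fixed depth, with samples below
the depth dropped under a logged warning.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.diversity.alpha import goods_coverage as _skbio_goods
from skbio.diversity.alpha import shannon as _skbio_shannon
from skbio.stats import subsample_counts

from .io import CountTable

logger = logging.getLogger("rhizoassembly")

__all__ = [
    "rarefy",
    "chao1",
    "shannon",
    "goods_coverage",
    "observed_richness",
    "alpha_diversity_table",
    "accumulation_curve",
]


def _check_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.ndim != 1:
        raise ValueError("expected a single sample's count vector")
    if (arr < 0).any():
        raise ValueError("negative counts")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValueError("counts must be integers")
        arr = arr.astype(np.int64)
    if arr.sum() == 0:
        raise ValueError("all-zero sample")
    return arr


def rarefy(table: CountTable, depth: int | str = "min", seed: int = 0) -> CountTable:
    """Subsample every sample to the same depth, without replacement.

    ``depth="min"`` uses the minimum per-sample total.  Samples whose
    total is below an explicit integer depth are dropped with a logged
    warning rather than padded.
    """
    totals = table.sample_totals()
    if depth == "min":
        depth_i = int(totals.min())
    else:
        depth_i = int(depth)
    if depth_i <= 0:
        raise ValueError("rarefaction depth must be > 0")
    keep = totals[totals >= depth_i].index
    dropped = [s for s in table.sample_ids if s not in set(keep)]
    if dropped:
        logger.warning("rarefy: dropping %d samples below depth %d: %s",
                       len(dropped), depth_i, dropped)
    if len(keep) == 0:
        raise ValueError(f"no samples at or above depth {depth_i}")
    rng = np.random.default_rng(int(seed))
    rows = []
    for s in keep:
        vec = table.data.loc[s].to_numpy()
        if vec.sum() == depth_i:
            rows.append(vec)
        else:
            rows.append(subsample_counts(vec, depth_i, seed=int(rng.integers(2**31))))
    out = pd.DataFrame(np.vstack(rows), index=list(keep), columns=table.taxon_ids)
    return CountTable(out)


def observed_richness(counts) -> int:
    return int((np.asarray(_check_counts(counts)) > 0).sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1))."""
    return float(_skbio_chao1(_check_counts(counts), bias_corrected=True))


def shannon(counts, base: float = np.e) -> float:
    """Shannon entropy -sum p_i log p_i, natural log by default."""
    return float(_skbio_shannon(_check_counts(counts), base=base))


def goods_coverage(counts) -> float:
    """Good's coverage 1 - F1/N (F1 = singleton count, N = total reads)."""
    return float(_skbio_goods(_check_counts(counts)))


def alpha_diversity_table(table: CountTable, base: float = np.e) -> pd.DataFrame:
    """Per-sample Chao1, Shannon, Good's coverage and observed richness."""
    records = []
    for s in table.sample_ids:
        vec = table.data.loc[s].to_numpy()
        records.append(
            {
                "sample_id": s,
                "observed_richness": observed_richness(vec),
                "chao1": chao1(vec),
                "shannon": shannon(vec, base=base),
                "goods_coverage": goods_coverage(vec),
            }
        )
    return pd.DataFrame(records)


def accumulation_curve(
    table: CountTable, n_permutations: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Species accumulation: mean richness after k samples over random
    sample orderings (the curve that should approach an asymptote when
    sequencing effort suffices)."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(int(seed))
    presence = (table.counts > 0)
    n = table.n_samples
    acc = np.zeros((n_permutations, n))
    for p in range(n_permutations):
        order = rng.permutation(n)
        seen = np.zeros(table.n_taxa, dtype=bool)
        for k, idx in enumerate(order):
            seen |= presence[idx]
            acc[p, k] = seen.sum()
    return pd.DataFrame(
        {"n_samples": np.arange(1, n + 1), "mean_richness": acc.mean(axis=0),
         "sd_richness": acc.std(axis=0, ddof=0)}
    )
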