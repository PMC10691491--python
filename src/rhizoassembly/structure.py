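"""Beta diversity, ordination, PERMANOVA and set arithmetic.

Bray-Curtis dissimilarities feed a permutation MANOVA (pseudo-F with
R^2 = SS_between / SS_total and an add-one permutation p) and a
non-metric multidimensional scaling (Kruskal stress-1, SMACOF with
isotonic regression, best of several random starts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from .io import CountTable

__all__ = [
    "bray_curtis",
    "permanova",
    "PermanovaResult",
    "nmds",
    "NmdsResult",
    "welch_ttest",
    "shared_sets",
]


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis: sum|x_ik - x_jk| / sum(x_ik + x_jk)."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    totals = table.sample_totals()
    zero = totals[totals == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-total samples: {zero}")
    d = squareform(pdist(table.counts.astype(float), metric="braycurtis"))
    return DistanceMatrix(d, ids=table.sample_ids)


@dataclass
class PermanovaResult:
    factor: str
    r2: float
    pseudo_f: float
    p: float
    n_permutations: int


def _ss_within(d2: np.ndarray, labels_idx: np.ndarray, n_groups: int) -> float:
    # SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2
    ss = 0.0
    for g in range(n_groups):
        mask = labels_idx == g
        n_g = int(mask.sum())
        if n_g < 2:
            continue
        ss += d2[np.ix_(mask, mask)].sum() / (2.0 * n_g)
    return ss


def permanova(
    dm: DistanceMatrix,
    labels: Sequence[str] | Mapping[str, str],
    n_permutations: int = 999,
    seed: int = 0,
    factor: str = "factor",
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    SS_total = (1/N) sum_{i<j} d^2; pseudo-F uses (a-1, N-a) degrees of
    freedom; the p-value is (#{F_perm >= F_obs} + 1) / (n_perm + 1), so
    it is never reported as 0.  Degenerate inputs (all distances equal
    within rounding) return pseudo_f = NaN, R^2 = 0, p = 1.
    """
    ids = list(dm.ids)
    if isinstance(labels, Mapping):
        lab = [labels[i] for i in ids]
    else:
        lab = list(labels)
        if len(lab) != len(ids):
            raise ValueError("labels length must match distance matrix")
    levels = sorted(set(lab))
    n_groups = len(levels)
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    counts = pd.Series(lab).value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with a single sample: {small}")
    idx = np.array([levels.index(x) for x in lab])
    n = len(ids)
    d2 = np.asarray(dm.data) ** 2
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _ss_within(d2, idx, n_groups)
    ss_between = ss_total - ss_within
    if ss_total <= 1e-12:
        return PermanovaResult(factor, 0.0, float("nan"), 1.0, n_permutations)
    f_obs = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups)) if ss_within > 0 else np.inf
    rng = np.random.default_rng(int(seed))
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(idx)
        ss_w = _ss_within(d2, perm, n_groups)
        f_perm = (
            ((ss_total - ss_w) / (n_groups - 1)) / (ss_w / (n - n_groups))
            if ss_w > 0
            else np.inf
        )
        if f_perm >= f_obs:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return PermanovaResult(factor, float(ss_between / ss_total), float(f_obs), float(p), n_permutations)


@dataclass
class NmdsResult:
    coordinates: pd.DataFrame
    stress: float
    converged: bool


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_starts: int = 8,
    max_iter: int = 300,
    seed: int = 0,
) -> NmdsResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    SMACOF majorization with isotonic regression of the disparities
    (ties averaged within blocks), restarted from ``n_starts`` random
    configurations; the lowest-stress solution is kept.
    """
    from sklearn.manifold import MDS

    n = len(dm.ids)
    if k <= 0:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError("k must be < number of samples")
    model = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        n_init=n_starts,
        max_iter=max_iter,
        random_state=int(seed),
        init="random",
        normalized_stress=True,
    )
    coords = model.fit_transform(np.asarray(dm.data))
    cols = [f"NMDS{i + 1}" for i in range(k)]
    df = pd.DataFrame(coords, index=list(dm.ids), columns=cols)
    converged = model.n_iter_ < max_iter
    return NmdsResult(df, float(model.stress_), bool(converged))


def welch_ttest(x, y) -> tuple[float, float, float]:
    """Two-sided Welch t-test; returns (t, Welch-Satterthwaite df, p).

    Zero variance in both groups with equal means returns t=0, p=1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need n >= 2 per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if np.isclose(x.mean(), y.mean()):
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return float("inf") * np.sign(x.mean() - y.mean()), float(len(x) + len(y) - 2), 0.0
    res = scipy.stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def shared_sets(groups: Mapping[str, set]) -> pd.DataFrame:
    """All Venn regions over the groups' taxon-id sets.

    Each region is the set of elements in exactly the named groups and
    no others; the region counts partition the union.
    """
    names = list(groups)
    if not names:
        raise ValueError("no groups")
    sets = {g: set(groups[g]) for g in names}
    union = set().union(*sets.values())
    rows = []
    for mask in range(1, 2 ** len(names)):
        members = [names[i] for i in range(len(names)) if mask >> i & 1]
        region = set(union)
        for g in names:
            if g in members:
                region &= sets[g]
            else:
                region -= sets[g]
        rows.append(
            {
                "region": "&".join(members),
                "n_groups": len(members),
                "count": len(region),
                "members": sorted(region),
            }
        )
    return pd.DataFrame(rows)
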