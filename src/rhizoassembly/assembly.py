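"""Null-model partitioning of community assembly processes.

For every sample pair the pipeline computes:

* βMNTD — abundance-weighted mean distance from each taxon in one
  community to its nearest relative in the other, from the cophenetic
  matrix of a rooted phylogeny;
* βNTI — the z-score of observed βMNTD against a null built by
  shuffling taxon labels across all tree tips (which randomizes
  phylogenetic relatedness while preserving composition);
* RCbray — the Bray-Curtis-based Raup-Crick index: observed
  dissimilarity ranked within a null that reassembles each community by
  drawing its observed richness of taxa (probability proportional to
  occupancy across samples) and filling its observed number of reads
  (each drawn taxon seeded with one read, the remainder multinomial
  with regional-abundance weights), rescaled to [-1, 1].

Pairs with |βNTI| > 2 are deterministic (heterogeneous selection when
positive, homogeneous when negative); the remaining stochastic pairs
split on RCbray into dispersal limitation (> 0.95), homogenizing
dispersal (< -0.95) and drift (otherwise).  Ties at the thresholds fall
to the stochastic / drift side (the deterministic rules are strict
inequalities).
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

from .io import CountTable, cophenetic_matrix

logger = logging.getLogger("rhizoassembly")

__all__ = [
    "bmntd",
    "bnti",
    "rc_bray",
    "rc_bray_exact",
    "classify_pair",
    "process_fractions",
    "assembly_analysis",
    "PROCESSES",
]

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)


def _freq_presence(table: CountTable, weighted: bool) -> tuple[np.ndarray, np.ndarray]:
    counts = table.counts.astype(float)
    pres = counts > 0
    if weighted:
        freq = counts / counts.sum(axis=1, keepdims=True)
    else:
        freq = pres / pres.sum(axis=1, keepdims=True)
    return freq, pres


def _pair_bmntd(
    d: np.ndarray,
    fi: np.ndarray,
    fj: np.ndarray,
    ai: np.ndarray,
    aj: np.ndarray,
) -> float:
    sub = d[np.ix_(ai, aj)]
    return 0.5 * (fi[ai] @ sub.min(axis=1) + fj[aj] @ sub.min(axis=0))


def bmntd(table: CountTable, tree: TreeNode, weighted: bool = True) -> DistanceMatrix:
    """Between-community mean nearest taxon distance matrix.

    A taxon shared by both communities contributes distance 0 (its
    nearest relative in the other community is itself).  Every taxon
    with a nonzero count must be a tip of the tree.
    """
    present_taxa = [t for t, tot in table.data.sum(axis=0).items() if tot > 0]
    sub = table.select_taxa(present_taxa)
    d, _ = cophenetic_matrix(tree, present_taxa)
    freq, pres = _freq_presence(sub, weighted)
    n = sub.n_samples
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        ai, aj = np.flatnonzero(pres[i]), np.flatnonzero(pres[j])
        out[i, j] = out[j, i] = _pair_bmntd(d, freq[i], freq[j], ai, aj)
    return DistanceMatrix(out, ids=sub.sample_ids)


def bnti(
    table: CountTable,
    tree: TreeNode,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
    batch: int = 64,
) -> pd.DataFrame:
    """Per-pair βNTI against a taxa-label-shuffling null.

    Labels are shuffled across *all* tips of the tree — including tips
    absent from the table — so the null randomizes phylogenetic
    relatedness over the whole pool, and the same ``n_null``
    permutations are applied to every pair.  Pairs whose null
    distribution is degenerate (zero standard deviation, e.g. identical
    communities or a star phylogeny) get βNTI = 0 and
    ``degenerate=True``; downstream classification then relies on
    RCbray alone.
    """
    if n_null < 10:
        raise ValueError("n_null must be >= 10")
    present_taxa = [t for t, tot in table.data.sum(axis=0).items() if tot > 0]
    all_tips = sorted(t.name for t in tree.tips())
    missing = sorted(set(present_taxa) - set(all_tips))
    if missing:
        raise ValueError(f"taxa absent from tree: {missing}")
    order = present_taxa + [t for t in all_tips if t not in set(present_taxa)]
    sub = table.select_taxa(present_taxa)
    d, _ = cophenetic_matrix(tree, order)
    freq, pres = _freq_presence(sub, weighted)
    n = sub.n_samples
    n_taxa = len(order)  # shuffle across the full tip set
    rng = np.random.default_rng(int(seed))
    perms = np.vstack([rng.permutation(n_taxa) for _ in range(n_null)])

    rows = []
    for i, j in itertools.combinations(range(n), 2):
        ai, aj = np.flatnonzero(pres[i]), np.flatnonzero(pres[j])
        obs = _pair_bmntd(d, freq[i], freq[j], ai, aj)
        nulls = np.empty(n_null)
        wi, wj = freq[i][ai], freq[j][aj]
        for start in range(0, n_null, batch):
            pr = perms[start : start + batch]
            rowsel = pr[:, ai]  # (b, a)
            colsel = pr[:, aj]  # (b, c)
            subd = d[rowsel[:, :, None], colsel[:, None, :]]  # (b, a, c)
            nulls[start : start + batch] = 0.5 * (
                subd.min(axis=2) @ wi + subd.min(axis=1) @ wj
            )
        mu, sd = float(nulls.mean()), float(nulls.std(ddof=0))
        degenerate = sd <= 1e-12
        z = 0.0 if degenerate else (obs - mu) / sd
        rows.append(
            {
                "sample_i": sub.sample_ids[i],
                "sample_j": sub.sample_ids[j],
                "bmntd_obs": obs,
                "bmntd_null_mean": mu,
                "bmntd_null_sd": sd,
                "bnti": z,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def _bray_curtis_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    num = np.abs(x - y).sum(axis=-1)
    den = (x + y).sum(axis=-1)
    return num / den


def rc_bray(
    table: CountTable, n_null: int = 999, seed: int = 0
) -> pd.DataFrame:
    """Per-pair Bray-Curtis Raup-Crick index in [-1, 1].

    Null assemblies preserve each sample's observed richness and read
    total; taxon identity is drawn with probability proportional to
    occupancy across all samples, and reads beyond the one seeded per
    drawn taxon with probability proportional to regional relative
    abundance.  Equal null and observed dissimilarities count half.
    """
    if table.n_samples < 2:
        raise ValueError("need >= 2 samples")
    counts = table.counts.astype(float)
    occupancy = (counts > 0).sum(axis=0).astype(float)
    regional = counts.sum(axis=0)
    if (occupancy == 0).any():
        keep = occupancy > 0
        counts = counts[:, keep]
        occupancy = occupancy[keep]
        regional = regional[keep]
    n_taxa = counts.shape[1]
    rng = np.random.default_rng(int(seed))

    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1).astype(int)
    if (richness > n_taxa).any():  # pragma: no cover - impossible by construction
        raise ValueError("sample richness exceeds regional pool size")

    def null_communities(s_idx: int) -> np.ndarray:
        s = int(richness[s_idx])
        n_reads = int(totals[s_idx])
        # weighted sampling without replacement via Gumbel top-k
        keys = np.log(occupancy) + rng.gumbel(size=(n_null, n_taxa))
        drawn = np.argpartition(-keys, s - 1, axis=1)[:, :s]
        comm = np.zeros((n_null, n_taxa))
        np.put_along_axis(comm, drawn, 1.0, axis=1)
        remaining = n_reads - s
        if remaining > 0:
            probs = comm * regional
            probs /= probs.sum(axis=1, keepdims=True)
            comm += rng.multinomial(remaining, probs)
        return comm

    rows = []
    n = table.n_samples
    for i, j in itertools.combinations(range(n), 2):
        bc_obs = float(_bray_curtis_rows(counts[i], counts[j]))
        x = null_communities(i)
        y = null_communities(j)
        bc_null = _bray_curtis_rows(x, y)
        equal = np.isclose(bc_null, bc_obs, rtol=0.0, atol=1e-10)
        less = (bc_null < bc_obs) & ~equal
        rc = 2.0 * ((less.sum() + 0.5 * equal.sum()) / n_null) - 1.0
        rows.append(
            {
                "sample_i": table.sample_ids[i],
                "sample_j": table.sample_ids[j],
                "bc_obs": bc_obs,
                "rc_bray": float(rc),
            }
        )
    return pd.DataFrame(rows)


def _subset_probabilities(weights: np.ndarray, k: int) -> dict[tuple[int, ...], float]:
    """Probability of each size-k subset under sequential weighted
    sampling without replacement (exhaustive over orderings)."""
    n = len(weights)
    out: dict[tuple[int, ...], float] = {}
    for subset in itertools.combinations(range(n), k):
        p = 0.0
        for order in itertools.permutations(subset):
            q = 1.0
            rem = weights.sum()
            for t in order:
                q *= weights[t] / rem
                rem -= weights[t]
            p += q
        out[subset] = p
    return out


def _allocation_probabilities(
    subset: tuple[int, ...], weights: np.ndarray, extra: int
) -> list[tuple[np.ndarray, float]]:
    """All multinomial allocations of ``extra`` reads over the drawn
    taxa (each already holding one read) with their probabilities."""
    k = len(subset)
    w = weights[list(subset)]
    q = w / w.sum()
    out = []
    for comp in _compositions(extra, k):
        logp = (
            math.lgamma(extra + 1)
            - sum(math.lgamma(c + 1) for c in comp)
            + sum(c * math.log(qi) for c, qi in zip(comp, q) if c > 0)
        )
        vec = np.zeros(len(weights))
        for t, c in zip(subset, comp):
            vec[t] = 1 + c
        out.append((vec, math.exp(logp)))
    return out


def _compositions(total: int, parts: int):
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def rc_bray_exact(table: CountTable, sample_i: str, sample_j: str) -> float:
    """Exact RCbray for one pair by exhaustive enumeration of the null.

    Tractable only for tiny regional pools (<= ~5 taxa, a few reads per
    sample); serves as the ground-truth check of the Monte-Carlo
    estimator.
    """
    counts = table.counts.astype(float)
    occupancy = (counts > 0).sum(axis=0).astype(float)
    regional = counts.sum(axis=0)
    i = table.sample_ids.index(sample_i)
    j = table.sample_ids.index(sample_j)
    bc_obs = float(_bray_curtis_rows(counts[i], counts[j]))

    def community_distribution(idx: int) -> list[tuple[np.ndarray, float]]:
        s = int((counts[idx] > 0).sum())
        n_reads = int(counts[idx].sum())
        out = []
        for subset, p_sub in _subset_probabilities(occupancy, s).items():
            for vec, p_alloc in _allocation_probabilities(
                subset, regional, n_reads - s
            ):
                out.append((vec, p_sub * p_alloc))
        return out

    dist_i = community_distribution(i)
    dist_j = community_distribution(j)
    p_less = p_equal = 0.0
    for vec_x, px in dist_i:
        for vec_y, py in dist_j:
            bc = float(_bray_curtis_rows(vec_x, vec_y))
            if np.isclose(bc, bc_obs, rtol=0.0, atol=1e-10):
                p_equal += px * py
            elif bc < bc_obs:
                p_less += px * py
    return 2.0 * (p_less + 0.5 * p_equal) - 1.0


def classify_pair(bnti_value: float, rc: float) -> str:
    """Five-way process call from (βNTI, RCbray); strict thresholds."""
    if not (np.isfinite(bnti_value) and np.isfinite(rc)):
        raise ValueError("non-finite inputs")
    if not -1.0 - 1e-9 <= rc <= 1.0 + 1e-9:
        raise ValueError("RCbray outside [-1, 1]")
    if bnti_value > 2:
        return "heterogeneous_selection"
    if bnti_value < -2:
        return "homogeneous_selection"
    if rc > 0.95:
        return "dispersal_limitation"
    if rc < -0.95:
        return "homogenizing_dispersal"
    return "drift"


def assembly_analysis(
    table: CountTable,
    tree: TreeNode,
    n_null_bnti: int = 999,
    n_null_rc: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> pd.DataFrame:
    """βNTI + RCbray + process call for every sample pair."""
    z = bnti(table, tree, n_null=n_null_bnti, seed=seed, weighted=weighted)
    rc = rc_bray(table, n_null=n_null_rc, seed=seed + 1)
    merged = z.merge(rc, on=["sample_i", "sample_j"], validate="one_to_one")
    merged["process"] = [
        classify_pair(b, r) for b, r in zip(merged["bnti"], merged["rc_bray"])
    ]
    return merged


def process_fractions(
    pairs: pd.DataFrame, grouping: Mapping[str, str]
) -> pd.DataFrame:
    """Per-group fractions of each process over within-group pairs."""
    rows = []
    gi = pairs["sample_i"].map(dict(grouping))
    gj = pairs["sample_j"].map(dict(grouping))
    within = pairs[gi == gj].assign(group=gi[gi == gj])
    if within.empty:
        raise ValueError("no within-group pairs")
    for group, chunk in within.groupby("group"):
        frac = {p: float((chunk["process"] == p).mean()) for p in PROCESSES}
        rows.append({"group": group, "n_pairs": len(chunk), **frac})
    return pd.DataFrame(rows)
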