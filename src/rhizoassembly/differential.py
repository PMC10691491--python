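"""Negative-binomial exact-test enrichment between compartments.

The procedure mirrors the classic count-based differential-abundance
workflow for small balanced designs: an overall relative-abundance
filter, TMM (trimmed mean of M-values) scaling factors, library-size
equalization to the geometric-mean effective library size, a common
dispersion estimated by conditional maximum likelihood, and a two-sided
exact test of the group split conditioned on the taxon total.  Taxa are
called enriched / depleted at FDR-adjusted p < 0.05 and |log2 fold
change| > 1 (strict), matching the filtering rule used throughout the
pipeline.

``dispersion=0`` is the exact Poisson limit, in which the conditional
distribution of the group split given the total is binomial.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .io import CountTable

logger = logging.getLogger("rhizoassembly")

__all__ = [
    "abundance_filter",
    "tmm_factors",
    "nb_exact_test",
    "estimate_common_dispersion",
    "bh_adjust",
    "classify",
    "enrichment_analysis",
]


def abundance_filter(table: CountTable, min_rel: float) -> CountTable:
    """Keep taxa whose overall relative abundance (taxon total over the
    grand total) is strictly greater than ``min_rel``."""
    if not 0.0 <= min_rel < 1.0:
        raise ValueError("min_rel must be in [0, 1)")
    totals = table.data.sum(axis=0)
    grand = totals.sum()
    keep = totals[totals / grand > min_rel].index
    if len(keep) == 0:
        raise ValueError("abundance filter removed all taxa")
    logger.info("abundance_filter: kept %d / %d taxa at min_rel=%g",
                len(keep), table.n_taxa, min_rel)
    return table.select_taxa(list(keep))


def tmm_factors(
    table: CountTable, trim_logfc: float = 0.30, trim_abs: float = 0.05
) -> pd.Series:
    """TMM normalization factors, geometric mean 1.

    The reference is the sample whose 75th percentile of relative
    abundance is closest to the mean across samples.  Per sample,
    log2 abundance ratios (M) against the reference are trimmed by
    ``trim_logfc`` in each tail and log2 average abundances (A) by
    ``trim_abs``; the factor is 2 to the precision-weighted mean of the
    surviving M values.
    """
    if table.n_samples < 2:
        raise ValueError("need >= 2 samples")
    counts = table.counts.astype(float)
    lib = counts.sum(axis=1)
    rel = counts / lib[:, None]
    q75 = np.percentile(rel, 75, axis=1)
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    ref = counts[ref_idx]
    ref_lib = lib[ref_idx]
    log_factors = np.zeros(table.n_samples)
    for i in range(table.n_samples):
        if i == ref_idx:
            continue
        obs = counts[i]
        both = (obs > 0) & (ref > 0)
        if not both.any():
            logger.warning("tmm_factors: sample %s shares no taxa with the "
                           "reference; factor set to 1", table.sample_ids[i])
            continue
        y, r = obs[both], ref[both]
        m = np.log2((y / lib[i]) / (r / ref_lib))
        a = 0.5 * np.log2((y / lib[i]) * (r / ref_lib))
        # asymptotic inverse variance of M (delta method)
        w = (lib[i] - y) / (lib[i] * y) + (ref_lib - r) / (ref_lib * r)
        n = len(m)
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        # symmetric double trim: drop floor(n*trim) values from each tail
        lo_m = np.floor(n * trim_logfc) + 1
        lo_a = np.floor(n * trim_abs) + 1
        keep = (
            (rank_m >= lo_m)
            & (rank_m <= n + 1 - lo_m)
            & (rank_a >= lo_a)
            & (rank_a <= n + 1 - lo_a)
        )
        if not keep.any():
            keep = np.ones(n, dtype=bool)
        log_factors[i] = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=table.sample_ids, name="tmm_factor")


def _nb_logpmf(k: np.ndarray, mean: float, dispersion: float) -> np.ndarray:
    """NB log-pmf parametrized by mean and dispersion (var = m + phi m^2);
    dispersion 0 is the Poisson limit."""
    k = np.asarray(k, dtype=float)
    if dispersion == 0.0:
        return k * np.log(mean) - mean - gammaln(k + 1)
    r = 1.0 / dispersion
    return (
        gammaln(k + r)
        - gammaln(r)
        - gammaln(k + 1)
        + r * np.log(r / (r + mean))
        + k * np.log(mean / (r + mean))
    )


def _exact_p_integer(y1: int, t: int, n1: int, n2: int, dispersion: float) -> float:
    """Two-sided conditional exact p at an integer split y1 of total t.

    Sums the conditional probabilities of every split whose probability
    does not exceed that of the observed split (small-p two-sided rule).
    """
    ks = np.arange(t + 1)
    m = t / (n1 + n2)  # per-sample mean under the null
    lp = _nb_logpmf(ks, n1 * m, dispersion / n1) + _nb_logpmf(
        ks[::-1], n2 * m, dispersion / n2
    )
    lp -= logsumexp(lp)
    obs = lp[y1]
    mask = lp <= obs + 1e-10
    return float(min(1.0, np.exp(logsumexp(lp[mask]))))


def _exact_p(y1: float, t: float, n1: int, n2: int, dispersion: float) -> float:
    """Exact-test p with linear interpolation for non-integer
    library-size-adjusted pseudo-sums."""
    t_int = max(1, int(round(t)))
    y = y1 * t_int / t if t > 0 else 0.0
    y = min(max(y, 0.0), float(t_int))
    lo, hi = int(np.floor(y)), int(np.ceil(y))
    p_lo = _exact_p_integer(lo, t_int, n1, n2, dispersion)
    if hi == lo:
        return p_lo
    p_hi = _exact_p_integer(min(hi, t_int), t_int, n1, n2, dispersion)
    w = y - lo
    return (1 - w) * p_lo + w * p_hi


def _pseudo_counts(table: CountTable) -> tuple[pd.DataFrame, float]:
    """Scale each sample to the geometric-mean effective library size."""
    factors = tmm_factors(table)
    lib = table.sample_totals().astype(float)
    eff = lib * factors
    target = float(np.exp(np.mean(np.log(eff))))
    pseudo = table.data.astype(float).mul(target / eff, axis=0)
    return pseudo, target


def estimate_common_dispersion(
    pseudo: pd.DataFrame, labels: pd.Series
) -> float:
    """Common NB dispersion by conditional maximum likelihood.

    Maximizes, over all taxa and groups, the likelihood of the
    within-group counts conditional on their group sum (which removes
    the per-taxon mean as a nuisance parameter).
    """
    groups = [pseudo.loc[labels.index[labels == g]].to_numpy()
              for g in labels.unique()]

    def neg_cll(log_phi: float) -> float:
        phi = np.exp(log_phi)
        r = 1.0 / phi
        total = 0.0
        for y in groups:
            n_g = y.shape[0]
            z = y.sum(axis=0)
            total += (
                gammaln(y + r).sum()
                - n_g * y.shape[1] * gammaln(r)
                + gammaln(n_g * r) * y.shape[1]
                - gammaln(z + n_g * r).sum()
            )
        return -total

    res = minimize_scalar(neg_cll, bounds=(np.log(1e-4), np.log(10.0)),
                          method="bounded", options={"xatol": 1e-4})
    return float(np.exp(res.x))


def nb_exact_test(
    table: CountTable,
    groups: Mapping[str, str] | pd.Series,
    dispersion: float | str = "estimate",
    group_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-taxon exact NB test between two groups of samples.

    Returns a frame with ``log2fc`` (first group over second, with a
    0.5 prior count on the normalized group means) and the two-sided
    exact ``p`` conditioned on each taxon's total.
    """
    labels = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    labels = labels.loc[[s for s in table.sample_ids if s in labels.index]]
    levels = list(pd.unique(labels))
    if group_order is not None:
        if sorted(group_order) != sorted(levels):
            raise ValueError("group_order does not match the labels present")
        levels = list(group_order)
    if len(levels) != 2:
        raise ValueError(f"exactly 2 groups required, got {levels}")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("need >= 2 samples per group")
    if isinstance(dispersion, (int, float)) and dispersion < 0:
        raise ValueError("dispersion must be >= 0")

    sub = table.select_samples(list(labels.index))
    pseudo, _ = _pseudo_counts(sub)
    if dispersion == "estimate":
        phi = estimate_common_dispersion(pseudo, labels)
        logger.info("nb_exact_test: common dispersion (CML) = %.4g", phi)
    else:
        phi = float(dispersion)

    idx1 = labels.index[labels == levels[0]]
    idx2 = labels.index[labels == levels[1]]
    n1, n2 = len(idx1), len(idx2)
    y1 = pseudo.loc[idx1].sum(axis=0)
    y2 = pseudo.loc[idx2].sum(axis=0)
    rows = []
    for taxon in pseudo.columns:
        a, b = float(y1[taxon]), float(y2[taxon])
        t = a + b
        if t <= 0:
            p = 1.0
        else:
            p = _exact_p(a, t, n1, n2, phi)
        log2fc = float(np.log2((a / n1 + 0.5) / (b / n2 + 0.5)))
        rows.append({"taxon_id": taxon, "log2fc": log2fc, "p": max(p, 1e-300)})
    out = pd.DataFrame(rows).set_index("taxon_id")
    out.attrs["dispersion"] = phi
    out.attrs["groups"] = tuple(levels)
    return out


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up with monotonicity enforcement."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify(
    log2fc: float, fdr_p: float, alpha: float = 0.05, lfc: float = 1.0
) -> str:
    """Enriched / depleted / ns per FDR < alpha and |log2FC| > lfc (strict)."""
    if fdr_p < alpha and log2fc > lfc:
        return "enriched"
    if fdr_p < alpha and log2fc < -lfc:
        return "depleted"
    return "ns"


def enrichment_analysis(
    table: CountTable,
    groups: Mapping[str, str] | pd.Series,
    min_rel: float = 1e-4,
    dispersion: float | str = "estimate",
    alpha: float = 0.05,
    lfc: float = 1.0,
    group_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Filter, test, adjust and label; sorted by FDR-adjusted p."""
    labels = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    sub = table.select_samples([s for s in table.sample_ids if s in labels.index])
    filtered = abundance_filter(sub, min_rel)
    res = nb_exact_test(filtered, labels, dispersion=dispersion,
                        group_order=group_order)
    res["fdr_p"] = bh_adjust(res["p"].to_numpy())
    res["label"] = [classify(l, q, alpha=alpha, lfc=lfc)
                    for l, q in zip(res["log2fc"], res["fdr_p"])]
    rel = filtered.relative_abundance().mean(axis=0)
    res["mean_relative_abundance"] = rel.loc[res.index]
    return res.sort_values("fdr_p").reset_index()
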