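"""Spearman co-occurrence networks, RMT thresholding, keystone taxa.

Dominant taxa (overall relative abundance above a floor, detected in at
least a fraction of samples) are correlated by Spearman's rho; the
correlation cutoff is chosen where the thresholded matrix's
nearest-neighbour eigenvalue-spacing distribution transitions from the
Gaussian orthogonal ensemble (correlated, Wigner-Dyson) to Poisson
(uncorrelated) statistics, the random-matrix-theory criterion.  Nodes
with high degree (top 20%) but low betweenness centrality (bottom 20%
of those high-degree nodes) are flagged as keystone taxa.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

from .differential import bh_adjust
from .io import CountTable

logger = logging.getLogger("rhizoassembly")

__all__ = [
    "prevalence_filter",
    "spearman_matrix",
    "rmt_threshold",
    "build_network",
    "topology",
    "keystone_taxa",
    "CooccurrenceNetwork",
    "NetworkTopology",
    "network_analysis",
]


def prevalence_filter(
    table: CountTable,
    min_rel: float = 1e-4,
    min_prevalence_fraction: float = 1 / 3,
) -> CountTable:
    """Keep taxa above an overall relative-abundance floor that occur in
    at least ceil(fraction x n_samples) samples."""
    if not (0 <= min_rel <= 1 and 0 <= min_prevalence_fraction <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    totals = table.data.sum(axis=0)
    grand = totals.sum()
    prevalence = (table.data > 0).sum(axis=0)
    needed = int(np.ceil(min_prevalence_fraction * table.n_samples))
    keep = totals.index[
        (totals / grand > min_rel) & (prevalence >= max(needed, 0))
    ]
    if len(keep) < 4:
        raise ValueError(
            f"only {len(keep)} taxa survive the prevalence filter; "
            "a co-occurrence network needs at least 4"
        )
    logger.info("prevalence_filter: kept %d / %d taxa", len(keep), table.n_taxa)
    return table.select_taxa(list(keep))


def spearman_matrix(table: CountTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rank correlation across samples.

    Average ranks for ties; two-sided p by the t approximation.
    Constant taxa have undefined correlation: recorded as rho = 0 with
    p = 1 (and a logged flag) so they can never seed an edge.
    """
    if table.n_samples < 5:
        raise ValueError("need >= 5 samples for a stable rank correlation")
    counts = pd.DataFrame(table.counts.astype(float))
    n = table.n_samples
    ranks = counts.rank(axis=0, method="average").to_numpy()
    constant = ranks.std(axis=0) == 0
    centered = ranks - ranks.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    norms[norms == 0] = 1.0
    rho = (centered / norms).T @ (centered / norms)
    rho = np.clip(rho, -1.0, 1.0)
    # two-sided p via the t approximation on n-2 df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - rho**2))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1.0 - 1e-12] = 0.0
    if constant.any():
        logger.warning("spearman_matrix: %d constant taxa set to rho=0",
                       int(constant.sum()))
        rho[constant, :] = 0.0
        rho[:, constant] = 0.0
        p[constant, :] = 1.0
        p[:, constant] = 1.0
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    p = np.nan_to_num(p, nan=1.0)
    ids = table.taxon_ids
    return (
        pd.DataFrame(rho, index=ids, columns=ids),
        pd.DataFrame(p, index=ids, columns=ids),
    )


def _nnsd_chisq(spacings: np.ndarray, n_bins: int = 10, s_max: float = 3.0
                ) -> tuple[float, float]:
    """Chi-square distances of the spacing histogram to the Poisson and
    Wigner-Dyson (GOE) forms."""
    edges = np.linspace(0.0, s_max, n_bins + 1)
    obs, _ = np.histogram(np.clip(spacings, 0, s_max - 1e-12), bins=edges)
    n = obs.sum()
    # expected bin mass under each law
    poisson_cdf = 1.0 - np.exp(-edges)
    goe_cdf = 1.0 - np.exp(-np.pi * edges**2 / 4.0)
    exp_poisson = n * np.diff(poisson_cdf) / poisson_cdf[-1]
    exp_goe = n * np.diff(goe_cdf) / goe_cdf[-1]
    chi_p = float(np.sum((obs - exp_poisson) ** 2 / np.maximum(exp_poisson, 1e-9)))
    chi_g = float(np.sum((obs - exp_goe) ** 2 / np.maximum(exp_goe, 1e-9)))
    return chi_p, chi_g


def _unfolded_spacings(eigs: np.ndarray, degree: int = 7) -> np.ndarray | None:
    """Unfold a spectrum via a smooth polynomial fit of its cumulative
    density; returns mean-one nearest-neighbour spacings or None when
    the spectrum is too degenerate to unfold."""
    uniq = np.unique(np.round(np.sort(eigs), 8))
    n = len(uniq)
    if n < 15:
        return None
    cdf = (np.arange(n) + 0.5) / n
    deg = min(degree, n - 2)
    coeffs = np.polyfit(uniq, cdf, deg)
    unfolded = n * np.polyval(coeffs, uniq)
    s = np.diff(unfolded)
    s = s[s > 0]
    if len(s) < 10:
        return None
    return s / s.mean()


def rmt_threshold(
    rho: pd.DataFrame | np.ndarray,
    scan_min: float = 0.30,
    scan_max: float = 0.95,
    step: float = 0.01,
) -> float:
    """Smallest cutoff at which the thresholded correlation matrix's
    NNSD is closer to Poisson than to GOE statistics.

    Falls back to ``scan_max`` with a warning when no cutoff in the
    scan shows the transition (e.g. an identity matrix whose spectrum
    is fully degenerate at every cutoff).
    """
    r = np.asarray(rho, dtype=float)
    if r.shape[0] < 20:
        raise ValueError(
            "matrix smaller than 20x20: the eigenvalue spectrum is too "
            "short for RMT; pass a fixed threshold instead"
        )
    for cut in np.arange(scan_min, scan_max + step / 2, step):
        a = np.where(np.abs(r) >= cut, r, 0.0)
        np.fill_diagonal(a, 0.0)
        eigs = np.linalg.eigvalsh(a)
        spacings = _unfolded_spacings(eigs)
        if spacings is None:
            continue
        chi_p, chi_g = _nnsd_chisq(spacings)
        if chi_p < chi_g:
            return float(round(cut, 10))
    warnings.warn(
        "no GOE-to-Poisson transition found in the scan; returning scan_max",
        stacklevel=2,
    )
    return float(scan_max)


@dataclass
class CooccurrenceNetwork:
    graph: nx.Graph = field(repr=False)
    threshold_used: float = 0.0

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def node_table(self) -> pd.DataFrame:
        deg = dict(self.graph.degree())
        btw = nx.betweenness_centrality(self.graph, normalized=False)
        return pd.DataFrame(
            {
                "taxon_id": list(self.graph.nodes),
                "degree": [deg[n] for n in self.graph.nodes],
                "betweenness": [btw[n] for n in self.graph.nodes],
            }
        )

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"taxon_i": u, "taxon_j": v,
             "rho": d["rho"], "sign": d["sign"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["taxon_i", "taxon_j", "rho", "sign"])


@dataclass
class NetworkTopology:
    n_nodes: int
    n_edges: int
    average_degree: float
    average_clustering: float
    modularity: float
    n_components: int


def build_network(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    threshold: float,
    fdr: float | None = 0.05,
) -> CooccurrenceNetwork:
    """Simple undirected graph with an edge wherever |rho| >= threshold
    (and, unless ``fdr`` is None, BH-adjusted correlation p < fdr)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    ids = list(rho.index)
    g = nx.Graph()
    g.add_nodes_from(ids)
    pairs = list(itertools.combinations(range(len(ids)), 2))
    pvals = np.array([p.iat[i, j] for i, j in pairs])
    if fdr is not None:
        adj = bh_adjust(np.clip(pvals, 1e-300, 1.0))
    else:
        adj = np.zeros(len(pairs))
    rmat = rho.to_numpy()
    for (i, j), q in zip(pairs, adj):
        r = rmat[i, j]
        if abs(r) >= threshold and (fdr is None or q < fdr):
            g.add_edge(ids[i], ids[j], rho=abs(float(r)),
                       sign=int(np.sign(r)))
    return CooccurrenceNetwork(g, threshold_used=float(threshold))


def topology(net: CooccurrenceNetwork) -> NetworkTopology:
    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        return NetworkTopology(0, 0, 0.0, 0.0, 0.0, 0)
    avg_deg = 2.0 * e / n
    clustering = nx.average_clustering(g) if n > 0 else 0.0
    if e > 0:
        communities = nx.community.greedy_modularity_communities(g)
        mod = nx.community.modularity(g, communities)
    else:
        mod = 0.0
    return NetworkTopology(
        n_nodes=n,
        n_edges=e,
        average_degree=float(avg_deg),
        average_clustering=float(clustering),
        modularity=float(mod),
        n_components=nx.number_connected_components(g),
    )


def _nearest_rank(sorted_vals: np.ndarray, q: float) -> float:
    """Nearest-rank percentile (1-based ceil rule) of pre-sorted values."""
    n = len(sorted_vals)
    k = max(1, int(np.ceil(q * n)))
    return float(sorted_vals[k - 1])


def keystone_taxa(net: CooccurrenceNetwork) -> pd.DataFrame:
    """High-degree (top 20%), low-betweenness (bottom 20% within the
    high-degree set) nodes; ties at either cut are included, and at
    least one node is returned whenever the high-degree set is
    non-empty (ceiling rule)."""
    g = net.graph
    if g.number_of_nodes() < 5:
        raise ValueError("need >= 5 nodes for the keystone rule")
    nodes = net.node_table()
    deg = nodes["degree"].to_numpy(dtype=float)
    deg_cut = _nearest_rank(np.sort(deg), 0.80)
    nodes["high_degree"] = nodes["degree"] >= deg_cut
    high = nodes[nodes["high_degree"]]
    nodes["keystone"] = False
    if len(high) > 0:
        btw = high["betweenness"].to_numpy(dtype=float)
        k = max(1, int(np.ceil(0.20 * len(high))))
        btw_cut = float(np.sort(btw)[k - 1])
        flag = high.index[high["betweenness"] <= btw_cut + 1e-12]
        nodes.loc[flag, "keystone"] = True
        if nodes.loc[high.index, "keystone"].all() and len(high) > k:
            logger.warning("keystone_taxa: betweenness fully tied within the "
                           "high-degree set; all %d flagged", len(high))
    return nodes


def network_analysis(
    table: CountTable,
    min_rel: float = 1e-4,
    min_prevalence_fraction: float = 1 / 3,
    threshold: float | None = None,
    fdr: float | None = 0.05,
) -> tuple[CooccurrenceNetwork, pd.DataFrame, NetworkTopology]:
    """Filter, correlate, threshold (RMT unless fixed), build and score."""
    filtered = prevalence_filter(table, min_rel, min_prevalence_fraction)
    rho, p = spearman_matrix(filtered)
    if threshold is None:
        threshold = rmt_threshold(rho)
    net = build_network(rho, p, threshold, fdr=fdr)
    nodes = keystone_taxa(net)
    rel = filtered.relative_abundance().mean(axis=0)
    nodes["mean_relative_abundance"] = nodes["taxon_id"].map(rel)
    return net, nodes, topology(net)
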