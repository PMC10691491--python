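"""Synthetic metacommunity generator with controlled assembly regimes.

Downstream stages (null models, networks, enrichment) need data whose
true assembly process is known.  This module grows a Yule phylogeny,
evolves a one-dimensional environmental-optimum trait along it by
Brownian motion (so selection regimes are phylogenetically detectable),
and then assembles count tables under one of three regimes:

``selection``
    Each (plant, compartment) group has an environment value ``E_g``;
    a taxon's sampling weight is its lognormal base abundance times a
    Gaussian niche filter ``exp(-strength * (trait - E_g)**2)``.  Equal
    ``E_g`` across groups gives a homogeneous-selection test bed,
    distinct values a heterogeneous one.
``dispersal_limitation``
    Each group draws from a group-private subsample of the regional
    pool (a fraction ``dispersal_rate`` of all taxa).
``drift``
    Every sample is an independent multinomial draw from the shared
    regional relative-abundance vector.

In every regime a per-sample lognormal ``demographic_noise`` factor
multiplies each taxon's sampling weight before the multinomial draw.
This is ecological drift proper: replicate communities diverge by
demographic stochasticity, not merely by read-sampling noise.  With
``demographic_noise=0`` replicate samples are exact multinomial
resamples of one vector — the complete-mixing end-member, which null
models read as communities *more* similar than chance.

Read depths are Poisson around the configured expectation and counts
are multinomial, mimicking amplicon library-size variation.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import CountTable

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "evolve_traits",
    "assemble_communities",
    "simulate_dataset",
]

REGIMES = ("selection", "dispersal_limitation", "drift")


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults mirror the study design
    (2 hosts x 4 compartments x 6 replicates, amplicon-like depth)."""

    n_taxa: int = 300
    n_samples_per_group: int = 6
    groups: Sequence[tuple[str, str]] = field(
        default_factory=lambda: [
            (p, c) for p in ("S_glauca", "S_salsa") for c in ("BS", "RS", "RP", "ES")
        ]
    )
    regime: str = "drift"
    trait_conservatism: float = 1.0
    selection_strength: float = 0.0
    dispersal_rate: float = 1.0
    depth: float = 2000.0
    seed: int = 0
    # lognormal rank-abundance skew of the regional pool
    base_abundance_sigma: float = 1.5
    # per-sample lognormal sd of demographic (ecological-drift) noise
    demographic_noise: float = 0.35
    # environment value per group label; None = evenly spaced in [-2, 2]
    environments: Mapping[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.depth < 100:
            raise ValueError("depth must be >= 100")
        if not (
            np.isfinite(self.trait_conservatism)
            and np.isfinite(self.selection_strength)
            and np.isfinite(self.dispersal_rate)
        ):
            raise ValueError("rates must be finite")
        if self.trait_conservatism <= 0:
            raise ValueError("trait_conservatism must be > 0")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be >= 0")
        if not 0.0 <= self.dispersal_rate <= 1.0:
            raise ValueError("dispersal_rate must be in [0, 1]")
        if self.demographic_noise < 0 or not np.isfinite(self.demographic_noise):
            raise ValueError("demographic_noise must be finite and >= 0")
        if self.selection_strength > 0 and self.regime != "selection":
            raise ValueError(
                "selection_strength > 0 is only meaningful under the "
                "'selection' regime"
            )


def simulate_tree(n_taxa: int, seed: int) -> TreeNode:
    """Pure-birth (Yule) ultrametric phylogeny with ``n_taxa`` tips.

    Tips are labelled ``T0001`` ... in tree order.  Identical seeds give
    identical Newick strings.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = _random.Random(int(seed))
    taxa = dendropy.TaxonNamespace([f"T{i + 1:04d}" for i in range(n_taxa)])
    dtree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        taxon_namespace=taxa,
        rng=rng,
    )
    newick = dtree.as_string(schema="newick", suppress_rooting=True)
    tree = TreeNode.read([newick])
    # dendropy may leave the root edge lengthless; cophenetic distances
    # only involve internal branches, but normalize for strict readers
    if tree.length is None:
        tree.length = 0.0
    return tree


def evolve_traits(
    tree: TreeNode, rate: float, seed: int
) -> dict[str, float]:
    """Brownian-motion trait evolution along the tree.

    The root trait is 0; each branch adds a Normal(0, rate * length)
    increment, so two tips covary by ``rate`` times their shared
    root-to-MRCA path length — the phylogenetic signal the niche
    filtering downstream relies on.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    rng = np.random.default_rng(int(seed))
    depths = [t.depth() for t in tree.tips()]
    if max(depths) - min(depths) > 1e-6 * max(max(depths), 1.0):
        import warnings

        warnings.warn("tree is not ultrametric; traits evolve anyway", stacklevel=2)
    traits: dict[int, float] = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        parent_val = traits[id(node.parent)]
        bl = node.length if node.length is not None else 0.0
        traits[id(node)] = parent_val + rng.normal(0.0, np.sqrt(rate * bl))
    return {tip.name: traits[id(tip)] for tip in tree.tips()}


def _group_key(plant: str, compartment: str) -> str:
    return f"{plant}|{compartment}"


def assemble_communities(
    config: SimulationConfig,
    tree: TreeNode,
    traits: Mapping[str, float],
) -> tuple[CountTable, pd.DataFrame, dict[str, float | None]]:
    """Draw count tables under the configured regime.

    Returns the samples x taxa table, a metadata frame (sample_id,
    plant, compartment, replicate) and the environment value used for
    each group (None outside the selection regime).
    """
    taxon_ids = sorted(t.name for t in tree.tips())
    missing = [t for t in taxon_ids if t not in traits]
    if missing:
        raise ValueError(f"traits missing for taxa: {missing}")
    if len(taxon_ids) != config.n_taxa:
        raise ValueError(
            f"tree has {len(taxon_ids)} tips but config.n_taxa={config.n_taxa}"
        )
    rng = np.random.default_rng(int(config.seed))
    trait_vec = np.array([traits[t] for t in taxon_ids])
    base = rng.lognormal(mean=0.0, sigma=config.base_abundance_sigma, size=len(taxon_ids))

    groups = list(config.groups)
    if config.environments is not None:
        envs = {_group_key(*g): float(config.environments[g]) for g in groups}
    elif len(groups) == 1:
        envs = {_group_key(*groups[0]): 0.0}
    else:
        vals = np.linspace(-2.0, 2.0, len(groups))
        envs = {_group_key(*g): float(v) for g, v in zip(groups, vals)}

    rows: list[np.ndarray] = []
    meta_rows: list[dict] = []
    env_out: dict[str, float | None] = {}
    for plant, compartment in groups:
        key = _group_key(plant, compartment)
        if config.regime == "selection":
            e_g = envs[key]
            weights = base * np.exp(
                -config.selection_strength * (trait_vec - e_g) ** 2
            )
            env_out[key] = e_g
        elif config.regime == "dispersal_limitation":
            n_pool = max(2, int(round(config.dispersal_rate * config.n_taxa)))
            pool_idx = rng.choice(config.n_taxa, size=n_pool, replace=False)
            weights = np.zeros(config.n_taxa)
            weights[pool_idx] = base[pool_idx]
            env_out[key] = None
        else:  # drift: one shared regional vector
            weights = base
            env_out[key] = None
        for rep in range(1, config.n_samples_per_group + 1):
            if config.demographic_noise > 0:
                jitter = rng.lognormal(0.0, config.demographic_noise,
                                       size=config.n_taxa)
            else:
                jitter = 1.0
            w = weights * jitter
            probs = w / w.sum()
            depth = max(1, int(rng.poisson(config.depth)))
            counts = rng.multinomial(depth, probs)
            if counts.sum() == 0:  # pragma: no cover - depth >= 1 guards this
                counts[rng.integers(len(probs))] = 1
            rows.append(counts)
            meta_rows.append(
                {
                    "sample_id": f"{plant}_{compartment}_r{rep}",
                    "plant": plant,
                    "compartment": compartment,
                    "replicate": rep,
                }
            )

    data = pd.DataFrame(
        np.vstack(rows),
        index=[m["sample_id"] for m in meta_rows],
        columns=taxon_ids,
    )
    metadata = pd.DataFrame(meta_rows)
    metadata = metadata.set_index("sample_id", drop=False)
    metadata.index.name = None
    return CountTable(data), metadata, env_out


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[CountTable, pd.DataFrame, TreeNode, dict[str, float], dict[str, float | None]]:
    """One-call convenience: tree + traits + communities from a config."""
    tree = simulate_tree(config.n_taxa, config.seed)
    traits = evolve_traits(tree, config.trait_conservatism, config.seed + 1)
    table, metadata, envs = assemble_communities(config, tree, traits)
    return table, metadata, tree, traits, envs
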