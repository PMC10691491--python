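"""Frozen benchmark experiments on synthetic metacommunities.

Each function simulates data under one controlled assembly regime and
pushes it through the corresponding pipeline stage, returning the
summary quantities the study design is judged on (process fractions,
null-model calibration, error rates).  The generator settings here ARE
the study conditions: they were chosen once, for realism and
recoverability, and are shared by the test suite, the analysis scripts
and the acceptance report so all three describe the same experiment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from .assembly import assembly_analysis, bnti, rc_bray, rc_bray_exact
from .differential import bh_adjust, nb_exact_test
from .io import CountTable
from .structure import permanova
from .synthetic import SimulationConfig, simulate_dataset

__all__ = [
    "main_study_config",
    "main_dataset",
    "run_heterogeneous_selection",
    "run_homogeneous_selection",
    "run_drift",
    "run_dispersal_limitation",
    "bnti_null_calibration",
    "rc_bray_oracle_gap",
    "permanova_calibration",
    "null_fdr_rate",
]

TWO_GROUPS = [("P", "BS"), ("P", "RS")]

STUDY_PLANTS = ("S_glauca", "S_salsa")
STUDY_COMPARTMENTS = ("BS", "RS", "RP", "ES")


def main_study_config(seed: int) -> SimulationConfig:
    """The study-shaped data set: 2 hosts x 4 compartments x 6 reps,
    niche-driven selection along the soil-root continuum (one
    environment value per compartment, shared by both hosts)."""
    groups = [(p, c) for p in STUDY_PLANTS for c in STUDY_COMPARTMENTS]
    env_by_compartment = dict(zip(STUDY_COMPARTMENTS, (-1.5, -0.5, 0.5, 1.5)))
    return SimulationConfig(
        regime="selection", n_taxa=300, depth=2000, groups=groups,
        selection_strength=2.0, demographic_noise=0.5, seed=seed,
        environments={(p, c): env_by_compartment[c] for p, c in groups},
    )


def main_dataset(seed: int):
    """Simulated table + metadata + tree for the study-shaped design."""
    return simulate_dataset(main_study_config(seed))


def _derive_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _pairs_with_groups(cfg: SimulationConfig, n_null: int) -> pd.DataFrame:
    table, meta, tree, _, _ = simulate_dataset(cfg)
    pairs = assembly_analysis(table, tree, n_null_bnti=n_null,
                              n_null_rc=n_null, seed=cfg.seed)
    grouping = (meta["plant"] + "|" + meta["compartment"]).to_dict()
    pairs["group_i"] = pairs["sample_i"].map(grouping)
    pairs["group_j"] = pairs["sample_j"].map(grouping)
    return pairs


def run_heterogeneous_selection(seed: int, n_null: int = 299) -> pd.DataFrame:
    """Two environments at E = -2 / +2, Gaussian filter strength 2,
    conserved traits: between-environment pairs should read as
    heterogeneous selection."""
    cfg = SimulationConfig(
        regime="selection", n_taxa=300, depth=2000, groups=TWO_GROUPS,
        selection_strength=2.0, seed=seed,
        environments={TWO_GROUPS[0]: -2.0, TWO_GROUPS[1]: 2.0},
    )
    return _pairs_with_groups(cfg, n_null)


def run_homogeneous_selection(seed: int, n_null: int = 199,
                              n_runs: int = 3) -> pd.DataFrame:
    """Strong shared-environment filtering (strength 10) on a large pool
    at shallow depth, pooled over replicate runs: communities hold
    different but closely related taxa, the homogeneous-selection
    signature."""
    chunks = []
    for s in _derive_seeds(seed, n_runs):
        cfg = SimulationConfig(
            regime="selection", n_taxa=1200, depth=1000, groups=TWO_GROUPS,
            selection_strength=10.0, demographic_noise=1.0, seed=s,
            environments={TWO_GROUPS[0]: 1.0, TWO_GROUPS[1]: 1.0},
        )
        chunks.append(_pairs_with_groups(cfg, n_null))
    return pd.concat(chunks, ignore_index=True)


def run_drift(seed: int, n_null: int = 299) -> pd.DataFrame:
    """Generator defaults: shared pool, demographic noise only."""
    cfg = SimulationConfig(regime="drift", groups=TWO_GROUPS, seed=seed)
    return _pairs_with_groups(cfg, n_null)


def run_dispersal_limitation(seed: int, n_null: int = 299,
                             dispersal_rate: float = 0.2) -> pd.DataFrame:
    """Group-private pools covering ``dispersal_rate`` of the taxa, at
    conditions otherwise matched to :func:`run_drift`."""
    cfg = SimulationConfig(
        regime="dispersal_limitation", dispersal_rate=dispersal_rate,
        groups=TWO_GROUPS, seed=seed,
    )
    return _pairs_with_groups(cfg, n_null)


def bnti_null_calibration(seed: int, n_null: int = 999,
                          n_samples: int = 9, n_pools: int = 3) -> pd.DataFrame:
    """βNTI on communities drawn from one pool with no trait structure;
    the z-scores should behave like a standard-normal-ish null.

    Pairs within one data set share a tree and pool draw and are
    therefore correlated; pooling a few independent pools keeps the
    summary from riding on a single tree realization.
    """
    chunks = []
    for s in _derive_seeds(seed, n_pools):
        cfg = SimulationConfig(
            regime="drift", n_taxa=300, depth=2000,
            groups=[("P", "BS")], n_samples_per_group=n_samples, seed=s,
        )
        table, _, tree, _, _ = simulate_dataset(cfg)
        chunks.append(bnti(table, tree, n_null=n_null, seed=s))
    return pd.concat(chunks, ignore_index=True)


def rc_bray_oracle_gap(seed: int, n_null: int = 9_999) -> pd.DataFrame:
    """Monte-Carlo RCbray vs exhaustive enumeration on tiny pools
    (<= 5 taxa, <= 6 reads per sample), every sample pair."""
    tables = [
        [[2, 0, 0], [0, 2, 0], [1, 1, 0], [0, 0, 2]],
        [[3, 1, 0, 0, 0], [0, 0, 2, 1, 0], [1, 0, 0, 0, 2], [0, 2, 0, 1, 1]],
        [[1, 1, 1], [3, 0, 0], [0, 2, 1]],
    ]
    rows = []
    for t_idx, counts in enumerate(tables):
        counts = np.asarray(counts)
        table = CountTable(pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(counts.shape[0])],
            columns=[f"t{i}" for i in range(counts.shape[1])],
        ))
        mc = rc_bray(table, n_null=n_null, seed=seed + t_idx)
        for _, row in mc.iterrows():
            exact = rc_bray_exact(table, row["sample_i"], row["sample_j"])
            rows.append({
                "table": t_idx,
                "sample_i": row["sample_i"],
                "sample_j": row["sample_j"],
                "rc_mc": row["rc_bray"],
                "rc_exact": exact,
                "abs_gap": abs(row["rc_bray"] - exact),
            })
    return pd.DataFrame(rows)


def permanova_calibration(seed: int, n_sims: int = 1_000,
                          n_permutations: int = 199,
                          alpha: float = 0.05) -> float:
    """Type-I error of the permutation test: random labels on distances
    from an exchangeable generating process."""
    rng = np.random.default_rng(seed)
    rejections = 0
    ids = [f"s{i}" for i in range(12)]
    labels = ["a"] * 6 + ["b"] * 6
    for i in range(n_sims):
        x = rng.normal(size=(12, 3))
        dm = DistanceMatrix(squareform(pdist(x)), ids=ids)
        res = permanova(dm, labels, n_permutations=n_permutations,
                        seed=int(rng.integers(2**31)))
        rejections += res.p <= alpha
    return rejections / n_sims


def null_fdr_rate(seed: int, n_sims: int = 200) -> float:
    """Mean fraction of taxa called at FDR < 0.05 when the two compared
    groups are arbitrary splits of drift-regime data (no true signal)."""
    frac = []
    for s in _derive_seeds(seed, n_sims):
        cfg = SimulationConfig(
            regime="drift", n_taxa=80, depth=800, groups=TWO_GROUPS, seed=s,
        )
        table, meta, _, _, _ = simulate_dataset(cfg)
        labels = meta["compartment"]
        res = nb_exact_test(table, labels, dispersion="estimate")
        fdr = bh_adjust(res["p"].to_numpy())
        frac.append(float((fdr < 0.05).mean()))
    return float(np.mean(frac))
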