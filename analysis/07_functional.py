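#!/usr/bin/env python
"""Functional-gene comparison between bulk soil and rhizoplane.

A synthetic gene-abundance panel (plant-growth-promotion traits, ion
transport, N/S-cycle steps; lengths and counts drawn here, not from any
real annotation) is TPM-normalized, summed per category, and compared
between niches with Welch t-tests and BH adjustment.  Genes in the PGP
and N-cycle panels are planted 2-4x more abundant in the rhizoplane, so
those categories should surface with positive fold changes.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from rhizoassembly import aggregate_by_category, compare_groups, tpm, write_result

SEED = 20_240_601
OUT = Path(__file__).resolve().parent.parent / "results"

PANELS = {
    "PGP_traits": 8,        # IAA synthesis, siderophores, phosphatase...
    "N_cycle": 6,           # narG/napA-style steps
    "S_cycle": 5,
    "ion_transport": 6,     # K+/H+, Na+ transporters
    "housekeeping": 10,
}
ENRICHED_IN_RP = {"PGP_traits": 3.0, "N_cycle": 2.0}


def simulate_gene_table(seed: int):
    """Synthetic shotgun-style gene counts for 6 BS + 6 RP samples."""
    rng = np.random.default_rng(seed)
    genes, cats = [], {}
    for panel, n in PANELS.items():
        for i in range(n):
            g = f"{panel}_g{i + 1}"
            genes.append(g)
            cats[g] = panel
    lengths = pd.Series(rng.integers(300, 3000, len(genes)), index=genes)
    base = rng.lognormal(4, 1, len(genes))
    samples, labels = [], {}
    counts = {}
    for niche in ("BS", "RP"):
        for rep in range(1, 7):
            s = f"{niche}_r{rep}"
            mu = base.copy()
            if niche == "RP":
                for panel, fold in ENRICHED_IN_RP.items():
                    idx = [i for i, g in enumerate(genes)
                           if g.startswith(panel)]
                    mu[idx] *= fold
            counts[s] = rng.poisson(mu * rng.lognormal(0, 0.2))
            labels[s] = niche
            samples.append(s)
    table = pd.DataFrame(counts, index=genes)
    return table, lengths, pd.Series(cats), pd.Series(labels)


def main() -> None:
    counts, lengths, annotation, labels = simulate_gene_table(SEED)
    tpm_table = tpm(counts, lengths)
    cats = aggregate_by_category(tpm_table, annotation)
    res = compare_groups(cats, labels, group_order=["RP", "BS"])
    write_result(res, OUT / "functional_comparison.tsv")
    print("category comparison (RP vs BS, TPM sums):")
    cols = ["category", "log2fc", "p", "fdr_p", "stars"]
    print(res[cols].round(4).to_string(index=False))
    planted = res.set_index("category").loc[list(ENRICHED_IN_RP)]
    print(f"\nplanted panels recovered with positive fold change: "
          f"{(planted['log2fc'] > 0).all()}")


if __name__ == "__main__":
    main()
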