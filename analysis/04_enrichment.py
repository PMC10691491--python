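#!/usr/bin/env python
"""Differential taxon enrichment between bulk soil and rhizoplane.

Per host: filter taxa above 0.01% overall relative abundance, TMM-
normalize, run the common-dispersion NB exact test, BH-adjust, and
label taxa enriched / depleted at FDR < 0.05 and |log2FC| > 1.
"""

from pathlib import Path

from rhizoassembly import enrichment_analysis, write_result
from rhizoassembly.experiments import main_dataset

SEED = 20_240_601
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table, meta, _, _, _ = main_dataset(SEED)
    for plant in sorted(meta["plant"].unique()):
        mask = (meta["plant"] == plant) & meta["compartment"].isin(["BS", "RP"])
        labels = meta.loc[mask, "compartment"]
        res = enrichment_analysis(
            table.select_samples(list(labels.index)),
            labels, min_rel=1e-4, group_order=["RP", "BS"],
        )
        write_result(res, OUT / f"enrichment_{plant}_RP_vs_BS.tsv")
        n_enr = int((res["label"] == "enriched").sum())
        n_dep = int((res["label"] == "depleted").sum())
        print(f"{plant} RP vs BS: {n_enr} enriched, {n_dep} depleted "
              f"of {len(res)} taxa passing the abundance filter")


if __name__ == "__main__":
    main()
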