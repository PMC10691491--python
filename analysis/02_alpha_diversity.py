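#!/usr/bin/env python
"""Rarefy to the minimum depth and compare alpha diversity by niche.

Chao1 richness, Shannon entropy and Good's coverage per sample, plus
Welch t-tests of each index between hosts within a compartment (the
comparison the boxplot asterisks in amplicon studies encode).
"""

from pathlib import Path

import pandas as pd

from rhizoassembly import alpha_diversity_table, rarefy, welch_ttest, write_result
from rhizoassembly.experiments import main_dataset

SEED = 20_240_601
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table, meta, _, _, _ = main_dataset(SEED)
    rare = rarefy(table, depth="min", seed=SEED)
    alpha = alpha_diversity_table(rare).merge(
        meta, left_on="sample_id", right_on="sample_id")
    write_result(alpha, OUT / "alpha_diversity.tsv")

    rows = []
    for comp, chunk in alpha.groupby("compartment"):
        plants = sorted(chunk["plant"].unique())
        for index in ("chao1", "shannon"):
            x = chunk.loc[chunk["plant"] == plants[0], index]
            y = chunk.loc[chunk["plant"] == plants[1], index]
            t, df, p = welch_ttest(x, y)
            rows.append({"compartment": comp, "index": index,
                         "t": t, "df": df, "p": p})
    tests = pd.DataFrame(rows)
    write_result(tests, OUT / "alpha_diversity_tests.tsv")

    print(f"rarefied to depth {int(rare.sample_totals().iloc[0])}; "
          f"{rare.n_samples} samples retained")
    summary = alpha.groupby("compartment")[["chao1", "shannon",
                                            "goods_coverage"]].mean().round(3)
    print("mean alpha diversity by compartment:")
    print(summary.to_string())
    sig = tests[tests["p"] < 0.05]
    print(f"{len(sig)} of {len(tests)} host contrasts at p < 0.05")


if __name__ == "__main__":
    main()
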