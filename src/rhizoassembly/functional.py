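"""Niche-wise comparison of functional-gene abundance tables.

Raw gene counts are length-normalized to transcripts per million
(TPM), summed into annotation categories (KEGG level-2 paths, gene
panels such as plant-growth-promotion traits or N/S-cycle steps), and
compared between two groups of samples by Welch t-tests with BH
adjustment across categories.  Normalization precedes aggregation:
category TPM is the sum of member-gene TPM.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .differential import bh_adjust
from .structure import welch_ttest

logger = logging.getLogger("rhizoassembly")

__all__ = ["tpm", "aggregate_by_category", "compare_groups", "star_label"]

FOLD_CHANGE_CAP = 20.0


def tpm(counts: pd.DataFrame, lengths_bp: pd.Series | Mapping[str, float]) -> pd.DataFrame:
    """TPM from raw counts (genes x samples) and gene lengths in bp.

    tpm_g = (count_g / length_kb_g) / sum_h(count_h / length_kb_h) * 1e6;
    every column sums to one million.
    """
    lengths = pd.Series(dict(lengths_bp)) if not isinstance(lengths_bp, pd.Series) else lengths_bp
    lengths = lengths.loc[counts.index].astype(float)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise ValueError(f"non-positive gene lengths: {bad}")
    rate = counts.div(lengths / 1000.0, axis=0)
    totals = rate.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"all-zero samples: {zero}")
    return rate.div(totals, axis=1) * 1e6


def aggregate_by_category(
    table: pd.DataFrame, annotation: Mapping[str, Sequence[str]] | pd.Series
) -> pd.DataFrame:
    """Sum gene abundances into categories (categories x samples).

    ``annotation`` maps gene id to one or more category labels; a gene
    annotated to several categories contributes its full abundance to
    each (multi-mapping counted per category).  Unannotated genes are
    dropped with a logged count.
    """
    if isinstance(annotation, pd.Series):
        annotation = annotation.to_dict()
    rows: dict[str, np.ndarray] = {}
    unannotated = 0
    for gene in table.index:
        cats = annotation.get(gene)
        if cats is None or (isinstance(cats, float) and np.isnan(cats)):
            unannotated += 1
            continue
        if isinstance(cats, str):
            cats = [c for c in cats.split(";") if c]
        if len(cats) == 0:
            unannotated += 1
            continue
        vec = table.loc[gene].to_numpy(dtype=float)
        for cat in cats:
            rows[cat] = rows.get(cat, 0) + vec
    if unannotated:
        logger.info("aggregate_by_category: dropped %d unannotated genes",
                    unannotated)
    if not rows:
        raise ValueError("no annotated genes")
    return pd.DataFrame(rows, index=table.columns).T.sort_index()


def star_label(p: float) -> str:
    """Figure-legend significance stars on the raw p-value."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(
    category_table: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    group_order: Sequence[str] | None = None,
    pseudo: float = 0.5,
) -> pd.DataFrame:
    """Welch t-test per category between two sample groups.

    Fold changes use a ``pseudo``-TPM prior on the group means; a
    category entirely absent from one group would otherwise be
    infinite and is capped at +/-20 with a flag.  Stars follow the raw
    p (as in the figure legends); BH-adjusted p is reported alongside.
    """
    labels = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    labels = labels.loc[[s for s in category_table.columns if s in labels.index]]
    levels = list(pd.unique(labels))
    if group_order is not None:
        if sorted(group_order) != sorted(levels):
            raise ValueError("group_order does not match labels")
        levels = list(group_order)
    if len(levels) != 2:
        raise ValueError(f"exactly 2 groups required, got {levels}")
    if (labels.value_counts() < 2).any():
        raise ValueError("need n >= 2 per group")
    a_cols = labels.index[labels == levels[0]]
    b_cols = labels.index[labels == levels[1]]
    rows = []
    for cat in category_table.index:
        a = category_table.loc[cat, a_cols].to_numpy(dtype=float)
        b = category_table.loc[cat, b_cols].to_numpy(dtype=float)
        t, df, p = welch_ttest(a, b)
        raw_fc = np.log2((a.mean() + pseudo) / (b.mean() + pseudo))
        capped = bool(abs(raw_fc) > FOLD_CHANGE_CAP) or (a.mean() == 0) != (b.mean() == 0) and not np.isfinite(raw_fc)
        log2fc = float(np.clip(raw_fc, -FOLD_CHANGE_CAP, FOLD_CHANGE_CAP))
        rows.append(
            {
                "category": cat,
                f"mean_{levels[0]}": float(a.mean()),
                f"mean_{levels[1]}": float(b.mean()),
                "log2fc": log2fc,
                "fc_capped": capped,
                "t": t,
                "p": float(min(max(p, 1e-300), 1.0)),
                "stars": star_label(p),
            }
        )
    out = pd.DataFrame(rows)
    out["fdr_p"] = bh_adjust(out["p"].to_numpy())
    return out
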