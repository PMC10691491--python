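"""Readers, writers and core domain containers.

Count tables are stored on disk in the common amplicon convention
(taxa in rows, samples in columns, first column holds the taxon id) and
transposed to samples x taxa in memory.  Phylogenies are scikit-bio
``TreeNode`` objects read from Newick; cophenetic (tip-to-tip patristic)
distances feed the phylogenetic turnover null models.
"""

from __future__ import annotations

import io as _io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("rhizoassembly")

__all__ = [
    "CountTable",
    "read_count_table",
    "write_count_table",
    "read_tree",
    "write_tree",
    "cophenetic_matrix",
    "read_metadata",
    "write_metadata",
    "write_result",
    "read_result",
]


@dataclass
class CountTable:
    """Samples x taxa matrix of non-negative integer counts.

    The universal currency of the pipeline: every downstream stage
    (diversity, ordination, enrichment, null models, networks) consumes
    one of these.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by sample id, columns by taxon id, integer dtype.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise ValueError("count table needs at least 1 sample and 1 taxon")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon ids: {dups}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            # accept float matrices that are exactly integral (e.g. BIOM)
            if not np.all(np.isfinite(arr)) or not np.all(arr == np.floor(arr)):
                bad = np.argwhere(~(np.isfinite(arr) & (arr == np.floor(arr))))
                r, c = bad[0]
                raise ValueError(
                    f"non-integer count at sample {df.index[r]!r}, "
                    f"taxon {df.columns[c]!r}: {arr[r, c]!r}"
                )
            df = df.astype(np.int64)
        if (df.to_numpy() < 0).any():
            r, c = np.argwhere(df.to_numpy() < 0)[0]
            raise ValueError(
                f"negative count at sample {df.index[r]!r}, "
                f"taxon {df.columns[c]!r}: {df.iat[r, c]}"
            )
        self.data = df.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalized proportions."""
        totals = self.data.sum(axis=1)
        return self.data.div(totals, axis=0)

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        return CountTable(self.data.loc[list(sample_ids)])

    def select_taxa(self, taxon_ids: Sequence[str]) -> "CountTable":
        return CountTable(self.data.loc[:, list(taxon_ids)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.data.equals(other.data)


def read_count_table(path: str | Path, dialect: str = "tsv") -> CountTable:
    """Read a count table from TSV (taxa in rows) or BIOM v2.

    TSV convention: first column = taxon id, header row = sample ids;
    '#' comment lines are ignored.  The table is transposed to
    samples x taxa on load.  Sample order follows file order.
    """
    path = Path(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValueError(f"{path}: empty count table")
        try:
            numeric = df.apply(pd.to_numeric)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: non-numeric count: {exc}") from exc
        table = CountTable(numeric.T)
    elif dialect == "biom":
        import biom

        bt = biom.load_table(str(path))
        # biom stores observations (taxa) x samples
        df = pd.DataFrame(
            bt.matrix_data.toarray().T,
            index=list(bt.ids("sample")),
            columns=list(bt.ids("observation")),
        )
        table = CountTable(df)
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'biom')")
    logger.info(
        "read_count_table %s: %d samples x %d taxa", path, table.n_samples, table.n_taxa
    )
    return table


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write taxa-in-rows TSV (inverse of :func:`read_count_table`)."""
    out = table.data.T
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted Newick phylogeny.

    Every non-root branch must carry a finite, non-negative length and
    tip labels must be unique; violations raise rather than being
    silently patched, since branch lengths feed cophenetic distances.
    """
    tree = TreeNode.read(str(path), format="newick")
    _validate_tree(tree)
    return tree


def _validate_tree(tree: TreeNode) -> None:
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        seen: set[str] = set()
        dups = sorted({t for t in tips if t in seen or seen.add(t)})  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate tip labels: {dups}")
    if any(t is None for t in tips):
        raise ValueError("unnamed tip in tree")
    for node in tree.traverse(include_self=False):
        bl = node.length
        if bl is None or not np.isfinite(bl):
            raise ValueError(
                f"missing or non-finite branch length at node {node.name!r}"
            )
        if bl < 0:
            raise ValueError(f"negative branch length at node {node.name!r}")


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def cophenetic_matrix(
    tree: TreeNode, taxon_order: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Tip-to-tip patristic distance matrix, optionally in a given order.

    Raises a hard error listing the offenders when ``taxon_order``
    contains labels that are not tips of the tree.
    """
    dm = tree.tip_tip_distances()
    ids = list(dm.ids)
    if taxon_order is None:
        return dm.data.copy(), ids
    missing = sorted(set(taxon_order) - set(ids))
    if missing:
        raise ValueError(f"taxa absent from tree: {missing}")
    idx = [ids.index(t) for t in taxon_order]
    return dm.data[np.ix_(idx, idx)], list(taxon_order)


METADATA_COLUMNS = ("sample_id", "plant", "compartment", "replicate")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV (sample_id, plant, compartment, replicate).

    Unknown plant/compartment levels are preserved verbatim; there is no
    hard-coded vocabulary.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty metadata file")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dups}")
    df["replicate"] = df["replicate"].astype(int)
    df = df.set_index("sample_id", drop=False)
    df.index.name = None
    logger.info(
        "read_metadata %s: %d samples, %d plant x compartment groups",
        path,
        len(df),
        df.groupby(["plant", "compartment"], observed=True).ngroups,
    )
    return df


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.loc[:, list(METADATA_COLUMNS)].to_csv(path, sep="\t", index=False)


def align_metadata(table: CountTable, metadata: pd.DataFrame) -> pd.DataFrame:
    """Resolve every sample of ``table`` to exactly one metadata row."""
    missing = [s for s in table.sample_ids if s not in metadata.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    return metadata.loc[table.sample_ids]


def write_result(obj, path: str | Path, format: str = "tsv") -> None:
    """Write a result object (DataFrame or mapping) to TSV or JSON."""
    path = Path(path)
    if format == "tsv":
        if not isinstance(obj, pd.DataFrame):
            obj = pd.DataFrame(obj)
        obj.to_csv(path, sep="\t", index=False)
    elif format == "json":
        if isinstance(obj, pd.DataFrame):
            payload = obj.to_dict(orient="records")
        else:
            payload = obj
        path.write_text(json.dumps(payload, indent=2, default=_jsonify) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_result(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        if df.shape[0] == 0:
            raise ValueError(f"{path}: empty result file")
        return df
    if format == "json":
        return pd.DataFrame(json.loads(path.read_text()))
    raise ValueError(f"unknown format {format!r}")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
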