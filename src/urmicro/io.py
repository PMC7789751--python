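"""Readers and writers for the standard tabular microbiome formats.

In-memory containers are plain pandas objects:

* **OTU table** -- ``DataFrame`` of non-negative integer read counts,
  rows = OTU ids, columns = sample ids.
* **Taxonomy** -- ``DataFrame`` indexed by OTU id with one column per rank
  (kingdom ... species), empty string for unassigned slots.
* **Sample metadata** -- ``DataFrame`` indexed by sample id with a
  categorical ``group`` column plus numeric clinical covariates.
* **Tree** -- ``skbio.TreeNode`` (rooted, leaf labels = OTU ids).
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
from skbio import TreeNode

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


def validate_otu_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate an OTU count table (OTUs x samples) and coerce to int64.

    Raises :class:`FormatError` on duplicate identifiers, non-integer or
    negative cells, or an empty table.
    """
    if table.index.has_duplicates:
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate OTU ids: {dups}")
    if table.columns.has_duplicates:
        dups = table.columns[table.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample ids: {dups}")
    if table.shape[0] < 1 or table.shape[1] < 1:
        raise FormatError("OTU table must have at least one OTU and one sample")
    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        try:
            values = values.astype(float)
        except ValueError as exc:
            raise FormatError(f"non-numeric count in OTU table: {exc}") from exc
    if np.isnan(values).any():
        raise FormatError("missing value in OTU table")
    if (values < 0).any():
        raise FormatError("negative count in OTU table")
    if not np.array_equal(values, np.floor(values)):
        raise FormatError("non-integer count in OTU table")
    out = pd.DataFrame(values.astype(np.int64), index=table.index, columns=table.columns)
    out.index.name = "#OTU_ID"
    return out


def read_otu_table(path: str | os.PathLike, orientation: str = "otus") -> pd.DataFrame:
    """Read a tab-separated OTU table.

    Accepts the plain one-header-line dialect (first cell ``#OTU_ID``) and the
    two-line BIOM-TSV dialect whose first line is ``# Constructed from biom
    file``.

    Parameters
    ----------
    orientation:
        ``"otus"`` if rows are OTUs (default), ``"samples"`` if rows are
        samples (the table is transposed to OTUs x samples).
    """
    if orientation not in ("otus", "samples"):
        raise ValueError(f"orientation must be 'otus' or 'samples', got {orientation!r}")
    with open(path) as fh:
        first = fh.readline()
        skiprows = 1 if first.startswith("# Constructed from biom file") else 0
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skiprows, dtype=str)
    if df.isna().any().any():
        raise FormatError(f"ragged or incomplete rows in {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "samples":
        df = df.T
    return validate_otu_table(df)


def write_otu_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write an OTU table as TSV with a ``#OTU_ID`` header column."""
    out = table.copy()
    out.index.name = "#OTU_ID"
    out.to_csv(path, sep="\t")


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a Greengenes lineage string (``k__X; p__Y; ...``) into rank labels.

    Missing or empty slots map to ``""``; prefixes are stripped.
    """
    out = {rank: "" for rank in RANKS}
    for token in lineage.split(";"):
        token = token.strip()
        if not token:
            continue
        for rank, prefix in zip(RANKS, RANK_PREFIXES):
            if token.startswith(prefix):
                out[rank] = token[len(prefix):].strip()
                break
    return out


def format_lineage(row: pd.Series | dict) -> str:
    return "; ".join(f"{p}{row.get(r, '')}" for r, p in zip(RANKS, RANK_PREFIXES))


def read_taxonomy(path: str | os.PathLike) -> pd.DataFrame:
    """Read a two-column TSV ``otu_id<TAB>lineage`` into a rank table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["otu_id", "lineage"], dtype=str)
    if df["otu_id"].duplicated().any():
        raise FormatError("duplicate OTU ids in taxonomy file")
    records = [parse_lineage(s if isinstance(s, str) else "") for s in df["lineage"]]
    tax = pd.DataFrame(records, index=df["otu_id"].astype(str))
    tax.index.name = "otu_id"
    return tax[list(RANKS)]


def write_taxonomy(tax: pd.DataFrame, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for otu_id, row in tax.iterrows():
            fh.write(f"{otu_id}\t{format_lineage(row)}\n")


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    """Read sample metadata: TSV with a ``sample_id`` index column and a
    required ``group`` column; remaining columns are parsed as numeric
    covariates where possible."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    if meta.index.has_duplicates:
        raise FormatError("duplicate sample ids in metadata")
    if "group" not in meta.columns:
        raise FormatError("metadata must contain a 'group' column")
    for col in meta.columns:
        if col == "group":
            continue
        meta[col] = pd.to_numeric(meta[col], errors="coerce")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | os.PathLike) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_tree(path: str | os.PathLike) -> TreeNode:
    """Read a rooted Newick tree whose leaves are OTU ids."""
    tree = TreeNode.read(str(path), format="newick")
    labels = [t.name for t in tree.tips()]
    if len(labels) != len(set(labels)):
        raise FormatError("duplicate leaf labels in tree")
    return tree


def write_tree(tree: TreeNode, path: str | os.PathLike) -> None:
    tree.write(str(path), format="newick")


def check_paired(table: pd.DataFrame, meta: pd.DataFrame) -> None:
    """Ensure every sample in the table carries a group label."""
    missing = [s for s in table.columns if s not in meta.index]
    if missing:
        raise FormatError(f"samples missing from metadata: {missing}")


def group_labels(table: pd.DataFrame, meta: pd.DataFrame) -> pd.Series:
    """Group label per table sample, in table column order."""
    check_paired(table, meta)
    return meta.loc[list(table.columns), "group"]


def as_relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Column-normalise a count table to proportions.

    Raises on all-zero sample columns, which indicate an upstream error.
    """
    sums = table.sum(axis=0)
    if (sums == 0).any():
        bad = list(sums.index[sums == 0])
        raise ValueError(f"zero-sum sample columns: {bad}")
    return table / sums


def sample_ids(table: pd.DataFrame) -> list[str]:
    return list(table.columns)


def otu_ids(table: pd.DataFrame) -> list[str]:
    return list(table.index)


def subset_samples(table: pd.DataFrame, keep: Iterable[str]) -> pd.DataFrame:
    keep = [s for s in table.columns if s in set(keep)]
    return table[keep]
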