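"""Quality-control filters and taxonomic aggregation.

Two filters are applied to every cohort before analysis, in this order:

1. samples whose total assigned reads fall *below* a depth threshold
   (default 8000) are excluded;
2. OTUs whose total count falls *below* a fixed fraction of the grand total
   of the table (default 0.01%) are discarded.

Both thresholds are inclusive: a sample or OTU sitting exactly on the
threshold is kept ("less than" removal rule).
"""

from __future__ import annotations

import pandas as pd

from .io import RANKS, as_relative_abundance


def filter_samples_min_reads(table: pd.DataFrame, min_reads: int = 8000) -> pd.DataFrame:
    """Drop samples with column sum strictly below ``min_reads``.

    The returned table records the removed sample ids under
    ``table.attrs["removed_samples"]``.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    depth = table.sum(axis=0)
    keep = depth >= min_reads
    if not keep.any():
        raise ValueError(f"all samples have fewer than {min_reads} reads")
    out = table.loc[:, keep].copy()
    out.attrs["removed_samples"] = list(depth.index[~keep])
    return out


def filter_otus_min_fraction(table: pd.DataFrame, min_fraction: float = 1e-4) -> pd.DataFrame:
    """Drop OTUs whose total count is strictly below ``min_fraction`` of the
    grand total of the table.

    The returned table records the removed OTU ids under
    ``table.attrs["removed_otus"]``.
    """
    if not 0 <= min_fraction < 1:
        raise ValueError("min_fraction must be in [0, 1)")
    totals = table.sum(axis=1)
    threshold = min_fraction * table.to_numpy().sum()
    keep = totals >= threshold
    if not keep.any():
        raise ValueError("all OTUs fall below the abundance threshold")
    out = table.loc[keep].copy()
    out.attrs["removed_otus"] = list(totals.index[~keep])
    return out


def aggregate_by_rank(table: pd.DataFrame, tax: pd.DataFrame, rank: str = "genus") -> pd.DataFrame:
    """Sum counts over OTUs sharing a rank label and normalise per sample.

    OTUs with an empty label at ``rank`` pool into ``unclassified_<rank>`` so
    each sample column still sums to 1. Returns a relative-abundance table
    (taxa x samples), rows sorted lexicographically.
    """
    if rank not in RANKS[:-1]:  # species-level tables are just the OTU table
        raise ValueError(f"rank must be one of {RANKS[:-1]}, got {rank!r}")
    missing = [o for o in table.index if o not in tax.index]
    if missing:
        raise KeyError(f"OTUs missing from taxonomy: {missing[:5]}")
    labels = tax.loc[list(table.index), rank].astype(str)
    labels = labels.where(labels != "", f"unclassified_{rank}")
    counts = table.groupby(labels.values).sum().sort_index()
    counts.index.name = rank
    return as_relative_abundance(counts)


def top_n_with_others(rel: pd.DataFrame, n: int = 35, others_label: str = "Others") -> pd.DataFrame:
    """Keep the ``n`` taxa of highest mean relative abundance; pool the rest
    into an ``Others`` row. Ties at rank ``n`` break lexicographically on the
    taxon id. If ``n`` >= the number of taxa the table is returned unchanged
    (no Others row)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n >= rel.shape[0]:
        return rel.copy()
    order = (
        rel.mean(axis=1)
        .rename("mean")
        .reset_index()
        .sort_values(["mean", rel.index.name or "index"], ascending=[False, True])
    )
    top = order.iloc[:n, 0].tolist()
    rest = [t for t in rel.index if t not in set(top)]
    out = rel.loc[[t for t in rel.index if t in set(top)]].copy()
    out.loc[others_label] = rel.loc[rest].sum(axis=0)
    return out
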