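"""Rarefaction, alpha diversity, beta diversity and shared-OTU counting.

Alpha diversity reports observed richness, Shannon entropy (natural log by
default), the Gini-Simpson index ``1 - sum(p_i^2)``, bias-corrected Chao1 and
ACE (rare threshold 10). Beta diversity offers Bray-Curtis on relative
abundances and unweighted / normalized-weighted UniFrac on a rooted tree.
The index conventions follow scikit-bio, which performs the underlying
computation.
"""

from __future__ import annotations

import itertools
from typing import Iterable

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import ace, chao1, shannon, simpson

from .io import as_relative_abundance, group_labels

DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))


def rarefy(sample_counts: pd.Series | np.ndarray, depth: int, seed: int | None = None) -> np.ndarray | pd.Series:
    """Subsample a count vector to ``depth`` reads without replacement
    (multivariate hypergeometric draw). ``depth`` equal to the total returns
    the input unchanged; ``depth`` greater than the total is an error."""
    values = np.asarray(sample_counts, dtype=np.int64)
    total = int(values.sum())
    if depth < 0 or depth > total:
        raise ValueError(f"depth must be in [0, {total}], got {depth}")
    if depth == total:
        out = values.copy()
    else:
        rng = np.random.default_rng(seed)
        out = rng.multivariate_hypergeometric(values, depth)
    if isinstance(sample_counts, pd.Series):
        return pd.Series(out, index=sample_counts.index)
    return out


def rarefaction_curve(
    table: pd.DataFrame,
    fractions: Iterable[float] = DEFAULT_FRACTIONS,
    repeats: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Observed-OTU rarefaction curve per sample.

    For each sample and subsampling fraction of its own depth, reports the
    mean and sd of the number of nonzero OTUs over ``repeats`` random
    subsamples. Returns a tidy frame with columns
    ``sample, fraction, mean_otus, sd_otus``.
    """
    fractions = sorted(set(float(f) for f in fractions))
    if not fractions:
        raise ValueError("fractions must be non-empty")
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for sample in table.columns:
        counts = table[sample].to_numpy(dtype=np.int64)
        total = int(counts.sum())
        for frac in fractions:
            depth = int(round(frac * total))
            if depth == total:
                obs = np.array([(counts > 0).sum()] * repeats, dtype=float)
            else:
                obs = np.empty(repeats)
                for r in range(repeats):
                    sub = rng.multivariate_hypergeometric(counts, depth)
                    obs[r] = (sub > 0).sum()
            rows.append((sample, frac, obs.mean(), obs.std(ddof=1) if repeats > 1 else 0.0))
    return pd.DataFrame(rows, columns=["sample", "fraction", "mean_otus", "sd_otus"])


def alpha_diversity(
    table: pd.DataFrame,
    shannon_base: float | None = None,
    chao1_bias_corrected: bool = True,
) -> pd.DataFrame:
    """Per-sample alpha-diversity indices.

    Columns: ``observed_otus``, ``shannon`` (natural log unless
    ``shannon_base`` given), ``simpson`` (Gini-Simpson, ``1 - sum p^2``),
    ``chao1`` (bias-corrected by default) and ``ace`` (rare threshold 10).
    """
    if (table.sum(axis=0) == 0).any():
        raise ValueError("zero-sum sample column")
    records = {}
    for sample in table.columns:
        counts = table[sample].to_numpy(dtype=np.int64)
        try:
            ace_value = float(ace(counts))
        except ValueError:
            # ACE's sample coverage is zero when every rare taxon is a
            # singleton; the estimator is undefined for such samples
            ace_value = float("nan")
        records[sample] = {
            "observed_otus": int((counts > 0).sum()),
            "shannon": float(shannon(counts, base=shannon_base)),
            "simpson": float(simpson(counts)),
            "chao1": float(chao1(counts, bias_corrected=chao1_bias_corrected)),
            "ace": ace_value,
        }
    out = pd.DataFrame.from_dict(records, orient="index")
    out.index.name = "sample"
    return out


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples, on relative abundances."""
    if table.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    rel = as_relative_abundance(table)
    return beta_diversity("braycurtis", rel.T.to_numpy(), ids=list(table.columns))


def _check_tree(table: pd.DataFrame, tree: TreeNode) -> None:
    if len(tree.children) > 2:
        raise ValueError("tree appears unrooted (root has more than 2 children)")
    leaves = {t.name for t in tree.tips()}
    present = table.index[(table.sum(axis=1) > 0).to_numpy()]
    missing = [o for o in present if o not in leaves]
    if missing:
        raise ValueError(f"OTUs absent from tree: {missing[:5]}")


def unifrac(
    table: pd.DataFrame,
    tree: TreeNode,
    weighted: bool = False,
    normalized: bool = True,
) -> DistanceMatrix:
    """Unweighted or weighted UniFrac distance between samples.

    The weighted variant is normalized by default so both forms are bounded
    in [0, 1]; pass ``normalized=False`` for the raw weighted form.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    _check_tree(table, tree)
    taxa = list(table.index)
    counts = table.T.to_numpy(dtype=float)
    if weighted:
        return beta_diversity(
            "weighted_unifrac", counts, ids=list(table.columns),
            tree=tree, taxa=taxa, normalized=normalized,
        )
    return beta_diversity(
        "unweighted_unifrac", counts, ids=list(table.columns), tree=tree, taxa=taxa
    )


def shared_unique_otus(table: pd.DataFrame, meta: pd.DataFrame) -> dict[tuple[str, ...], int]:
    """Venn-style partition of OTUs by the set of groups they occur in.

    An OTU is "present" in a group when it has a nonzero count in at least
    one of the group's samples. Returns counts keyed by the sorted tuple of
    groups; keys cover every nonempty subset (zero counts included), and the
    values sum to the number of OTUs with any presence.
    """
    labels = group_labels(table, meta)
    groups = sorted(labels.unique())
    presence = {}
    for g in groups:
        cols = labels.index[labels == g]
        if len(cols) == 0:
            raise ValueError(f"group {g!r} has no samples")
        presence[g] = table[list(cols)].sum(axis=1) > 0
    membership = pd.DataFrame(presence)
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(groups) + 1):
        for subset in itertools.combinations(groups, r):
            mask = np.ones(len(table), dtype=bool)
            for g in groups:
                want = g in subset
                mask &= membership[g].to_numpy() == want
            counts[subset] = int(mask.sum())
    return counts


def group_mean_curve(curve: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Average per-sample rarefaction curves within groups."""
    merged = curve.merge(
        meta["group"], left_on="sample", right_index=True, how="left"
    )
    return (
        merged.groupby(["group", "fraction"], observed=True)["mean_otus"]
        .agg(["mean", "std"])
        .reset_index()
        .rename(columns={"mean": "mean_otus", "std": "sd_otus"})
    )
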