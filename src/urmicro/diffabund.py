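"""Two-group differential abundance and the LDA-effect-size screen.

``differential_taxa`` runs a per-taxon Wilcoxon rank-sum test between two
groups on relative abundances, applies Benjamini-Hochberg FDR within that
pairwise family, and assigns significance tiers (q<0.01, q<0.05, p<0.05, ns).
``lefse_like`` is a two-stage biomarker screen: a Kruskal-Wallis test across
all groups followed by a one-dimensional linear-discriminant effect size on
per-million-scaled abundances (bootstrap-averaged), reported on a log10
scale against a cutoff (default 4).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import group_labels

TIERS = ("q<0.01", "q<0.05", "p<0.05", "ns")

#: combined sample size at or below which the exact Wilcoxon null is used
EXACT_LIMIT = 12


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact permutation null when the combined sample size is at most
    12 and there are no ties; otherwise the normal approximation with tie
    and continuity corrections. Returns ``(U_statistic, p)``; degenerate
    inputs where all values are identical return p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample vector")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2), 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    if x.size + y.size <= EXACT_LIMIT and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _tier(p: float, q: float) -> str:
    if np.isnan(p):
        return "ns"
    if q < 0.01:
        return "q<0.01"
    if q < 0.05:
        return "q<0.05"
    if p < 0.05:
        return "p<0.05"
    return "ns"


def differential_taxa(
    rel: pd.DataFrame,
    meta: pd.DataFrame,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Per-taxon Wilcoxon test of ``group_a`` vs ``group_b`` with BH FDR.

    ``rel`` is a relative-abundance table (taxa x samples). Returns one row
    per taxon with group means, the U statistic, raw p, BH q (adjusted
    within this comparison), the enriched group (by mean difference), the
    significance tier, and a ``degenerate`` flag for taxa absent from both
    groups (p undefined, reported ns, excluded from the BH family).
    """
    labels = group_labels(rel, meta)
    cols_a = list(labels.index[labels == group_a])
    cols_b = list(labels.index[labels == group_b])
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(f"both groups need >= 2 samples ({group_a}: {len(cols_a)}, {group_b}: {len(cols_b)})")
    rows = []
    for taxon in rel.index:
        xa = rel.loc[taxon, cols_a].to_numpy(dtype=float)
        xb = rel.loc[taxon, cols_b].to_numpy(dtype=float)
        degenerate = bool(np.all(xa == 0) and np.all(xb == 0))
        if degenerate:
            stat, p = np.nan, np.nan
        else:
            stat, p = wilcoxon_rank_sum(xa, xb)
        mean_a, mean_b = float(xa.mean()), float(xb.mean())
        if mean_a > mean_b:
            enriched = group_a
        elif mean_b > mean_a:
            enriched = group_b
        else:
            enriched = ""
        rows.append((taxon, mean_a, mean_b, stat, p, enriched, degenerate))
    out = pd.DataFrame(
        rows,
        columns=["taxon", f"mean_{group_a}", f"mean_{group_b}", "statistic", "p", "enriched", "degenerate"],
    ).set_index("taxon")
    out["q"] = np.nan
    defined = ~out["p"].isna()
    if defined.any():
        out.loc[defined, "q"] = bh_adjust(out.loc[defined, "p"].to_numpy())
    out["tier"] = [_tier(p, q) for p, q in zip(out["p"], out["q"])]
    out.attrs["group_a"] = group_a
    out.attrs["group_b"] = group_b
    return out


def joint_bh_adjust(diffs: list[pd.DataFrame]) -> list[pd.DataFrame]:
    """Re-adjust a set of pairwise results as one joint BH family.

    The default (and conventional) treatment adjusts each pairwise
    comparison separately; this pools the defined p-values of all
    comparisons into a single family, rewrites ``q`` and re-derives the
    tiers. Returns new frames in the input order.
    """
    lengths, pooled = [], []
    for d in diffs:
        defined = d["p"].dropna()
        lengths.append(defined)
        pooled.append(defined.to_numpy())
    q_all = bh_adjust(np.concatenate(pooled)) if pooled else np.array([])
    out, start = [], 0
    for d, defined in zip(diffs, lengths):
        new = d.copy()
        new.attrs.update(d.attrs)
        new.loc[defined.index, "q"] = q_all[start:start + len(defined)]
        start += len(defined)
        new["tier"] = [_tier(p, q) for p, q in zip(new["p"], new["q"])]
        out.append(new)
    return out


def _lda_effect_size(
    scaled: pd.DataFrame,
    labels: pd.Series,
    rng: np.random.Generator,
    n_boot: int,
    boot_fraction: float = 2 / 3,
) -> pd.Series:
    """Bootstrap-averaged one-dimensional discriminant effect per taxon.

    For a single feature the linear discriminant axis is the feature itself,
    so the discriminant effect reduces to the largest absolute difference in
    class means on the per-million scale. Each bootstrap draws a
    ``boot_fraction`` subset (without replacement) within every group.
    """
    groups = sorted(labels.unique())
    effects = np.zeros((n_boot, scaled.shape[0]))
    cols_by_group = {g: list(labels.index[labels == g]) for g in groups}
    for b in range(n_boot):
        means = []
        for g in groups:
            cols = cols_by_group[g]
            take = max(2, int(np.ceil(boot_fraction * len(cols))))
            take = min(take, len(cols))
            picked = list(rng.choice(cols, size=take, replace=False))
            means.append(scaled[picked].mean(axis=1).to_numpy())
        means = np.stack(means)  # groups x taxa
        effects[b] = means.max(axis=0) - means.min(axis=0)
    return pd.Series(effects.mean(axis=0), index=scaled.index)


def lefse_like(
    rel: pd.DataFrame,
    meta: pd.DataFrame,
    kw_alpha: float = 0.05,
    lda_cutoff: float = 4.0,
    n_boot: int = 30,
    seed: int | None = None,
) -> pd.DataFrame:
    """Kruskal-Wallis + LDA-effect-size biomarker screen across all groups.

    Stage 1 keeps taxa with Kruskal-Wallis p below ``kw_alpha``. Stage 2
    scores each survivor with a bootstrap-averaged one-dimensional
    discriminant effect on abundances scaled to parts-per-million;
    ``lda_score = log10(1 + effect)``. Rows passing ``lda_score >
    lda_cutoff`` are returned with the group of highest mean abundance.
    """
    labels = group_labels(rel, meta)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    cols_by_group = {g: list(labels.index[labels == g]) for g in groups}
    if any(len(c) < 2 for c in cols_by_group.values()):
        raise ValueError("degenerate grouping: every group needs >= 2 samples")
    kw_p = {}
    for taxon in rel.index:
        samples = [rel.loc[taxon, cols_by_group[g]].to_numpy(dtype=float) for g in groups]
        pooled = np.concatenate(samples)
        if np.all(pooled == pooled[0]):
            kw_p[taxon] = 1.0
        else:
            kw_p[taxon] = float(stats.kruskal(*samples).pvalue)
    kw_p = pd.Series(kw_p, name="kw_p")
    passing = kw_p.index[kw_p < kw_alpha]
    if len(passing) == 0:
        return pd.DataFrame(columns=["kw_p", "lda_score", "enriched"])
    rng = np.random.default_rng(seed)
    scaled = rel.loc[passing] * 1e6
    effect = _lda_effect_size(scaled, labels, rng, n_boot=n_boot)
    score = np.log10(1.0 + effect)
    group_means = pd.DataFrame(
        {g: rel.loc[passing, cols_by_group[g]].mean(axis=1) for g in groups}
    )
    out = pd.DataFrame(
        {
            "kw_p": kw_p.loc[passing],
            "lda_score": score,
            "enriched": group_means.idxmax(axis=1),
        }
    )
    out = out[out["lda_score"] > lda_cutoff].sort_values("lda_score", ascending=False)
    out.index.name = "taxon"
    return out
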