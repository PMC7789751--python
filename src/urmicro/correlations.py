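"""Spearman correlation networks among taxa and against clinical covariates."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with t-approximation p-value.

    Ties receive average ranks. A constant vector has no defined rank
    correlation: returns ``(nan, nan)``. ``rho = +/-1`` reports p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def genus_network(
    rel: pd.DataFrame,
    taxa: list[str] | None = None,
    threshold: float = 0.45,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Spearman co-occurrence network over selected taxa.

    Edges connect taxon pairs with ``|rho| > threshold`` (strict). By default
    all samples are pooled across groups; pass ``samples`` (e.g. one group's
    sample ids) for a within-group network. Returns an undirected edge list
    (``source < target`` lexicographically within the input order, each pair
    stored once) with columns ``source, target, rho, p, sign``.
    """
    taxa = list(rel.index) if taxa is None else list(taxa)
    missing = [t for t in taxa if t not in rel.index]
    if missing:
        raise KeyError(f"taxa not in table: {missing[:5]}")
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    sub = rel.loc[taxa]
    if samples is not None:
        sub = sub[[s for s in sub.columns if s in set(samples)]]
    edges = []
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            rho, p = spearman(sub.iloc[i], sub.iloc[j])
            if np.isnan(rho) or abs(rho) <= threshold:
                continue
            edges.append((taxa[i], taxa[j], rho, p, "positive" if rho > 0 else "negative"))
    return pd.DataFrame(edges, columns=["source", "target", "rho", "p", "sign"])


@dataclass
class TaxonCovariateResult:
    """Spearman rho/p between each taxon and each clinical covariate."""

    rho: pd.DataFrame  # taxa x covariates
    p: pd.DataFrame
    significant: pd.DataFrame  # bool, raw p < alpha
    alpha: float
    errors: dict[str, str] = field(default_factory=dict)  # per-covariate failures


def genus_covariate_matrix(
    rel: pd.DataFrame,
    meta: pd.DataFrame,
    covariates: list[str] | None = None,
    alpha: float = 0.05,
    bh: bool = False,
    group: str | None = None,
) -> TaxonCovariateResult:
    """Correlate every taxon's relative abundance with every covariate.

    Missing covariate values are pairwise-dropped. A covariate with fewer
    than 3 non-missing values (or constant values) is reported in
    ``errors`` while the others are still computed. Significance flags use
    raw p at ``alpha`` (the figure-asterisk convention) unless ``bh=True``,
    in which case BH-adjusted p-values are flagged instead. All samples are
    pooled across groups unless ``group`` restricts to one group.
    """
    if covariates is None:
        covariates = [
            c for c in meta.columns if c != "group" and pd.api.types.is_numeric_dtype(meta[c])
        ]
    missing = [c for c in covariates if c not in meta.columns]
    if missing:
        raise KeyError(f"covariates not in metadata: {missing}")
    samples = [s for s in rel.columns if s in meta.index]
    if group is not None:
        samples = [s for s in samples if meta.loc[s, "group"] == group]
    rho = pd.DataFrame(index=rel.index, columns=covariates, dtype=float)
    pmat = pd.DataFrame(index=rel.index, columns=covariates, dtype=float)
    errors: dict[str, str] = {}
    for cov in covariates:
        values = pd.to_numeric(meta.loc[samples, cov], errors="coerce")
        ok = values.notna()
        if ok.sum() < 3:
            errors[cov] = f"fewer than 3 non-missing values ({int(ok.sum())})"
            continue
        kept = values[ok]
        for taxon in rel.index:
            x = rel.loc[taxon, kept.index].to_numpy(dtype=float)
            r, p = spearman(x, kept.to_numpy()) if not np.all(x == x[0]) else (np.nan, np.nan)
            rho.loc[taxon, cov] = r
            pmat.loc[taxon, cov] = p
    flag_p = pmat.copy()
    if bh:
        flat = pmat.to_numpy().ravel()
        ok = ~np.isnan(flat)
        if ok.any():
            from .diffabund import bh_adjust

            adj = flat.copy()
            adj[ok] = bh_adjust(flat[ok])
            flag_p = pd.DataFrame(
                adj.reshape(pmat.shape), index=pmat.index, columns=pmat.columns
            )
    significant = flag_p < alpha
    return TaxonCovariateResult(rho=rho, p=pmat, significant=significant, alpha=alpha, errors=errors)
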