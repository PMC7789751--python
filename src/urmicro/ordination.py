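"""Principal coordinates analysis and PERMANOVA on distance matrices.

PCoA uses Gower double-centering of ``-d^2/2`` followed by a symmetric
eigendecomposition; coordinates are eigenvectors scaled by the square root
of their (positive) eigenvalues, and negative eigenvalues are reported but
contribute no axes. PERMANOVA partitions the sum of squared distances into
between- and within-group components and assesses the pseudo-F statistic by
label permutation, with the ``(count + 1) / (n_perm + 1)`` p-value
convention so p is floored at ``1/(n_perm + 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # over positive eigenvalues only


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    group_sizes: dict[str, int] = field(default_factory=dict)


def _as_distance_matrix(d) -> DistanceMatrix:
    if isinstance(d, DistanceMatrix):
        return d
    if isinstance(d, pd.DataFrame):
        return DistanceMatrix(d.to_numpy(), ids=list(d.index))
    return DistanceMatrix(np.asarray(d))


def pcoa(d, n_axes: int | None = None) -> OrdinationResult:
    """Classical metric multidimensional scaling of a distance matrix.

    ``n_axes`` beyond the number of positive eigenvalues is truncated with a
    warning. Axis columns are labelled ``PC1``, ``PC2``, ...
    """
    dm = _as_distance_matrix(d)
    ids = list(dm.ids)
    n = len(ids)
    a = -0.5 * dm.data**2
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = centerer @ a @ centerer
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12 if n else 0.0
    n_pos = int((eigvals > tol).sum())
    if n_axes is None:
        n_axes = n_pos
    elif n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
        n_axes = n_pos
    coords = eigvecs[:, :n_axes] * np.sqrt(eigvals[:n_axes]) if n_axes else np.zeros((n, 0))
    pos = eigvals[:n_pos]
    proportion = pos / pos.sum() if n_pos else np.array([])
    frame = pd.DataFrame(coords, index=ids, columns=[f"PC{i + 1}" for i in range(n_axes)])
    return OrdinationResult(frame, eigvals, proportion)


def _group_array(d: DistanceMatrix, grouping) -> np.ndarray:
    if isinstance(grouping, pd.DataFrame):
        grouping = grouping["group"]
    if isinstance(grouping, pd.Series):
        labels = grouping.loc[list(d.ids)].to_numpy()
    else:
        labels = np.asarray(grouping)
        if len(labels) != len(d.ids):
            raise ValueError("grouping length does not match distance matrix")
    return labels


def _ss_within(d2: np.ndarray, labels_int: np.ndarray, sizes: np.ndarray) -> float:
    ssw = 0.0
    for g, n_g in enumerate(sizes):
        mask = labels_int == g
        ssw += d2[np.ix_(mask, mask)].sum() / (2 * n_g)
    return ssw


def permanova(
    d,
    grouping,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA of a distance matrix against a categorical grouping.

    ``grouping`` may be a metadata frame with a ``group`` column (indexed by
    sample id), a Series, or a plain label array ordered like the matrix.
    Permutations are simple label shuffles.
    """
    dm = _as_distance_matrix(d)
    labels = _group_array(dm, grouping)
    uniq, labels_int = np.unique(labels, return_inverse=True)
    sizes = np.bincount(labels_int)
    if len(uniq) < 2 or (sizes < 2).any():
        raise ValueError(
            "degenerate grouping: need >= 2 groups with >= 2 samples each, got "
            + str(dict(zip(uniq, sizes)))
        )
    n, g = len(labels), len(uniq)
    d2 = dm.data**2
    ss_total = d2.sum() / (2 * n)

    def pseudo_f(ssw: float) -> float:
        return ((ss_total - ssw) / (g - 1)) / (ssw / (n - g))

    f_obs = pseudo_f(_ss_within(d2, labels_int, sizes))

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    permuted = labels_int[perms]  # (n_perm, n)
    ssw_perm = np.zeros(n_perm)
    for grp in range(g):
        m = (permuted == grp).astype(float)
        ssw_perm += np.einsum("pi,ij,pj->p", m, d2, m) / (2 * sizes[grp])
    f_perm = ((ss_total - ssw_perm) / (g - 1)) / (ssw_perm / (n - g))
    p = (np.count_nonzero(f_perm >= f_obs) + 1) / (n_perm + 1)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=n_perm,
        group_sizes={str(u): int(s) for u, s in zip(uniq, sizes)},
    )
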