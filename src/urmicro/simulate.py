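"""Dirichlet-multinomial cohort simulator.

Generates OTU count tables with the statistical structure the downstream
analysis assumes: per-sample sequencing depth drawn from a truncated normal,
per-sample composition drawn from a Dirichlet whose concentration vector
carries group-specific multiplicative fold-changes on planted OTUs, and
counts drawn multinomially at that depth. Planting effects on *concentrations*
(not final proportions) preserves the compositional renormalisation confound
present in real 16S data. A random coalescent tree over the OTUs supplies the
UniFrac substrate, and numeric clinical covariates are generated as monotone
transforms of planted-OTU relative abundance plus Gaussian noise to hit a
target Spearman correlation.

The default configuration (:func:`default_config`) emulates a three-group
urinary-retention cohort: 25 controls, 34 stone-UR and 25 tumor-UR samples
(two stone-UR samples planted below the 8000-read QC threshold, so 82
survive filtering), 310 OTUs in 45 genera, mean depth 36,072 +/- 3,376 reads,
ten genera 4-fold enriched in both UR groups, five genera depleted in both
UR groups, and one tumor-only discriminative genus.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import RANKS

GROUP_CONTROL = "control"
GROUP_STONE = "stone_UR"
GROUP_TUMOR = "tumor_UR"

#: (mean, sd, lower clip) templates for clinical covariates, loosely modelled
#: on routine blood/urine chemistry of an adult cohort.
COVARIATE_TEMPLATES: dict[str, tuple[float, float, float]] = {
    "eGFR": (70.0, 30.0, 5.0),
    "UA": (380.0, 120.0, 100.0),
    "RBC": (1400.0, 3000.0, 0.0),
    "WBC": (1200.0, 2500.0, 0.0),
    "DBIL": (3.7, 2.5, 0.3),
    "IBIL": (5.4, 2.6, 0.5),
    "ALP": (109.0, 80.0, 20.0),
}


@dataclass
class SyntheticConfig:
    """Parameters of one simulated cohort.

    ``planted_effects`` are ``(otu_id, group, fold)`` triples: the OTU's
    Dirichlet concentration is multiplied by ``fold`` in samples of that
    group. ``covariate_links`` are ``(covariate, otu_id, rho)`` triples
    targeting a signed Spearman correlation between the covariate and the
    OTU's relative abundance.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {GROUP_CONTROL: 25, GROUP_STONE: 34, GROUP_TUMOR: 25}
    )
    n_otus: int = 310
    n_genera: int = 45
    n_phyla: int = 8
    base_concentration: list[float] | None = None  # None -> lognormal, drawn from seed
    total_concentration: float = 50.0
    planted_effects: list[tuple[str, str, float]] = field(default_factory=list)
    depth_mean: float = 36072.0
    depth_sd: float = 3376.0
    n_shallow: int = 0
    shallow_group: str | None = None
    shallow_depth: int = 8000
    covariate_links: list[tuple[str, str, float]] = field(default_factory=list)
    covariates: tuple[str, ...] = tuple(COVARIATE_TEMPLATES)
    seed: int = 0

    def validate(self) -> None:
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group needs at least 2 samples")
        if self.n_otus < 2:
            raise ValueError("n_otus must be >= 2")
        if self.base_concentration is not None:
            arr = np.asarray(self.base_concentration, dtype=float)
            if arr.shape != (self.n_otus,):
                raise ValueError("base_concentration length must equal n_otus")
            if (arr <= 0).any():
                raise ValueError("concentrations must be > 0")
        ids = set(otu_id_list(self.n_otus))
        for otu, group, fold in self.planted_effects:
            if fold <= 0:
                raise ValueError(f"fold-change must be > 0, got {fold}")
            if group not in self.group_sizes:
                raise ValueError(f"unknown group in planted effect: {group}")
            if otu not in ids:
                raise ValueError(f"unknown OTU in planted effect: {otu}")
        for cov, otu, rho in self.covariate_links:
            if not -1 < rho < 1:
                raise ValueError("target correlation must be in (-1, 1)")
            if otu not in ids:
                raise ValueError(f"unknown OTU in covariate link: {otu}")
        if self.n_shallow and self.shallow_group is not None:
            if self.shallow_group not in self.group_sizes:
                raise ValueError(f"unknown shallow_group: {self.shallow_group}")

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "SyntheticConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["planted_effects"] = [tuple(t) for t in raw.get("planted_effects", [])]
        raw["covariate_links"] = [tuple(t) for t in raw.get("covariate_links", [])]
        raw["covariates"] = tuple(raw.get("covariates", tuple(COVARIATE_TEMPLATES)))
        return cls(**raw)


def otu_id_list(n_otus: int) -> list[str]:
    return [f"OTU_{i + 1:04d}" for i in range(n_otus)]


def genus_name(j: int) -> str:
    return f"Genus{j + 1:02d}"


def genus_assignment(cfg: SyntheticConfig) -> pd.Series:
    """Deterministic contiguous-block assignment of OTUs to synthetic genera."""
    ids = otu_id_list(cfg.n_otus)
    blocks = np.floor(np.arange(cfg.n_otus) * cfg.n_genera / cfg.n_otus).astype(int)
    return pd.Series([genus_name(j) for j in blocks], index=ids, name="genus")


def otus_of_genus(cfg: SyntheticConfig, j: int) -> list[str]:
    g = genus_assignment(cfg)
    return list(g.index[g == genus_name(j)])


def make_taxonomy(cfg: SyntheticConfig) -> pd.DataFrame:
    genera = genus_assignment(cfg)
    genus_idx = genera.str.removeprefix("Genus").astype(int) - 1
    phylum_idx = genus_idx % cfg.n_phyla
    tax = pd.DataFrame(index=genera.index, columns=list(RANKS), data="")
    tax.index.name = "otu_id"
    tax["kingdom"] = "Bacteria"
    tax["phylum"] = [f"Phylum{i + 1:02d}" for i in phylum_idx]
    tax["class"] = [f"Class{i + 1:02d}" for i in phylum_idx]
    tax["order"] = [f"Order{i + 1:02d}" for i in phylum_idx]
    tax["family"] = [f"Family{i + 1:02d}" for i in genus_idx]
    tax["genus"] = genera
    return tax


def simulate_tree(n_leaves: int, seed: int) -> TreeNode:
    """Random coalescent-style rooted bifurcating tree with exponential
    branch lengths; leaves are labelled ``OTU_0001`` ... in input order."""
    if n_leaves < 2:
        raise ValueError("n_leaves must be >= 2")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=name, length=None) for name in otu_id_list(n_leaves)]
    heights = [0.0] * n_leaves
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(scale=2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = TreeNode(length=None)
        a, b = nodes[i], nodes[j]
        a.length = t - heights[i]
        b.length = t - heights[j]
        parent.extend([a, b])
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)] + [parent]
        heights = [h for idx, h in enumerate(heights) if idx not in (i, j)] + [t]
    root = nodes[0]
    root.length = None
    return root


def _sample_ids(cfg: SyntheticConfig) -> tuple[list[str], list[str]]:
    """Sample ids in group order and their group labels."""
    prefix = {GROUP_CONTROL: "C", GROUP_STONE: "S", GROUP_TUMOR: "T"}
    ids, groups = [], []
    for g, n in cfg.group_sizes.items():
        p = prefix.get(g, g[:1].upper())
        for i in range(n):
            ids.append(f"{p}{i + 1:02d}")
            groups.append(g)
    return ids, groups


def _covariate_values(
    rng: np.random.Generator, name: str, abundance: np.ndarray | None, rho: float
) -> np.ndarray:
    """Covariate with target Spearman correlation against ``abundance``.

    Normal scores of the abundance ranks (a monotone transform) are mixed
    with independent Gaussian noise at the target correlation, then mapped
    onto the covariate's clinical template scale.
    """
    mean, sd, lo = COVARIATE_TEMPLATES.get(name, (0.0, 1.0, -np.inf))
    n = len(abundance) if abundance is not None else 0
    if abundance is None or rho == 0:
        return np.maximum(rng.normal(mean, sd, size=n), lo)
    ranks = pd.Series(abundance).rank(method="average").to_numpy()
    z = (ranks - ranks.mean()) / max(ranks.std(ddof=0), 1e-12)
    eps = rng.normal(size=n)
    mixed = rho * z + np.sqrt(1 - rho**2) * eps
    return np.maximum(mean + sd * mixed, lo)


def simulate_community(
    cfg: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TreeNode]:
    """Simulate one cohort.

    Returns ``(otu_table, taxonomy, metadata, tree)`` where the OTU table is
    counts (OTUs x samples), taxonomy is a rank table, metadata carries the
    group label and covariates, and the tree spans all OTUs.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    s_conc, s_depth, s_comp, s_tree, s_cov = ss.spawn(5)
    otus = otu_id_list(cfg.n_otus)
    sample_ids, groups = _sample_ids(cfg)
    n_samples = len(sample_ids)

    if cfg.base_concentration is None:
        rng_c = np.random.default_rng(s_conc)
        base = rng_c.lognormal(mean=0.0, sigma=1.0, size=cfg.n_otus)
        base *= cfg.total_concentration / base.sum()
    else:
        base = np.asarray(cfg.base_concentration, dtype=float)

    # per-group concentration vectors with planted fold-changes
    conc = {g: base.copy() for g in cfg.group_sizes}
    otu_pos = {o: i for i, o in enumerate(otus)}
    for otu, group, fold in cfg.planted_effects:
        conc[group][otu_pos[otu]] *= fold

    rng_d = np.random.default_rng(s_depth)
    depths = np.maximum(np.rint(rng_d.normal(cfg.depth_mean, cfg.depth_sd, n_samples)), 1).astype(int)
    if cfg.n_shallow:
        target = cfg.shallow_group
        pool = [i for i, g in enumerate(groups) if target is None or g == target]
        if cfg.n_shallow > len(pool):
            raise ValueError("n_shallow exceeds the shallow group's size")
        picked = rng_d.choice(pool, size=cfg.n_shallow, replace=False)
        depths[picked] = rng_d.integers(cfg.shallow_depth // 2, cfg.shallow_depth, cfg.n_shallow)

    rng_x = np.random.default_rng(s_comp)
    counts = np.zeros((cfg.n_otus, n_samples), dtype=np.int64)
    for j, (sid, g) in enumerate(zip(sample_ids, groups)):
        p = rng_x.dirichlet(conc[g])
        counts[:, j] = rng_x.multinomial(depths[j], p)
    table = pd.DataFrame(counts, index=otus, columns=sample_ids)
    table.index.name = "#OTU_ID"

    tax = make_taxonomy(cfg)
    tree = simulate_tree(cfg.n_otus, seed=int(s_tree.generate_state(1)[0] % (2**31)))

    rng_v = np.random.default_rng(s_cov)
    rel = table / table.sum(axis=0).replace(0, 1)
    meta = pd.DataFrame({"group": groups}, index=sample_ids)
    meta.index.name = "sample_id"
    links = {name: (otu, rho) for name, otu, rho in cfg.covariate_links}
    for name in cfg.covariates:
        if name in links:
            otu, rho = links[name]
            meta[name] = _covariate_values(rng_v, name, rel.loc[otu].to_numpy(), rho)
        else:
            meta[name] = _covariate_values(rng_v, name, np.zeros(n_samples), 0.0)
    return table, tax, meta, tree


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The standard three-group urinary-retention cohort (see module docs).

    Planted structure, by genus index (0-based):

    * genera 0-9: 4-fold enriched in both stone_UR and tumor_UR ("case" genera);
    * genera 10-14: 4-fold depleted (fold 0.25) in both UR groups
      ("control-enriched" genera);
    * genus 15: 3-fold enriched in tumor_UR only (the stone-vs-tumor marker).

    Covariates: eGFR negatively (rho -0.5) and UA positively (rho +0.5)
    linked to case genera, WBC (+0.4) and RBC (+0.3) positively linked;
    DBIL, IBIL, ALP are unlinked noise.
    """
    kwargs: dict = {"seed": seed, "n_shallow": 2, "shallow_group": GROUP_STONE}
    kwargs.update(overrides)
    cfg = SyntheticConfig(**kwargs)
    effects: list[tuple[str, str, float]] = []
    for j in range(10):
        for otu in otus_of_genus(cfg, j):
            effects.append((otu, GROUP_STONE, 4.0))
            effects.append((otu, GROUP_TUMOR, 4.0))
    for j in range(10, 15):
        for otu in otus_of_genus(cfg, j):
            effects.append((otu, GROUP_STONE, 0.25))
            effects.append((otu, GROUP_TUMOR, 0.25))
    for otu in otus_of_genus(cfg, 15):
        effects.append((otu, GROUP_TUMOR, 3.0))
    cfg.planted_effects = effects
    cfg.covariate_links = [
        ("eGFR", otus_of_genus(cfg, 0)[0], -0.5),
        ("UA", otus_of_genus(cfg, 1)[0], 0.5),
        ("WBC", otus_of_genus(cfg, 2)[0], 0.4),
        ("RBC", otus_of_genus(cfg, 0)[0], 0.3),
    ]
    cfg.validate()
    return cfg


#: genera planted as enriched in both UR groups under :func:`default_config`
DEFAULT_CASE_GENERA = tuple(genus_name(j) for j in range(10))
#: genera planted as enriched in controls under :func:`default_config`
DEFAULT_CONTROL_GENERA = tuple(genus_name(j) for j in range(10, 15))
#: the tumor-only genus under :func:`default_config`
DEFAULT_TUMOR_GENUS = genus_name(15)
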