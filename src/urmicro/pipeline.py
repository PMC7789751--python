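"""End-to-end study workflow with a seeded, checksummed run manifest.

``run_full_analysis`` executes the seven analysis stages in order --
data (simulate or ingest), QC, diversity, ordination/PERMANOVA, differential
abundance, correlation networks, marker selection/POD -- writing plain
TSV/JSON outputs to the run directory plus a ``manifest.json`` recording the
package version, every threshold and derived seed, and a SHA-256 checksum of
every output file. All randomness derives from the single master seed, so
two runs with the same configuration produce identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, correlations, diffabund, diversity, io, markers, ordination, qc
from .simulate import SyntheticConfig, simulate_community

logger = logging.getLogger("urmicro")

STAGES = ("data", "qc", "diversity", "ordination", "differential", "correlations", "markers")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``synthetic`` or the four input paths must be provided. Threshold
    defaults are the study's stated analysis parameters.
    """

    out_dir: str = "urmicro_run"
    synthetic: SyntheticConfig | None = None
    otu_table: str | None = None
    taxonomy: str | None = None
    metadata: str | None = None
    tree: str | None = None
    control_group: str = "control"
    min_reads: int = 8000
    min_otu_frac: float = 1e-4
    kw_alpha: float = 0.05
    lda_cutoff: float = 4.0
    corr_threshold: float = 0.45
    n_perm: int = 999
    trials: int = 5
    folds: int = 5
    runs: int = 100
    n_estimators: int = 500
    rank: str = "genus"
    top_n: int = 35
    rarefaction_repeats: int = 5
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if raw.get("synthetic") is not None:
            syn = raw["synthetic"]
            syn["planted_effects"] = [tuple(t) for t in syn.get("planted_effects", [])]
            syn["covariate_links"] = [tuple(t) for t in syn.get("covariate_links", [])]
            if "covariates" in syn:
                syn["covariates"] = tuple(syn["covariates"])
            raw["synthetic"] = SyntheticConfig(**syn)
        return cls(**raw)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    return str(obj)


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _StageRunner:
    def __init__(self):
        self.completed: list[str] = []

    def run(self, name: str, fn):
        logger.info("stage %s: start", name)
        try:
            out = fn()
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        self.completed.append(name)
        logger.info("stage %s: done", name)
        return out


def run_full_analysis(cfg: RunConfig) -> dict:
    """Execute the full workflow; returns the manifest dictionary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {
        name: int(c.generate_state(1)[0] % (2**31))
        for name, c in zip(STAGES, np.random.SeedSequence(cfg.seed).spawn(len(STAGES)))
    }
    runner = _StageRunner()

    # stage 1: data ---------------------------------------------------------
    def stage_data():
        if cfg.synthetic is not None:
            syn = dataclasses.replace(cfg.synthetic, seed=seeds["data"])
            table, tax, meta, tree = simulate_community(syn)
        elif cfg.otu_table:
            table = io.read_otu_table(cfg.otu_table)
            tax = io.read_taxonomy(cfg.taxonomy)
            meta = io.read_metadata(cfg.metadata)
            tree = io.read_tree(cfg.tree)
        else:
            raise ValueError("config provides neither synthetic settings nor input paths")
        io.write_otu_table(table, out / "otu_table.tsv")
        io.write_taxonomy(tax, out / "taxonomy.tsv")
        io.write_metadata(meta, out / "metadata.tsv")
        io.write_tree(tree, out / "tree.nwk")
        return table, tax, meta, tree

    table, tax, meta, tree = runner.run("data", stage_data)

    # stage 2: qc -----------------------------------------------------------
    def stage_qc():
        t1 = qc.filter_samples_min_reads(table, cfg.min_reads)
        removed_samples = t1.attrs["removed_samples"]
        t2 = qc.filter_otus_min_fraction(t1, cfg.min_otu_frac)
        removed_otus = t2.attrs["removed_otus"]
        io.write_otu_table(t2, out / "filtered_otu_table.tsv")
        _write_json(
            {
                "n_samples_in": table.shape[1],
                "n_samples_kept": t2.shape[1],
                "removed_samples": removed_samples,
                "n_otus_in": table.shape[0],
                "n_otus_kept": t2.shape[0],
                "removed_otus": removed_otus,
            },
            out / "qc_summary.json",
        )
        return t2

    filtered = runner.run("qc", stage_qc)
    meta_f = meta.loc[[s for s in filtered.columns]]
    groups = sorted(meta_f["group"].unique())
    pairs = list(itertools.combinations(groups, 2))

    # stage 3: diversity ----------------------------------------------------
    def stage_diversity():
        alpha = diversity.alpha_diversity(filtered)
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
        tests = []
        for a, b in pairs:
            sa = meta_f.index[meta_f["group"] == a]
            sb = meta_f.index[meta_f["group"] == b]
            for metric in alpha.columns:
                xa = alpha.loc[sa, metric].dropna()
                xb = alpha.loc[sb, metric].dropna()
                if len(xa) and len(xb):
                    stat, p = diffabund.wilcoxon_rank_sum(xa, xb)
                else:  # index undefined for every sample of a group
                    stat, p = float("nan"), float("nan")
                tests.append((metric, a, b, stat, p))
        pd.DataFrame(tests, columns=["metric", "group_a", "group_b", "statistic", "p"]).to_csv(
            out / "alpha_tests.tsv", sep="\t", index=False
        )
        curve = diversity.rarefaction_curve(
            filtered, repeats=cfg.rarefaction_repeats, seed=seeds["diversity"]
        )
        curve.to_csv(out / "rarefaction.tsv", sep="\t", index=False)
        diversity.group_mean_curve(curve, meta_f).to_csv(
            out / "rarefaction_groups.tsv", sep="\t", index=False
        )
        venn = diversity.shared_unique_otus(filtered, meta_f)
        _write_json({" & ".join(k): v for k, v in venn.items()}, out / "venn_counts.json")
        return alpha

    runner.run("diversity", stage_diversity)

    # stage 4: ordination / PERMANOVA ---------------------------------------
    def stage_ordination():
        dms = {
            "bray_curtis": diversity.bray_curtis(filtered),
            "unweighted_unifrac": diversity.unifrac(filtered, tree, weighted=False),
            "weighted_unifrac_normalized": diversity.unifrac(filtered, tree, weighted=True),
        }
        for name, dm in dms.items():
            pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
                out / f"distance_{name}.tsv", sep="\t"
            )
        ord_res = ordination.pcoa(dms["unweighted_unifrac"], n_axes=min(3, filtered.shape[1] - 1))
        ord_res.coordinates.to_csv(out / "pcoa_unweighted_unifrac.tsv", sep="\t")
        results = {}
        rng_seeds = markers._seed_stream(seeds["ordination"], len(dms) + len(pairs))
        for i, (name, dm) in enumerate(sorted(dms.items())):
            res = ordination.permanova(dm, meta_f, n_perm=cfg.n_perm, seed=rng_seeds[i])
            results[name] = dataclasses.asdict(res)
        pairwise = []
        uw = dms["unweighted_unifrac"]
        for j, (a, b) in enumerate(pairs):
            keep = meta_f.index[meta_f["group"].isin([a, b])]
            sub = uw.filter([s for s in uw.ids if s in set(keep)])
            res = ordination.permanova(sub, meta_f, n_perm=cfg.n_perm, seed=rng_seeds[len(dms) + j])
            pairwise.append({"group_a": a, "group_b": b, **dataclasses.asdict(res)})
        raw = [r["p_value"] for r in pairwise]
        for r, q in zip(pairwise, diffabund.bh_adjust(raw)):
            r["q_value"] = float(q)
        _write_json(
            {"overall": results, "pairwise_unweighted_unifrac": pairwise},
            out / "permanova.json",
        )
        return results

    runner.run("ordination", stage_ordination)

    # stage 5: differential abundance ---------------------------------------
    def stage_differential():
        rel_rank = qc.aggregate_by_rank(filtered, tax, cfg.rank)
        rel_rank.to_csv(out / f"relabund_{cfg.rank}.tsv", sep="\t")
        rel_phylum = qc.aggregate_by_rank(filtered, tax, "phylum")
        rel_phylum.to_csv(out / "relabund_phylum.tsv", sep="\t")
        qc.top_n_with_others(rel_rank, cfg.top_n).to_csv(
            out / f"composition_top{cfg.top_n}_{cfg.rank}.tsv", sep="\t"
        )
        diffs = {}
        for a, b in pairs:
            d = diffabund.differential_taxa(rel_rank, meta_f, a, b)
            d.to_csv(out / f"diff_{cfg.rank}_{a}_vs_{b}.tsv", sep="\t")
            diffs[(a, b)] = d
        lefse = diffabund.lefse_like(
            rel_rank, meta_f, kw_alpha=cfg.kw_alpha, lda_cutoff=cfg.lda_cutoff,
            seed=seeds["differential"],
        )
        lefse.to_csv(out / "lefse.tsv", sep="\t")
        return rel_rank, diffs

    rel_rank, diffs = runner.run("differential", stage_differential)

    # stage 6: correlations --------------------------------------------------
    def stage_correlations():
        sig = sorted(
            set().union(*(d.index[d["q"] < 0.05] for d in diffs.values()))
        )
        if len(sig) >= 2:
            edges = correlations.genus_network(rel_rank, sig, threshold=cfg.corr_threshold)
        else:
            edges = pd.DataFrame(columns=["source", "target", "rho", "p", "sign"])
        edges.to_csv(out / "correlation_network.tsv", sep="\t", index=False)
        cov = correlations.genus_covariate_matrix(rel_rank, meta_f)
        cov.rho.to_csv(out / "genus_covariate_rho.tsv", sep="\t")
        cov.p.to_csv(out / "genus_covariate_p.tsv", sep="\t")
        return sig

    runner.run("correlations", stage_correlations)

    # stage 7: markers / POD -------------------------------------------------
    def stage_markers():
        model_specs = []
        cases = [g for g in groups if g != cfg.control_group]
        for case in cases:
            if (case, cfg.control_group) in diffs or (cfg.control_group, case) in diffs:
                model_specs.append((case, cfg.control_group, "q<0.05"))
        if len(cases) == 2:
            model_specs.append((cases[1], cases[0], "p<0.05"))
        m_seeds = markers._seed_stream(seeds["markers"], 2 * len(model_specs))
        summaries = {}
        for m_idx, (case, ctrl, mode) in enumerate(model_specs):
            key = (ctrl, case) if (ctrl, case) in diffs else (case, ctrl)
            diff = diffs[key]
            tag = f"{case}_vs_{ctrl}"
            try:
                cand = markers.select_candidates(diff, case, alpha_mode=mode)
            except ValueError as exc:
                # no enriched taxa for this pair is a reportable outcome, not
                # a pipeline failure
                summaries[tag] = {"case": case, "control": ctrl, "alpha_mode": mode,
                                  "error": str(exc)}
                continue
            X, y = markers.build_feature_matrix(rel_rank, meta_f, case, ctrl, cand)
            sel = markers.cv_error_curve(
                X, y, n_trials=cfg.trials, n_folds=cfg.folds,
                seed=m_seeds[2 * m_idx], n_estimators=cfg.n_estimators,
            )
            sel.error_curve_.to_csv(out / f"markers_{tag}_error_curve.tsv", sep="\t")
            clf = markers.evaluate_auc_100(
                sel.transform(X), y, case_class=case, n_runs=cfg.runs,
                seed=m_seeds[2 * m_idx + 1], n_estimators=cfg.n_estimators,
            )
            pd.DataFrame({"auc": clf.auc_runs_}).to_csv(
                out / f"markers_{tag}_auc.tsv", sep="\t", index=False
            )
            clf.mda_.rename("mda").to_csv(out / f"markers_{tag}_mda.tsv", sep="\t")
            pod = pd.DataFrame({"pod": clf.pod_, "group": y})
            pod.to_csv(out / f"markers_{tag}_pod.tsv", sep="\t")
            summaries[tag] = {
                "case": case,
                "control": ctrl,
                "alpha_mode": mode,
                "n_candidates": len(cand),
                "candidates": cand,
                "optimal_k": sel.optimal_k_,
                "optimal_set": sel.optimal_features_,
                "cv_cutoff": sel.cutoff_,
                "mean_auc": clf.mean_auc_,
                "pod_p_value": clf.pod_p_value_,
                "mean_pod_case": float(clf.pod_[y == case].mean()),
                "mean_pod_control": float(clf.pod_[y == ctrl].mean()),
            }
        _write_json(summaries, out / "marker_summaries.json")
        return summaries

    runner.run("markers", stage_markers)

    # manifest ---------------------------------------------------------------
    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "urmicro_version": __version__,
        "config": dataclasses.asdict(cfg),
        "stages": runner.completed,
        "stage_seeds": seeds,
        "checksums": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    _write_json(manifest, out / "manifest.json")
    return manifest
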