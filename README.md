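# urmicro

Downstream analysis of 16S rRNA amplicon OTU tables for case/control
microbiome studies, built around the workflow used to characterise urine
microbiota in obstructive urinary retention (UR): healthy controls versus
retention caused by urinary stones (stone UR) or urinary-tract tumors
(tumor UR).

Starting from an OTU count table, a Greengenes-style taxonomy, a rooted
phylogeny and sample metadata, the package provides:

* **QC filtering** — drop samples with fewer than 8,000 assigned reads and
  OTUs carrying less than 0.01% of all reads (exact-threshold rows/columns
  are kept);
* **Diversity** — rarefaction curves by subsampling without replacement;
  alpha diversity (observed OTUs, Shannon −Σ pᵢ ln pᵢ, Gini–Simpson
  1 − Σ pᵢ², bias-corrected Chao1, ACE); beta diversity (Bray–Curtis,
  unweighted and normalized weighted UniFrac); shared/unique OTU (Venn)
  counts;
* **Ordination & inference** — principal coordinates analysis (Gower
  double-centering of −d²/2) and one-way PERMANOVA with the pseudo-F
  statistic and a seeded permutation p-value, p = (#{F* ≥ F} + 1)/(B + 1);
* **Differential abundance** — per-taxon Wilcoxon rank-sum tests with
  Benjamini–Hochberg FDR and tiered significance calls (q<0.01, q<0.05,
  p<0.05), plus a Kruskal–Wallis + LDA-effect-size biomarker screen
  (log₁₀ score, cutoff 4);
* **Correlation networks** — Spearman genus–genus networks (|ρ| > 0.45
  edges) and genus–clinical-covariate matrices;
* **Marker selection & POD** — the random-forest biomarker procedure:
  candidates are taxa significantly enriched in the case group; nested
  top-k subsets ranked by out-of-bag mean decrease accuracy (MDA) are
  scored by five-times-repeated five-fold cross-validation; the cut-off is
  the minimum mean CV error plus its SD, and the smallest subset under the
  cut-off is the optimal marker set. Its discriminatory power is the mean
  AUC of 100 independently seeded forests (out-of-bag votes), and each
  sample's probability of disease (POD) is the fraction of its out-of-bag
  trees voting the case class, averaged over the repeated forests;
* **Synthetic cohorts** — a Dirichlet-multinomial community simulator with
  planted group fold-changes, a random coalescent phylogeny, shallow
  samples to exercise the read filter, and clinical covariates with target
  Spearman correlations, so the whole pipeline is testable end to end.

`MarkerSelector` and `PodClassifier` are scikit-learn style estimators
(`fit`, fitted attributes with trailing underscores, `get_params`); the
remaining stages are plain functions over pandas DataFrames.

## Worked example

```python
from urmicro import simulate, qc, diversity, ordination, diffabund, markers

cfg = simulate.default_config(seed=42)          # 25 control / 34 stone / 25 tumor
table, tax, meta, tree = simulate.simulate_community(cfg)

table = qc.filter_samples_min_reads(table, 8000)
table = qc.filter_otus_min_fraction(table, 1e-4)

dm = diversity.unifrac(table, tree, weighted=False)
res = ordination.permanova(dm, meta, n_perm=999, seed=0)
print(f"PERMANOVA: pseudo-F = {res.pseudo_f:.2f}, p = {res.p_value:.3f}")

rel = qc.aggregate_by_rank(table, tax, rank="genus")
diff = diffabund.differential_taxa(rel, meta, "control", "stone_UR")
cand = markers.select_candidates(diff, "stone_UR")

X, y = markers.build_feature_matrix(rel, meta, "stone_UR", "control", cand)
sel = markers.cv_error_curve(X, y, seed=1, n_estimators=200)
clf = markers.evaluate_auc_100(sel.transform(X), y, case_class="stone_UR",
                               n_runs=100, seed=2, n_estimators=200)
print(f"optimal marker set ({sel.optimal_k_}): {sel.optimal_features_}")
print(f"mean AUC over 100 forests: {clf.mean_auc_:.4f}")
```

prints (exact numbers depend on the seed):

```
PERMANOVA: pseudo-F = 2.62, p = 0.031
optimal marker set (6): ['Genus08', 'Genus01', 'Genus06', 'Genus07', 'Genus10', 'Genus05']
mean AUC over 100 forests: 0.9998
```

The cohort carries ten genera planted at a 4-fold concentration increase in
both UR groups; the marker procedure recovers a subset of them, separates
cases from controls essentially perfectly, and the per-sample POD averages
0.90 in the stone-UR group against 0.13 in controls (Wilcoxon p ≈ 1e-10).

The same workflow is available from the shell:

```bash
urmicro simulate --out-dir fixtures --seed 42
urmicro qc --table fixtures/otu_table.tsv --min-reads 8000 \
           --min-otu-frac 0.0001 --out filtered.tsv
urmicro run --config run.json    # full pipeline with a seeded manifest
```

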