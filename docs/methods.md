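# Methods

## Scope and data model

The package analyses a closed-reference OTU count table (OTUs × samples,
non-negative integers), a ranked Greengenes-style taxonomy, a rooted
phylogeny over the OTUs and a sample table with one categorical `group`
column plus numeric clinical covariates. Nothing upstream of the OTU table
(read merging, OTU picking, chimera removal) is in scope, and no functional
prediction from 16S profiles is attempted.

## Quality control

Two filters run in a fixed order: samples first, then OTUs.

* **Sample depth** (`min_reads`, default 8000): a sample is removed when
  its total assigned reads are *strictly below* the threshold; a sample at
  exactly 8000 reads is kept. The removal rule is a "less than" rule, and
  both filters follow it, so exact-threshold rows/columns always survive.
* **OTU abundance** (`min_otu_frac`, default 1e-4 = 0.01%): an OTU is
  removed when its total count is strictly below `min_otu_frac` × grand
  total of the table, with the grand total computed *after* sample
  exclusion. Whether the OTU filter should see the pre- or post-exclusion
  total is genuinely open; samples-first matches the order in which the
  filters are usually described and is the documented choice.

Both filters are idempotent, and each reports the identifiers it removed.

Aggregation to a rank sums counts over OTUs sharing that rank label. Empty
labels pool into `unclassified_<rank>` rather than being dropped, so
per-sample proportions still sum to one. For composition overviews the top
N taxa by mean relative abundance (default 35) are kept and the remainder
pooled into `Others`; ties at rank N break lexicographically, as do all
other ties in the package, for determinism.

## Diversity

* **Rarefaction** subsamples reads without replacement (a multivariate
  hypergeometric draw), so the value at fraction 1.0 equals the observed
  richness with zero variance. Curves are computed per sample at fractions
  of each sample's own depth and averaged within groups afterwards; whether
  to pool reads per group instead is ambiguous in the source workflow, and
  per-sample-then-average is the exposed behaviour.
* **Alpha diversity** reports observed OTUs, Shannon entropy (natural log
  by default, any base by argument), the Gini–Simpson index 1 − Σ pᵢ²,
  Chao1 and ACE. Shannon in nats is a choice, not a given; the Gini–Simpson
  form is used because it increases with diversity, matching how the index
  ordering is interpreted downstream. Chao1 ships bias-corrected,
  S_obs + F₁(F₁−1)/(2(F₂+1)), which is defined even when doubletons are
  absent; the classic form is available by flag. ACE uses the standard
  rare/abundant threshold of 10 and truncates the coefficient of variation
  γ² at zero; when every rare taxon in a sample is a singleton the sample
  coverage estimate is zero and ACE is undefined — such samples report NaN
  and are dropped from downstream group comparisons of that index.
  Computation is delegated to scikit-bio; tests pin each index
  to closed forms and an independently transcribed ACE definition. Alpha
  diversity is computed on the filtered, unrarefied table; rarefaction is a
  separate, explicit operation.
* **Beta diversity**: Bray–Curtis on relative abundances; unweighted
  UniFrac (fraction of branch length unique to either sample) and weighted
  UniFrac in its *normalized* form, Σ bᵢ|pᵢ−qᵢ| / Σ bᵢ(pᵢ+qᵢ), so both
  variants live on [0, 1] and are directly comparable (the raw weighted
  form is a flag away). Trees must be rooted; a trifurcating root is
  rejected. Tests compare both variants against a brute-force per-branch
  enumeration oracle on hundreds of random small trees.

## Ordination and PERMANOVA

PCoA applies Gower double-centering to −d²/2 and an `eigh`
eigendecomposition; coordinates are eigenvectors scaled by √λ over the
positive eigenvalues only, negative eigenvalues are reported but never
embedded, and variance proportions are taken over the positive spectrum.

PERMANOVA partitions ΣΣ_{i<j} d²ᵢⱼ/n into within- and between-group sums of
squares and forms pseudo-F = (SS_B/(g−1))/(SS_W/(n−g)). Significance comes
from simple label shuffles (no strata) with the (+1)/(+1) convention, so
the p-value is floored at 1/(B+1) — 0.001 at the default 999 permutations —
and can never be zero. The permutation loop is vectorised (an einsum over a
stack of permuted group masks), which makes the 500-simulation calibration
test cheap; the implementation is cross-checked against vegan-style
reference output via scikit-bio in the test suite. Pairwise group
comparisons are independent two-group calls with BH adjustment across the
three pairwise p-values.

## Differential abundance

Per-taxon two-group tests use the Wilcoxon rank-sum statistic: exact
enumeration when the pooled sample size is ≤ 12 and tie-free, otherwise the
normal approximation with tie and continuity corrections (average ranks for
ties). BH adjustment is applied within each pairwise comparison family —
the tier stars are per-comparison — with a joint family over all pairwise
comparisons available through ``joint_bh_adjust``. Taxa absent from both
groups have no defined test and are flagged rather than entering the BH
family. Tiers are mutually exclusive: q<0.01, then q<0.05, then p<0.05,
else ns.

The effect-size screen keeps taxa with Kruskal–Wallis p < `kw_alpha`
(default 0.05) across all groups, then scores each survivor on abundances
scaled to parts-per-million. Because the discriminant is fitted one taxon
at a time, the one-dimensional linear-discriminant effect reduces to the
largest absolute difference in group means of the scaled feature; it is
averaged over 30 bootstrap draws of two-thirds of each group, and the
reported score is log₁₀(1 + effect) against a cutoff of 4. This is a
deliberate simplification of the full LEfSe algorithm: with no subclass
structure the one-against-all subclass stage is vacuous and is skipped, and
exact parity with the Galaxy web service is out of scope.

## Correlation networks

Spearman correlations use average ranks and the t-approximation for p.
Networks over selected taxa draw an edge when |ρ| strictly exceeds the
threshold (default 0.45), storing the sign for rendering. Taxon–covariate
matrices pairwise-drop missing covariate values; a covariate with fewer
than three usable values is reported as a per-covariate error while the
rest compute. Correlations pool all samples across groups by default; the
network accepts a sample subset and the covariate matrix a ``group``
restriction for within-group analyses. Significance flags use raw p at
α = 0.05 to match the
asterisk convention of exploratory heatmaps, with BH flags by option.

## Marker selection and POD

Candidates for a case-vs-control model are the taxa significantly enriched
in the case group — q < 0.05 for the two case/control models, raw p < 0.05
for the case-vs-case model, where few taxa survive FDR.

`MarkerSelector.fit` ranks candidates by out-of-bag mean decrease accuracy
(MDA) from a forest on all samples. MDA is computed natively: each tree's
bootstrap indices are reconstructed from its seeded RNG draw (the
documented `RandomState(seed).randint(0, n, n)` scheme, verified in tests
against scikit-learn's own `oob_decision_function_`), and per-feature OOB
accuracy drops under within-feature permutation are averaged over trees,
unscaled. Nested top-k subsets of the ranking are then scored by stratified
five-fold cross-validation repeated five times with distinct fold seeds;
the error curve is the trial mean per k with the between-trial SD. The
cut-off is min(mean error) + SD at the argmin, every k whose mean error is
≤ the cut-off is eligible, and the smallest eligible k is the optimal set.
Enumerating all subsets of candidates is exponential; importance-ordered
nesting is the established convention for this procedure and is the only
family considered. The ranking is computed once on all samples by default —
the conventional, slightly optimistic choice — with a `nested=True` option
that re-ranks inside every training fold.

`PodClassifier.fit` trains `n_runs` (default 100) forests with distinct
seeds. Per run, each sample's out-of-bag trees vote; the run AUC is the ROC
area of those OOB case-vote fractions against the truth, and the reported
AUC is the arithmetic mean over runs. POD is the per-sample OOB case-vote
fraction averaged over runs — bounded in [0, 1] by construction, with no
tree ever voting on its own training sample — and the case/control POD
difference is tested by Wilcoxon rank-sum. A "ratio of case-voting to
control-voting trees" reading of POD is unbounded and cannot produce
box-plots on [0, 1]; the vote-fraction form is therefore the only mode.
Out-of-bag evaluation is used instead of a held-out split to avoid
consuming small cohorts; with 500-tree forests the probability that a
sample is never out of bag is negligible, and the degenerate case raises.
The probability-of-tumor index is the same machinery with the tumor group
as the case class; fitting the complementary case class with the same seed
yields POD values summing to one per sample.

Forest hyperparameters: 500 trees by default, √m feature subsampling,
fully grown trees (so per-tree probabilities are 0/1 votes), stratified
folds. The whole procedure is bit-reproducible under a fixed master seed;
child seeds are spawned from a `SeedSequence` and kept below 2³¹.

## Synthetic cohorts

The simulator emulates the statistical structure the analysis assumes
without modelling sequences. Per sample: depth ~ round(N(36072, 3376²))
truncated at 1 (the depth profile of a typical MiSeq 16S run);
composition ~ Dirichlet(α_g) where α_g is a base concentration vector
(lognormal, normalised to total concentration 50 — strong overdispersion
typical of 16S data) with group-specific multiplicative fold-changes
applied to planted OTUs; counts ~ Multinomial(depth, composition).
Planting effects on *concentrations* rather than final proportions keeps
the compositional renormalisation confound: raising one taxon necessarily
depresses the observed proportions of all others. The default cohort has
25/34/25 control/stone/tumor samples with two stone samples forced below
the 8000-read threshold (so 82 survive QC), 310 OTUs in 45 genera across 8
phyla, ten genera 4-fold enriched in both UR groups, five genera at
0.25-fold (control-enriched), and one tumor-only genus at 3-fold for the
case-vs-case model. The phylogeny is a random coalescent-style rooted
bifurcating tree with exponential waiting times. Clinical covariates are
normal-score transforms of a planted OTU's relative abundance mixed with
Gaussian noise to hit a target Spearman correlation (eGFR −0.5, uric acid
+0.5, white cells +0.4, red cells +0.3), then mapped onto clinical template
scales; the remaining covariates are pure noise.

What the simulator does **not** reproduce: real taxon co-occurrence beyond
the planted structure, sequencing error, contamination, batch effects, or
zero-inflation beyond what the Dirichlet-multinomial induces. Passing tests
therefore demonstrate that the procedures recover known planted structure
under realistic overdispersion and compositionality — not that any
particular biological claim about real cohorts is reproduced.

## Problem sizes and numerical choices

The test suite and acceptance script run the cohort-scale model fits with
200-tree forests (the library default stays 500) and exercise end-to-end
determinism on a reduced cohort (60 OTUs, 10/12/10 samples, 8 forest
runs); determinism is size-independent, and AUC is insensitive to forest
size at these sample sizes. Distance matrices are validated to symmetry
1e-12 with an exactly zero diagonal; PCoA treats eigenvalues below
max(λ)·1e-12 as zero; all tie-breaks are lexicographic; every stochastic
step takes an explicit seed and the pipeline manifest records every derived
seed, threshold and output checksum.

## Known limitations

* LEfSe scoring is the documented one-dimensional simplification; scores
  are comparable in spirit, not numerically identical to the Galaxy
  service.
* The fixed-once importance ranking inside `MarkerSelector` carries the
  usual selection optimism into the error curve; `nested=True` quantifies
  it at extra cost.
* PERMANOVA supports one-way designs with simple shuffles only (no strata
  or covariates).
* The simulator's genus blocks are contiguous and deterministic, which
  makes planted sets easy to reason about but is not a model of real
  taxonomic structure.
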