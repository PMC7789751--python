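"""Random-forest biomarker selection and the probability-of-disease index.

The procedure mirrors the established microbiome marker workflow:

1. candidate taxa are those significantly enriched in the case group of a
   pairwise differential-abundance comparison;
2. candidates are ranked by out-of-bag mean decrease accuracy (MDA) from a
   forest trained on all samples, and nested top-k subsets are evaluated by
   stratified five-fold cross-validation repeated five times;
3. the cut-off is the minimum mean CV error plus the between-trial SD at
   that point; among all subset sizes whose mean error does not exceed the
   cut-off, the smallest is the optimal marker set;
4. the optimal set's discriminatory ability is summarised by the mean AUC
   of 100 independently seeded forests (out-of-bag votes), and per-sample
   probability of disease (POD) is the fraction of out-of-bag trees voting
   the case class, averaged over the repeated forests.

`MarkerSelector` and `PodClassifier` are scikit-learn style estimators; the
module-level functions are thin wrappers over them.
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .diffabund import wilcoxon_rank_sum

DEFAULT_N_ESTIMATORS = 500


# ---------------------------------------------------------------------------
# out-of-bag machinery


def _tree_oob_mask(tree_random_state: int, n_samples: int) -> np.ndarray:
    """Boolean OOB mask of one forest tree.

    scikit-learn draws each tree's bootstrap as
    ``RandomState(tree.random_state).randint(0, n, n)``; samples never drawn
    are out of bag.
    """
    rs = np.random.RandomState(tree_random_state)
    sampled = rs.randint(0, n_samples, n_samples)
    mask = np.ones(n_samples, dtype=bool)
    mask[sampled] = False
    return mask


def oob_vote_matrix(forest: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Per-sample class-vote proportions using only each sample's OOB trees.

    Returns an ``(n_samples, n_classes)`` array; rows of samples that were
    in-bag for every tree are NaN. With fully grown trees each tree's
    predicted probability is a 0/1 vote, so the average is the vote
    fraction.
    """
    n = X.shape[0]
    votes = np.zeros((n, forest.n_classes_))
    counts = np.zeros(n)
    for tree in forest.estimators_:
        oob = _tree_oob_mask(tree.random_state, n)
        if not oob.any():
            continue
        votes[oob] += tree.predict_proba(X[oob])
        counts[oob] += 1
    with np.errstate(invalid="ignore"):
        out = votes / counts[:, None]
    out[counts == 0] = np.nan
    return out


def oob_mda(
    forest: RandomForestClassifier,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean decrease accuracy: per-feature OOB permutation importance.

    For every tree, the accuracy on its OOB samples is compared with the
    accuracy after permuting one feature's OOB values; the drops are
    averaged over trees (unscaled, in accuracy units).
    """
    n, p = X.shape
    # forest trees predict encoded class indices, not the original labels
    class_index = {c: i for i, c in enumerate(forest.classes_)}
    y_enc = np.array([class_index[v] for v in y], dtype=float)
    deltas = np.zeros(p)
    used = 0
    for tree in forest.estimators_:
        oob = _tree_oob_mask(tree.random_state, n)
        m = int(oob.sum())
        if m < 2:
            continue
        used += 1
        Xo, yo = X[oob], y_enc[oob]
        stacked = np.tile(Xo, (p + 1, 1))
        for f in range(p):
            block = slice((f + 1) * m, (f + 2) * m)
            stacked[block, f] = Xo[rng.permutation(m), f]
        preds = tree.predict(stacked)
        base_acc = float(np.mean(preds[:m] == yo))
        for f in range(p):
            block = slice((f + 1) * m, (f + 2) * m)
            deltas[f] += base_acc - float(np.mean(preds[block] == yo))
    if used == 0:
        raise RuntimeError("no tree had out-of-bag samples")
    return deltas / used


# ---------------------------------------------------------------------------
# candidate selection


def select_candidates(
    diff: pd.DataFrame,
    case_group: str,
    alpha_mode: str = "q<0.05",
) -> list[str]:
    """Taxa significantly enriched in the case group of a pairwise test.

    ``diff`` is the output of :func:`urmicro.diffabund.differential_taxa`.
    ``alpha_mode`` selects the significance rule: ``"q<0.05"`` (adjusted,
    the default for case-vs-control models) or ``"p<0.05"`` (raw, used for
    the case-vs-case model where few taxa survive FDR).
    """
    if alpha_mode not in ("q<0.05", "p<0.05"):
        raise ValueError("alpha_mode must be 'q<0.05' or 'p<0.05'")
    if case_group not in (diff.attrs.get("group_a"), diff.attrs.get("group_b")):
        raise ValueError(f"{case_group!r} is not one of the compared groups")
    if alpha_mode == "q<0.05":
        sig = diff["q"] < 0.05
    else:
        sig = diff["p"] < 0.05
    chosen = diff.index[sig & (diff["enriched"] == case_group)]
    if len(chosen) == 0:
        raise ValueError("no candidates: no taxon is significantly enriched in the case group")
    return sorted(chosen)


def build_feature_matrix(
    rel: pd.DataFrame,
    meta: pd.DataFrame,
    case_group: str,
    control_group: str,
    taxa: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Samples-by-taxa feature matrix and label vector for a two-group model."""
    taxa = list(rel.index) if taxa is None else list(taxa)
    labels = meta.loc[[s for s in rel.columns if s in meta.index], "group"]
    keep = labels[labels.isin([case_group, control_group])].index
    X = rel.loc[taxa, list(keep)].T
    y = labels.loc[keep]
    return X, y


# ---------------------------------------------------------------------------
# estimators


def _as_array(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [f"feature_{i}" for i in range(X.shape[1])]


def _seed_stream(random_state, n: int) -> list[int]:
    """Deterministic child seeds below 2**31 derived from ``random_state``."""
    if random_state is None or isinstance(random_state, numbers.Integral):
        ss = np.random.SeedSequence(random_state)
    else:  # Generator / SeedSequence passthrough
        ss = random_state
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


class MarkerSelector(BaseEstimator):
    """Importance-ranked nested marker-set selection by repeated CV.

    Parameters
    ----------
    n_trials, n_folds:
        Stratified ``n_folds``-fold cross-validation is repeated
        ``n_trials`` times with distinct fold seeds (default 5 x 5).
    n_estimators:
        Trees per forest (default 500).
    nested:
        If True the importance ranking is recomputed inside every training
        fold (avoids selection optimism); the default ranks once on all
        samples, matching the conventional workflow.
    random_state:
        Master seed; fixes the ranking forest, fold shuffles and CV forests.

    Attributes (after ``fit``)
    --------------------------
    mda_ : pd.Series
        OOB mean-decrease-accuracy importance of every candidate.
    ranking_ : list[str]
        Candidates ordered by decreasing importance (ties lexicographic).
    error_curve_ : pd.DataFrame
        Per subset size k: ``mean_error`` and ``sd_error`` over trials.
    cutoff_ : float
        Minimum mean error + SD at the argmin.
    eligible_sizes_ : list[int]
        Subset sizes whose mean error does not exceed the cut-off.
    optimal_k_ : int, optimal_features_ : list[str]
        The smallest eligible subset and its members.
    """

    def __init__(
        self,
        n_trials: int = 5,
        n_folds: int = 5,
        n_estimators: int = DEFAULT_N_ESTIMATORS,
        nested: bool = False,
        random_state: int | None = None,
    ):
        self.n_trials = n_trials
        self.n_folds = n_folds
        self.n_estimators = n_estimators
        self.nested = nested
        self.random_state = random_state

    def _rank(self, X: np.ndarray, y: np.ndarray, names: list[str], seed: int) -> tuple[pd.Series, list[str]]:
        forest = RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=seed, n_jobs=1
        ).fit(X, y)
        mda = oob_mda(forest, X, y, np.random.default_rng(seed))
        series = pd.Series(mda, index=names)
        order = sorted(names, key=lambda f: (-series[f], f))
        return series, order

    def fit(self, X, y) -> "MarkerSelector":
        Xa, names = _as_array(X)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {list(classes)}")
        if (counts < self.n_folds).any():
            raise ValueError(
                f"every class needs >= n_folds={self.n_folds} samples, got {dict(zip(classes, counts))}"
            )
        n_feat = Xa.shape[1]
        seeds = _seed_stream(self.random_state, 1 + self.n_trials)
        self.mda_, self.ranking_ = self._rank(Xa, y, names, seeds[0])
        name_pos = {f: i for i, f in enumerate(names)}

        trial_errors = np.zeros((self.n_trials, n_feat))
        for t in range(self.n_trials):
            t_seed = seeds[1 + t]
            skf = StratifiedKFold(n_splits=self.n_folds, shuffle=True, random_state=t_seed)
            fold_errors = np.zeros((self.n_folds, n_feat))
            fold_seeds = _seed_stream(t_seed, self.n_folds)
            for f_idx, (train, test) in enumerate(skf.split(Xa, y)):
                if self.nested:
                    _, order = self._rank(Xa[train], y[train], names, fold_seeds[f_idx])
                else:
                    order = self.ranking_
                cols = [name_pos[f] for f in order]
                for k in range(1, n_feat + 1):
                    sub = cols[:k]
                    clf = RandomForestClassifier(
                        n_estimators=self.n_estimators,
                        random_state=fold_seeds[f_idx] + k,
                        n_jobs=1,
                    ).fit(Xa[np.ix_(train, sub)], y[train])
                    pred = clf.predict(Xa[np.ix_(test, sub)])
                    fold_errors[f_idx, k - 1] = np.mean(pred != y[test])
            trial_errors[t] = fold_errors.mean(axis=0)

        mean_err = trial_errors.mean(axis=0)
        sd_err = trial_errors.std(axis=0, ddof=1) if self.n_trials > 1 else np.zeros(n_feat)
        self.error_curve_ = pd.DataFrame(
            {"k": np.arange(1, n_feat + 1), "mean_error": mean_err, "sd_error": sd_err}
        ).set_index("k")
        argmin = int(np.argmin(mean_err))  # ties -> smallest k
        self.cutoff_ = float(mean_err[argmin] + sd_err[argmin])
        eligible = np.flatnonzero(mean_err <= self.cutoff_) + 1
        self.eligible_sizes_ = [int(k) for k in eligible]
        self.optimal_k_ = int(eligible.min())
        self.optimal_features_ = self.ranking_[: self.optimal_k_]
        self.classes_ = classes
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = n_feat
        return self

    def transform(self, X) -> pd.DataFrame:
        """Restrict a feature matrix to the optimal marker set."""
        check_is_fitted(self, "optimal_features_")
        if isinstance(X, pd.DataFrame):
            return X[self.optimal_features_]
        idx = [list(self.feature_names_in_).index(f) for f in self.optimal_features_]
        return np.asarray(X)[:, idx]


class PodClassifier(BaseEstimator, ClassifierMixin):
    """Repeated-forest classifier with out-of-bag POD index and averaged AUC.

    ``n_runs`` forests are trained with distinct seeds. For every run, each
    training sample receives the fraction of its out-of-bag trees voting
    the case class; the per-sample POD is that fraction averaged over runs.
    The run AUC is computed from the OOB vote fractions against the true
    labels, and MDA importance is averaged over runs.

    Attributes (after ``fit``)
    --------------------------
    pod_ : pd.Series            per-sample POD in [0, 1]
    pod_p_value_ : float        Wilcoxon rank-sum p, case vs control POD
    auc_runs_ : np.ndarray      one AUC per run
    mean_auc_ : float           arithmetic mean of ``auc_runs_``
    mda_ : pd.Series            per-feature MDA averaged over runs
    """

    def __init__(
        self,
        case_class=None,
        n_runs: int = 100,
        n_estimators: int = DEFAULT_N_ESTIMATORS,
        compute_mda: bool = True,
        random_state: int | None = None,
    ):
        self.case_class = case_class
        self.n_runs = n_runs
        self.n_estimators = n_estimators
        self.compute_mda = compute_mda
        self.random_state = random_state

    def fit(self, X, y) -> "PodClassifier":
        Xa, names = _as_array(X)
        if Xa.shape[1] == 0:
            raise ValueError("empty marker set")
        index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(Xa))
        y = pd.Series(np.asarray(y), index=index)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {list(classes)}")
        case = self.case_class if self.case_class is not None else classes[1]
        if case not in classes:
            raise ValueError(f"case_class {case!r} not among labels {list(classes)}")
        y_arr = y.to_numpy()
        case_col = int(np.flatnonzero(classes == case)[0])

        seeds = _seed_stream(self.random_state, self.n_runs)
        n = len(y_arr)
        vote_sum = np.zeros(n)
        vote_cnt = np.zeros(n)
        aucs = np.empty(self.n_runs)
        mda_sum = np.zeros(Xa.shape[1])
        self.forests_ = []
        y_bin = (y_arr == case).astype(int)
        for r, seed in enumerate(seeds):
            forest = RandomForestClassifier(
                n_estimators=self.n_estimators, random_state=seed, n_jobs=1
            ).fit(Xa, y_arr)
            votes = oob_vote_matrix(forest, Xa)[:, case_col]
            ok = ~np.isnan(votes)
            vote_sum[ok] += votes[ok]
            vote_cnt[ok] += 1
            aucs[r] = roc_auc_score(y_bin[ok], votes[ok])
            if self.compute_mda:
                mda_sum += oob_mda(forest, Xa, y_arr, np.random.default_rng(seed))
            self.forests_.append(forest)
        if (vote_cnt == 0).any():
            raise RuntimeError(
                "some samples were never out-of-bag across all runs; increase n_runs or n_estimators"
            )
        self.classes_ = classes
        self.case_class_ = case
        self.pod_ = pd.Series(vote_sum / vote_cnt, index=index, name="pod")
        self.auc_runs_ = aucs
        self.mean_auc_ = float(aucs.mean())
        self.mda_ = pd.Series(mda_sum / self.n_runs if self.compute_mda else np.nan, index=names)
        pod_case = self.pod_[y == case].to_numpy()
        pod_ctrl = self.pod_[y != case].to_numpy()
        self.pod_p_value_ = wilcoxon_rank_sum(pod_case, pod_ctrl)[1]
        self.labels_ = y
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = Xa.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "forests_")
        Xa, _ = _as_array(X)
        return np.mean([f.predict_proba(Xa) for f in self.forests_], axis=0)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def pod(self, X) -> np.ndarray:
        """Case-class vote fraction for new samples (all trees vote)."""
        proba = self.predict_proba(X)
        case_col = int(np.flatnonzero(self.classes_ == self.case_class_)[0])
        return proba[:, case_col]


# ---------------------------------------------------------------------------
# functional wrappers


def cv_error_curve(
    features,
    labels,
    n_trials: int = 5,
    n_folds: int = 5,
    seed: int | None = None,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
    nested: bool = False,
) -> MarkerSelector:
    """Fit and return a :class:`MarkerSelector` (see class docs)."""
    return MarkerSelector(
        n_trials=n_trials,
        n_folds=n_folds,
        n_estimators=n_estimators,
        nested=nested,
        random_state=seed,
    ).fit(features, labels)


def evaluate_auc_100(
    features,
    labels,
    case_class=None,
    n_runs: int = 100,
    seed: int | None = None,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
) -> PodClassifier:
    """Average OOB AUC and MDA over ``n_runs`` independently seeded forests."""
    return PodClassifier(
        case_class=case_class, n_runs=n_runs, n_estimators=n_estimators, random_state=seed
    ).fit(features, labels)


def pod_index(
    features,
    labels,
    case_class=None,
    n_runs: int = 100,
    seed: int | None = None,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
) -> PodClassifier:
    """Per-sample probability of disease from repeated out-of-bag votes.

    Identical machinery to :func:`evaluate_auc_100`; the fitted classifier
    exposes ``pod_`` and the case-vs-control Wilcoxon ``pod_p_value_``.
    """
    return PodClassifier(
        case_class=case_class,
        n_runs=n_runs,
        n_estimators=n_estimators,
        compute_mda=False,
        random_state=seed,
    ).fit(features, labels)


def probability_of_tumor(
    features,
    labels,
    tumor_class: str = "tumor_UR",
    n_runs: int = 100,
    seed: int | None = None,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
) -> PodClassifier:
    """Probability-of-tumor index: the POD machinery with the tumor group as
    the case class, comparing the two obstructive-retention groups."""
    return pod_index(
        features, labels, case_class=tumor_class, n_runs=n_runs, seed=seed, n_estimators=n_estimators
    )
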