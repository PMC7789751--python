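import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

from urmicro.markers import (
    MarkerSelector,
    PodClassifier,
    build_feature_matrix,
    cv_error_curve,
    evaluate_auc_100,
    oob_mda,
    oob_vote_matrix,
    pod_index,
    probability_of_tumor,
    select_candidates,
)


def _diff_frame():
    df = pd.DataFrame(
        {
            "p": [0.001, 0.2, 0.001, 0.03, 0.004],
            "q": [0.01, 0.5, 0.01, 0.09, 0.02],
            "enriched": ["case", "case", "control", "case", "case"],
        },
        index=["gA", "gB", "gC", "gD", "gE"],
    )
    df.attrs["group_a"] = "control"
    df.attrs["group_b"] = "case"
    return df


def _separable(rng, n_per_class=15, n_noise=9):
    """One perfectly separating feature among uninformative ones."""
    n = 2 * n_per_class
    X = pd.DataFrame(
        rng.random((n, n_noise + 1)),
        columns=["signal"] + [f"noise{i:02d}" for i in range(n_noise)],
    )
    y = np.array(["ctrl"] * n_per_class + ["case"] * n_per_class)
    X.loc[y == "case", "signal"] += 2.0
    return X, y


class TestSelectCandidates:
    def test_direction_and_significance_filters(self):
        assert select_candidates(_diff_frame(), "case") == ["gA", "gE"]
        assert select_candidates(_diff_frame(), "case", alpha_mode="p<0.05") == [
            "gA",
            "gD",
            "gE",
        ]

    def test_control_enriched_taxa_excluded(self):
        assert "gC" not in select_candidates(_diff_frame(), "case")

    def test_no_candidates_raises(self):
        df = _diff_frame()
        df["q"] = 0.9
        df["p"] = 0.9
        with pytest.raises(ValueError, match="no candidates"):
            select_candidates(df, "case")

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            select_candidates(_diff_frame(), "tumor")

    def test_planted_fixture_recovers_case_genera(self, small_rel_genus):
        from urmicro.diffabund import differential_taxa

        rel, meta = small_rel_genus
        diff = differential_taxa(rel, meta, "control", "stone_UR")
        cand = select_candidates(diff, "stone_UR")
        planted = {f"Genus{j:02d}" for j in range(1, 11)}
        assert planted & set(cand)


class TestOobMachinery:
    def test_vote_matrix_matches_sklearn(self, rng):
        X = rng.random((40, 5))
        y = rng.integers(0, 2, 40)
        rf = RandomForestClassifier(n_estimators=120, oob_score=True, random_state=3).fit(X, y)
        mine = oob_vote_matrix(rf, X)
        assert np.allclose(mine, rf.oob_decision_function_, equal_nan=True)

    def test_separator_mda_beats_noise(self, rng):
        X, y = _separable(rng)
        rf = RandomForestClassifier(n_estimators=150, random_state=0).fit(X, y)
        mda = pd.Series(oob_mda(rf, X.to_numpy(), y, np.random.default_rng(0)), index=X.columns)
        assert mda["signal"] > mda.drop("signal").max()


class TestMarkerSelector:
    def test_planted_separator_found_with_zero_error(self, rng):
        X, y = _separable(rng)
        sel = cv_error_curve(X, y, n_trials=3, n_folds=3, seed=1, n_estimators=60)
        assert sel.optimal_k_ == 1
        assert sel.optimal_features_ == ["signal"]
        assert sel.error_curve_.loc[1, "mean_error"] == 0.0

    def test_deterministic_under_fixed_seed(self, rng):
        X, y = _separable(rng, n_per_class=10, n_noise=4)
        a = cv_error_curve(X, y, n_trials=2, n_folds=3, seed=7, n_estimators=40)
        b = cv_error_curve(X, y, n_trials=2, n_folds=3, seed=7, n_estimators=40)
        pd.testing.assert_frame_equal(a.error_curve_, b.error_curve_)
        assert a.optimal_features_ == b.optimal_features_

    def test_cutoff_rule_consequences(self, rng):
        X, y = _separable(rng, n_per_class=12, n_noise=6)
        sel = cv_error_curve(X, y, n_trials=3, n_folds=3, seed=2, n_estimators=40)
        curve = sel.error_curve_
        assert curve.loc[sel.optimal_k_, "mean_error"] <= sel.cutoff_
        assert sel.optimal_k_ == min(sel.eligible_sizes_)
        full_k = curve.index.max()
        assert curve.loc[sel.optimal_k_, "mean_error"] <= (
            curve.loc[full_k, "mean_error"] + curve.loc[full_k, "sd_error"] + sel.cutoff_
        )

    def test_small_class_rejected(self, rng):
        X = pd.DataFrame(rng.random((6, 3)))
        y = ["a"] * 4 + ["b"] * 2
        with pytest.raises(ValueError, match="n_folds"):
            MarkerSelector(n_folds=5).fit(X, y)

    def test_transform_restricts_to_optimal_set(self, rng):
        X, y = _separable(rng, n_per_class=10, n_noise=4)
        sel = cv_error_curve(X, y, n_trials=2, n_folds=3, seed=3, n_estimators=40)
        assert list(sel.transform(X).columns) == sel.optimal_features_

    def test_sklearn_params_round_trip(self):
        sel = MarkerSelector(n_trials=2, n_folds=3, random_state=1)
        assert MarkerSelector(**sel.get_params()).get_params() == sel.get_params()


class TestPodClassifier:
    def test_perfect_separator_gives_auc_one(self, rng):
        X, y = _separable(rng)
        clf = evaluate_auc_100(X[["signal"]], y, case_class="case", n_runs=10, seed=0,
                               n_estimators=80)
        assert clf.mean_auc_ == pytest.approx(1.0)
        assert (clf.auc_runs_ == 1.0).all()

    def test_pod_bounds_and_separation(self, rng):
        X, y = _separable(rng)
        clf = pod_index(X[["signal"]], y, case_class="case", n_runs=10, seed=1,
                        n_estimators=80)
        assert ((clf.pod_ >= 0) & (clf.pod_ <= 1)).all()
        assert clf.pod_[y == "case"].mean() > clf.pod_[y == "ctrl"].mean()
        assert clf.pod_p_value_ < 0.01

    def test_bitwise_reproducible(self, rng):
        X, y = _separable(rng, n_per_class=10, n_noise=3)
        a = pod_index(X, y, case_class="case", n_runs=5, seed=9, n_estimators=50)
        b = pod_index(X, y, case_class="case", n_runs=5, seed=9, n_estimators=50)
        assert (a.pod_ == b.pod_).all()
        assert (a.auc_runs_ == b.auc_runs_).all()

    def test_shuffled_labels_near_chance(self, rng):
        X, y = _separable(rng, n_per_class=20, n_noise=4)
        y_shuffled = rng.permutation(y)
        clf = pod_index(X, y_shuffled, case_class="case", n_runs=20, seed=2,
                        n_estimators=80)
        assert 0.3 < clf.mean_auc_ < 0.7  # chance band at this small n

    def test_complement_rule_between_case_choices(self, rng):
        X, y = _separable(rng, n_per_class=10, n_noise=3)
        a = pod_index(X, y, case_class="case", n_runs=5, seed=4, n_estimators=50)
        b = pod_index(X, y, case_class="ctrl", n_runs=5, seed=4, n_estimators=50)
        assert np.allclose(a.pod_ + b.pod_, 1.0)

    def test_probability_of_tumor_direction(self, rng):
        n = 12
        X = pd.DataFrame({"marker": rng.random(2 * n)})
        y = np.array(["stone_UR"] * n + ["tumor_UR"] * n)
        X.loc[y == "tumor_UR", "marker"] += 1.5
        clf = probability_of_tumor(X, y, n_runs=8, seed=0, n_estimators=60)
        assert clf.pod_[y == "tumor_UR"].mean() > clf.pod_[y == "stone_UR"].mean()

    def test_empty_marker_set_rejected(self, rng):
        X = pd.DataFrame(index=range(10))
        with pytest.raises(ValueError):
            PodClassifier().fit(X, ["a"] * 5 + ["b"] * 5)

    def test_auc_stable_when_doubling_runs(self, rng):
        X, y = _separable(rng, n_per_class=12, n_noise=4)
        X["signal"] -= 1.2 * (y == "case")  # weaken the separator
        a = pod_index(X, y, case_class="case", n_runs=10, seed=5, n_estimators=60)
        b = pod_index(X, y, case_class="case", n_runs=20, seed=5, n_estimators=60)
        assert abs(a.mean_auc_ - b.mean_auc_) < 0.05


class TestBuildFeatureMatrix:
    def test_orientation_and_label_subset(self, small_rel_genus):
        rel, meta = small_rel_genus
        X, y = build_feature_matrix(rel, meta, "stone_UR", "control", ["Genus01", "Genus02"])
        assert list(X.columns) == ["Genus01", "Genus02"]
        assert set(y.unique()) == {"stone_UR", "control"}
        assert len(X) == len(y) == (meta["group"] != "tumor_UR").sum()
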