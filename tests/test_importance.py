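"""Forest importance (weighted Gini decrease), RFI, stage collapsing,
screening and profile clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster
from sklearn.ensemble import RandomForestClassifier

from funcfly.errors import DegenerateModelError, ParameterError
from funcfly.importance import (
    ImportanceProfile,
    cluster_profiles,
    collapse_timepoints,
    default_stage_map,
    expression_profile,
    forest_importance,
    high_relevance_terms,
    relative_importance,
    stage_summary,
)


# ---------------------------------------------------------------------------
# tree-walk oracle (independent of the implementation's vectorised pass)
# ---------------------------------------------------------------------------

def _oracle_tree_importance(tree, n_features):
    """Recursive per-node weighted impurity decrease."""
    t = tree.tree_
    out = np.zeros(n_features)

    def walk(node):
        left, right = t.children_left[node], t.children_right[node]
        if left < 0:
            return
        dec = (
            t.weighted_n_node_samples[node] * t.impurity[node]
            - t.weighted_n_node_samples[left] * t.impurity[left]
            - t.weighted_n_node_samples[right] * t.impurity[right]
        ) / t.weighted_n_node_samples[0]
        out[t.feature[node]] += dec
        walk(left)
        walk(right)

    walk(0)
    return out


class TestForestImportance:
    def test_single_depth_one_tree_perfect_split_gives_half(self):
        # 50/50 classes, root Gini 0.5, pure children: decrease = 0.5
        X = np.array([[0.0, 5.0], [0.0, 6.0], [1.0, 5.0], [1.0, 6.0]])
        y = np.array([0, 0, 1, 1])
        forest = RandomForestClassifier(
            n_estimators=1, max_depth=1, bootstrap=False, max_features=None,
            random_state=0,
        ).fit(X, y)
        fi = forest_importance(forest, feature_names=["split", "noise"])
        assert fi.fi["split"] == pytest.approx(0.5)
        assert fi.fi["noise"] == 0.0

    def test_unused_feature_has_zero_importance(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.normal(size=60), np.zeros(60)])
        y = (X[:, 0] > 0).astype(int)
        forest = RandomForestClassifier(n_estimators=10, random_state=0).fit(X, y)
        fi = forest_importance(forest, feature_names=["signal", "constant"])
        assert fi.fi["constant"] == 0.0

    def test_fi_is_mean_of_per_tree_contributions(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 5))
        y = (X[:, 2] + 0.5 * rng.normal(size=80) > 0).astype(int)
        forest = RandomForestClassifier(n_estimators=7, random_state=1).fit(X, y)
        fi = forest_importance(forest)
        np.testing.assert_allclose(fi.fi.to_numpy(),
                                   fi.per_tree.to_numpy().mean(axis=0))
        assert fi.n_trees == 7

    def test_matches_recursive_tree_walk_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 4))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        forest = RandomForestClassifier(
            n_estimators=5, max_depth=2, random_state=2
        ).fit(X, y)
        fi = forest_importance(forest)
        expected = np.mean(
            [_oracle_tree_importance(t, 4) for t in forest.estimators_], axis=0
        )
        np.testing.assert_allclose(fi.fi.to_numpy(), expected, atol=1e-12)

    def test_total_importance_conserves_weighted_impurity_decrease(self):
        # summed FI equals mean over trees of (root impurity - leaf impurity mix)
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 3))
        y = rng.integers(0, 2, size=50)
        y[:5], y[5:10] = 1, 0
        forest = RandomForestClassifier(
            n_estimators=4, max_depth=2, random_state=3
        ).fit(X, y)
        totals = []
        for est in forest.estimators_:
            t = est.tree_
            leaves = t.children_left < 0
            leaf_mix = (
                t.weighted_n_node_samples[leaves] * t.impurity[leaves]
            ).sum() / t.weighted_n_node_samples[0]
            totals.append(t.impurity[0] - leaf_mix)
        fi = forest_importance(forest)
        assert fi.fi.sum() == pytest.approx(np.mean(totals), abs=1e-12)

    def test_non_forest_model_rejected(self):
        with pytest.raises(TypeError):
            forest_importance(object())


class TestRelativeImportance:
    def test_expression_feature_at_global_max_has_rfi_one(self):
        fi = pd.Series({"seq_a": 0.3, "ave_t05": 0.8, "num_t05": 0.1})
        rfi = relative_importance(fi, ["ave_t05", "num_t05"])
        assert rfi["ave_t05"] == pytest.approx(1.0)

    def test_zero_fi_gives_zero_rfi(self):
        fi = pd.Series({"seq_a": 0.5, "ave_t01": 0.0, "ave_t02": 0.2})
        assert relative_importance(fi, ["ave_t01", "ave_t02"])["ave_t01"] == 0.0

    def test_worked_value_sqrt_0625(self):
        # global max 0.8 on a sequence feature, local max 0.5 -> RFI(0.5)
        fi = pd.Series({"seq_a": 0.8, "ave_t01": 0.5, "ave_t02": 0.1})
        rfi = relative_importance(fi, ["ave_t01", "ave_t02"])
        assert rfi["ave_t01"] == pytest.approx(np.sqrt(0.625))
        assert rfi["ave_t01"] == pytest.approx(0.7906, abs=5e-5)

    def test_linear_identity_and_bound_on_random_vectors(self):
        rng = np.random.default_rng(4)
        for _ in range(1000):
            n = rng.integers(3, 12)
            fi = pd.Series(rng.uniform(0, 1, size=n),
                           index=[f"f{i}" for i in range(n)])
            k = rng.integers(1, n)
            expr = [f"f{i}" for i in rng.choice(n, size=k, replace=False)]
            gmax, lmax = fi.max(), fi[expr].max()
            if lmax == 0:
                continue
            rfi = relative_importance(fi, expr)
            np.testing.assert_allclose(
                rfi.to_numpy(), (fi[expr] / np.sqrt(gmax * lmax)).to_numpy(),
                atol=1e-12,
            )
            assert (rfi <= np.sqrt(lmax / gmax) + 1e-12).all()
            assert (rfi <= 1.0 + 1e-12).all()

    def test_all_zero_importances_rejected(self):
        fi = pd.Series({"a": 0.0, "b": 0.0})
        with pytest.raises(DegenerateModelError):
            relative_importance(fi, ["b"])

    def test_zero_local_max_gives_all_zero_rfi(self):
        fi = pd.Series({"seq_a": 0.4, "ave_t01": 0.0})
        assert (relative_importance(fi, ["ave_t01"]) == 0.0).all()


class TestCollapseAndStages:
    def test_worked_triple_collapses_to_max(self):
        vecs = {
            "Num": np.full(30, 0.01), "Ave": np.full(30, 0.02),
            "Main": np.full(30, 0.03),
        }
        vecs["Num"][0], vecs["Ave"][0], vecs["Main"][0] = 0.2, 0.5, 0.4
        assert collapse_timepoints(vecs)[0] == pytest.approx(0.5)

    def test_single_group_is_identity(self):
        v = np.linspace(0, 1, 30)
        np.testing.assert_allclose(collapse_timepoints({"Ave": v}), v)

    def test_all_zero_groups_collapse_to_zero(self):
        out = collapse_timepoints({"Num": np.zeros(30), "Ave": np.zeros(30)})
        assert (out == 0.0).all()

    def test_empty_mapping_rejected(self):
        with pytest.raises(ParameterError):
            collapse_timepoints({})

    def test_rfi_commutes_with_collapsing(self):
        """Because RFI is linear in FI, collapsing per-time-point maxima
        before or after the RFI transform gives the same profile."""
        rng = np.random.default_rng(5)
        fi = {g: rng.uniform(0, 0.5, size=30) for g in ("Num", "Ave", "Main")}
        names = {g: [f"{g.lower()}_t{i:02d}" for i in range(1, 31)]
                 for g in fi}
        series = pd.Series(
            {**{names[g][i]: fi[g][i] for g in fi for i in range(30)},
             "seq_x": 0.9}
        )
        expr = [n for g in fi for n in names[g]]
        rfi = relative_importance(series, expr)
        collapsed_after = collapse_timepoints(
            {g: rfi[names[g]].to_numpy() for g in fi}
        )
        gmax, lmax = series.max(), series[expr].max()
        collapsed_before = collapse_timepoints(fi) / np.sqrt(gmax * lmax)
        np.testing.assert_allclose(collapsed_after, collapsed_before, atol=1e-12)

    def test_stage_summary_embryo_carries_peak_at_t5(self):
        v = np.zeros(30)
        v[4] = 0.9
        stages = stage_summary(v)
        assert stages["embryo"] == pytest.approx(0.9)
        assert max(stages.values()) == stages["embryo"]

    def test_constant_profile_gives_equal_stage_maxima(self):
        stages = stage_summary(np.full(30, 0.3))
        assert list(stages.values()) == pytest.approx([0.3] * 4)

    def test_matches_brute_force_range_max(self):
        rng = np.random.default_rng(6)
        stage_map = default_stage_map()
        for _ in range(20):
            v = rng.uniform(size=30)
            stages = stage_summary(v)
            for stage, idx in stage_map.items():
                assert stages[stage] == pytest.approx(max(v[i] for i in idx))

    def test_non_partition_stage_map_rejected(self):
        with pytest.raises(ParameterError):
            stage_summary(np.zeros(30), {"only": tuple(range(29))})


def _profile(term, vec):
    vec = np.asarray(vec, dtype=float)
    return ImportanceProfile(
        term_id=term,
        rfi_timepoint=vec,
        rfi_stage=stage_summary(vec),
        fi_max_global=1.0,
        fi_max_local=float(vec.max()),
    )


class TestScreenAndClustering:
    def test_screen_threshold_is_strict(self):
        low = _profile("GO:low", np.full(30, 0.6))
        high = _profile("GO:high", np.r_[np.full(29, 0.1), 0.71])
        assert high_relevance_terms([low, high]) == ["GO:high"]

    def test_screen_matches_brute_force_filter(self):
        rng = np.random.default_rng(7)
        profiles = [_profile(f"GO:{i}", rng.uniform(size=30)) for i in range(20)]
        got = set(high_relevance_terms(profiles, threshold=0.7))
        expected = {p.term_id for p in profiles if p.rfi_timepoint.max() > 0.7}
        assert got == expected

    def test_identical_profiles_merge_at_distance_zero(self):
        v = np.linspace(0, 1, 30)
        clustering = cluster_profiles([_profile("GO:a", v), _profile("GO:b", v)])
        assert clustering.linkage[0, 2] == pytest.approx(0.0)

    def test_planted_partition_recovered_by_first_split(self):
        rng = np.random.default_rng(8)
        early, late = np.zeros(30), np.zeros(30)
        early[:6], late[22:28] = 0.9, 0.9
        profiles = [
            _profile(f"GO:e{i}", np.clip(early + rng.normal(0, 0.03, 30), 0, 1))
            for i in range(4)
        ] + [
            _profile(f"GO:l{i}", np.clip(late + rng.normal(0, 0.03, 30), 0, 1))
            for i in range(4)
        ]
        clustering = cluster_profiles(profiles)
        flat = fcluster(clustering.linkage, t=2, criterion="maxclust")
        groups = {tid[3] for tid, c in zip(clustering.term_ids, flat) if c == flat[0]}
        assert groups == {"e"} or groups == {"l"}

    def test_leaf_set_equals_input_set(self):
        rng = np.random.default_rng(9)
        profiles = [_profile(f"GO:{i}", rng.uniform(size=30)) for i in range(5)]
        clustering = cluster_profiles(profiles)
        assert sorted(clustering.order) == sorted(p.term_id for p in profiles)

    def test_single_profile_rejected(self):
        with pytest.raises(ParameterError):
            cluster_profiles([_profile("GO:a", np.zeros(30))])


class TestExpressionProfile:
    def test_profile_from_planted_forest_peaks_at_informative_timepoint(
        self, small_benchmark
    ):
        from funcfly.classifier_bank import ClassifierSpec
        from funcfly.dataset_builder import (
            build_term_dataset, propagate_annotations, split_train_test,
        )
        from funcfly.expression_features import (
            compose_feature_group, gene_to_protein_features,
        )

        bench = small_benchmark
        term = next(
            t for t, v in bench.manifest.terms.items() if v.driver == "expression"
        )
        truth = bench.manifest.terms[term]
        expr = gene_to_protein_features(bench.expression)
        matrix = compose_feature_group(
            [bench.seq_features, expr], ("Seq", "Num", "Ave", "Main")
        )
        prop = propagate_annotations(bench.annotations, bench.dag)
        ds = split_train_test(build_term_dataset(term, matrix, prop, bench.dag),
                              seed=0)
        forest = ClassifierSpec("RF", (("n_estimators", 100),)).build(0)
        forest.fit(ds.X_train, ds.y_train)
        fi = forest_importance(forest, feature_names=matrix.feature_names)
        profile = expression_profile(term, fi, matrix.groups.to_dict())
        assert profile.rfi_timepoint.shape == (30,)
        assert ((0 <= profile.rfi_timepoint) & (profile.rfi_timepoint <= 1)).all()
        peak = int(np.argmax(profile.rfi_timepoint))
        assert peak + 1 in truth.informative_timepoints
        # stage maxima are consistent with the collapsed profile
        assert profile.max_stage_rfi == pytest.approx(profile.rfi_timepoint.max())
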