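"""Variance ranking, clustering/MDS oracles, panels, cluster assignment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score

import aqmeth as aq
from aqmeth.signature import _classical_mds, _pairwise_distances
from aqmeth.simulate import SUBTYPE_CONTRAST
from conftest import make_betas
from oracles import brute_force_agglomerate


class TestTopVariableProbes:
    def test_constant_matrix_falls_back_to_lexicographic(self):
        betas = make_betas(np.full((5, 4), 0.5),
                           probes=["e", "d", "c", "b", "a"])
        assert aq.top_variable_probes(betas, k=3) == ["a", "b", "c"]

    def test_single_variable_probe_wins(self):
        vals = np.full((4, 6), 0.5)
        vals[2] = [0.1, 0.9, 0.1, 0.9, 0.1, 0.9]
        betas = make_betas(vals)
        assert aq.top_variable_probes(betas, k=1) == ["cg002"]

    def test_order_matches_brute_force_sd_sort(self):
        rng = np.random.default_rng(21)
        betas = make_betas(rng.random((100, 8)))
        got = aq.top_variable_probes(betas, k=100)
        sd = betas.beta.std(axis=1, ddof=1)
        expected = [p for p, _ in sorted(sd.items(),
                                         key=lambda kv: (-kv[1], kv[0]))]
        assert got == expected

    def test_k_larger_than_eligible_warns_and_returns_all(self):
        betas = make_betas(np.random.default_rng(1).random((5, 3)))
        with pytest.warns(UserWarning):
            got = aq.top_variable_probes(betas, k=50)
        assert len(got) == 5

    def test_selector_estimator_transform(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.random((6, 30)),
                         columns=[f"cg{i:03d}" for i in range(30)])
        sel = aq.TopVariableProbeSelector(k=10).fit(X)
        out = sel.transform(X)
        assert out.shape == (6, 10)
        assert set(out.columns) == set(sel.selected_ids_)


class TestHCluster:
    def test_duplicate_profiles_merge_first_at_zero(self):
        vals = np.array([[0.1, 0.1, 0.9], [0.2, 0.2, 0.8],
                         [0.3, 0.3, 0.1]])
        betas = make_betas(vals)
        tree = aq.hcluster(betas)
        assert tree.Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        first = sorted(int(i) for i in tree.Z[0, :2])
        assert [tree.leaves[i] for i in first] == ["S0", "S1"]

    @pytest.mark.parametrize("linkage", ["complete", "average"])
    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_matches_brute_force_oracle(self, n, linkage):
        rng = np.random.default_rng(100 + n)
        for _ in range(5):
            X = rng.random((n, 7))
            betas = make_betas(X.T)
            tree = aq.hcluster(betas, linkage=linkage)
            D = _pairwise_distances(X, "euclidean")
            heights, partitions = brute_force_agglomerate(D, linkage)
            assert np.allclose(sorted(tree.Z[:, 2]), sorted(heights),
                               atol=1e-10)
            for k in range(1, n + 1):
                labels = aq.cut_k(tree, k)
                got = {frozenset(np.where(labels.to_numpy() == g)[0])
                       for g in set(labels)}
                assert got == partitions[k]

    def test_planted_subtypes_separate_at_k2(self, cohort_small):
        betas, sheet, truth = cohort_small
        tumors = list(sheet.index[sheet.role == "tumor"])
        panel = list(truth.planted(SUBTYPE_CONTRAST))
        tree = aq.hcluster(betas, probes=panel, samples=tumors)
        labels = aq.cut_k(tree, 2)
        true = [truth.subtype_labels[s] for s in labels.index]
        assert adjusted_rand_score(true, labels.to_numpy()) == 1.0

    def test_high_missingness_sample_rejected(self):
        vals = np.random.default_rng(3).random((10, 3))
        vals[:6, 0] = np.nan
        betas = make_betas(vals)
        with pytest.raises(ValueError, match="S0"):
            aq.hcluster(betas)

    def test_tree_json_round_trip(self, tmp_path):
        betas = make_betas(np.random.default_rng(4).random((6, 4)))
        tree = aq.hcluster(betas)
        path = tmp_path / "tree.json"
        tree.to_json(path)
        back = aq.LinkageTree.from_json(path)
        assert back.leaves == tree.leaves
        assert np.allclose(back.Z, tree.Z)


class TestCutK:
    def test_extreme_cuts(self):
        betas = make_betas(np.random.default_rng(5).random((8, 5)))
        tree = aq.hcluster(betas)
        assert aq.cut_k(tree, 1).nunique() == 1
        assert aq.cut_k(tree, 5).nunique() == 5

    def test_five_leaf_manual_cut(self):
        # two tight groups far apart: the k=2 cut splits at the tall merge
        vals = np.array([[0.0, 0.01, 0.02, 1.0, 0.99]])
        betas = make_betas(np.repeat(vals, 4, axis=0))
        tree = aq.hcluster(betas)
        labels = aq.cut_k(tree, 2)
        assert labels["S0"] == labels["S1"] == labels["S2"]
        assert labels["S3"] == labels["S4"] != labels["S0"]

    def test_out_of_range_rejected(self):
        betas = make_betas(np.random.default_rng(6).random((4, 3)))
        tree = aq.hcluster(betas)
        with pytest.raises(ValueError):
            aq.cut_k(tree, 0)
        with pytest.raises(ValueError):
            aq.cut_k(tree, 4)


class TestMDS:
    def test_identical_profiles_coincide(self):
        vals = np.array([[0.1, 0.1, 0.8], [0.5, 0.5, 0.2],
                         [0.9, 0.9, 0.4]])
        betas = make_betas(vals)
        coords = aq.mds_embed(betas, dims=2)
        assert np.allclose(coords.loc["S0"], coords.loc["S1"], atol=1e-9)

    def test_triangle_embeds_exactly(self):
        D = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        coords = _classical_mds(D, 2)
        assert np.allclose(sorted(pdist(coords)), [3.0, 4.0, 5.0],
                           atol=1e-6)

    def test_classical_mds_estimator_precomputed(self):
        D = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        est = aq.ClassicalMDS(n_components=2, dissimilarity="precomputed")
        emb = est.fit_transform(D)
        assert np.allclose(sorted(pdist(emb)), [3.0, 4.0, 5.0], atol=1e-6)

    def test_first_axis_separates_planted_groups(self, cohort_small):
        betas, sheet, truth = cohort_small
        tumors = list(sheet.index[sheet.role == "tumor"])
        panel = list(truth.planted(SUBTYPE_CONTRAST))
        coords = aq.mds_embed(betas, probes=panel, samples=tumors)
        ax1 = coords["MDS1"]
        s1 = ax1[[s for s in tumors if truth.subtype_labels[s] == 1]]
        s2 = ax1[[s for s in tumors if truth.subtype_labels[s] == 2]]
        assert s1.max() < s2.min() or s2.max() < s1.min()

    def test_degenerate_distances_give_zero_coords(self):
        betas = make_betas(np.full((4, 3), 0.5))
        with pytest.warns(UserWarning):
            coords = aq.mds_embed(betas, dims=2)
        assert np.allclose(coords.to_numpy(), 0.0)


class TestDerivePanel:
    def test_extreme_thresholds_give_empty_panel(self, cohort_small):
        betas, sheet, _ = cohort_small
        tumors = list(sheet.index[sheet.role == "tumor"])
        retina = list(sheet.index[sheet.role == "retina"])
        with pytest.warns(UserWarning):
            panel = aq.derive_panel(betas, tumors, retina,
                                    delta_thresh=0.99, p_thresh=1e-9)
        assert len(panel) == 0

    def test_recovers_planted_outcome_panel(self, cohort_small):
        betas, sheet, truth = cohort_small
        ah = sheet.index[sheet.role == "AH"]
        tumors = list(sheet.index[sheet.role == "tumor"])
        sv = [s for s in tumors if sheet.loc[s, "outcome"] == "SV"]
        enuc = [s for s in tumors if sheet.loc[s, "outcome"] != "SV"]
        assert len(ah) > 0
        panel = aq.derive_panel(betas, sv, enuc, label="sv_vs_enuc")
        planted = set(truth.planted(SUBTYPE_CONTRAST))
        recovered = len(planted & set(panel.probe_ids)) / len(planted)
        assert recovered >= 0.99

    def test_second_round_contains_planted_subtype_panel(self, cohort_small):
        betas, sheet, truth = cohort_small
        tumors = list(sheet.index[sheet.role == "tumor"])
        first = aq.derive_panel(
            betas,
            [s for s in tumors if sheet.loc[s, "outcome"] == "SV"],
            [s for s in tumors if sheet.loc[s, "outcome"] != "SV"])
        asg = aq.assign_clusters(betas, first, samples=tumors,
                                 outcomes=sheet["outcome"])
        second = aq.derive_panel(betas, asg.members("A"), asg.members("B"),
                                 label="clusterA_vs_B")
        planted = set(truth.planted(SUBTYPE_CONTRAST))
        assert planted <= set(second.probe_ids)

    def test_panel_tsv_round_trip(self, tmp_path, cohort_small):
        betas, sheet, _ = cohort_small
        tumors = list(sheet.index[sheet.role == "tumor"])
        panel = aq.derive_panel(
            betas,
            [s for s in tumors if sheet.loc[s, "outcome"] == "SV"],
            [s for s in tumors if sheet.loc[s, "outcome"] != "SV"],
            label="rt")
        path = tmp_path / "panel.tsv"
        panel.to_tsv(path)
        back = aq.SignaturePanel.from_tsv(path)
        assert back.label == "rt"
        assert back.probe_ids == panel.probe_ids
        assert back.arm_a == panel.arm_a


class TestAssignClusters:
    def test_recovers_planted_subtypes(self, cohort_small):
        betas, sheet, truth = cohort_small
        tumors = list(sheet.index[sheet.role == "tumor"])
        sv = [s for s in tumors if sheet.loc[s, "outcome"] == "SV"]
        enuc = [s for s in tumors if sheet.loc[s, "outcome"] != "SV"]
        panel = aq.derive_panel(betas, sv, enuc)
        asg = aq.assign_clusters(betas, panel, samples=tumors,
                                 outcomes=sheet["outcome"])
        true = [truth.subtype_labels[s] for s in asg.labels.index]
        pred = [1 if l == "A" else 2 for l in asg.labels]
        assert adjusted_rand_score(true, pred) == 1.0
        # salvage-enriched cluster is "A"
        assert set(asg.members("A")) == set(sv)

    def test_invariant_to_sample_and_probe_order(self, cohort_small):
        betas, sheet, _ = cohort_small
        tumors = list(sheet.index[sheet.role == "tumor"])
        sv = [s for s in tumors if sheet.loc[s, "outcome"] == "SV"]
        enuc = [s for s in tumors if sheet.loc[s, "outcome"] != "SV"]
        panel = aq.derive_panel(betas, sv, enuc)
        a = aq.assign_clusters(betas, panel, samples=tumors,
                               outcomes=sheet["outcome"])
        flipped = aq.SignaturePanel(
            label=panel.label, table=panel.table.iloc[::-1],
            delta_thresh=panel.delta_thresh, p_thresh=panel.p_thresh)
        b = aq.assign_clusters(betas, flipped, samples=tumors[::-1],
                               outcomes=sheet["outcome"])
        assert a.labels.sort_index().equals(b.labels.sort_index())

    def test_duplicated_cohort_coassigns_duplicates(self, cohort_small):
        betas, sheet, _ = cohort_small
        tumors = list(sheet.index[sheet.role == "tumor"])
        sv = [s for s in tumors if sheet.loc[s, "outcome"] == "SV"]
        enuc = [s for s in tumors if sheet.loc[s, "outcome"] != "SV"]
        panel = aq.derive_panel(betas, sv, enuc)
        dup = betas.beta[tumors].copy()
        dup.columns = [f"{s}_dup" for s in tumors]
        doubled = aq.BetaMatrix(pd.concat([betas.beta[tumors], dup], axis=1))
        asg = aq.assign_clusters(doubled, panel)
        for s in tumors:
            assert asg.labels[s] == asg.labels[f"{s}_dup"]

    def test_homogeneous_cohort_flagged_weak(self, cohort_small):
        betas, sheet, truth = cohort_small
        s1 = [s for s, v in truth.subtype_labels.items()
              if v == 1 and sheet.loc[s, "role"] == "tumor"]
        panel_probes = list(truth.planted(SUBTYPE_CONTRAST))
        table = pd.DataFrame({"delta_beta": 0.5, "p_value": 1e-4,
                              "direction": "hyper"}, index=panel_probes)
        panel = aq.SignaturePanel(label="forced", table=table,
                                  delta_thresh=0.4, p_thresh=0.01)
        asg = aq.assign_clusters(betas, panel, samples=s1)
        assert asg.weak_separation
        assert abs(asg.silhouette) < 0.25

    def test_missing_panel_probe_rejected(self, cohort_small):
        betas, _, _ = cohort_small
        table = pd.DataFrame({"delta_beta": [0.5], "p_value": [1e-4],
                              "direction": ["hyper"]}, index=["cg_missing"])
        panel = aq.SignaturePanel(label="bad", table=table,
                                  delta_thresh=0.4, p_thresh=0.01)
        with pytest.raises(KeyError):
            aq.assign_clusters(betas, panel)

    def test_signature_clusterer_estimator(self, cohort_small):
        betas, sheet, truth = cohort_small
        tumors = list(sheet.index[sheet.role == "tumor"])
        panel = list(truth.planted(SUBTYPE_CONTRAST))
        X = betas.beta.loc[panel, tumors].T
        est = aq.SignatureClusterer().fit(X)
        true = [truth.subtype_labels[s] for s in tumors]
        assert adjusted_rand_score(true, est.labels_) == 1.0
        assert est.silhouette_ > 0.5 and not est.weak_separation_


class TestClusterOutcomeTest:
    def test_perfect_separation_exact_p(self):
        labels = pd.Series(["A"] * 4 + ["B"] * 8,
                           index=[f"s{i}" for i in range(12)])
        outcomes = pd.Series(["SV"] * 4 + ["PE"] * 4 + ["SE"] * 4,
                             index=labels.index)
        res = aq.cluster_outcome_test(labels, outcomes)
        assert res.p_value == pytest.approx(2 / 495, abs=1e-12)
        assert res.odds_ratio == np.inf
        assert res.containment == (True, True)
        assert res.table.to_numpy().tolist() == [[4, 0], [0, 8]]

    def test_doubled_tail_matches_scipy_one_sided(self):
        from scipy.stats import fisher_exact
        rng = np.random.default_rng(9)
        for _ in range(20):
            a, b, c, d = rng.integers(0, 8, size=4)
            if (a + b) == 0 or (c + d) == 0:
                continue
            labels = pd.Series(["A"] * (a + b) + ["B"] * (c + d))
            labels.index = [f"s{i}" for i in range(len(labels))]
            outcomes = pd.Series(["SV"] * a + ["PE"] * b + ["SV"] * c
                                 + ["SE"] * d, index=labels.index)
            res = aq.cluster_outcome_test(labels, outcomes)
            table = [[a, b], [c, d]]
            p_g = fisher_exact(table, alternative="greater").pvalue
            p_l = fisher_exact(table, alternative="less").pvalue
            assert res.p_value == pytest.approx(min(1.0, 2 * min(p_g, p_l)),
                                                rel=1e-9)

    def test_containment_worked_example(self):
        # cluster A (19) inside subtype 1 (27), cluster B (24) inside 2 (37),
        # shared cohort of 43 clustered samples
        labels = pd.Series(["A"] * 19 + ["B"] * 24,
                           index=[f"t{i}" for i in range(43)])
        subtype = pd.Series(["1"] * 19 + ["2"] * 24, index=labels.index)
        res = aq.cluster_outcome_test(labels, subtype)
        assert res.containment == (True, True)
        assert res.p_value < 0.01

    def test_independent_labels_not_significant(self):
        rng = np.random.default_rng(15)
        labels = pd.Series(rng.choice(["A", "B"], size=60),
                           index=[f"s{i}" for i in range(60)])
        outcomes = pd.Series(rng.choice(["SV", "PE"], size=60),
                             index=labels.index)
        res = aq.cluster_outcome_test(labels, outcomes)
        assert res.p_value > 0.01
        assert res.containment == (False, False)

    def test_missing_outcome_rejected(self):
        labels = pd.Series(["A", "B"], index=["s1", "s2"])
        with pytest.raises(ValueError):
            aq.cluster_outcome_test(labels, pd.Series({"s1": "SV"}))
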