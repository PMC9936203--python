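import itertools
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ncscreen import profiles, simulate


class TestTransform:
    def test_zero_counts_map_to_zero(self):
        c = pd.DataFrame(np.zeros((3, 2)), columns=["a", "b"])
        sf = pd.Series([1.0, 1.0], index=["a", "b"])
        assert (profiles.transform(c, sf) == 0).all().all()

    def test_count_three_unit_factor_gives_two(self):
        c = pd.DataFrame({"a": [3]})
        sf = pd.Series([1.0], index=["a"])
        assert profiles.transform(c, sf).iloc[0, 0] == pytest.approx(2.0)

    def test_positive_factors_required(self):
        c = pd.DataFrame({"a": [3]})
        with pytest.raises(ValueError):
            profiles.transform(c, pd.Series([0.0], index=["a"]))


class TestConditionMeans:
    def test_identical_replicates_equal_single_value(self):
        design = simulate.make_design(n_reps=2)
        mat = pd.DataFrame(
            np.tile([[1.0, 2.0, 3.0, 4.0]], 2).reshape(1, 8)[:, [0, 4, 1, 5, 2, 6, 3, 7]],
            columns=design.index,
        )
        # make both replicates of each condition identical
        cond = design["strain"].astype(str) + "@" + design["day"].astype(str)
        for name in cond.unique():
            cols = cond.index[cond == name]
            mat[cols[1]] = mat[cols[0]]
        out = profiles.condition_means(mat, design)
        assert list(out.columns) == list(profiles.CONDITION_ORDER)
        for name in out.columns:
            cols = cond.index[cond == name]
            assert out[name].iloc[0] == mat[cols[0]].iloc[0]


class TestPca:
    def test_duplicated_samples_coincide(self, rng):
        base = rng.normal(size=(100, 3))
        mat = pd.DataFrame(
            np.hstack([base, base[:, :1]]), columns=["s1", "s2", "s3", "s1b"]
        )
        coords, ratio = profiles.pca_top_variable(mat, n_top=50)
        assert np.allclose(coords.loc["s1"], coords.loc["s1b"], atol=1e-8)
        assert ratio.sum() <= 1.0 + 1e-9

    def test_planted_groups_separate_on_pc1(self, rng):
        base = rng.normal(0, 0.2, size=(200, 8))
        base[:50, 4:] += 3.0  # 50 genes shifted in the second sample group
        mat = pd.DataFrame(
            base, columns=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        )
        coords, _ = profiles.pca_top_variable(mat, n_top=100)
        pc1 = coords["PC1"].to_numpy()
        assert (pc1[:4].max() < pc1[4:].min()) or (pc1[:4].min() > pc1[4:].max())

    def test_n_top_exceeding_genes_warns(self, rng):
        mat = pd.DataFrame(rng.normal(size=(20, 4)))
        with pytest.warns(UserWarning):
            profiles.pca_top_variable(mat, n_top=500)


@pytest.fixture(scope="module")
def separated():
    rng = np.random.default_rng(3)
    cents = np.array([[0, 0, 0, 0], [8, 8, 0, 0], [0, 8, 8, 0]], float)
    X = np.vstack([c + rng.normal(0, 0.3, size=(60, 4)) for c in cents])
    return pd.DataFrame(X, index=[f"g{i}" for i in range(180)])


class TestKmeansElbow:
    def test_recovers_planted_k(self, separated):
        res = profiles.kmeans_elbow(separated, k_range=range(2, 10), seed=1)
        assert res.k == 3

    def test_deterministic_for_seed(self, separated):
        r1 = profiles.kmeans_elbow(separated, k_range=range(2, 6), seed=5)
        r2 = profiles.kmeans_elbow(separated, k_range=range(2, 6), seed=5)
        assert r1.assignments.equals(r2.assignments)

    def test_wss_zero_at_k_equals_distinct_points(self):
        pts = pd.DataFrame([[0.0, 0], [1, 1], [2, 2], [3, 3]])
        res = profiles.kmeans_elbow(pts, k_range=range(2, 5), seed=0, n_init=5)
        assert res.inertia_curve.loc[4] == pytest.approx(0.0, abs=1e-12)

    def test_assignment_invariant_to_gene_permutation(self, separated):
        res = profiles.kmeans_elbow(separated, k_range=range(3, 4), seed=2)
        perm = separated.sample(frac=1.0, random_state=9)
        res_p = profiles.kmeans_elbow(perm, k_range=range(3, 4), seed=2)
        # same partition: co-membership must agree for a sample of pairs
        a = res.assignments
        b = res_p.assignments
        genes = list(separated.index[::7])
        for g1, g2 in itertools.combinations(genes, 2):
            assert (a[g1] == a[g2]) == (b[g1] == b[g2])


class TestHypergeom:
    def test_zero_overlap_p_is_one(self):
        row = profiles.hypergeom_enrich(
            {"a", "b"}, {"c", "d", "e"}, {"a", "b", "c", "d", "e"}, min_size=1
        )
        assert row.p_raw == pytest.approx(1.0)

    def test_hand_value(self):
        u = set(range(20))
        row = profiles.hypergeom_enrich(set(range(10)), set(range(5)), u, min_size=1)
        assert row.p_raw == pytest.approx(comb(5, 5) * comb(15, 5) / comb(20, 10))

    def test_small_set_skipped(self):
        u = {str(i) for i in range(30)}
        s = {str(i) for i in range(9)}
        assert profiles.hypergeom_enrich(u, s, u, min_size=10) is None

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            profiles.hypergeom_enrich(set(), set(), set())

    def test_matches_exhaustive_enumeration(self, rng):
        """Oracle: enumerate all draws of |cluster| genes from the universe
        and count those with at least the observed overlap."""
        universe = list(range(18))
        gene_set = set(rng.choice(universe, 6, replace=False).tolist())
        cluster = set(rng.choice(universe, 7, replace=False).tolist())
        overlap = len(cluster & gene_set)
        hits = total = 0
        for draw in itertools.combinations(universe, len(cluster)):
            total += 1
            if len(set(draw) & gene_set) >= overlap:
                hits += 1
        row = profiles.hypergeom_enrich(
            cluster, gene_set, set(universe), min_size=1
        )
        assert row.p_raw == pytest.approx(hits / total)


class TestGoElim:
    def test_edgeless_equals_classic(self, rng):
        dag = nx.DiGraph()
        terms = [f"t{i}" for i in range(4)]
        dag.add_nodes_from(terms)
        universe = {f"g{i}" for i in range(40)}
        g2t = {
            f"g{i}": {terms[i % 4]} for i in range(40)
        }
        cluster = {f"g{i}" for i in range(12)}
        elim_rows = {
            r.set_id: r.p_raw
            for r in profiles.go_elim(dag, g2t, cluster, universe, min_size=1)
        }
        for t in terms:
            genes_t = {g for g, ts in g2t.items() if t in ts}
            classic = profiles.hypergeom_enrich(cluster, genes_t, universe, min_size=1)
            assert elim_rows[t] == pytest.approx(classic.p_raw)

    def test_chain_child_drives_parent_elimination(self):
        dag = nx.DiGraph()
        dag.add_edge("child", "parent")
        universe = {f"g{i}" for i in range(30)}
        cluster = {f"g{i}" for i in range(10)}
        g2t = {f"g{i}": {"child"} for i in range(10)}
        for i in range(10, 22):
            g2t[f"g{i}"] = {"parent"}
        rows = {r.set_id: r for r in profiles.go_elim(dag, g2t, cluster, universe,
                                                      alpha=0.05, min_size=5)}
        assert rows["child"].p_raw < 0.05
        # without elimination the parent would enrich (p ~ 0.0215)
        no_elim = profiles.hypergeom_enrich(
            cluster, {g for g, t in g2t.items()}, universe, min_size=1
        )
        assert rows["parent"].p_raw > no_elim.p_raw
        assert rows["parent"].overlap == 0

    def test_insignificant_child_leaves_parent_unchanged(self):
        dag = nx.DiGraph()
        dag.add_edge("child", "parent")
        universe = {f"g{i}" for i in range(30)}
        cluster = {f"g{i}" for i in range(0, 30, 3)}
        g2t = {f"g{i}": {"child"} for i in range(0, 30, 2)}
        rows = {r.set_id: r for r in profiles.go_elim(dag, g2t, cluster, universe,
                                                      alpha=1e-6, min_size=1)}
        classic = profiles.hypergeom_enrich(
            cluster, {g for g in g2t}, universe, min_size=1
        )
        assert rows["parent"].p_raw == pytest.approx(classic.p_raw)

    def test_cyclic_graph_rejected(self):
        dag = nx.DiGraph([("a", "b"), ("b", "a")])
        with pytest.raises(ValueError):
            profiles.go_elim(dag, {}, set(), {"g"})


class TestRegulons:
    def test_table_style_representation_percents(self):
        """Representation = 100*overlap/regulon-size at two decimals."""
        assert profiles.representation_percent(69, 273) == 25.27
        assert profiles.representation_percent(24, 59) == 40.68
        assert profiles.representation_percent(8, 12) == 66.67
        assert profiles.representation_percent(20, 93) == 21.51
        assert profiles.representation_percent(9, 11) == 81.82

    def test_enriched_regulon_detected_with_percent(self):
        background = {f"g{i}" for i in range(200)}
        reg = {f"g{i}" for i in range(20)}          # regulon of 20
        clusters = {
            "c1": {f"g{i}" for i in range(15)} | {f"g{i}" for i in range(100, 120)},
            "c2": {f"g{i}" for i in range(40, 100)},
        }
        df = profiles.regulon_overrepresentation(clusters, {"reg": reg}, background)
        row = df[(df.set_id == "reg") & (df.cluster_id == "c1")].iloc[0]
        assert row.overlap == 15
        assert row.representation_percent == 75.0
        assert row.p_adj <= 0.01

    def test_size_at_threshold_excluded(self):
        background = {f"g{i}" for i in range(100)}
        reg10 = {f"g{i}" for i in range(10)}
        reg11 = {f"g{i}" for i in range(11)}
        clusters = {"c": {f"g{i}" for i in range(12)}}
        df = profiles.regulon_overrepresentation(
            clusters, {"r10": reg10, "r11": reg11}, background
        )
        assert "r10" not in set(df.get("set_id", []))

    def test_outside_background_intersected_with_warning(self):
        background = {f"g{i}" for i in range(50)}
        reg = {f"g{i}" for i in range(40, 70)}
        with pytest.warns(UserWarning):
            profiles.regulon_overrepresentation(
                {"c": set(list(background)[:10])}, {"reg": reg}, background
            )
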