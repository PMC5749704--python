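import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polyarray import diversity as div


class TestAlleleFrequenciesAndPic:
    @pytest.mark.parametrize(
        "calls, expected",
        [
            (["AA", "AA", "BB", "BB"], [0.5, 0.5]),
            (["AA", "AB", "BB", "NN"], [0.5, 0.5]),
            (["AA", "AA"], [1.0]),
            (["AA", "AB", "OO"], [0.75, 0.25]),  # OO excluded from A/B counts
        ],
    )
    def test_frequencies_from_calls(self, calls, expected):
        np.testing.assert_allclose(div.allele_frequencies(calls), expected)

    def test_all_missing_column_raises(self):
        with pytest.raises(ValueError):
            div.allele_frequencies(["NN", "OO"])

    @pytest.mark.parametrize(
        "spectrum, expected",
        [([1.0], 0.0), ([0.5, 0.5], 0.5), ([0.25, 0.75], 0.375)],
    )
    def test_pic_values(self, spectrum, expected):
        assert div.pic(spectrum) == pytest.approx(expected)

    def test_pic_rejects_invalid_spectrum(self):
        with pytest.raises(ValueError):
            div.pic([0.5, 0.4])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=6))
    def test_pic_bounds(self, raw):
        p = np.asarray(raw) / np.sum(raw)
        p = p / p.sum()
        value = div.pic(p)
        n = len(p)
        assert -1e-12 <= value <= 1.0 - 1.0 / n + 1e-12
        if n == 1:
            assert value == 0.0


class TestSimpleMatching:
    def test_identical_and_fully_different_rows(self):
        m = pd.DataFrame(
            {"L1": ["AA", "AA", "BB"], "L2": ["AB", "AB", "AA"]},
            index=["s1", "s2", "s3"],
        )
        d, n = div.simple_matching_distance(m)
        assert d.loc["s1", "s2"] == 0.0
        assert d.loc["s1", "s3"] == 1.0
        assert n.loc["s1", "s3"] == 2

    def test_pairwise_complete_counting(self):
        row1 = ["AA"] * 10
        row2 = ["BB", "AB"] + ["AA"] * 8
        row2[5] = "NN"  # drops locus 5 from the comparison
        m = pd.DataFrame([row1, row2], index=["a", "b"])
        d, n = div.simple_matching_distance(m)
        assert n.loc["a", "b"] == 9
        assert d.loc["a", "b"] == pytest.approx(2 / 9)

    def test_otv_fourth_state_vs_missing_modes(self):
        m = pd.DataFrame([["AA", "OO"], ["AA", "AA"]], index=["a", "b"])
        d4, _ = div.simple_matching_distance(m, otv_mode="fourth_state")
        dm, nm = div.simple_matching_distance(m, otv_mode="missing")
        assert d4.loc["a", "b"] == pytest.approx(0.5)
        assert dm.loc["a", "b"] == 0.0
        assert nm.loc["a", "b"] == 1

    def test_symmetry_zero_diagonal_and_range(self, panel_two_groups):
        matrix, _ = panel_two_groups
        d, _ = div.simple_matching_distance(matrix)
        v = d.to_numpy()
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 0.0)
        assert np.nanmin(v) >= 0.0 and np.nanmax(v) <= 1.0

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            div.simple_matching_distance(pd.DataFrame([["AA"]], index=["a"]))


def _dist(df):
    labels = list(df.index)
    return df, labels


class TestWard:
    def test_identical_samples_merge_first_at_zero_height(self):
        d = pd.DataFrame(
            [[0.0, 0.0, 0.9], [0.0, 0.0, 0.9], [0.9, 0.9, 0.0]],
            index=list("abc"), columns=list("abc"),
        )
        res = div.ward_cluster(d)
        assert res.linkage[0, 2] == 0.0
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_closest_pair_merges_first(self):
        d = pd.DataFrame(
            [[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]],
            index=list("abc"), columns=list("abc"),
        )
        res = div.ward_cluster(d)
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_merge_heights_monotone_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 10))
            x = rng.random((n, 3))
            d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
            df = pd.DataFrame(d, index=range(n), columns=range(n))
            res = div.ward_cluster(df)
            heights = res.linkage[:, 2]
            assert np.all(np.diff(heights) >= -1e-12)

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0.0, 0.2], [0.3, 0.0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError):
            div.ward_cluster(d)


# ---- brute-force NJ oracle: enumerate unrooted topologies, least-squares fit ----

def _enumerate_topologies(n_leaves):
    trees = [([(0, n_leaves), (1, n_leaves), (2, n_leaves)], n_leaves + 1)]
    for leaf in range(3, n_leaves):
        nxt_trees = []
        for edges, nxt in trees:
            for i, (u, v) in enumerate(edges):
                e2 = edges[:i] + edges[i + 1 :] + [(u, nxt), (v, nxt), (leaf, nxt)]
                nxt_trees.append((e2, nxt + 1))
        trees = nxt_trees
    return [t[0] for t in trees]


def _path_design_matrix(edges, n_leaves):
    adj = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    pairs = list(itertools.combinations(range(n_leaves), 2))
    A = np.zeros((len(pairs), len(edges)))
    for row, (a, b) in enumerate(pairs):
        stack = [(a, -1, [])]
        while stack:
            node, prev, path = stack.pop()
            if node == b:
                A[row, path] = 1.0
                break
            for nxt, eidx in adj[node]:
                if nxt != prev:
                    stack.append((nxt, node, path + [eidx]))
    return A, pairs


def _oracle_nj(dmat):
    """Enumerate all unrooted binary topologies; return the patristic matrix
    of the (unique) topology that fits the distances exactly."""
    n = dmat.shape[0]
    pairs = list(itertools.combinations(range(n), 2))
    d = np.array([dmat[i, j] for i, j in pairs])
    best = None
    for edges in _enumerate_topologies(n):
        A, _ = _path_design_matrix(edges, n)
        x, *_ = np.linalg.lstsq(A, d, rcond=None)
        resid = np.abs(A @ x - d).max()
        if resid < 1e-9 and (x > -1e-9).all():
            fitted = np.zeros((n, n))
            for (i, j), val in zip(pairs, A @ x):
                fitted[i, j] = fitted[j, i] = val
            best = fitted
            break
    assert best is not None, "no topology reproduces the additive matrix"
    return best


def _random_additive_matrix(n, seed):
    """Patristic matrix of a random binary tree with positive branch lengths."""
    rng = np.random.default_rng(seed)
    edges = _enumerate_topologies(n)[int(rng.integers(0, 3))] if n == 4 else None
    if edges is None:
        all_topos = _enumerate_topologies(n)
        edges = all_topos[int(rng.integers(0, len(all_topos)))]
    lengths = rng.uniform(0.5, 3.0, len(edges))
    A, pairs = _path_design_matrix(edges, n)
    d = A @ lengths
    out = np.zeros((n, n))
    for (i, j), val in zip(pairs, d):
        out[i, j] = out[j, i] = val
    return out


def _patristic(tree_result, labels):
    dm = tree_result.tree.tip_tip_distances(list(map(str, labels)))
    out = np.zeros((len(labels), len(labels)))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            out[i, j] = dm[str(a), str(b)]
    return out


class TestNeighborJoining:
    def test_four_taxon_tree_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:1)) gives the additive matrix below
        labels = list("ABCD")
        d = pd.DataFrame(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]],
            index=labels, columns=labels, dtype=float,
        )
        res = div.nj_tree(d)
        np.testing.assert_allclose(_patristic(res, labels), d.to_numpy(), atol=1e-9)

    def test_three_taxa_closed_form(self):
        labels = list("ABC")
        d = pd.DataFrame(
            [[0.0, 0.4, 0.6], [0.4, 0.0, 0.8], [0.6, 0.8, 0.0]],
            index=labels, columns=labels,
        )
        res = div.nj_tree(d)
        # closed form: a = (d_AB + d_AC - d_BC)/2 etc.
        np.testing.assert_allclose(_patristic(res, labels), d.to_numpy(), atol=1e-9)

    def test_duplicated_taxon_gets_zero_length_terminal_branch(self):
        labels = list("ABCD")
        base = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], dtype=float
        )
        base[0, 1] = base[1, 0] = 0.0  # B duplicates A
        base[1, 2:] = base[0, 2:]
        base[2:, 1] = base[2:, 0]
        d = pd.DataFrame(base, index=labels, columns=labels)
        res = div.nj_tree(d)
        p = _patristic(res, labels)
        assert p[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_too_few_samples_rejected(self):
        d = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError):
            div.nj_tree(d)

    @pytest.mark.parametrize("n, seed", [(4, 1), (5, 2), (6, 3), (8, 4)])
    def test_matches_enumeration_oracle_on_additive_matrices(self, n, seed):
        d = _random_additive_matrix(n, seed)
        oracle = _oracle_nj(d)
        np.testing.assert_allclose(oracle, d, atol=1e-9)
        labels = list(range(n))
        res = div.nj_tree(pd.DataFrame(d, index=labels, columns=labels))
        np.testing.assert_allclose(_patristic(res, labels), oracle, atol=1e-8)


def _clades(tree_result):
    """Tip-name bipartitions induced by the tree's internal edges."""
    tips = {t.name for t in tree_result.tree.tips()}
    out = []
    for node in tree_result.tree.non_tips():
        out.append(frozenset(t.name for t in node.tips()))
    return tips, out


class TestGroupRecovery:
    def test_nj_and_ward_separate_two_divergent_groups(self, panel_two_groups):
        matrix, truth = panel_two_groups
        d, _ = div.simple_matching_distance(matrix)
        groups = truth.categories
        g1 = frozenset(groups[groups == "group1"].index)

        res = div.nj_tree(d)
        tips, clades = _clades(res)
        assert g1 in clades or frozenset(tips - g1) in clades

        ward = div.ward_cluster(d)
        from scipy.cluster.hierarchy import fcluster

        assignment = fcluster(ward.linkage, 2, criterion="maxclust")
        labels = pd.Series(assignment, index=d.index)
        # each true group lands in a single Ward cluster
        assert labels[list(g1)].nunique() == 1
        assert labels[list(tips - g1)].nunique() == 1


class TestPav:
    def test_encoding_and_filters(self):
        m = pd.DataFrame(
            {
                "L1": ["AA", "OO", "AB"],   # OTV locus, fully called
                "L2": ["AA", "NN", "BB"],   # OTV locus with missing -> dropped
                "L3": ["AA", "BB", "AA"],   # PHR locus -> dropped
            },
            index=["s1", "s2", "s3"],
        )
        cats = pd.Series({"L1": "OTV", "L2": "OTV", "L3": "PHR"})
        pav = div.otv_pav_matrix(m, cats)
        assert list(pav.columns) == ["L1"]
        assert pav["L1"].tolist() == [1, 0, 1]

    def test_no_qualifying_loci_warns_and_returns_empty(self):
        m = pd.DataFrame({"L1": ["AA", "NN"]}, index=["s1", "s2"])
        with pytest.warns(UserWarning):
            pav = div.otv_pav_matrix(m, pd.Series({"L1": "OTV"}))
        assert pav.shape[1] == 0
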