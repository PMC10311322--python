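"""Graph Laplacian construction, pathway file parsing, feature restriction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pikn.pathways import (LaplacianMatrix, PathwaySubnetwork, build_restriction,
                           degree_matrix, load_laplacian_matrix, load_pathways,
                           normalized_laplacian, pathway_laplacian,
                           restrict_to_pathway, unnormalized_laplacian,
                           write_laplacian_matrix)


def random_graph(d, rng, p_edge=0.5):
    W = np.triu((rng.random((d, d)) < p_edge) * rng.random((d, d)), k=1)
    return W + W.T


TRIANGLE = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)


class TestDegreeMatrix:
    @pytest.mark.parametrize("W, expected", [
        ([[0, 1], [1, 0]], [1, 1]),
        (np.zeros((3, 3)), [0, 0, 0]),
        ([[0, 2, 1], [2, 0, 0], [1, 0, 0]], [3, 2, 1]),  # hand row-sum oracle
    ])
    def test_row_sums(self, W, expected):
        D = degree_matrix(np.asarray(W, dtype=float))
        assert np.array_equal(np.diag(D), expected)
        assert np.array_equal(D, np.diag(np.diag(D)))

    def test_rejects_asymmetric_naming_entries(self):
        with pytest.raises(ValueError, match=r"W\[0,1\]"):
            degree_matrix(np.array([[0.0, 1.0], [0.5, 0.0]]))

    def test_rejects_non_square(self):
        with pytest.raises(ValueError, match="square"):
            degree_matrix(np.zeros((2, 3)))

    def test_rejects_negative_weights(self):
        with pytest.raises(ValueError, match="nonnegative"):
            degree_matrix(np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestLaplacians:
    def test_single_edge(self):
        L = unnormalized_laplacian(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert np.array_equal(L.matrix, [[1, -1], [-1, 1]])
        # degrees are all 1 so the normalized Laplacian is identical
        Ls = normalized_laplacian(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert np.allclose(Ls.matrix, [[1, -1], [-1, 1]])

    def test_empty_graph(self):
        assert np.array_equal(unnormalized_laplacian(np.zeros((3, 3))).matrix, np.zeros((3, 3)))

    def test_triangle_closed_forms(self):
        L = unnormalized_laplacian(TRIANGLE)
        assert np.array_equal(L.matrix, 2 * np.eye(3) - TRIANGLE)
        Ls = normalized_laplacian(TRIANGLE)
        assert np.allclose(Ls.matrix, np.eye(3) - TRIANGLE / 2)

    def test_isolated_node_rows_are_zero(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        Ls = normalized_laplacian(W).matrix
        assert np.array_equal(Ls[2], np.zeros(3))
        assert np.array_equal(Ls[:, 2], np.zeros(3))

    def test_row_sums_exactly_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            W = random_graph(6, rng)
            L = unnormalized_laplacian(W).matrix
            assert np.allclose(L.sum(axis=1), 0.0, atol=1e-12)

    @pytest.mark.parametrize("d", [2, 3, 4, 5, 6])
    def test_clique_closed_form(self, d):
        W = np.ones((d, d)) - np.eye(d)
        Ls = normalized_laplacian(W).matrix
        assert np.allclose(Ls, np.eye(d) - W / (d - 1), atol=1e-12)

    def test_null_space_is_sqrt_degree_vector(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            W = random_graph(7, rng)
            W += (W.sum(axis=1) == 0)[:, None] * 0  # may contain isolated nodes; skip those
            d = W.sum(axis=1)
            if np.any(d == 0):
                continue
            Ls = normalized_laplacian(W).matrix
            v = np.sqrt(d)
            assert np.linalg.norm(Ls @ v) < 1e-8 * max(1.0, np.linalg.norm(v))

    def test_quadratic_form_nonnegative(self):
        rng = np.random.default_rng(2)
        W = random_graph(8, rng)
        Ls = normalized_laplacian(W).matrix
        for _ in range(100):
            v = rng.standard_normal(8)
            assert v @ Ls @ v >= -1e-10

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_normalized_eigenvalues_in_0_2(self, seed):
        rng = np.random.default_rng(seed)
        W = random_graph(int(rng.integers(2, 9)), rng)
        evals = np.linalg.eigvalsh(normalized_laplacian(W).matrix)
        assert evals.min() >= -1e-8
        assert evals.max() <= 2 + 1e-8


class TestGMT:
    def test_clique_construction(self, tmp_path):
        gmt = tmp_path / "sets.gmt"
        gmt.write_text("pw1\tdesc\tg1\tg2\tg3\n")
        (pw,) = load_pathways(gmt)
        assert pw.node_names == ["g1", "g2", "g3"]
        assert np.array_equal(pw.weight_matrix, np.ones((3, 3)) - np.eye(3))

    def test_single_member_pathway(self, tmp_path):
        gmt = tmp_path / "sets.gmt"
        gmt.write_text("pw1\tdesc\tg1\n")
        (pw,) = load_pathways(gmt)
        assert pw.size == 1 and pw.weight_matrix.item() == 0.0
        assert pathway_laplacian(pw).matrix.item() == 0.0

    def test_duplicate_member_deduplicated_with_warning(self, tmp_path):
        gmt = tmp_path / "sets.gmt"
        gmt.write_text("pw2\tdesc\tg1\tg1\tg2\n")
        with pytest.warns(UserWarning, match="duplicate"):
            (pw,) = load_pathways(gmt)
        assert pw.size == 2

    def test_empty_line_skipped_with_warning(self, tmp_path):
        gmt = tmp_path / "sets.gmt"
        gmt.write_text("pw1\tdesc\tg1\tg2\n\npw2\tdesc\tg3\tg4\n")
        with pytest.warns(UserWarning, match="empty"):
            pws = load_pathways(gmt)
        assert [p.pathway_id for p in pws] == ["pw1", "pw2"]

    def test_edge_list_policy(self, tmp_path):
        gmt = tmp_path / "sets.gmt"
        gmt.write_text("pwA\tdesc\tg1\tg2\tg3\n")
        edge_dir = tmp_path / "edges"
        edge_dir.mkdir()
        (edge_dir / "pwA.tsv").write_text("g1\tg2\t2.5\n")
        (pw,) = load_pathways(gmt, edge_weight_policy="external-edge-list", edge_dir=edge_dir)
        assert pw.weight_matrix[0, 1] == 2.5
        assert pw.weight_matrix[2].sum() == 0          # g3 isolated

    def test_missing_edge_file_errors(self, tmp_path):
        gmt = tmp_path / "sets.gmt"
        gmt.write_text("pwB\tdesc\tg1\tg2\n")
        with pytest.raises(FileNotFoundError, match="pwB"):
            load_pathways(gmt, edge_weight_policy="external-edge-list", edge_dir=tmp_path)


class TestLaplacianIO:
    def test_round_trip(self, tmp_path):
        lap = normalized_laplacian(TRIANGLE, pathway_id="tri", node_names=["a", "b", "c"])
        path = tmp_path / "tri.tsv"
        write_laplacian_matrix(lap, path)
        back = load_laplacian_matrix(path)
        assert back.node_names == ["a", "b", "c"]
        assert np.allclose(back.matrix, lap.matrix, atol=1e-12)
        assert back.kind == "normalized"

    def test_valid_two_node_laplacian(self, tmp_path):
        path = tmp_path / "l.tsv"
        path.write_text("\tg1\tg2\ng1\t1\t-1\ng2\t-1\t1\n")
        lap = load_laplacian_matrix(path)
        assert lap.size == 2

    def test_asymmetric_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("\tg1\tg2\ng1\t1\t0\ng2\t1\t1\n")
        with pytest.raises(ValueError, match="asymmetric"):
            load_laplacian_matrix(path)

    def test_indefinite_rejected(self, tmp_path):
        path = tmp_path / "neg.tsv"
        path.write_text("\tg1\tg2\ng1\t0\t1\ng2\t1\t0\n")
        with pytest.raises(ValueError, match="eigenvalue"):
            load_laplacian_matrix(path)

    def test_unnormalized_kind_inferred(self, tmp_path):
        # star with 4 leaves: unnormalized Laplacian has an eigenvalue 5 > 2
        W = np.zeros((5, 5))
        W[0, 1:] = W[1:, 0] = 1.0
        lap = unnormalized_laplacian(W, pathway_id="star")
        path = tmp_path / "star.tsv"
        write_laplacian_matrix(lap, path)
        assert load_laplacian_matrix(path).kind == "unnormalized"


class TestRestriction:
    def setup_method(self):
        self.features = ["g1", "g2", "g3", "g4", "g5"]
        self.X = np.arange(15, dtype=float).reshape(3, 5)

    def test_column_selection_in_pathway_order(self):
        pw = PathwaySubnetwork("pw", ["g4", "g2"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        Xr, _ = restrict_to_pathway(self.X, self.features, pw)
        assert np.array_equal(Xr, self.X[:, [3, 1]])

    def test_zero_fill_missing_node(self):
        pw = PathwaySubnetwork("pw", ["g2", "g4", "g9"], np.zeros((3, 3)))
        Xr, out = restrict_to_pathway(self.X, self.features, pw)
        assert np.array_equal(Xr[:, 2], np.zeros(3))
        assert out is pw

    def test_drop_node_reduces_pathway(self):
        W = np.ones((3, 3)) - np.eye(3)
        pw = PathwaySubnetwork("pw", ["g2", "g9", "g4"], W)
        Xr, reduced = restrict_to_pathway(self.X, self.features, pw,
                                          missing_policy="drop-node")
        assert reduced.node_names == ["g2", "g4"]
        assert Xr.shape == (3, 2)
        assert reduced.weight_matrix.shape == (2, 2)

    def test_drop_node_on_precomputed_laplacian(self):
        lap = LaplacianMatrix("pw", ["g2", "g9"], np.array([[1.0, -1.0], [-1.0, 1.0]]))
        Xr, reduced = restrict_to_pathway(self.X, self.features, lap,
                                          missing_policy="drop-node")
        assert reduced.node_names == ["g2"] and reduced.matrix.shape == (1, 1)

    def test_permutation_invariance_and_idempotence(self):
        pw = PathwaySubnetwork("pw", ["g5", "g1", "g3"], np.zeros((3, 3)))
        Xr, _ = restrict_to_pathway(self.X, self.features, pw)
        rng = np.random.default_rng(4)
        perm = rng.permutation(5)
        Xp, _ = restrict_to_pathway(self.X[:, perm],
                                    [self.features[i] for i in perm], pw)
        assert np.array_equal(Xr, Xp)
        # idempotent: restricting the restricted matrix changes nothing
        Xrr, _ = restrict_to_pathway(Xr, pw.node_names, pw)
        assert np.array_equal(Xr, Xrr)

    def test_zero_overlap_names_pathway(self):
        pw = PathwaySubnetwork("orphan", ["h1", "h2"], np.zeros((2, 2)))
        with pytest.raises(ValueError, match="orphan"):
            restrict_to_pathway(self.X, self.features, pw)

    def test_build_restriction_apply_matches(self):
        restr = build_restriction(self.features, ["g4", "g9", "g2"])
        out = restr.apply(self.X)
        assert np.array_equal(out[:, 0], self.X[:, 3])
        assert np.array_equal(out[:, 1], np.zeros(3))
        assert np.array_equal(out[:, 2], self.X[:, 1])
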