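import numpy as np
import pytest

from braincontrol import network_model as nm
from braincontrol.network_model import (BinaryDirectedNetwork,
                                        NetworkFormatError, WeightedNetwork,
                                        bidirect, binarize, properties,
                                        read_network, remove_isolated,
                                        write_network)

from conftest import make_net


class TestIO:
    def test_matrix_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        w = rng.random((9, 9)) * (rng.random((9, 9)) < 0.3)
        np.fill_diagonal(w, 0)
        net = WeightedNetwork(w, labels=[f"R{i}" for i in range(9)])
        path = tmp_path / "net.csv"
        write_network(net, path)
        back = read_network(path)
        assert np.allclose(back.weights, w)
        assert back.labels == net.labels

    def test_edgelist_round_trip(self, tmp_path):
        path = tmp_path / "net.tsv"
        path.write_text("A\tB\t2.5\n")
        net = read_network(path, format="edgelist")
        assert net.n_nodes == 2
        assert net.labels == ["A", "B"]
        # i -> j stored at weights[j, i]
        i, j = net.labels.index("A"), net.labels.index("B")
        assert net.weights[j, i] == 2.5
        out = tmp_path / "out.tsv"
        write_network(net, out)
        assert np.allclose(read_network(out).weights, net.weights)

    def test_empty_matrix_reads_as_zero_links(self, tmp_path):
        path = tmp_path / "z.csv"
        write_network(WeightedNetwork(np.zeros((5, 5))), path)
        net = read_network(path)
        assert net.n_nodes == 5 and not net.weights.any()

    def test_binary_round_trip_exact(self, tmp_path):
        rng = np.random.default_rng(3)
        a = (rng.random((12, 12)) < 0.2).astype(np.int8)
        np.fill_diagonal(a, 0)
        net = BinaryDirectedNetwork(a)
        path = tmp_path / "b.csv"
        write_network(net, path)
        assert np.array_equal(binarize(read_network(path)).adjacency, a)

    @pytest.mark.parametrize("content,err", [
        ("1,2,3\n4,5,6\n", "square"),
        ("0,-1\n0,0\n", "negative"),
    ])
    def test_malformed_matrix_rejected(self, tmp_path, content, err):
        path = tmp_path / "bad.csv"
        path.write_text(content)
        with pytest.raises(NetworkFormatError, match=err):
            read_network(path)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(NetworkFormatError, match="duplicate"):
            WeightedNetwork(np.zeros((2, 2)), labels=["A", "A"])


class TestConstruction:
    def test_binarize_thresholds_positive_weights(self):
        w = np.array([[0, 0.3], [7.1, 0]])
        assert np.array_equal(binarize(WeightedNetwork(w)).adjacency,
                              [[0, 1], [1, 0]])

    def test_binarize_zeroes_diagonal_with_warning(self):
        w = np.eye(3) * 2.0
        with pytest.warns(UserWarning, match="self-loop"):
            b = binarize(WeightedNetwork(w))
        assert not b.adjacency.any()

    def test_binarize_preserves_symmetry(self):
        rng = np.random.default_rng(1)
        w = rng.random((8, 8)) * (rng.random((8, 8)) < 0.4)
        w = w + w.T
        np.fill_diagonal(w, 0)
        assert binarize(WeightedNetwork(w)).is_symmetric

    def test_bidirect_creates_both_directions_and_is_idempotent(self):
        net = make_net([(0, 1)], 2)
        bi = bidirect(net)
        assert bi.adjacency[1, 0] == bi.adjacency[0, 1] == 1
        assert np.array_equal(bidirect(bi).adjacency, bi.adjacency)
        empty = BinaryDirectedNetwork(np.zeros((3, 3), dtype=np.int8))
        assert not bidirect(empty).adjacency.any()

    def test_remove_isolated(self):
        a = np.zeros((4, 4), dtype=np.int8)
        a[0, 1] = a[1, 0] = 1
        net = BinaryDirectedNetwork(a, labels=list("WXYZ"))
        sub, removed = remove_isolated(net)
        assert removed == ["Y", "Z"]
        assert sub.n_nodes == 2 and sub.labels == ["W", "X"]
        # adjacency restricted to survivors is unchanged
        assert np.array_equal(sub.adjacency, a[:2, :2])

    def test_remove_isolated_noop_and_degenerate(self):
        net = make_net([(0, 1), (1, 0)], 2)
        same, removed = remove_isolated(net)
        assert removed == [] and np.array_equal(same.adjacency, net.adjacency)
        alliso = BinaryDirectedNetwork(np.zeros((3, 3), dtype=np.int8))
        emptied, gone = remove_isolated(alliso)
        assert emptied.n_nodes == 0 and len(gone) == 3


class TestProperties:
    def test_regular_network_has_zero_heterogeneity(self):
        # directed 5-cycle: all in/out degrees equal 1
        net = make_net([(i, (i + 1) % 5) for i in range(5)], 5)
        assert nm.heterogeneity(net) == 0.0

    def test_toy_mean_degree(self, toy):
        assert properties(toy).mean_degree == pytest.approx(4 / 5)

    def test_star_heterogeneity_matches_double_sum_oracle(self):
        net = make_net([(0, 1), (0, 2), (0, 3)], 4)  # center -> 3 leaves
        for r in (1.0, 2.5):
            got = nm.heterogeneity(net, r_const=r)

            def brute(k):
                return sum(abs(int(a) - int(b)) for a in k for b in k) \
                    / (r * len(k) ** 2)

            assert got == pytest.approx(
                max(brute(net.in_degrees), brute(net.out_degrees)))

    def test_symmetric_network_has_equal_in_out_degrees(self):
        rng = np.random.default_rng(5)
        a = (rng.random((10, 10)) < 0.3).astype(np.int8)
        a = ((a + a.T) > 0).astype(np.int8)
        np.fill_diagonal(a, 0)
        net = BinaryDirectedNetwork(a)
        assert np.array_equal(net.in_degrees, net.out_degrees)

    def test_mean_distance_complete_and_cycle(self):
        n = 6
        complete = BinaryDirectedNetwork(
            (np.ones((n, n)) - np.eye(n)).astype(np.int8))
        assert properties(complete).mean_distance == pytest.approx(1.0)
        cycle = make_net([(i, (i + 1) % n) for i in range(n)], n)
        assert properties(cycle).mean_distance == pytest.approx(n / 2)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            properties(BinaryDirectedNetwork(np.zeros((0, 0), dtype=np.int8)))

    def test_isolated_nodes_reported(self):
        a = np.zeros((3, 3), dtype=np.int8)
        a[0, 1] = a[1, 0] = 1
        p = properties(BinaryDirectedNetwork(a, labels=["a", "b", "iso"]))
        assert p.isolated_nodes == ["iso"]
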