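import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from epinet.network_model import (
    BipartiteNetwork, NetworkError, NetworkMetadata, binarize, network_size,
    prune_empty, read_manifest, read_network, write_network,
)


@pytest.fixture
def toy_net():
    return BipartiteNetwork(("h1", "h2"), ("e1", "e2"),
                            np.array([[4.0, 2.0], [2.0, 1.0]]))


class TestReadNetwork:
    def test_matrix_csv_parses_counts_and_total(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(",e1,e2\nh1,4,2\nh2,2,1\n")
        net = read_network(p)
        assert net.row_labels == ("h1", "h2")
        assert net.col_labels == ("e1", "e2")
        assert net.total == 9

    def test_edge_list_duplicates_are_summed(self, tmp_path):
        p = tmp_path / "e.csv"
        p.write_text("row_label,col_label,count\nh1,e1,3\nh1,e1,2\nh2,e2,1\n")
        net = read_network(p, format="edge_list")
        assert net.to_frame().loc["h1", "e1"] == 5

    def test_zero_row_parses_but_is_flagged_for_pruning(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(",e1,e2\nh1,1,2\nh2,0,0\nh3,3,1\n")
        net = read_network(p)
        assert net.has_empty_margins()

    @pytest.mark.parametrize("body,fragment", [
        (",e1,e2\nh1,-1,2\nh2,2,1\n", "negative"),
        (",e1,e2\nh1,x,2\nh2,2,1\n", "non-numeric"),
        ("", "empty"),
    ])
    def test_malformed_inputs_rejected_with_reason(self, tmp_path, body, fragment):
        p = tmp_path / "bad.csv"
        p.write_text(body)
        with pytest.raises(NetworkError, match=fragment):
            read_network(p)

    def test_negative_error_names_the_cell(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(",e1,e2\nh1,4,2\nh2,2,-3\n")
        with pytest.raises(NetworkError, match="h2.*e2"):
            read_network(p)

    def test_noninteger_counts_need_explicit_opt_in(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(",e1,e2\nh1,1.5,2\nh2,2,1\n")
        with pytest.raises(NetworkError, match="non-integer"):
            read_network(p)
        net = read_network(p, allow_noninteger=True)
        assert net.total == pytest.approx(6.5)

    @pytest.mark.parametrize("format", ["matrix_csv", "edge_list"])
    def test_round_trip(self, tmp_path, toy_net, format):
        p = tmp_path / "net.csv"
        write_network(toy_net, p, format=format)
        back = read_network(p, format=format)
        assert back.row_labels == toy_net.row_labels
        assert back.col_labels == toy_net.col_labels
        np.testing.assert_array_equal(back.weights, toy_net.weights)


class TestInvariants:
    def test_duplicate_labels_rejected(self):
        with pytest.raises(NetworkError, match="unique"):
            BipartiteNetwork(("a", "a"), ("x", "y"), np.ones((2, 2)))

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(NetworkError, match="no interactions"):
            BipartiteNetwork(("a", "b"), ("x", "y"), np.zeros((2, 2)))

    def test_unknown_interaction_type_rejected(self):
        with pytest.raises(NetworkError):
            NetworkMetadata(interaction_type="XX")


class TestPrune:
    def test_drops_zero_row(self):
        net = BipartiteNetwork(
            ("a", "b", "c"), ("x", "y", "z"),
            np.array([[1, 0, 2], [0, 0, 0], [3, 1, 0]], dtype=float))
        pruned = prune_empty(net)
        assert pruned.row_labels == ("a", "c")
        assert pruned.weights.shape == (2, 3)

    def test_identity_when_no_empty_margins(self, toy_net):
        pruned = prune_empty(toy_net)
        np.testing.assert_array_equal(pruned.weights, toy_net.weights)

    def test_idempotent_on_random_matrices(self, rng):
        for _ in range(30):
            w = rng.integers(0, 3, size=(5, 6)).astype(float)
            if w.sum() == 0:
                continue
            net = BipartiteNetwork(
                tuple(f"r{i}" for i in range(5)),
                tuple(f"c{j}" for j in range(6)), w)
            try:
                once = prune_empty(net)
            except NetworkError:
                continue  # degenerate after pruning
            twice = prune_empty(once)
            assert once.row_labels == twice.row_labels
            np.testing.assert_array_equal(once.weights, twice.weights)
            assert network_size(once) <= network_size(net)

    def test_degenerate_result_rejected(self):
        net = BipartiteNetwork(("a", "b"), ("x", "y"),
                               np.array([[1.0, 0.0], [0.0, 0.0]]))
        with pytest.raises(NetworkError, match="degenerate"):
            prune_empty(net)


def test_binarize_thresholds_positive_counts(toy_net):
    np.testing.assert_array_equal(binarize(toy_net), np.ones((2, 2), dtype=int))
    np.testing.assert_array_equal(
        binarize(np.array([[2, 0], [0, 3]])), np.eye(2, dtype=int))


def test_network_size_sums_both_guilds(toy_net):
    assert network_size(toy_net) == 4
    big = BipartiteNetwork(
        tuple(f"r{i}" for i in range(10)), tuple(f"c{j}" for j in range(6)),
        np.ones((10, 6)))
    assert network_size(big) == 16


@settings(max_examples=60, deadline=None, derandomize=True)
@given(arrays(np.int64, (4, 5), elements=st.integers(0, 5)))
def test_round_trip_and_prune_properties(w):
    """Write/read round-trips exactly and pruning is idempotent for any
    small integer matrix with at least one interaction."""
    import tempfile
    from pathlib import Path

    if w.sum() == 0:
        return
    net = BipartiteNetwork(tuple(f"r{i}" for i in range(4)),
                           tuple(f"c{j}" for j in range(5)),
                           w.astype(float))
    with tempfile.TemporaryDirectory() as td:
        for fmt in ("matrix_csv", "edge_list"):
            p = Path(td) / f"n.{fmt}"
            write_network(net, p, format=fmt)
            back = read_network(p, format=fmt)
            if fmt == "matrix_csv":
                np.testing.assert_array_equal(back.weights, net.weights)
            else:  # edge lists only carry positive cells
                np.testing.assert_array_equal(
                    back.to_frame().reindex(
                        index=net.row_labels, columns=net.col_labels,
                        fill_value=0).to_numpy(),
                    net.weights)
    try:
        once = prune_empty(net)
    except NetworkError:
        return  # degenerate after pruning
    twice = prune_empty(once)
    np.testing.assert_array_equal(once.weights, twice.weights)
    assert network_size(once) <= network_size(net)


class TestManifest:
    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "man.tsv"
        p.write_text("network_id\tpath\nn1\tx.csv\n")
        with pytest.raises(NetworkError, match="missing columns"):
            read_manifest(p)

    def test_reads_required_fields(self, tmp_path):
        p = tmp_path / "man.tsv"
        p.write_text("network_id\tpath\tinteraction_type\tlocality\n"
                     "n1\tx.csv\tEP\tloc1\n")
        df = read_manifest(p)
        assert list(df["network_id"]) == ["n1"]
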