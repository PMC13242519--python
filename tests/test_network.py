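import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grnloop import network as net


def path_exists_bruteforce(mask: np.ndarray, i: int, j: int) -> bool:
    """Exhaustive path check (>=1 edge) by boolean matrix powers."""
    n = mask.shape[0]
    reach = mask.copy()
    power = mask.copy()
    for _ in range(n - 1):
        power = (power @ mask) > 0
        reach |= power
    return bool(reach[i, j])


def prune_oracle(adj: net.SignedAdjacency) -> net.SignedAdjacency:
    """Independent re-statement of the pruning rule via path enumeration."""
    m = adj.matrix.copy()
    out = m.copy()
    for weight, direct in ((2, 1), (-2, -1)):
        mask = m == direct
        for i, j in zip(*np.nonzero(m == weight)):
            if path_exists_bruteforce(mask, i, j):
                out[i, j] = 0
    return net.SignedAdjacency(adj.genes, out)


def random_adjacency(rng, n_nodes=5, max_edges=8):
    genes = tuple(sorted(f"N{i}" for i in range(n_nodes)))
    m = np.zeros((n_nodes, n_nodes), dtype=int)
    n_edges = rng.integers(0, max_edges + 1)
    for _ in range(n_edges):
        i, j = rng.integers(0, n_nodes, size=2)
        m[i, j] = rng.choice([-2, -1, 1, 2])
    return net.SignedAdjacency(genes, m)


class TestEnumeratePairs:
    def test_two_genes_give_four_ordered_pairs(self):
        pairs = net.enumerate_pairs(["A", "B"])
        assert set(pairs) == {("A", "B"), ("B", "A"), ("A", "A"), ("B", "B")}

    def test_single_gene_self_pair(self):
        assert net.enumerate_pairs(["X"]) == [("X", "X")]

    @pytest.mark.parametrize("n", [3, 5])
    def test_cardinality_is_n_squared(self, n):
        genes = [f"G{i}" for i in range(n)]
        pairs = net.enumerate_pairs(genes)
        assert len(pairs) == n * n
        assert set(pairs) == {(a, b) for a in genes for b in genes}


class TestEnumerateBackloopPairs:
    def test_cardinality_2n_plus_1(self):
        pairs = net.enumerate_backloop_pairs("R", ["A", "B", "C"])
        assert len(pairs) == 7

    def test_empty_network_gives_self_pair_only(self):
        assert net.enumerate_backloop_pairs("R", []) == [("R", "R")]

    def test_set_equality_with_definition(self):
        genes = ["B", "D", "A"]
        pairs = set(net.enumerate_backloop_pairs("R", genes))
        expected = {("R", g) for g in genes} | {(g, "R") for g in genes} \
            | {("R", "R")}
        assert pairs == expected

    def test_regulator_already_present_is_an_error(self):
        with pytest.raises(ValueError):
            net.enumerate_backloop_pairs("A", ["A", "B"])


class TestBuildAdjacency:
    def test_single_verdict(self):
        adj = net.build_adjacency([("A", "B", 1)])
        assert adj.genes == ("A", "B")
        assert adj.weight("A", "B") == 1
        assert adj.n_edges() == 1

    def test_empty_verdicts_with_declared_genes(self):
        adj = net.build_adjacency([], genes=["B", "A"])
        assert adj.genes == ("A", "B")
        assert adj.n_edges() == 0

    def test_order_invariance(self):
        rows = [("A", "B", 1), ("B", "C", -2), ("C", "A", 2), ("A", "A", -1)]
        a = net.build_adjacency(rows)
        b = net.build_adjacency(rows[::-1])
        assert a == b

    def test_conflicting_duplicates_fail_loudly(self):
        with pytest.raises(net.VerdictConflictError):
            net.build_adjacency([("A", "B", 1), ("A", "B", -1)])

    def test_out_of_alphabet_value_rejected(self):
        with pytest.raises(ValueError):
            net.build_adjacency([("A", "B", 3)])


class TestPruneRedundant:
    def test_direct_activation_path_removes_indirect(self):
        adj = net.build_adjacency([("A", "B", 1), ("B", "C", 1), ("A", "C", 2)])
        out = net.prune_redundant(adj)
        assert out.weight("A", "C") == 0
        assert out.weight("A", "B") == 1 and out.weight("B", "C") == 1

    def test_mixed_sign_path_does_not_qualify(self):
        adj = net.build_adjacency([("A", "B", 1), ("B", "C", -1),
                                   ("A", "C", -2)])
        assert net.prune_redundant(adj) == adj

    def test_no_indirect_edges_is_identity(self):
        adj = net.build_adjacency([("A", "B", 1), ("B", "A", -1)])
        assert net.prune_redundant(adj) == adj

    def test_inhibition_only_path_removes_indirect_inhibition(self):
        adj = net.build_adjacency([("A", "B", -1), ("B", "C", -1),
                                   ("A", "C", -2)])
        out = net.prune_redundant(adj)
        assert out.weight("A", "C") == 0

    def test_self_loop_removed_only_via_direct_cycle(self):
        cyc = net.build_adjacency([("A", "B", 1), ("B", "A", 1), ("A", "A", 2)])
        assert net.prune_redundant(cyc).weight("A", "A") == 0
        no_cyc = net.build_adjacency([("A", "B", 1), ("A", "A", 2)])
        assert net.prune_redundant(no_cyc).weight("A", "A") == 2

    def test_simultaneous_removal_uses_input_reachability(self):
        # the +2 chain edges cover each other only through +1 edges that
        # remain; both indirect edges must vanish together
        adj = net.build_adjacency([("A", "B", 1), ("B", "C", 1),
                                   ("C", "D", 1), ("A", "C", 2),
                                   ("B", "D", 2)])
        out = net.prune_redundant(adj)
        assert out.weight("A", "C") == 0 and out.weight("B", "D") == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(60):
            adj = random_adjacency(rng)
            assert net.prune_redundant(adj) == prune_oracle(adj)

    @pytest.mark.parametrize("seed", range(3))
    def test_idempotent_and_conservative(self, seed):
        rng = np.random.default_rng(100 + seed)
        for _ in range(40):
            adj = random_adjacency(rng)
            once = net.prune_redundant(adj)
            assert net.prune_redundant(once) == once
            direct = np.abs(adj.matrix) == 1
            np.testing.assert_array_equal(once.matrix[direct],
                                          adj.matrix[direct])
            created = (once.matrix != 0) & (adj.matrix == 0)
            assert not created.any()


class TestExtendAdjacency:
    def test_new_gene_block_preserves_base(self):
        base = net.build_adjacency([("A", "B", 1)])
        out = net.extend_adjacency(base, [("C", "A", 1)])
        assert out.genes == ("A", "B", "C")
        assert out.weight("A", "B") == 1 and out.weight("C", "A") == 1

    def test_empty_verdicts_identity(self):
        base = net.build_adjacency([("A", "B", -2)])
        assert net.extend_adjacency(base, []) == base

    def test_conflict_with_baseline_raises(self):
        base = net.build_adjacency([("A", "B", 1)])
        with pytest.raises(net.VerdictConflictError):
            net.extend_adjacency(base, [("A", "B", -1)])

    def test_matches_dictionary_merge_oracle(self):
        rng = np.random.default_rng(9)
        base = random_adjacency(rng, n_nodes=4, max_edges=5)
        new = [("X1", g, int(rng.choice([-1, 1]))) for g in base.genes]
        out = net.extend_adjacency(base, new)
        merged = {(s, t): w for s, t, w in base.edges()}
        merged.update({(s, t): w for s, t, w in new})
        assert {(s, t): w for s, t, w in out.edges()} == \
               {k: v for k, v in merged.items() if v != 0}


class TestTopologyExport:
    def test_sign_mapping(self):
        adj = net.build_adjacency([("A", "B", -2)])
        edges = net.to_edge_list(adj)
        row = edges.iloc[0]
        assert (row["source"], row["sign"], row["target"]) == ("A", "-", "B")

    def test_zero_matrix_gives_empty_edges_full_gene_column(self):
        adj = net.build_adjacency([], genes=["A", "B", "C"])
        edges = net.to_edge_list(adj)
        assert (edges["source"] == "").all()
        assert list(edges["gene"]) == ["A", "B", "C"]

    @pytest.mark.parametrize("seed", range(4))
    def test_graphml_round_trip(self, seed):
        rng = np.random.default_rng(200 + seed)
        adj = random_adjacency(rng)
        doc = net.to_graphml(adj)
        assert net.from_graphml(doc) == adj

    def test_export_topology_writes_files(self, tmp_path):
        adj = net.build_adjacency([("A", "B", 1), ("B", "A", -1)])
        edge_csv = tmp_path / "topo.csv"
        graphml = tmp_path / "topo.graphml"
        net.export_topology(adj, edge_csv=edge_csv, graphml_path=graphml)
        assert edge_csv.exists() and graphml.exists()


class TestAdjacencyCSV:
    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(33)
        adj = random_adjacency(rng)
        path = tmp_path / "adj.csv"
        adj.to_csv(path)
        assert net.SignedAdjacency.from_csv(path) == adj

    def test_unsorted_genes_rejected(self):
        with pytest.raises(ValueError):
            net.SignedAdjacency(("B", "A"), np.zeros((2, 2), dtype=int))

    def test_out_of_alphabet_weight_rejected(self):
        with pytest.raises(ValueError):
            net.SignedAdjacency(("A", "B"), np.array([[0, 3], [0, 0]]))


@given(st.integers(0, 2 ** 20))
@settings(max_examples=60, deadline=None)
def test_prune_oracle_agreement_fuzzed(seed):
    """Sampled signed digraphs (<=5 nodes, <=8 edges): pruning == oracle."""
    rng = np.random.default_rng(seed)
    adj = random_adjacency(rng)
    assert net.prune_redundant(adj) == prune_oracle(adj)
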