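import numpy as np
import pandas as pd
import pytest

from syndromirnet import (build_weighted_network, compare_networks, extract_hubs,
                          up_subnetwork)
from syndromirnet.consensus import ConsensusTargetSet
from syndromirnet.network import (WeightedBipartiteNetwork, write_edge_list,
                                  write_graphml)


def _de_table(rows):
    """rows: (mirna, log2fc, significant)"""
    return pd.DataFrame(
        {
            "mean_case": 0.0,
            "mean_control": 0.0,
            "log2fc": [r[1] for r in rows],
            "t": 0.0,
            "df": 10.0,
            "p": 0.001,
            "significant": [r[2] for r in rows],
            "direction": [("up" if r[1] >= 0 else "down") for r in rows],
        },
        index=pd.Index([r[0] for r in rows], name="mirna_id"),
    )


def _cts(targets):
    return ConsensusTargetSet(data_a={}, data_b={}, consensus=targets,
                              validated_added={})


def test_hand_counted_network():
    de = _de_table([("m1", 1.2, True), ("m2", -0.8, True)])
    net = build_weighted_network(_cts({"m1": {"g1", "g2"}, "m2": {"g2"}}), de)
    assert net.n_edges == 3
    assert net.weight("g2") == 2 and net.weight("g1") == 1
    assert net.weight("m1") == pytest.approx(1.2)   # |log2fc|
    assert net.weight("m2") == pytest.approx(0.8)
    assert sum(net.graph.degree(n) for n in net.mirna_nodes) == 3
    net.check_invariants()


def test_only_significant_mirnas_enter():
    de = _de_table([("m1", 2.0, True), ("m2", 2.0, False)])
    net = build_weighted_network(_cts({"m1": {"g1"}, "m2": {"g2"}}), de)
    assert net.mirna_nodes == {"m1"}


def test_empty_consensus_gives_valid_empty_network():
    net = build_weighted_network(_cts({}), _de_table([("m1", 1.0, True)]))
    assert net.n_edges == 0 and not net.mirna_nodes
    net.check_invariants()


def test_missing_de_record_rejected():
    with pytest.raises(KeyError, match="m2"):
        build_weighted_network(_cts({"m2": {"g1"}}),
                               _de_table([("m1", 1.0, True)]))


def _random_network(rng, n_mirnas=12, n_genes=30):
    rows = [(f"m{i}", float(rng.uniform(-3, 3)), True) for i in range(n_mirnas)]
    targets = {f"m{i}": set(rng.choice([f"g{j}" for j in range(n_genes)],
                                       size=rng.integers(1, 9), replace=False))
               for i in range(n_mirnas)}
    return build_weighted_network(_cts(targets), _de_table(rows))


def test_invariants_on_random_networks():
    rng = np.random.default_rng(8)
    for _ in range(100):
        net = _random_network(rng)
        net.check_invariants()  # bipartite, gene weight == degree, degree sums
        assert sum(net.graph.degree(n) for n in net.gene_nodes) == net.n_edges


def test_hub_extraction_star_and_empty():
    de = _de_table([("m1", 1.0, True), ("m2", 1.0, True)])
    targets = {"m1": {f"g{i}" for i in range(6)}, "m2": {"g0"}}
    net = build_weighted_network(_cts(targets), de)
    hubs = extract_hubs(net, min_degree=5)
    assert "m1" in hubs.mirna_nodes
    assert "m2" not in hubs.mirna_nodes
    none = extract_hubs(net, min_degree=50)
    assert not set(none.graph.nodes)


def test_hub_nodes_qualify_in_parent_and_idempotence():
    rng = np.random.default_rng(3)
    for _ in range(20):
        net = _random_network(rng)
        hubs = extract_hubs(net, min_degree=5)
        # every node kept either qualifies in the parent or rides along as an
        # endpoint of a hub's edge
        for n in hubs.graph:
            qualifies = net.graph.degree(n) >= 5
            touches_hub = any(net.graph.degree(nb) >= 5
                              for nb in hubs.graph.neighbors(n))
            assert qualifies or touches_hub
        twice = extract_hubs(hubs, min_degree=5)
        again = extract_hubs(twice, min_degree=5)
        assert set(twice.graph.nodes) == set(again.graph.nodes)
        assert ({frozenset(e) for e in twice.graph.edges}
                == {frozenset(e) for e in again.graph.edges})


def test_up_subnetwork_fraction():
    rows = [(f"m{i}", 1.0 if i < 3 else -1.0, True) for i in range(8)]
    targets = {f"m{i}": {f"g{i}"} for i in range(8)}
    net = build_weighted_network(_cts(targets), _de_table(rows))
    sub, frac = up_subnetwork(net)
    assert frac == 37.5
    assert sub.mirna_nodes == {"m0", "m1", "m2"}
    none_up = build_weighted_network(
        _cts({"m0": {"g0"}}), _de_table([("m0", -1.0, True)]))
    sub2, frac2 = up_subnetwork(none_up)
    assert frac2 == 0.0 and not set(sub2.graph.nodes)


def test_up_fraction_binomial_bound():
    """Planted 50/50 directions at 400 DE miRNAs land near 50%."""
    from syndromirnet import SimulationConfig, differential_mirnas, simulate_expression

    cfg = SimulationConfig(n_mirnas=400, n_genes=10,
                           group_sizes={"Normal": 7, "LGDHS": 3},
                           n_de_per_group=400, de_log2fc=3.0, seed=21)
    m, _ = simulate_expression(cfg)
    de = differential_mirnas(m, "LGDHS", "Normal")
    targets = {mid: {"gX"} for mid in de.index[de["significant"]]}
    net = build_weighted_network(_cts(targets), de)
    _, frac = up_subnetwork(net)
    assert abs(frac - 50.0) <= 6.0


def test_compare_identical_networks():
    net = _random_network(np.random.default_rng(5))
    cmp_res = compare_networks(net, net, n_perm=500, seed=0)
    assert cmp_res.computable
    assert cmp_res.rank_correlation == pytest.approx(1.0)
    assert cmp_res.shared_mirnas == net.mirna_nodes
    assert all(d == 0.0 for _, d in cmp_res.deregulated)


def test_compare_disjoint_networks_not_computable():
    a = build_weighted_network(_cts({"m1": {"g1"}}), _de_table([("m1", 1.0, True)]))
    b = build_weighted_network(_cts({"m2": {"g2"}}), _de_table([("m2", 1.0, True)]))
    cmp_res = compare_networks(a, b, n_perm=100, seed=0)
    assert not cmp_res.computable
    assert cmp_res.rank_correlation is None
    assert cmp_res.shared_nodes == set()


def test_compare_rank_reversed_weights():
    """Exactly reversed weight ranks give rho = -1 and an extreme p."""
    import networkx as nx

    n_shared = 20
    n_perm = 2000
    gA, gB = nx.Graph(), nx.Graph()
    for i in range(n_shared):
        gA.add_node(f"m{i}", kind="mirna", weight=float(i + 1), direction="up")
        gB.add_node(f"m{i}", kind="mirna", weight=float(n_shared - i), direction="up")
    netA = WeightedBipartiteNetwork(graph=gA)
    netB = WeightedBipartiteNetwork(graph=gB)
    cmp_res = compare_networks(netA, netB, n_perm=n_perm, seed=1)
    assert cmp_res.rank_correlation == pytest.approx(-1.0)
    assert cmp_res.permutation_p <= 2 / (n_perm + 1)


def test_overlap_symmetry():
    rng = np.random.default_rng(6)
    a, b = _random_network(rng), _random_network(rng)
    ab = compare_networks(a, b, n_perm=50, seed=0)
    ba = compare_networks(b, a, n_perm=50, seed=0)
    assert ab.shared_mirnas == ba.shared_mirnas
    assert ab.shared_nodes == ba.shared_nodes


def test_exports_are_text(tmp_path):
    net = _random_network(np.random.default_rng(9))
    write_edge_list(net, tmp_path / "edges.tsv")
    write_graphml(net, tmp_path / "net.graphml")
    assert (tmp_path / "edges.tsv").read_text().startswith("mirna_id")
    assert "<graphml" in (tmp_path / "net.graphml").read_text()
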