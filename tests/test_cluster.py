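import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from syndromirnet import average_linkage, correlation_distance, to_newick
from syndromirnet.cluster import Dendrogram


def _dist(arr, labels):
    return pd.DataFrame(arr, index=labels, columns=labels)


def test_correlation_distance_extremes():
    df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8],
                       "c": [4.0, 3, 2, 1]}).T
    d = correlation_distance(df, axis="rows")
    assert d.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)   # identical direction
    assert d.loc["a", "c"] == pytest.approx(2.0, abs=1e-12)   # exact anti-correlation


def test_correlation_distance_symmetry_and_diagonal():
    rng = np.random.default_rng(2)
    df = pd.DataFrame(rng.normal(size=(20, 6)),
                      index=[f"r{i}" for i in range(20)])
    d = correlation_distance(df, axis="rows")
    np.testing.assert_allclose(d.values, d.values.T, atol=1e-12)
    np.testing.assert_allclose(np.diag(d.values), 0.0, atol=1e-12)
    assert (d.values >= -1e-12).all() and (d.values <= 2 + 1e-12).all()


def test_correlation_distance_constant_vector_named():
    df = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
    with pytest.raises(ValueError, match="flat"):
        correlation_distance(df, axis="rows")


def test_three_point_hand_agglomeration():
    d = _dist([[0, 1, 4], [1, 0, 4], [4, 4, 0]], list("ABC"))
    dend = average_linkage(d)
    (l1, r1, h1, _), (_, _, h2, _) = dend.merges
    assert {dend.labels[l1], dend.labels[r1]} == {"A", "B"}
    assert h1 == pytest.approx(1.0)
    assert h2 == pytest.approx(4.0)
    assert dend.leaf_order == ["A", "B", "C"]


def test_two_points_single_merge():
    d = _dist([[0, 0.3], [0.3, 0]], ["x", "y"])
    dend = average_linkage(d)
    assert len(dend.merges) == 1
    assert dend.heights[0] == pytest.approx(0.3)


def test_merge_heights_match_direct_mean_distance():
    """Every merge height equals the mean original-pair distance between the
    two merged leaf sets, and heights agree with scipy's UPGMA."""
    rng = np.random.default_rng(7)
    for _ in range(50):
        arr = rng.uniform(0.1, 2.0, size=(8, 8))
        arr = (arr + arr.T) / 2
        np.fill_diagonal(arr, 0.0)
        labels = [f"p{i}" for i in range(8)]
        d = _dist(arr, labels)
        dend = average_linkage(d)

        members = {i: [i] for i in range(8)}
        for left, right, h, new in dend.merges:
            cross = [arr[i, j] for i in members[left] for j in members[right]]
            assert h == pytest.approx(np.mean(cross), abs=1e-9)
            members[new] = members[left] + members[right]

        Z = hierarchy.linkage(squareform(arr, checks=False), method="average")
        np.testing.assert_allclose(sorted(dend.heights), sorted(Z[:, 2]), atol=1e-9)


def test_tie_break_is_lexicographic():
    # two pairs at identical height: the pair holding 'A' must merge first
    arr = np.full((4, 4), 5.0)
    np.fill_diagonal(arr, 0.0)
    arr[0, 1] = arr[1, 0] = 1.0   # A-B
    arr[2, 3] = arr[3, 2] = 1.0   # C-D
    d = _dist(arr, list("ABCD"))
    dend = average_linkage(d)
    first = {dend.labels[dend.merges[0][0]], dend.labels[dend.merges[0][1]]}
    assert first == {"A", "B"}
    assert dend.leaf_order == ["A", "B", "C", "D"]


def test_heights_non_decreasing_and_leaf_order_valid():
    rng = np.random.default_rng(1)
    arr = rng.uniform(0.1, 2.0, size=(10, 10))
    arr = (arr + arr.T) / 2
    np.fill_diagonal(arr, 0.0)
    labels = [f"m{i}" for i in range(10)]
    dend = average_linkage(_dist(arr, labels))
    # UPGMA on a metric-ish random matrix: merge heights sorted equal heights
    assert sorted(dend.leaf_order) == sorted(labels)
    assert len(set(dend.leaf_order)) == 10


def test_non_symmetric_rejected():
    d = _dist([[0, 1], [2, 0]], ["a", "b"])
    with pytest.raises(ValueError):
        average_linkage(d)


def test_newick_export_parses():
    import io

    from Bio import Phylo

    d = _dist([[0, 1, 4], [1, 0, 4], [4, 4, 0]], list("ABC"))
    tree = Phylo.read(io.StringIO(to_newick(average_linkage(d))), "newick")
    assert sorted(t.name for t in tree.get_terminals()) == ["A", "B", "C"]


def test_sample_clustering_recovers_group_partition():
    """Strong planted group effects put case and control samples in the two
    top-level clusters in nearly every simulation."""
    from syndromirnet import SimulationConfig, simulate_expression, standardize_samples

    hits = 0
    n_seeds = 20
    for seed in range(n_seeds):
        cfg = SimulationConfig(n_mirnas=150, n_genes=10,
                               group_sizes={"Normal": 7, "LGDHS": 3},
                               n_de_per_group=40, de_log2fc=4.0, seed=seed)
        m, _ = simulate_expression(cfg)
        z = standardize_samples(m)
        d = correlation_distance(z.values.T, axis="rows")
        dend = average_linkage(d)
        # 2-cluster cut = the two children of the final merge
        n = len(dend.labels)
        children = {new: (a, b) for a, b, _, new in dend.merges}

        def leaves(node):
            if node < n:
                return {dend.labels[node]}
            a, b = children[node]
            return leaves(a) | leaves(b)

        a, b = children[dend.merges[-1][3]]
        part = {frozenset(leaves(a)), frozenset(leaves(b))}
        want = {frozenset(s for s in dend.labels if s.startswith("LGDHS")),
                frozenset(s for s in dend.labels if s.startswith("Normal"))}
        hits += part == want
    assert hits / n_seeds >= 0.95
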