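import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from syndromirnet import (GeneSetCollection, bh_fdr, hypergeom_enrich, read_gmt,
                          term_overlap)
from syndromirnet.enrichment import write_gmt


def _collection(sets, universe_size=100):
    universe = {f"G{i}" for i in range(universe_size)}
    return GeneSetCollection(sets=sets, universe=universe)


def test_exact_combinatorial_example():
    """N=10, K=4, n=5, k=4 -> p = C(4,4) C(6,1) / C(10,5) = 6/252."""
    universe = {f"G{i}" for i in range(10)}
    members = {f"G{i}" for i in range(4)}
    coll = GeneSetCollection(sets={"S": ("s", "GO", members)}, universe=universe)
    query = members | {"G9"}
    res = hypergeom_enrich(query, coll, min_overlap=1)
    assert res.loc["S", "k"] == 4
    assert res.loc["S", "p"] == pytest.approx(6 / 252, rel=1e-12)


def test_zero_overlap_p_is_one():
    coll = _collection({"S": ("s", "GO", {f"G{i}" for i in range(10)})})
    res = hypergeom_enrich({f"G{i}" for i in range(90, 95)}, coll, min_overlap=1)
    assert res.loc["S", "k"] == 0
    assert res.loc["S", "p"] == pytest.approx(1.0)


def test_empty_query_gives_empty_result():
    coll = _collection({"S": ("s", "GO", {"G0", "G1", "G2", "G3", "G4"})})
    assert hypergeom_enrich(set(), coll).empty


def test_hypergeom_matches_fisher_exact():
    """The upper-tail hypergeometric p equals the one-sided Fisher exact p
    on the matching 2x2 table."""
    rng = np.random.default_rng(13)
    for _ in range(500):
        N = int(rng.integers(20, 200))
        K = int(rng.integers(5, N - 5))
        n = int(rng.integers(5, N - 5))
        k = int(rng.integers(max(0, K + n - N), min(K, n) + 1))
        p_hyper = float(stats.hypergeom.sf(k - 1, N, K, n))
        table = [[k, K - k], [n - k, N - K - (n - k)]]
        _, p_fisher = stats.fisher_exact(table, alternative="greater")
        assert abs(p_hyper - p_fisher) < 1e-12


def _bh_oracle(p):
    """Naive O(m^2) step-up: adj_i = min over j with p_j >= p_i of m*p_j/rank_j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running_min = min(running_min, m * p[i] / (rank_from_top + 1))
        adj[i] = running_min
    return np.minimum(adj, 1.0)


def test_bh_hand_example():
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])
    np.testing.assert_allclose(bh_fdr([0.3]), [0.3])


def test_bh_matches_naive_oracle():
    rng = np.random.default_rng(17)
    for _ in range(100):
        p = rng.uniform(size=rng.integers(1, 40))
        np.testing.assert_allclose(bh_fdr(p), _bh_oracle(p), atol=1e-12)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
def test_bh_monotone_and_bounded(pvals):
    adj = bh_fdr(np.array(pvals))
    assert (adj <= 1.0 + 1e-12).all() and (adj >= np.array(pvals) - 1e-12).all()
    order = np.argsort(pvals, kind="stable")
    assert (np.diff(adj[order]) >= -1e-12).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


def test_retained_conjunction_and_filter_order():
    """Retained requires k >= 5 AND raw p < .05 AND BH p < .05; sets failing
    the overlap filter never receive an FDR value when pre-filtering."""
    rng = np.random.default_rng(23)
    universe = {f"G{i}" for i in range(500)}
    query = {f"G{i}" for i in range(40)}
    sets = {"BIG": ("b", "GO", {f"G{i}" for i in range(30)}),          # k=30
            "TINY": ("t", "GO", {f"G{i}" for i in range(38, 48)}),     # k=2
            "NULL": ("n", "KEGG",
                     set(rng.choice(sorted(universe), 30, replace=False)))}
    coll = GeneSetCollection(sets=sets, universe=universe)
    res = hypergeom_enrich(query, coll)
    assert bool(res.loc["BIG", "retained"])
    assert not bool(res.loc["TINY", "retained"])
    assert np.isnan(res.loc["TINY", "fdr_p"])
    kept = res[res["retained"]]
    assert (kept["k"] >= 5).all() and (kept["p"] < 0.05).all() \
        and (kept["fdr_p"] < 0.05).all()


def test_query_genes_outside_universe_dropped_with_warning():
    coll = _collection({"S": ("s", "GO", {f"G{i}" for i in range(20)})})
    with pytest.warns(RuntimeWarning, match="outside the universe"):
        res = hypergeom_enrich({"G0", "G1", "ALIEN"}, coll, min_overlap=1)
    assert res.loc["S", "n"] == 2


def test_term_overlap_counts():
    import pandas as pd

    def _res(retained_ids, ids, cats):
        return pd.DataFrame({"category": cats,
                             "retained": [i in retained_ids for i in ids]},
                            index=pd.Index(ids, name="set_id"))

    ids = ["s1", "s2", "s3"]
    cats = ["GO", "GO", "KEGG"]
    a = _res({"s1", "s2"}, ids, cats)
    b = _res({"s2", "s3"}, ids, cats)
    assert term_overlap(a, b) == {"total": 1, "GO": 1}
    assert term_overlap(a, a)["total"] == 2
    assert term_overlap(a, _res(set(), ids, cats))["total"] == 0
    with pytest.raises(ValueError):
        term_overlap(a, _res({"s2"}, ["s1", "s2", "zz"], cats))


def test_false_positive_control_with_no_planting():
    """No planted sets: FDR keeps the mean number of retained sets tiny."""
    from syndromirnet import SimulationConfig, simulate_gene_sets

    retained_counts = []
    for seed in range(50):
        cfg = SimulationConfig(n_genes=500, n_gene_sets=40, gene_set_size=(20, 60),
                               planted_enriched_sets=0, seed=seed)
        genes = [f"G{i:05d}" for i in range(500)]
        rng = np.random.default_rng(1000 + seed)
        sets, _ = simulate_gene_sets(genes, cfg, rng=rng)
        coll = GeneSetCollection(sets=sets, universe=set(genes))
        query = set(rng.choice(genes, size=60, replace=False))
        res = hypergeom_enrich(query, coll)
        retained_counts.append(int(res["retained"].sum()))
    assert np.mean(retained_counts) <= 1.0


def test_planted_sets_are_recovered():
    """Five strongly planted sets are all retained in nearly every seed."""
    from syndromirnet import SimulationConfig, simulate_gene_sets

    hits = 0
    n_seeds = 50
    for seed in range(n_seeds):
        cfg = SimulationConfig(n_genes=500, n_gene_sets=40, gene_set_size=(30, 60),
                               planted_enriched_sets=5, seed=seed)
        genes = [f"G{i:05d}" for i in range(500)]
        rng = np.random.default_rng(2000 + seed)
        pool = set(rng.choice(genes, size=80, replace=False))
        sets, planted = simulate_gene_sets(genes, cfg, enriched_pool=pool, rng=rng)
        coll = GeneSetCollection(sets=sets, universe=set(genes))
        res = hypergeom_enrich(pool, coll)
        hits += planted <= set(res.index[res["retained"]])
    assert hits / n_seeds >= 0.95


def test_gmt_round_trip(tmp_path):
    coll = _collection({
        "S1": ("alpha", "GO", {"G1", "G2", "G3", "G4", "G5"}),
        "S2": ("beta", "KEGG", {"G2", "G6", "G7", "G8", "G9"}),
    })
    write_gmt(coll, tmp_path / "c.gmt")
    back = read_gmt(tmp_path / "c.gmt", universe=coll.universe)
    assert back.sets == coll.sets
    assert back.categories == {"GO", "KEGG"}
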