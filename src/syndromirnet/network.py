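"""Node-weighted bipartite miRNA-target networks and cross-network comparison.

One network is built per syndrome-vs-normal comparison from the consensus
target sets of its significantly differential miRNAs. miRNA nodes are
weighted by |log2 fold change|, gene nodes by their degree in the network.
Derived views: the hub subnetwork (nodes with degree >= 5 by default) and
the up-expression subnetwork (up-regulated miRNAs plus their targets, the
genes of which are interpreted as down-regulated). Networks for different
syndromes are compared by node-set overlap and by Spearman rank similarity
of shared-node weights with a permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WeightedBipartiteNetwork",
    "NetworkComparison",
    "build_weighted_network",
    "extract_hubs",
    "up_subnetwork",
    "compare_networks",
    "write_edge_list",
    "write_graphml",
]


@dataclass
class WeightedBipartiteNetwork:
    """Bipartite miRNA-gene graph with the weighting scheme baked in."""

    graph: nx.Graph
    comparison: str = ""

    @property
    def mirna_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("kind") == "mirna"}

    @property
    def gene_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("kind") == "gene"}

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, node: str) -> float:
        return float(self.graph.nodes[node]["weight"])

    def check_invariants(self) -> None:
        """Bipartiteness, gene weight == degree, degree-sum identity."""
        g = self.graph
        for u, v in g.edges():
            kinds = {g.nodes[u]["kind"], g.nodes[v]["kind"]}
            if kinds != {"mirna", "gene"}:
                raise AssertionError(f"non-bipartite edge {u}-{v}")
        for n in self.gene_nodes:
            if g.nodes[n]["weight"] != g.degree(n):
                raise AssertionError(f"gene weight != degree for {n}")
        deg_m = sum(g.degree(n) for n in self.mirna_nodes)
        deg_g = sum(g.degree(n) for n in self.gene_nodes)
        if not (deg_m == deg_g == g.number_of_edges()):
            raise AssertionError("degree-sum identity violated")


@dataclass
class NetworkComparison:
    """Overlap and rank-similarity report between two syndrome networks."""

    shared_mirnas: set[str]
    shared_up_mirnas: set[str]
    shared_nodes: set[str]
    rank_correlation: float | None
    permutation_p: float | None
    computable: bool
    deregulated: list[tuple[str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_shared_mirnas": len(self.shared_mirnas),
            "shared_mirnas": sorted(self.shared_mirnas),
            "n_shared_up_mirnas": len(self.shared_up_mirnas),
            "shared_up_mirnas": sorted(self.shared_up_mirnas),
            "rank_correlation": self.rank_correlation,
            "permutation_p": self.permutation_p,
            "computable": self.computable,
            "deregulated_nodes": [[n, d] for n, d in self.deregulated],
        }


def build_weighted_network(consensus, de: pd.DataFrame,
                           comparison: str = "") -> WeightedBipartiteNetwork:
    """Assemble the network for one comparison.

    Only significant miRNAs enter; each contributes edges to its final
    target set (consensus plus validated). Raises if a consensus miRNA with
    targets has no differential-expression record.
    """
    g = nx.Graph()
    sig = de[de["significant"]]
    edges = consensus.final_edges()
    mirnas_with_edges = {m for m, _, _ in edges}
    missing = mirnas_with_edges - set(de.index)
    if missing:
        raise KeyError(f"consensus miRNAs missing from DE table: {sorted(missing)}")

    for m, gene, source in sorted(edges):
        if m not in sig.index:
            continue
        if m not in g:
            g.add_node(m, kind="mirna",
                       weight=float(abs(sig.loc[m, "log2fc"])),
                       direction=str(sig.loc[m, "direction"]))
        if gene not in g:
            g.add_node(gene, kind="gene", weight=0)
        g.add_edge(m, gene, source=source)

    for n, d in g.nodes(data=True):
        if d["kind"] == "gene":
            d["weight"] = g.degree(n)
    net = WeightedBipartiteNetwork(graph=g, comparison=comparison)
    net.check_invariants()
    return net


def _refresh_gene_weights(g: nx.Graph) -> None:
    for n, d in g.nodes(data=True):
        if d["kind"] == "gene":
            d["weight"] = g.degree(n)


def extract_hubs(net: WeightedBipartiteNetwork, min_degree: int = 5,
                 ) -> WeightedBipartiteNetwork:
    """Subnetwork induced by nodes with degree >= ``min_degree`` in the
    PARENT network, plus their incident edges (so a retained hub keeps all
    its neighbors as endpoints of those edges)."""
    g = net.graph
    hubs = {n for n in g if g.degree(n) >= min_degree}
    sub = nx.Graph()
    for n in hubs:
        sub.add_node(n, **g.nodes[n])
    for u, v, d in g.edges(data=True):
        if u in hubs or v in hubs:
            for x in (u, v):
                if x not in sub:
                    sub.add_node(x, **g.nodes[x])
            sub.add_edge(u, v, **d)
    out = WeightedBipartiteNetwork(graph=sub, comparison=net.comparison)
    # note: gene 'weight' is kept from the parent; degree-sum identity is on
    # the subgraph, so refresh weights to the induced degrees
    _refresh_gene_weights(sub)
    out.check_invariants()
    return out


def up_subnetwork(net: WeightedBipartiteNetwork,
                  ) -> tuple[WeightedBipartiteNetwork, float]:
    """Subnetwork of up-regulated miRNAs and their targets.

    Returns (subnetwork, up_fraction) where up_fraction is the percentage of
    the parent network's miRNAs that are up-regulated, rounded to one
    decimal (the genes these miRNAs repress are read as down-regulated).
    """
    g = net.graph
    up = {n for n in net.mirna_nodes if g.nodes[n].get("direction") == "up"}
    sub = nx.Graph()
    for m in up:
        sub.add_node(m, **g.nodes[m])
        for gene in g.neighbors(m):
            if gene not in sub:
                sub.add_node(gene, **g.nodes[gene])
            sub.add_edge(m, gene, **g.edges[m, gene])
    _refresh_gene_weights(sub)
    n_mirnas = len(net.mirna_nodes)
    frac = round(100.0 * len(up) / n_mirnas, 1) if n_mirnas else 0.0
    out = WeightedBipartiteNetwork(graph=sub, comparison=net.comparison + "_up")
    out.check_invariants()
    return out, frac


def compare_networks(netA: WeightedBipartiteNetwork,
                     netB: WeightedBipartiteNetwork,
                     n_perm: int = 10000,
                     seed: int | None = None,
                     top_k: int = 20) -> NetworkComparison:
    """Overlap counts plus Spearman rank similarity of shared-node weights.

    The permutation null shuffles network B's weights over the shared nodes
    (two-sided, add-one p). Deregulated nodes are the shared nodes with the
    largest absolute within-network rank change, top ``top_k``.
    """
    gA, gB = netA.graph, netB.graph
    shared_mirnas = netA.mirna_nodes & netB.mirna_nodes
    shared_up = {m for m in shared_mirnas
                 if gA.nodes[m].get("direction") == "up"
                 and gB.nodes[m].get("direction") == "up"}
    shared = set(gA.nodes) & set(gB.nodes)

    if len(shared) < 3:
        return NetworkComparison(shared_mirnas=shared_mirnas,
                                 shared_up_mirnas=shared_up,
                                 shared_nodes=shared,
                                 rank_correlation=None, permutation_p=None,
                                 computable=False)

    nodes = sorted(shared)
    wA = np.array([gA.nodes[n]["weight"] for n in nodes], dtype=float)
    wB = np.array([gB.nodes[n]["weight"] for n in nodes], dtype=float)
    rA = stats.rankdata(wA)
    rB = stats.rankdata(wB)
    rho = float(stats.spearmanr(wA, wB).statistic)

    rng = np.random.default_rng(seed)
    # permutation of B's weights; Spearman = Pearson on mid-ranks
    rA_c = rA - rA.mean()
    denomA = np.sqrt((rA_c ** 2).sum())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(rB)
        perm_c = perm - perm.mean()
        denomB = np.sqrt((perm_c ** 2).sum())
        if denomA == 0 or denomB == 0:
            r = 0.0
        else:
            r = float((rA_c * perm_c).sum() / (denomA * denomB))
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)

    dereg = sorted(((n, float(abs(ra - rb))) for n, ra, rb in zip(nodes, rA, rB)),
                   key=lambda x: (-x[1], x[0]))[:top_k]
    return NetworkComparison(shared_mirnas=shared_mirnas,
                             shared_up_mirnas=shared_up,
                             shared_nodes=shared,
                             rank_correlation=rho, permutation_p=p,
                             computable=True, deregulated=dereg)


def write_edge_list(net: WeightedBipartiteNetwork, path: str | Path) -> None:
    g = net.graph
    rows = []
    for u, v, d in sorted(g.edges(data=True)):
        m, gene = (u, v) if g.nodes[u]["kind"] == "mirna" else (v, u)
        rows.append((m, gene, d.get("source", ""), g.nodes[m]["weight"],
                     g.nodes[gene]["weight"], g.nodes[m].get("direction", "")))
    pd.DataFrame(rows, columns=["mirna_id", "gene_id", "source", "mirna_weight",
                                "gene_weight", "direction"]).to_csv(
        path, sep="\t", index=False)


def write_graphml(net: WeightedBipartiteNetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, path)
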