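"""Network topology around shared DEGs: PPI subnetwork induction, degree-based
hub ranking, bipartite TF/miRNA regulator ranking and drug-target lookup.

Hubs are the highest-degree proteins of the PPI subnetwork induced on the
query genes (induced = both endpoints in the query; an optional
first-neighbour expansion exists behind a flag).  Regulators are scored by
the number of distinct DEGs among their known targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx

from diseasomics.dataio import DataError, InteractionNetwork


@dataclass(frozen=True)
class HubRanking:
    """Top-k nodes by degree: entries are (node, degree, rank).

    Ranks are competition-style (ties share the smallest rank) and ordering
    breaks ties lexicographically.  When the k-th degree is tied beyond k,
    all tied nodes are included and ``tie_extended`` is set.
    """

    entries: tuple[tuple[str, int, int], ...]
    k: int
    tie_extended: bool = False

    @property
    def nodes(self) -> list[str]:
        return [n for n, _, _ in self.entries]


@dataclass(frozen=True)
class RegulatorRanking:
    """Top regulators by number of distinct DEG targets."""

    regulator_class: str  # "TF" or "miRNA"
    entries: tuple[tuple[str, int, frozenset[str], int], ...]  # (reg, n, targets, rank)
    top_n: int
    tie_extended: bool = False

    @property
    def regulators(self) -> list[str]:
        return [r for r, _, _, _ in self.entries]


def induce_subnetwork(
    ppi: InteractionNetwork,
    genes,
    neighbor_expansion: bool = False,
) -> InteractionNetwork:
    """Node-induced PPI subgraph on the query genes.

    Query genes present in the PPI but without qualifying edges stay as
    isolated nodes; query genes absent from the PPI are listed in
    ``meta["unmapped"]``.  With ``neighbor_expansion`` the node set grows by
    the first neighbours of mapped query genes before induction.
    """
    if ppi.kind != "ppi_undirected":
        raise DataError(f"expected a ppi_undirected network, got {ppi.kind!r}")
    query = {str(g).upper() for g in genes}
    mapped = query & set(ppi.graph.nodes)
    unmapped = sorted(query - mapped)
    nodes = set(mapped)
    if neighbor_expansion:
        for g in mapped:
            nodes.update(ppi.graph.neighbors(g))
    sub = nx.Graph()
    sub.add_nodes_from(sorted(nodes))
    sub.add_edges_from(
        (a, b, d) for a, b, d in ppi.graph.edges(nodes, data=True) if a in nodes and b in nodes
    )
    net = InteractionNetwork(kind="ppi_undirected", graph=sub)
    net.meta["unmapped"] = unmapped
    net.meta["neighbor_expansion"] = neighbor_expansion
    return net


def _competition_ranks(scores: list[int]) -> list[int]:
    """Competition ranks (1,2,2,4) for scores already sorted descending."""
    ranks = []
    for i, s in enumerate(scores):
        if i and s == scores[i - 1]:
            ranks.append(ranks[-1])
        else:
            ranks.append(i + 1)
    return ranks


def rank_hubs(net: InteractionNetwork, k: int = 10) -> HubRanking:
    """Top-k nodes by degree with deterministic tie handling."""
    if net.kind != "ppi_undirected":
        raise DataError(f"expected a ppi_undirected network, got {net.kind!r}")
    if net.graph.number_of_nodes() == 0:
        raise DataError("empty network")
    if k < 1:
        raise DataError(f"k must be >=1, got {k}")
    by_degree = sorted(net.graph.degree(), key=lambda nd: (-nd[1], nd[0]))
    cut = min(k, len(by_degree))
    tie_extended = False
    if cut < len(by_degree):
        kth = by_degree[cut - 1][1]
        while cut < len(by_degree) and by_degree[cut][1] == kth:
            cut += 1
            tie_extended = True
    top = by_degree[:cut]
    ranks = _competition_ranks([d for _, d in top])
    return HubRanking(
        entries=tuple((n, d, r) for (n, d), r in zip(top, ranks)),
        k=k,
        tie_extended=tie_extended,
    )


def rank_regulators(
    targets: InteractionNetwork,
    degs,
    top_n: int = 5,
    regulator_class: str = "TF",
) -> RegulatorRanking:
    """Rank regulators by count of distinct DEGs among their targets.

    Regulators touching no DEG are excluded; an entirely empty ranking is
    returned with a warning when no regulator targets any DEG.
    """
    if targets.kind != "regulator_bipartite":
        raise DataError(f"expected a regulator_bipartite network, got {targets.kind!r}")
    if top_n < 1:
        raise DataError(f"top_n must be >=1, got {top_n}")
    deg_set = {str(g).upper() for g in degs}
    scored = []
    for reg in targets.nodes_of_class("regulator"):
        hit = frozenset(t for t in targets.graph.neighbors(reg) if t in deg_set)
        if hit:
            scored.append((reg, len(hit), hit))
    if not scored:
        warnings.warn("no regulator targets any DEG; empty ranking", stacklevel=2)
        return RegulatorRanking(regulator_class=regulator_class, entries=(), top_n=top_n)
    scored.sort(key=lambda e: (-e[1], e[0]))
    cut = min(top_n, len(scored))
    tie_extended = False
    if cut < len(scored):
        kth = scored[cut - 1][1]
        while cut < len(scored) and scored[cut][1] == kth:
            cut += 1
            tie_extended = True
    top = scored[:cut]
    ranks = _competition_ranks([n for _, n, _ in top])
    return RegulatorRanking(
        regulator_class=regulator_class,
        entries=tuple((reg, n, hit, r) for (reg, n, hit), r in zip(top, ranks)),
        top_n=top_n,
        tie_extended=tie_extended,
    )


def drug_interactions(drug_targets: InteractionNetwork, genes) -> InteractionNetwork:
    """Subnetwork of drugs linked to at least one query gene.

    Only drug-(query gene) edges are retained; an empty network is a valid
    result.
    """
    if drug_targets.kind != "drug_bipartite":
        raise DataError(f"expected a drug_bipartite network, got {drug_targets.kind!r}")
    query = {str(g).upper() for g in genes}
    g = nx.Graph()
    for drug in sorted(drug_targets.nodes_of_class("drug")):
        hits = sorted(t for t in drug_targets.graph.neighbors(drug) if t in query)
        for t in hits:
            g.add_node(drug, node_class="drug")
            g.add_node(t, node_class="gene")
            g.add_edge(drug, t, weight=drug_targets.graph[drug][t].get("weight", 1.0))
    return InteractionNetwork(kind="drug_bipartite", graph=g)
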