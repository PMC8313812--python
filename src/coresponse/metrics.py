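"""Summaries of co-response networks: kingdom-partitioned counts and
positive/negative interaction ratios, hub ("keystone") detection, and
hypergeometric taxon enrichment against the source community."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import networkx as nx
import pandas as pd
from scipy import stats

from .network import CoResponseNetwork
from .tables import OtuTable, TaxonomyMap

__all__ = ["NetworkSummary", "HubSet", "EnrichmentResult",
           "summarize", "summarize_graph", "find_hubs", "enrich_taxa",
           "ratio_half_up"]


def ratio_half_up(positive: int, negative: int) -> float | None:
    """positive/negative rounded half-up to 2 decimals; None when negative=0."""
    if negative == 0:
        return None
    exact = Decimal(positive) / Decimal(negative)
    return float(exact.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class NetworkSummary:
    """The network-parameter table of one compartment's network.

    Edge counts are partitioned by the kingdoms of their endpoints
    (bacteria–bacteria, fungi–fungi, bacteria–fungi) and by sign; each
    partition's +/- interaction ratio is rounded half-up to two decimals
    (``None`` when the partition has no negative edges).
    """

    n_components: int
    n_nodes: int
    n_bacterial_nodes: int
    n_fungal_nodes: int
    n_other_nodes: int
    positive: dict[str, int]   # keys: total, bb, ff, bf
    negative: dict[str, int]
    ratios: dict[str, float | None]

    @property
    def n_edges(self) -> int:
        return self.positive["total"] + self.negative["total"]

    def as_series(self) -> pd.Series:
        def _ratio(key: str):
            value = self.ratios[key]
            return "undefined" if value is None else value

        rows = {
            "Number of connected components": self.n_components,
            "Number of nodes": self.n_nodes,
            "Bacterial nodes": self.n_bacterial_nodes,
            "Fungal nodes": self.n_fungal_nodes,
            "Number of total positive interactions": self.positive["total"],
            "Number of total negative interactions": self.negative["total"],
            "Total +/- interaction ratio": _ratio("total"),
            "Number of bacterial positive interactions": self.positive["bb"],
            "Number of bacterial negative interactions": self.negative["bb"],
            "Bacterial +/- interaction ratio": _ratio("bb"),
            "Number of fungal positive interactions": self.positive["ff"],
            "Number of fungal negative interactions": self.negative["ff"],
            "Fungal +/- interaction ratio": _ratio("ff"),
            "Number of bacteria-fungi positive interactions": self.positive["bf"],
            "Number of bacteria-fungi negative interactions": self.negative["bf"],
            "Bacterial-fungal +/- interaction ratio": _ratio("bf"),
        }
        if self.n_other_nodes:
            rows["Other nodes"] = self.n_other_nodes
        return pd.Series(rows, dtype=object)


def _partition_key(k_a: str, k_b: str) -> str | None:
    pair = frozenset((k_a, k_b))
    if pair == {"Bacteria"}:
        return "bb"
    if pair == {"Fungi"}:
        return "ff"
    if pair == {"Bacteria", "Fungi"}:
        return "bf"
    return None  # edges touching "other" count only toward the totals


def summarize_graph(graph: nx.Graph, taxonomy: TaxonomyMap) -> NetworkSummary:
    """Summarize any signed graph whose edges carry a ``sign`` attribute."""
    kingdoms = {}
    for node in graph.nodes:
        if node not in taxonomy:
            raise KeyError(f"node {node!r} missing from taxonomy")
        kingdoms[node] = taxonomy.kingdom(node)
    n_b = sum(1 for k in kingdoms.values() if k == "Bacteria")
    n_f = sum(1 for k in kingdoms.values() if k == "Fungi")
    n_o = len(kingdoms) - n_b - n_f
    pos = dict.fromkeys(("total", "bb", "ff", "bf"), 0)
    neg = dict.fromkeys(("total", "bb", "ff", "bf"), 0)
    for a, b, attrs in graph.edges(data=True):
        sign = attrs.get("sign", "positive")
        bucket = pos if sign == "positive" else neg
        bucket["total"] += 1
        key = _partition_key(kingdoms[a], kingdoms[b])
        if key is not None:
            bucket[key] += 1
    ratios = {k: ratio_half_up(pos[k], neg[k]) for k in ("total", "bb", "ff", "bf")}
    return NetworkSummary(
        n_components=nx.number_connected_components(graph),
        n_nodes=graph.number_of_nodes(),
        n_bacterial_nodes=n_b, n_fungal_nodes=n_f, n_other_nodes=n_o,
        positive=pos, negative=neg, ratios=ratios,
    )


def summarize(network: CoResponseNetwork, taxonomy: TaxonomyMap) -> NetworkSummary:
    return summarize_graph(network.graph, taxonomy)


@dataclass(frozen=True)
class HubSet:
    """Highest-degree ("responsive-to-water-deficit hub") nodes.

    The base hub count is floor(fraction x node count), at least 1; when the
    first excluded node ties the degree at the cutoff, every node of that
    degree is promoted (so a large shared top degree can make the hub set
    exceed the nominal fraction, as in a 59-way tie).
    """

    hubs: tuple[str, ...]       # sorted by degree descending, then by id
    cutoff_degree: int
    fraction: float
    tie_expanded: bool


def find_hubs(network: CoResponseNetwork | nx.Graph, fraction: float = 0.01) -> HubSet:
    graph = network.graph if isinstance(network, CoResponseNetwork) else network
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot find hubs of an empty network")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    degrees = dict(graph.degree())
    ranked = sorted(degrees, key=lambda n: (-degrees[n], str(n)))
    base = max(1, int(fraction * len(ranked)))
    cutoff = degrees[ranked[base - 1]]
    tie_expanded = False
    k = base
    while k < len(ranked) and degrees[ranked[k]] == cutoff:
        k += 1
        tie_expanded = True
    return HubSet(hubs=tuple(ranked[:k]), cutoff_degree=cutoff,
                  fraction=fraction, tie_expanded=tie_expanded)


@dataclass(frozen=True)
class EnrichmentResult:
    taxon: str
    rank: str
    community_count: int   # K: members of the taxon in the community
    community_size: int    # N
    network_count: int     # k: members of the taxon among network nodes
    network_size: int      # n
    p: float               # upper tail P(X >= k), X ~ Hypergeom(N, K, n)
    enriched: bool


def enrich_taxa(
    network: CoResponseNetwork | nx.Graph,
    community: OtuTable,
    taxonomy: TaxonomyMap,
    rank: str = "phylum",
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of taxa among network nodes.

    The population is the (prevalence-filtered) community the network was
    inferred from; for each taxon with K community members, the upper-tail
    probability that a random draw of n = |network nodes| OTUs contains at
    least the observed k members is computed; ``enriched`` flags p < alpha.
    """
    graph = network.graph if isinstance(network, CoResponseNetwork) else network
    population = list(community.otu_ids)
    nodes = [n for n in graph.nodes]
    outside = [n for n in nodes if n not in set(population)]
    if outside:
        raise ValueError(f"network nodes absent from community: {outside[:5]}")
    N = len(population)
    n = len(nodes)
    taxon_of = {o: taxonomy[o].at_rank(rank) for o in population}
    node_set = set(nodes)
    results = []
    for taxon in sorted(set(taxon_of.values())):
        members = [o for o in population if taxon_of[o] == taxon]
        K = len(members)
        k = sum(1 for o in members if o in node_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
        results.append(EnrichmentResult(taxon=taxon, rank=rank,
                                        community_count=K, community_size=N,
                                        network_count=k, network_size=n,
                                        p=p, enriched=bool(p < alpha)))
    return results
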