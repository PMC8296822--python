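"""MCODE-style dense-region detection, module scoring and hub-gene selection.

The algorithm follows the published molecular-complex-detection scheme:

1. vertex weighting — each vertex is scored by its core-clustering
   coefficient, k × density of the highest k-core of its closed neighborhood;
2. complex prediction — seeds are processed in decreasing weight and greedily
   expanded, admitting unassigned neighbors whose weight exceeds
   seed_weight × (1 − vwp);
3. post-processing — 'haircut' iteratively removes singly-connected members
   (the 2-core of the module); optional 'fluff' grows the boundary with
   neighbors whose closed-neighborhood density exceeds a cutoff.

A module's score is density × member count; modules scoring strictly above
``min_component_score`` are retained.  Hub genes are module members whose
degree in the tissue network strictly exceeds ``hub_threshold``; when no gene
qualifies, the single maximum-degree module gene is selected instead
(selection_rule 'fallback_max', lexicographic tie-break).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from ._util import edge_key


def _as_graph(network) -> nx.Graph:
    if isinstance(network, nx.Graph):
        return network
    return network.graph


def _highest_kcore(h: nx.Graph) -> tuple[int, nx.Graph]:
    """(k, subgraph) of the highest non-empty k-core of h."""
    if h.number_of_edges() == 0:
        return 0, h
    core = nx.core_number(h)
    k = max(core.values())
    nodes = [v for v, c in core.items() if c >= k]
    return k, h.subgraph(nodes)


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def vertex_weights(graph) -> dict[str, float]:
    """Core-clustering coefficient of every vertex.

    weight(v) = k × density of the highest k-core of v's closed neighborhood;
    isolated vertices weigh 0.
    """
    g = _as_graph(graph)
    weights: dict[str, float] = {}
    for v in g.nodes:
        closed = list(g[v]) + [v]
        if len(closed) == 1:
            weights[v] = 0.0
            continue
        k, core = _highest_kcore(g.subgraph(closed))
        weights[v] = k * _density(core)
    return weights


@dataclass
class ModuleRecord:
    """A detected dense module.

    ``tissue_provenance`` maps each member to the set of tissues contributing
    it (empty when the network carries no tissue annotation).
    """

    seed_gene: str
    member_genes: tuple[str, ...]
    density: float
    mcode_score: float
    tissue_provenance: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return len(self.member_genes)


def find_modules(
    graph,
    vwp: float = 0.2,
    haircut: bool = True,
    fluff: bool = False,
    fluff_density: float = 0.2,
    min_component_score: float = 3.0,
) -> list[ModuleRecord]:
    """Detect dense modules; fully deterministic (lexicographic tie-breaks).

    Each vertex joins at most one module.  Returned modules are sorted by
    decreasing score, then seed id.
    """
    if not 0.0 <= vwp < 1.0:
        raise ValueError("vwp must lie in [0, 1)")
    g = _as_graph(graph)
    if g.number_of_nodes() == 0:
        return []
    weights = vertex_weights(g)
    order = sorted(g.nodes, key=lambda v: (-weights[v], v))
    assigned: set[str] = set()
    modules: list[ModuleRecord] = []
    for seed in order:
        if seed in assigned:
            continue
        threshold = weights[seed] * (1.0 - vwp)
        members = {seed}
        frontier = [seed]
        while frontier:
            v = frontier.pop()
            for u in sorted(g[v]):
                if u in assigned or u in members:
                    continue
                if weights[u] > threshold:
                    members.add(u)
                    frontier.append(u)
        assigned |= members  # examined vertices never reseed another module
        sub = nx.Graph(g.subgraph(members))
        if haircut:
            while True:
                drop = [v for v in sub.nodes if sub.degree(v) < 2]
                if not drop:
                    break
                sub.remove_nodes_from(drop)
        if fluff:
            boundary = set()
            for v in list(sub.nodes):
                for u in g[v]:
                    if u in sub or u in boundary:
                        continue
                    closed = g.subgraph(list(g[u]) + [u])
                    if _density(closed) > fluff_density:
                        boundary.add(u)
            sub = nx.Graph(g.subgraph(set(sub.nodes) | boundary))
            assigned |= boundary
        if sub.number_of_nodes() < 2:
            continue
        density = _density(sub)
        score = density * sub.number_of_nodes()
        if score > min_component_score:
            provenance = {
                v: frozenset(g.nodes[v].get("tissues", ()))
                for v in sorted(sub.nodes)
            }
            modules.append(
                ModuleRecord(
                    seed_gene=seed,
                    member_genes=tuple(sorted(sub.nodes)),
                    density=density,
                    mcode_score=score,
                    tissue_provenance=provenance,
                )
            )
    modules.sort(key=lambda m: (-m.mcode_score, m.seed_gene))
    return modules


@dataclass
class HubGene:
    """A hub gene: high-degree module member of a tissue network."""

    gene_id: str
    hub_score: int
    tissue: str = ""
    selection_rule: str = "threshold"


def select_hubs(
    network,
    modules: Sequence[ModuleRecord],
    hub_threshold: int = 10,
) -> list[HubGene]:
    """Select hub genes among module members by network degree.

    A gene's score is its degree in the tissue network.  Genes scoring
    strictly above ``hub_threshold`` are hubs; when none qualifies, the single
    maximum-degree module gene is returned with rule 'fallback_max'
    (lexicographically smallest on ties).
    """
    g = _as_graph(network)
    tissue = getattr(network, "tissue", "") or g.graph.get("tissue", "")
    candidates = sorted({m for mod in modules for m in mod.member_genes})
    if not candidates:
        return []
    scores = {v: (g.degree(v) if v in g else 0) for v in candidates}
    hubs = [
        HubGene(v, scores[v], tissue, "threshold")
        for v in candidates
        if scores[v] > hub_threshold
    ]
    if hubs:
        return hubs
    best = min(candidates, key=lambda v: (-scores[v], v))
    return [HubGene(best, scores[best], tissue, "fallback_max")]


def merge_networks(networks: Mapping[str, object]) -> nx.Graph:
    """Node/edge union of per-tissue networks sharing an identifier space.

    Every node and edge is annotated with the frozenset of contributing
    tissues; DEG flags are kept tissue-resolved (``is_deg_by_tissue``) and
    unioned into ``is_deg``.
    """
    if len(networks) < 2:
        raise ValueError("need at least two networks to merge")
    merged = nx.Graph()
    for tissue in sorted(networks):
        g = _as_graph(networks[tissue])
        for n, d in g.nodes(data=True):
            if n not in merged:
                merged.add_node(n, tissues=frozenset(), is_deg=False, is_deg_by_tissue={})
            node = merged.nodes[n]
            node["tissues"] = node["tissues"] | {tissue}
            node["is_deg_by_tissue"][tissue] = bool(d.get("is_deg", False))
            node["is_deg"] = node["is_deg"] or bool(d.get("is_deg", False))
        for u, v in g.edges:
            a, b = edge_key(u, v)
            if not merged.has_edge(a, b):
                merged.add_edge(a, b, tissues=frozenset())
            merged.edges[a, b]["tissues"] = merged.edges[a, b]["tissues"] | {tissue}
    return merged


def modules_to_frame(modules: Sequence[ModuleRecord]):
    import pandas as pd

    rows = [
        {
            "module_id": i + 1,
            "seed": m.seed_gene,
            "n_nodes": m.n_members,
            "density": m.density,
            "score": m.mcode_score,
            "members": ";".join(m.member_genes),
            "tissues": ";".join(
                sorted(set().union(*m.tissue_provenance.values()))
                if m.tissue_provenance
                else []
            ),
        }
        for i, m in enumerate(modules)
    ]
    return pd.DataFrame(
        rows,
        columns=["module_id", "seed", "n_nodes", "density", "score", "members", "tissues"],
    )


def hubs_to_frame(hubs: Sequence[HubGene]):
    import pandas as pd

    rows = [
        {
            "gene_id": h.gene_id,
            "hub_score": h.hub_score,
            "tissue": h.tissue,
            "rule": h.selection_rule,
        }
        for h in hubs
    ]
    return pd.DataFrame(rows, columns=["gene_id", "hub_score", "tissue", "rule"])
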