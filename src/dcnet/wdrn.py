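"""Scored PPI handling and wild-type disease-related network (WDRN) construction.

The WDRN of a tissue is the subgraph of the confidence-filtered protein–protein
interaction (PPI) network restricted to edges with at least one differentially
expressed endpoint.  Its nodes are exactly the endpoints of retained edges:
a DEG with no retained incident interaction does not appear.  The DEG coverage
of a network is the percentage of its nodes that are DEGs, truncated (not
rounded) to two decimals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from ._util import edge_key, normalize_gene_id

PPI_COLUMNS = ("protein1", "protein2", "combined_score")


class PPIFormatError(ValueError):
    """Raised when a PPI edge list violates the STRING-dialect contract."""


@dataclass
class PPINetwork:
    """Undirected simple graph whose edges carry an integer ``combined_score``.

    Scores follow the STRING convention: integers in [0, 999].
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, int]]) -> "PPINetwork":
        g = nx.Graph()
        for a, b, score in edges:
            a, b = normalize_gene_id(a), normalize_gene_id(b)
            if a == b:
                raise PPIFormatError(f"self-loop on {a!r}")
            score = int(score)
            if not 0 <= score <= 999:
                raise PPIFormatError(f"score {score} for {a}–{b} outside [0, 999]")
            if g.has_edge(a, b):
                raise PPIFormatError(f"duplicate interaction {a}–{b}")
            g.add_edge(a, b, score=score)
        return cls(g)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PPINetwork":
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        if tuple(df.columns[:3]) != PPI_COLUMNS:
            raise PPIFormatError(
                f"{path}: expected header {PPI_COLUMNS}, got {tuple(df.columns[:3])}"
            )
        return cls.from_edges(
            df[list(PPI_COLUMNS)].itertuples(index=False, name=None)
        )

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (a, b, int(d["score"]))
            for (a, b), d in sorted(
                ((edge_key(u, v), d) for u, v, d in self.graph.edges(data=True))
            )
        ]
        pd.DataFrame(rows, columns=list(PPI_COLUMNS)).to_csv(
            path, sep="\t", index=False
        )

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str, int]]:
        """Edges as (gene_a, gene_b, score) with gene_a <= gene_b, sorted."""
        return sorted(
            (*edge_key(u, v), int(d["score"]))
            for u, v, d in self.graph.edges(data=True)
        )


def filter_ppi(ppi: PPINetwork, min_score: int = 900, strict: bool = True) -> PPINetwork:
    """Retain high-confidence interactions.

    ``strict`` (default) keeps scores strictly above ``min_score``; with
    ``strict=False`` the cutoff is inclusive, matching the more common STRING
    usage of a >= threshold.  Idempotent.
    """
    keep = (
        (lambda s: s > min_score) if strict else (lambda s: s >= min_score)
    )
    g = nx.Graph()
    for u, v, d in ppi.graph.edges(data=True):
        if keep(d["score"]):
            g.add_edge(u, v, score=d["score"])
    return PPINetwork(g)


@dataclass
class WDRN:
    """Wild-type disease-related network of one tissue.

    ``graph`` nodes carry a boolean ``is_deg`` attribute; every edge has at
    least one DEG endpoint, and the node set is the union of edge endpoints.
    """

    graph: nx.Graph
    tissue: str = ""

    @property
    def deg_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("is_deg")}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_wdrn(
    filtered_ppi: PPINetwork, deg_set: Iterable[str], tissue_label: str = ""
) -> WDRN:
    """Keep the PPI edges with at least one endpoint in ``deg_set``.

    DEGs absent from the PPI, and DEGs whose every incident interaction was
    filtered away, do not appear in the result.
    """
    degs = {normalize_gene_id(g) for g in deg_set}
    g = nx.Graph()
    for u, v, d in filtered_ppi.graph.edges(data=True):
        if u in degs or v in degs:
            g.add_edge(u, v, score=d["score"])
    for n in g.nodes:
        g.nodes[n]["is_deg"] = n in degs
    return WDRN(g, tissue=tissue_label)


def deg_coverage_pct(n_deg_nodes: int, n_nodes: int) -> float:
    """Percentage of network nodes that are DEGs, truncated to two decimals.

    Truncation (flooring at the second decimal) rather than rounding; computed
    in exact integer arithmetic so e.g. 859/5195 gives 16.53, not 16.54.
    """
    if n_nodes <= 0:
        raise ValueError("coverage undefined for an empty network")
    if n_deg_nodes < 0 or n_deg_nodes > n_nodes:
        raise ValueError("DEG node count must lie in [0, n_nodes]")
    return (n_deg_nodes * 10_000 // n_nodes) / 100


@dataclass
class CoverageStats:
    """Edge/node composition of a network and its DEG coverage.

    ``deg_coverage_pct`` is None for an empty network (coverage undefined).
    """

    n_edges: int
    n_nodes: int
    n_deg_nodes: int
    deg_coverage_pct: float | None

    def to_dict(self) -> dict:
        return {
            "n_edges": self.n_edges,
            "n_nodes": self.n_nodes,
            "n_deg_nodes": self.n_deg_nodes,
            "deg_coverage_pct": self.deg_coverage_pct,
        }


def coverage_stats(network: WDRN | nx.Graph) -> CoverageStats:
    """Composition statistics of a network whose nodes carry ``is_deg`` flags."""
    g = network.graph if isinstance(network, WDRN) else network
    n_nodes = g.number_of_nodes()
    n_deg = sum(1 for _, d in g.nodes(data=True) if d.get("is_deg"))
    pct = deg_coverage_pct(n_deg, n_nodes) if n_nodes else None
    return CoverageStats(g.number_of_edges(), n_nodes, n_deg, pct)


# --- on-disk representation -------------------------------------------------

def write_wdrn(wdrn: WDRN, directory: str | Path) -> dict[str, Path]:
    """Write edge TSV, node TSV, GraphML and coverage JSON into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": directory / "edges.tsv",
        "nodes": directory / "nodes.tsv",
        "graphml": directory / "network.graphml",
        "coverage": directory / "coverage.json",
    }
    edges = sorted(
        (*edge_key(u, v), int(d["score"]))
        for u, v, d in wdrn.graph.edges(data=True)
    )
    pd.DataFrame(edges, columns=["gene_a", "gene_b", "score"]).to_csv(
        paths["edges"], sep="\t", index=False
    )
    nodes = sorted(
        (n, bool(d.get("is_deg"))) for n, d in wdrn.graph.nodes(data=True)
    )
    pd.DataFrame(nodes, columns=["gene_id", "is_deg"]).to_csv(
        paths["nodes"], sep="\t", index=False
    )
    g = nx.Graph()
    g.add_nodes_from(sorted(wdrn.graph.nodes))
    g.add_edges_from(sorted(map(lambda e: edge_key(*e), wdrn.graph.edges)))
    for n in g.nodes:
        g.nodes[n]["is_deg"] = bool(wdrn.graph.nodes[n].get("is_deg"))
    for u, v in g.edges:
        g.edges[u, v]["score"] = int(wdrn.graph.edges[u, v]["score"])
    g.graph["tissue"] = wdrn.tissue
    nx.write_graphml(g, paths["graphml"])
    stats = coverage_stats(wdrn)
    paths["coverage"].write_text(
        json.dumps(stats.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    return paths


def read_wdrn(directory: str | Path) -> WDRN:
    """Read a WDRN back from the layout produced by :func:`write_wdrn`."""
    directory = Path(directory)
    edges = pd.read_csv(directory / "edges.tsv", sep="\t", dtype={0: str, 1: str})
    nodes = pd.read_csv(directory / "nodes.tsv", sep="\t", dtype={0: str})
    g = nx.Graph()
    for a, b, score in edges.itertuples(index=False, name=None):
        g.add_edge(normalize_gene_id(a), normalize_gene_id(b), score=int(score))
    for gene, is_deg in nodes.itertuples(index=False, name=None):
        gene = normalize_gene_id(gene)
        if gene not in g:
            g.add_node(gene)
        g.nodes[gene]["is_deg"] = bool(is_deg)
    tissue = ""
    graphml = directory / "network.graphml"
    if graphml.exists():
        tissue = nx.read_graphml(graphml).graph.get("tissue", "")
    return WDRN(g, tissue=tissue)


def read_deg_set(path: str | Path) -> set[str]:
    """DEG gene-id set from a DEG table TSV (rows with is_deg true)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "is_deg" in df.columns:
        df = df[df["is_deg"].astype(bool)]
    return {normalize_gene_id(g) for g in df["gene_id"]}


def coverage_from_counts(counts: Mapping[str, tuple[int, int, int]]) -> dict[str, CoverageStats]:
    """Coverage stats from (n_edges, n_nodes, n_deg_nodes) count triples."""
    return {
        label: CoverageStats(e, n, d, deg_coverage_pct(d, n))
        for label, (e, n, d) in counts.items()
    }
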