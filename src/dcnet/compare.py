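"""Cross-tissue set algebra: Venn partitions, housekeeping sets, shared hubs.

'Housekeeping' follows the multi-tissue-comparison usage — a gene (or gene
pair) that is differential in every tissue analyzed — NOT the conventional
constitutive-expression meaning.  A housekeeping DCG is an unordered gene
pair with a non-'none' differential-correlation status in all tissues,
irrespective of the gained/lost direction; the per-tissue directions are
reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._util import edge_key
from .dcg import DifferentialNetwork, EdgeCorrelation
from .mcode import HubGene


@dataclass
class VennPartition:
    """Exclusive region decomposition of labeled sets.

    ``regions`` maps every nonempty label subset (2^k − 1 regions) to the
    elements belonging to exactly those sets; regions are pairwise disjoint
    and their union is the union of the inputs.
    """

    labels: tuple[str, ...]
    regions: dict[frozenset[str], frozenset]

    def counts(self) -> dict[frozenset[str], int]:
        return {region: len(members) for region, members in self.regions.items()}

    def region(self, *labels: str) -> frozenset:
        return self.regions[frozenset(labels)]

    def union_size(self) -> int:
        return sum(len(m) for m in self.regions.values())


def _as_labeled_sets(sets) -> list[tuple[str, set]]:
    items = list(sets.items()) if isinstance(sets, Mapping) else list(sets)
    labels = [label for label, _ in items]
    if len(set(labels)) != len(labels):
        dup = next(l for l in labels if labels.count(l) > 1)
        raise ValueError(f"duplicate tissue label {dup!r}")
    return [(label, set(elements)) for label, elements in items]


def venn_partition(sets) -> VennPartition:
    """Partition elements of >= 2 labeled sets by exact membership signature."""
    items = _as_labeled_sets(sets)
    if len(items) < 2:
        raise ValueError("need at least two labeled sets")
    labels = tuple(label for label, _ in items)
    membership = {label: elements for label, elements in items}
    universe = set().union(*membership.values())
    regions: dict[frozenset[str], set] = {
        frozenset(subset): set()
        for r in range(1, len(labels) + 1)
        for subset in combinations(labels, r)
    }
    for element in universe:
        signature = frozenset(l for l in labels if element in membership[l])
        regions[signature].add(element)
    return VennPartition(labels, {k: frozenset(v) for k, v in regions.items()})


@dataclass
class HousekeepingResult:
    """Genes / gene pairs differential in every tissue.

    ``housekeeping_dcgs`` maps each unordered pair to its per-tissue
    gained/lost direction.
    """

    housekeeping_degs: frozenset[str]
    housekeeping_dcgs: dict[tuple[str, str], dict[str, str]]


def _edge_statuses(dn) -> dict[tuple[str, str], str]:
    if isinstance(dn, DifferentialNetwork):
        return dn.edge_statuses()
    if hasattr(dn, "edges"):  # bare graph with status edge attributes
        return {
            edge_key(u, v): d["status"]
            for u, v, d in dn.edges(data=True)
            if d.get("status", "none") != "none"
        }
    statuses: dict[tuple[str, str], str] = {}
    for ec in dn:
        if isinstance(ec, EdgeCorrelation):
            if ec.status != "none":
                statuses[edge_key(ec.gene_a, ec.gene_b)] = ec.status
        else:
            a, b, status = ec
            if status != "none":
                statuses[edge_key(a, b)] = status
    return statuses


def housekeeping(
    per_tissue_degs: Mapping[str, Iterable[str]],
    per_tissue_dns: Mapping[str, object],
) -> HousekeepingResult:
    """Intersect DEG sets and DCG pair sets across all tissues."""
    if len(per_tissue_degs) < 2 or len(per_tissue_dns) < 2:
        raise ValueError("need at least two tissues")
    deg_sets = [set(genes) for genes in per_tissue_degs.values()]
    hk_degs = frozenset(set.intersection(*deg_sets))
    statuses = {tissue: _edge_statuses(dn) for tissue, dn in per_tissue_dns.items()}
    pair_sets = [set(s) for s in statuses.values()]
    hk_pairs = set.intersection(*pair_sets) if pair_sets else set()
    hk_dcgs = {
        pair: {tissue: statuses[tissue][pair] for tissue in sorted(statuses)}
        for pair in sorted(hk_pairs)
    }
    return HousekeepingResult(hk_degs, hk_dcgs)


def shared_hubs(
    hubs_by_tissue: Mapping[str, Sequence[HubGene]],
) -> dict[frozenset[str], dict[str, dict[str, int]]]:
    """Hubs present in every tissue of each tissue subset (pairs and k-way).

    Returns, for every subset of >= 2 tissues, a mapping
    gene -> {tissue: hub_score}.
    """
    scores = {
        tissue: {h.gene_id: h.hub_score for h in hubs}
        for tissue, hubs in hubs_by_tissue.items()
    }
    out: dict[frozenset[str], dict[str, dict[str, int]]] = {}
    tissues = sorted(scores)
    for r in range(2, len(tissues) + 1):
        for subset in combinations(tissues, r):
            common = set.intersection(*(set(scores[t]) for t in subset))
            out[frozenset(subset)] = {
                gene: {t: scores[t][gene] for t in subset} for gene in sorted(common)
            }
    return out


def write_venn_tables(partition: VennPartition, directory: str | Path, prefix: str) -> list[Path]:
    """One membership TSV per Venn region (elements may be strings or pairs)."""
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for region in sorted(partition.regions, key=lambda r: (len(r), sorted(r))):
        name = "_and_".join(sorted(region))
        path = directory / f"{prefix}.{name}.tsv"
        members = sorted(
            "|".join(m) if isinstance(m, tuple) else str(m)
            for m in partition.regions[region]
        )
        pd.DataFrame({"member": members}).to_csv(path, sep="\t", index=False)
        written.append(path)
    return written


def venn_figure(partition: VennPartition, path: str | Path) -> None:
    """Three-set Venn counts as an SVG drawn with plain matplotlib circles."""
    if len(partition.labels) != 3:
        raise ValueError("the Venn figure supports exactly three sets")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    a, b, c = partition.labels
    centers = {a: (-0.5, 0.3), b: (0.5, 0.3), c: (0.0, -0.55)}
    counts = partition.counts()
    positions = {
        frozenset([a]): (-0.95, 0.55),
        frozenset([b]): (0.95, 0.55),
        frozenset([c]): (0.0, -1.1),
        frozenset([a, b]): (0.0, 0.65),
        frozenset([a, c]): (-0.6, -0.35),
        frozenset([b, c]): (0.6, -0.35),
        frozenset([a, b, c]): (0.0, 0.0),
    }
    fig, ax = plt.subplots(figsize=(5, 5))
    for label, center in centers.items():
        ax.add_patch(Circle(center, 1.0, alpha=0.25, label=label))
        ax.annotate(label, center, xytext=(center[0] * 1.9, center[1] * 2.2),
                    ha="center", fontsize=10)
    for region, pos in positions.items():
        ax.annotate(str(counts[region]), pos, ha="center", fontsize=9)
    ax.set_xlim(-2.2, 2.2)
    ax.set_ylim(-2.4, 2.0)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, format="svg", metadata={"Date": None})
    plt.close(fig)
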