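"""Synthetic scored PPI networks and two-condition expression matrices.

The generator emulates the data regime of small-animal two-group expression
studies: a scale-free scored protein–protein interaction network, log2-scale
expression with Gaussian noise, a planted fraction of differentially
expressed genes with a fixed log2 shift of random sign, and planted
condition-specific correlated gene pairs confined to high-confidence PPI
edges, together with ground-truth tables so that every downstream stage can
be benchmarked without any external download.

Correlation planting uses a latent-factor construction: for a 'gained' pair,
the disease-condition samples of both endpoint genes share a standard-normal
factor with loading beta = noise_sd * sqrt(rho / (1 - rho)), which makes the
model Pearson correlation of the pair exactly ``target_rho`` while the
healthy samples stay independent ('lost' pairs are symmetric).  Genes that
participate in several planted pairs receive an independent factor per pair;
the per-pair correlation is then attenuated below the target and a residual
cross-pair correlation appears — accepted and documented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import edge_key
from .expression import ExpressionMatrix
from .wdrn import PPINetwork

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ConfigurationError",
    "factor_loading",
    "generate_ppi",
    "generate_expression",
    "write_fixture",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally infeasible."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic tissue.

    Defaults describe a desk-scale two-group design with six samples per
    condition (a 3-per-condition preset mirrors small public array sets:
    use ``replace(cfg, n_healthy=3, n_disease=3)``).
    """

    n_genes: int = 200
    n_ppi_edges: int = 600
    score_range: tuple[int, int] = (700, 999)
    fraction_above_900: float | None = 0.35
    n_healthy: int = 6
    n_disease: int = 6
    baseline_mean_range: tuple[float, float] = (4.0, 12.0)
    noise_sd: float = 0.5
    deg_fraction: float = 0.2
    deg_shift: float = 1.0
    dcg_fraction_of_edges: float = 0.05
    target_rho: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_ppi_edges < 1:
            raise ConfigurationError("counts must be positive")
        if self.n_healthy < 1 or self.n_disease < 1:
            raise ConfigurationError("sample counts must be positive")
        lo, hi = self.score_range
        if not (150 <= lo <= hi <= 999):
            raise ConfigurationError("score_range must lie within [150, 999]")
        if self.fraction_above_900 is not None:
            if not 0.0 <= self.fraction_above_900 <= 1.0:
                raise ConfigurationError("fraction_above_900 must lie in [0, 1]")
            if self.fraction_above_900 > 0 and hi <= 900:
                raise ConfigurationError(
                    "fraction_above_900 > 0 requires score_range to reach above 900"
                )
            if self.fraction_above_900 < 1 and lo > 900:
                raise ConfigurationError(
                    "fraction_above_900 < 1 requires score_range to reach 900 or below"
                )
        for name in ("deg_fraction", "dcg_fraction_of_edges"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.target_rho < 1.0:
            raise ConfigurationError("target_rho must lie strictly inside (0, 1)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.n_ppi_edges > self.n_genes * (self.n_genes - 1) // 2:
            raise ConfigurationError(
                f"{self.n_ppi_edges} edges infeasible for {self.n_genes} genes"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Planted signal: DEG set and directionally labeled DCG edges."""

    true_degs: frozenset[str]
    gained_edges: frozenset[tuple[str, str]]
    lost_edges: frozenset[tuple[str, str]]

    @property
    def true_dcg_edges(self) -> dict[tuple[str, str], str]:
        out = {e: "gained" for e in self.gained_edges}
        out.update({e: "lost" for e in self.lost_edges})
        return out

    @classmethod
    def empty(cls) -> "GroundTruth":
        return cls(frozenset(), frozenset(), frozenset())


def factor_loading(noise_sd: float, target_rho: float) -> float:
    """Latent-factor loading beta = sigma * sqrt(rho / (1 - rho)).

    With x = mu + beta*z + eps, eps ~ N(0, sigma²) and z shared between the
    two genes of a pair, corr(x_a, x_b) = beta² / (beta² + sigma²) = rho.
    """
    return noise_sd * math.sqrt(target_rho / (1.0 - target_rho))


def _gene_ids(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


def generate_ppi(config: SimulationConfig) -> PPINetwork:
    """Scale-free scored PPI by preferential attachment.

    Nodes are attached one at a time to a degree-weighted existing node
    (yielding a preferential-attachment tree); remaining edges join
    degree-weighted distinct non-adjacent pairs.  Scores are integers from
    ``score_range``; when ``fraction_above_900`` is set, each edge falls above
    900 with that probability (uniform within the admissible part of the
    range on either side).
    """
    rng = np.random.default_rng([config.seed, 0])
    genes = _gene_ids(config.n_genes)
    n_edges = config.n_ppi_edges
    import networkx as nx

    g = nx.Graph()
    g.add_edge(genes[0], genes[1])
    attached = [genes[0], genes[1]]
    degree = {genes[0]: 1, genes[1]: 1}
    next_new = 2

    def _weighted_pick(exclude: str | None = None) -> str:
        nodes = [n for n in attached if n != exclude]
        weights = np.array([degree[n] for n in nodes], dtype=float)
        return nodes[rng.choice(len(nodes), p=weights / weights.sum())]

    while g.number_of_edges() < n_edges:
        if next_new < config.n_genes:
            new = genes[next_new]
            target = _weighted_pick()
            g.add_edge(new, target)
            degree[new] = 1
            degree[target] += 1
            attached.append(new)
            next_new += 1
        else:
            for _ in range(10_000):
                u = _weighted_pick()
                v = _weighted_pick(exclude=u)
                if not g.has_edge(u, v):
                    g.add_edge(u, v)
                    degree[u] += 1
                    degree[v] += 1
                    break
            else:  # pragma: no cover - dense pathological configs
                raise ConfigurationError("could not place a further distinct edge")

    lo, hi = config.score_range
    for u, v in sorted(edge_key(a, b) for a, b in g.edges):
        if config.fraction_above_900 is None:
            score = int(rng.integers(lo, hi + 1))
        elif rng.random() < config.fraction_above_900:
            score = int(rng.integers(max(lo, 901), hi + 1))
        else:
            score = int(rng.integers(lo, min(hi, 900) + 1))
        g.edges[u, v]["score"] = score
    return PPINetwork(g)


def generate_expression(
    ppi: PPINetwork,
    config: SimulationConfig,
    truth: GroundTruth | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Two-condition expression matrices with planted DEGs and DCG pairs.

    Baseline per-gene means are drawn once and shared across conditions;
    planted DEGs receive a ±deg_shift offset in the disease means.  Planted
    DCG edges are drawn from the PPI edges that both carry a combined score
    above 900 and touch a planted DEG, so that every planted edge survives
    the default WDRN construction.  Passing an existing ``truth`` reuses its
    planted structure (e.g. to share signal across tissues) while drawing
    fresh noise from ``config.seed``.
    """
    if ppi.n_edges == 0:
        raise ConfigurationError("PPI network is empty")
    rng = np.random.default_rng([config.seed, 1])
    genes = _gene_ids(config.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    baselines = rng.uniform(*config.baseline_mean_range, size=config.n_genes)

    if truth is None:
        n_degs = round(config.deg_fraction * config.n_genes)
        deg_idx = sorted(rng.choice(config.n_genes, size=n_degs, replace=False))
        true_degs = frozenset(genes[i] for i in deg_idx)
        signs = {genes[i]: (1.0 if rng.random() < 0.5 else -1.0) for i in deg_idx}

        n_dcg = round(config.dcg_fraction_of_edges * config.n_ppi_edges)
        eligible = [
            (a, b)
            for a, b, score in ppi.edges()
            if score > 900 and (a in true_degs or b in true_degs)
        ]
        if n_dcg > len(eligible):
            raise ConfigurationError(
                f"requested {n_dcg} planted DCG edges but only {len(eligible)} "
                "high-confidence edges touch a planted DEG"
            )
        # prefer a matching: each planted pair's model correlation equals
        # target_rho only when its genes host no other planted factor, so
        # endpoint sharing is allowed only once disjoint edges run out
        order = rng.permutation(len(eligible))
        chosen: list[tuple[str, str]] = []
        used: set[str] = set()
        for i in order:
            a, b = eligible[i]
            if len(chosen) == n_dcg:
                break
            if a not in used and b not in used:
                chosen.append((a, b))
                used.update((a, b))
        if len(chosen) < n_dcg:
            taken = set(chosen)
            for i in order:
                if len(chosen) == n_dcg:
                    break
                if eligible[i] not in taken:
                    chosen.append(eligible[i])
                    taken.add(eligible[i])
        gained, lost = [], []
        for e in sorted(chosen):
            (gained if rng.random() < 0.5 else lost).append(e)
        truth = GroundTruth(true_degs, frozenset(gained), frozenset(lost))
    else:
        signs = {}
        ppi_edges = {edge_key(a, b) for a, b, _ in ppi.edges()}
        for e in truth.true_dcg_edges:
            if e not in ppi_edges:
                raise ConfigurationError(f"ground-truth edge {e} is not a PPI edge")

    # sign draws for a reused truth come after the structural block above so a
    # fresh-vs-reused truth with the same seed still shifts the same way
    if not signs:
        signs = {
            g: (1.0 if rng.random() < 0.5 else -1.0) for g in sorted(truth.true_degs)
        }

    disease_means = baselines.copy()
    for g in sorted(truth.true_degs):
        if g in gene_pos:
            disease_means[gene_pos[g]] += signs[g] * config.deg_shift

    h = baselines[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, config.n_healthy)
    )
    d = disease_means[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, config.n_disease)
    )
    beta = factor_loading(config.noise_sd, config.target_rho)
    for a, b in sorted(truth.gained_edges):
        z = rng.standard_normal(config.n_disease)
        d[gene_pos[a]] += beta * z
        d[gene_pos[b]] += beta * z
    for a, b in sorted(truth.lost_edges):
        z = rng.standard_normal(config.n_healthy)
        h[gene_pos[a]] += beta * z
        h[gene_pos[b]] += beta * z

    h_samples = [f"H{i:03d}" for i in range(1, config.n_healthy + 1)]
    d_samples = [f"D{i:03d}" for i in range(1, config.n_disease + 1)]
    healthy = ExpressionMatrix(
        pd.DataFrame(h, index=pd.Index(genes, name="gene_id"), columns=h_samples),
        pd.Series("healthy", index=h_samples),
    )
    disease = ExpressionMatrix(
        pd.DataFrame(d, index=pd.Index(genes, name="gene_id"), columns=d_samples),
        pd.Series("disease", index=d_samples),
    )
    return healthy, disease, truth


def write_fixture(
    ppi: PPINetwork,
    healthy: ExpressionMatrix,
    disease: ExpressionMatrix,
    truth: GroundTruth,
    directory: str | Path,
) -> dict[str, Path]:
    """Write the fixture as plain TSVs round-tripping through the readers.

    Files: STRING-dialect ``ppi.tsv``; combined ``expression.tsv`` and
    ``conditions.tsv``; ``true_degs.tsv`` and ``true_dcg_edges.tsv``.
    No timestamps are embedded: identical inputs give identical bytes.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"cannot create fixture directory {directory}: {exc}") from exc
    paths = {
        "ppi": directory / "ppi.tsv",
        "expression": directory / "expression.tsv",
        "conditions": directory / "conditions.tsv",
        "true_degs": directory / "true_degs.tsv",
        "true_dcg_edges": directory / "true_dcg_edges.tsv",
    }
    ppi.to_tsv(paths["ppi"])
    combined = ExpressionMatrix.concat(healthy, disease)
    combined.data.to_csv(paths["expression"], sep="\t", index=True, float_format="%.10g")
    pd.DataFrame(
        {"sample_id": combined.data.columns, "condition": combined.conditions.to_numpy()}
    ).to_csv(paths["conditions"], sep="\t", index=False)
    pd.DataFrame({"gene_id": sorted(truth.true_degs)}).to_csv(
        paths["true_degs"], sep="\t", index=False
    )
    dcg_rows = sorted(
        [(a, b, "gained") for a, b in truth.gained_edges]
        + [(a, b, "lost") for a, b in truth.lost_edges]
    )
    pd.DataFrame(dcg_rows, columns=["gene_a", "gene_b", "direction"]).to_csv(
        paths["true_dcg_edges"], sep="\t", index=False
    )
    return paths


def read_ground_truth(directory: str | Path) -> GroundTruth:
    """Read ground-truth tables written by :func:`write_fixture`."""
    directory = Path(directory)
    degs = pd.read_csv(directory / "true_degs.tsv", sep="\t", dtype=str)
    dcgs = pd.read_csv(directory / "true_dcg_edges.tsv", sep="\t", dtype=str)
    gained, lost = [], []
    for a, b, direction in dcgs.itertuples(index=False, name=None):
        (gained if direction == "gained" else lost).append(edge_key(a, b))
    return GroundTruth(
        frozenset(degs["gene_id"]) if len(degs) else frozenset(),
        frozenset(gained),
        frozenset(lost),
    )


def three_sample_preset(config: SimulationConfig) -> SimulationConfig:
    """The 3-samples-per-condition variant of a configuration."""
    return replace(config, n_healthy=3, n_disease=3)
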