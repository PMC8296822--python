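"""Differentially correlated gene pairs (DCGs) and the differential network (DN).

For every edge of a tissue's WDRN, the Spearman rank correlation of the two
endpoint genes is tested separately under the healthy and the disease
condition.  An edge is a DCG when the correlation is significant (p < alpha)
in exactly one condition: 'gained' when significant only in disease, 'lost'
when significant only in health.  The DN is the WDRN subgraph of DCG edges;
each edge carries the perturbation rho_disease − rho_healthy, whose absolute
value is used as a width weight when rendering.

Significance uses an exact two-sided permutation test by default in the
small-sample regime (all n! rank orderings enumerated; the observed ordering
counts, so p > 0), because the usual t approximation is anticonservative at
the 3–6 samples per condition typical of these designs.  A ``t_approx`` mode
using t = r√((n−2)/(1−r²)) on n−2 df is provided for compatibility with
pipelines that relied on the approximation.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._util import edge_key
from .wdrn import WDRN

logger = logging.getLogger(__name__)

_EXACT_MAX_N = 8  # 8! = 40,320 orderings; beyond this `auto` switches to t
_TINY_P = 5e-324
_EPS = 1e-12

STATUSES = ("gained", "lost", "none")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation r_s = S_uv / sqrt(S_u² S_v²).

    Pearson's correlation of the average ranks of x and y.  Returns NaN (the
    undefined marker) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("need at least three observations")
    u = stats.rankdata(x)
    v = stats.rankdata(y)
    du = u - u.mean()
    dv = v - v.mean()
    su2 = float(du @ du)
    sv2 = float(dv @ dv)
    if su2 == 0.0 or sv2 == 0.0:
        return float("nan")
    # the (n-1) normalizations of S_uv, S_u², S_v² cancel
    return float((du @ dv) / math.sqrt(su2 * sv2))


@lru_cache(maxsize=16)
def _null_abs_rho(n: int) -> np.ndarray:
    """Sorted |r_s| over all n! permutations of untied ranks 1..n."""
    u = np.arange(1, n + 1, dtype=float)
    perms = np.array(list(itertools.permutations(u)), dtype=float)
    return np.sort(np.abs(_rho_against(u, perms)))


def _rho_against(u: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """r_s of fixed rank vector u against each row of a rank matrix."""
    du = u - u.mean()
    dv = perms - perms.mean(axis=1, keepdims=True)
    su2 = float(du @ du)
    sv2 = (dv * dv).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (dv @ du) / np.sqrt(su2 * sv2)


def _exact_pvalue(rho: float, n: int, ranks_x=None, ranks_y=None) -> float:
    if ranks_x is not None and ranks_y is not None:
        u = np.asarray(ranks_x, dtype=float)
        perms = np.array(list(itertools.permutations(np.asarray(ranks_y, dtype=float))))
        null = np.abs(_rho_against(u, perms))
        return float((null >= abs(rho) - _EPS).sum() / len(null))
    null = _null_abs_rho(n)
    idx = np.searchsorted(null, abs(rho) - _EPS, side="left")
    return float((null.size - idx) / null.size)


def exact_attained_level(alpha: float, n: int) -> float:
    """Largest achievable p-value of the exact test that is below ``alpha``.

    This is the effective per-test type-I error of the discrete exact
    permutation test at nominal level ``alpha`` (untied ranks): the test
    rejects with exactly this probability under the null.
    """
    null = _null_abs_rho(n)
    m = null.size
    # achievable p for observed |rho| = r is P(|rho_perm| >= r)
    pvals = np.unique([(m - np.searchsorted(null, r - _EPS)) / m for r in np.unique(null)])
    below = pvals[pvals < alpha]
    return float(below.max()) if below.size else 0.0


def spearman_pvalue(
    rho: float,
    n: int,
    method: str = "auto",
    x: Sequence[float] | None = None,
    y: Sequence[float] | None = None,
) -> float:
    """Two-sided p-value for an observed Spearman correlation.

    'exact' enumerates all n! equally likely rank orderings and counts those
    at least as extreme as observed (conditioning on the observed tie pattern
    when the data vectors are supplied and tied).  't_approx' uses the
    t = r√((n−2)/(1−r²)) approximation on n−2 df, with the smallest
    representable positive p when |r| = 1.  'auto' uses the exact test when
    n <= 8 and the data are untied (or not supplied), the approximation
    otherwise.
    """
    if method not in ("exact", "t_approx", "auto"):
        raise ValueError(f"unknown method {method!r}")
    if not n >= 3:
        raise ValueError("need at least three observations")
    if math.isnan(rho):
        return float("nan")
    if abs(rho) > 1 + _EPS:
        raise ValueError("|rho| cannot exceed 1")
    rho = max(-1.0, min(1.0, rho))

    ranks_x = ranks_y = None
    has_ties = False
    if x is not None and y is not None:
        ranks_x = stats.rankdata(np.asarray(x, dtype=float))
        ranks_y = stats.rankdata(np.asarray(y, dtype=float))
        has_ties = len(set(ranks_x)) < n or len(set(ranks_y)) < n

    if method == "auto":
        method = "exact" if (n <= _EXACT_MAX_N and not has_ties) else "t_approx"

    if method == "exact":
        if n > _EXACT_MAX_N:
            raise ValueError(f"exact enumeration limited to n <= {_EXACT_MAX_N}")
        if has_ties:
            return _exact_pvalue(rho, n, ranks_x, ranks_y)
        return _exact_pvalue(rho, n)

    if abs(rho) >= 1.0:
        return _TINY_P
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(min(max(p, _TINY_P), 1.0))


@dataclass
class EdgeCorrelation:
    """Condition-wise Spearman statistics for one WDRN edge.

    ``status`` is 'gained' when significant only under disease, 'lost' when
    significant only under health, 'none' otherwise (including edges whose
    correlation is undefined because a gene is constant; their rho/p are NaN).
    """

    gene_a: str
    gene_b: str
    rho_healthy: float
    rho_disease: float
    p_healthy: float
    p_disease: float
    n_healthy: int
    n_disease: int
    status: str

    @property
    def perturbation(self) -> float:
        return self.rho_disease - self.rho_healthy

    @property
    def magnitude(self) -> float:
        return abs(self.perturbation)


def _classify(p_healthy: float, p_disease: float, alpha: float) -> str:
    if math.isnan(p_healthy) or math.isnan(p_disease):
        return "none"
    sig_h = p_healthy < alpha
    sig_d = p_disease < alpha
    if sig_d and not sig_h:
        return "gained"
    if sig_h and not sig_d:
        return "lost"
    return "none"


def classify_edges(
    wdrn: WDRN,
    healthy,
    disease,
    alpha: float = 0.05,
    method: str = "auto",
) -> list[EdgeCorrelation]:
    """Test every WDRN edge for differential correlation.

    ``healthy`` and ``disease`` are gene × sample frames (or ExpressionMatrix
    objects) of the respective conditions.  Edges with a gene missing from
    either matrix are skipped with a warning; edges with a constant expression
    vector get status 'none' with NaN statistics.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    healthy = getattr(healthy, "data", healthy)
    disease = getattr(disease, "data", disease)
    n_h = healthy.shape[1]
    n_d = disease.shape[1]
    h_values = {g: healthy.loc[g].to_numpy(dtype=float) for g in healthy.index}
    d_values = {g: disease.loc[g].to_numpy(dtype=float) for g in disease.index}
    out: list[EdgeCorrelation] = []
    for a, b in sorted(edge_key(u, v) for u, v in wdrn.graph.edges):
        if a not in h_values or b not in h_values or a not in d_values or b not in d_values:
            logger.warning("edge %s–%s skipped: gene missing from an expression matrix", a, b)
            continue
        rho_h = spearman_rho(h_values[a], h_values[b])
        rho_d = spearman_rho(d_values[a], d_values[b])
        p_h = (
            spearman_pvalue(rho_h, n_h, method, x=h_values[a], y=h_values[b])
            if not math.isnan(rho_h)
            else float("nan")
        )
        p_d = (
            spearman_pvalue(rho_d, n_d, method, x=d_values[a], y=d_values[b])
            if not math.isnan(rho_d)
            else float("nan")
        )
        out.append(
            EdgeCorrelation(
                gene_a=a,
                gene_b=b,
                rho_healthy=rho_h,
                rho_disease=rho_d,
                p_healthy=p_h,
                p_disease=p_d,
                n_healthy=n_h,
                n_disease=n_d,
                status=_classify(p_h, p_d, alpha),
            )
        )
    return out


@dataclass
class DifferentialNetwork:
    """DN of one tissue: the WDRN subgraph of DCG edges.

    Edge attributes: rho/p per condition, status, perturbation, magnitude and
    sign (+1 for gained / activated in disease, −1 for lost / inactivated,
    the red/green convention of module renderings).  Nodes keep is_deg flags.
    """

    graph: nx.Graph
    tissue: str = ""

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_statuses(self) -> dict[tuple[str, str], str]:
        return {
            edge_key(u, v): d["status"] for u, v, d in self.graph.edges(data=True)
        }


def build_dn(
    edge_correlations: Iterable[EdgeCorrelation], wdrn: WDRN
) -> DifferentialNetwork:
    """Assemble the differential network from classified WDRN edges."""
    g = nx.Graph()
    for ec in edge_correlations:
        if ec.status == "none":
            continue
        g.add_edge(
            ec.gene_a,
            ec.gene_b,
            rho_healthy=ec.rho_healthy,
            rho_disease=ec.rho_disease,
            p_healthy=ec.p_healthy,
            p_disease=ec.p_disease,
            status=ec.status,
            perturbation=ec.perturbation,
            magnitude=ec.magnitude,
            sign=1 if ec.status == "gained" else -1,
        )
    for n in g.nodes:
        g.nodes[n]["is_deg"] = bool(wdrn.graph.nodes[n].get("is_deg", False))
    return DifferentialNetwork(g, tissue=wdrn.tissue)


def correlations_to_frame(edge_correlations: Iterable[EdgeCorrelation]) -> pd.DataFrame:
    rows = [
        {
            "gene_a": ec.gene_a,
            "gene_b": ec.gene_b,
            "rho_healthy": ec.rho_healthy,
            "p_healthy": ec.p_healthy,
            "rho_disease": ec.rho_disease,
            "p_disease": ec.p_disease,
            "status": ec.status,
            "perturbation": ec.perturbation,
        }
        for ec in edge_correlations
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_a",
            "gene_b",
            "rho_healthy",
            "p_healthy",
            "rho_disease",
            "p_disease",
            "status",
            "perturbation",
        ],
    )


def write_dn(
    dn: DifferentialNetwork,
    edge_correlations: Iterable[EdgeCorrelation],
    directory: str | Path,
) -> dict[str, Path]:
    """Write the DN edge table, GraphML, SIF export and coverage JSON."""
    import json

    from .wdrn import coverage_stats

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": directory / "dn_edges.tsv",
        "graphml": directory / "network.graphml",
        "sif": directory / "network.sif",
        "coverage": directory / "coverage.json",
    }
    correlations_to_frame(edge_correlations).to_csv(paths["edges"], sep="\t", index=False)
    g = nx.Graph()
    g.add_nodes_from(sorted(dn.graph.nodes))
    for u, v in sorted(edge_key(a, b) for a, b in dn.graph.edges):
        g.add_edge(u, v, **dn.graph.edges[u, v])
    for n in g.nodes:
        g.nodes[n]["is_deg"] = bool(dn.graph.nodes[n].get("is_deg"))
    g.graph["tissue"] = dn.tissue
    nx.write_graphml(g, paths["graphml"])
    with open(paths["sif"], "w") as fh:
        for u, v in sorted(edge_key(a, b) for a, b in dn.graph.edges):
            fh.write(f"{u}\tdcg\t{v}\n")
    paths["coverage"].write_text(
        json.dumps(coverage_stats(dn.graph).to_dict(), indent=2, sort_keys=True) + "\n"
    )
    return paths
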