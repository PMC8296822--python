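"""Configured end-to-end pipeline: simulate → DEG → WDRN → DCG/DN → modules → compare.

One run generates (or loads) per-tissue two-condition expression data and a
shared scored PPI, calls DEGs per tissue, builds the score-filtered WDRN,
classifies differentially correlated pairs into a differential network,
extracts dense modules and hub genes per tissue and in the merged network,
and writes every intermediate artifact plus a deterministic JSON summary.
Reruns with the same configuration produce byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from . import compare as cmp
from . import dcg as dcgmod
from . import expression as expr
from . import mcode
from . import simulate as sim
from . import wdrn as wdrnmod

logger = logging.getLogger(__name__)

DEFAULT_TISSUES = ("adipose", "cerebral_artery", "heart")


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run; YAML round-trippable."""

    tissues: tuple[str, ...] = DEFAULT_TISSUES
    simulation: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    share_truth: bool = False  # reuse tissue 0's planted signal in all tissues
    deg_method: str = "moderated"
    p_threshold: float = 0.05
    lfc_threshold: float = 0.5
    min_score: int = 900
    strict_score_filter: bool = True
    alpha: float = 0.05
    corr_method: str = "auto"
    vwp: float = 0.2
    haircut: bool = True
    min_component_score: float = 3.0
    hub_threshold: int = 10
    merge_on: str = "wdrn"  # or "dn"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tissues"] = list(self.tissues)
        d["simulation"]["score_range"] = list(self.simulation.score_range)
        d["simulation"]["baseline_mean_range"] = list(self.simulation.baseline_mean_range)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        simd = dict(d.pop("simulation", {}))
        for key in ("score_range", "baseline_mean_range"):
            if key in simd:
                simd[key] = tuple(simd[key])
        d["simulation"] = sim.SimulationConfig(**simd)
        if "tissues" in d:
            d["tissues"] = tuple(d["tissues"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute every stage for every tissue; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_resolved.yaml")
    logger.info("resolved config: %s", json.dumps(config.to_dict(), sort_keys=True))

    base = replace(config.simulation, seed=config.seed)
    ppi = sim.generate_ppi(base)
    filtered = wdrnmod.filter_ppi(ppi, config.min_score, config.strict_score_filter)

    summary: dict = {"tissues": {}, "compare": {}}
    deg_sets: dict[str, set[str]] = {}
    dns: dict[str, dcgmod.DifferentialNetwork] = {}
    wdrns: dict[str, wdrnmod.WDRN] = {}
    hubs_by_tissue: dict[str, list[mcode.HubGene]] = {}
    shared_truth: sim.GroundTruth | None = None

    for i, tissue in enumerate(config.tissues):
        stage = f"tissue {tissue}"
        try:
            tdir = out / tissue
            tcfg = replace(config.simulation, seed=config.seed + i + 1)
            healthy, disease, truth = sim.generate_expression(
                ppi, tcfg, truth=shared_truth
            )
            if config.share_truth and shared_truth is None:
                shared_truth = truth
            sim.write_fixture(ppi, healthy, disease, truth, tdir / "fixture")

            stage = f"deg calling for {tissue}"
            matrix = expr.ExpressionMatrix.concat(healthy, disease)
            degs = expr.call_degs(
                matrix, config.p_threshold, config.lfc_threshold, config.deg_method
            )
            expr.write_deg_table(degs, tdir / "degs.tsv")
            deg_sets[tissue] = expr.deg_set(degs)

            stage = f"wdrn construction for {tissue}"
            wdrn = wdrnmod.build_wdrn(filtered, deg_sets[tissue], tissue)
            wdrns[tissue] = wdrn
            wdrnmod.write_wdrn(wdrn, tdir / "wdrn")

            stage = f"dcg classification for {tissue}"
            correlations = dcgmod.classify_edges(
                wdrn, healthy, disease, config.alpha, config.corr_method
            )
            dn = dcgmod.build_dn(correlations, wdrn)
            dns[tissue] = dn
            dcgmod.write_dn(dn, correlations, tdir / "dn")

            stage = f"module detection for {tissue}"
            modules = mcode.find_modules(
                dn,
                vwp=config.vwp,
                haircut=config.haircut,
                min_component_score=config.min_component_score,
            )
            mcode.modules_to_frame(modules).to_csv(
                tdir / "modules.tsv", sep="\t", index=False
            )
            hubs = mcode.select_hubs(dn, modules, config.hub_threshold)
            hubs_by_tissue[tissue] = hubs
            mcode.hubs_to_frame(hubs).to_csv(tdir / "hubs.tsv", sep="\t", index=False)

            summary["tissues"][tissue] = {
                "n_degs": len(deg_sets[tissue]),
                "wdrn": wdrnmod.coverage_stats(wdrn).to_dict(),
                "dn": wdrnmod.coverage_stats(dn.graph).to_dict(),
                "n_dcg_edges": dn.n_edges,
                "n_modules": len(modules),
                "hubs": [
                    {"gene_id": h.gene_id, "hub_score": h.hub_score, "rule": h.selection_rule}
                    for h in hubs
                ],
                "n_true_degs": len(truth.true_degs),
                "n_true_dcg_edges": len(truth.true_dcg_edges),
            }
        except Exception as exc:
            raise RuntimeError(f"pipeline stage failed: {stage}: {exc}") from exc

    try:
        stage = "merged-network modules"
        sources = wdrns if config.merge_on == "wdrn" else dns
        merged = mcode.merge_networks(sources)
        merged_modules = mcode.find_modules(
            merged,
            vwp=config.vwp,
            haircut=config.haircut,
            min_component_score=config.min_component_score,
        )
        (out / "merged").mkdir(exist_ok=True)
        mcode.modules_to_frame(merged_modules).to_csv(
            out / "merged" / "modules.tsv", sep="\t", index=False
        )
        summary["merged"] = {
            "merge_on": config.merge_on,
            "n_nodes": merged.number_of_nodes(),
            "n_edges": merged.number_of_edges(),
            "n_modules": len(merged_modules),
        }

        stage = "cross-tissue comparison"
        deg_venn = cmp.venn_partition(deg_sets)
        node_venn = cmp.venn_partition(
            {t: set(dn.graph.nodes) for t, dn in dns.items()}
        )
        edge_venn = cmp.venn_partition(
            {t: set(dn.edge_statuses()) for t, dn in dns.items()}
        )
        cmp.write_venn_tables(deg_venn, out / "venn", "degs")
        cmp.write_venn_tables(node_venn, out / "venn", "dn_nodes")
        cmp.write_venn_tables(edge_venn, out / "venn", "dn_edges")
        hk = cmp.housekeeping(deg_sets, dns)
        shared = cmp.shared_hubs(hubs_by_tissue)

        def _region_key(region: frozenset[str]) -> str:
            return "&".join(sorted(region))

        summary["compare"] = {
            "deg_venn": {_region_key(r): n for r, n in deg_venn.counts().items()},
            "dn_node_venn": {_region_key(r): n for r, n in node_venn.counts().items()},
            "dn_edge_venn": {_region_key(r): n for r, n in edge_venn.counts().items()},
            "housekeeping_degs": sorted(hk.housekeeping_degs),
            "housekeeping_dcgs": {
                "|".join(pair): directions
                for pair, directions in hk.housekeeping_dcgs.items()
            },
            "shared_hubs": {
                _region_key(r): genes for r, genes in shared.items()
            },
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {stage}: {exc}") from exc

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return out
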