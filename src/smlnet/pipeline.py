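"""End-to-end orchestration of the analysis on synthetic or file inputs.

Stage order mirrors the analysis: DEL calling -> SMLN -> SSN/LLN ->
pharmacology -> clique modules (per k) -> co-expression/enrichment for
interface lncRNAs -> tissue specificity and the ATC/anatomy Jaccard map.
Each stage writes its artifacts to the output directory so later stages can
be re-run from cached intermediates; a JSON manifest records the config,
seed, per-stage timings, and a checksum for every artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__, io
from .cliques import annotate_interface_atc, interface_nodes, k_clique_communities
from .coexpression import coexpressed_partners, ora_enrichment
from .diffexpr import associations_from_instances
from .network import (
    build_smln,
    degree_distribution,
    fit_power_law,
    giant_component,
    side_nodes,
    sign_counts,
)
from .pharmacology import compare_connected_vs_rest, permutation_test
from .projections import build_lln, lln_graph, project_ssn
from .synthetic import (
    PlantedTruth,
    SynthConfig,
    generate_coexpression,
    generate_drug_annotations,
    generate_instances,
    generate_tissue_panel,
)
from .tissue import assign_specific, drug_tissue_jaccard_matrix

logger = logging.getLogger("smlnet")


@dataclass
class PipelineConfig:
    """Thresholds, seed and output location for a full run.

    Defaults are the analysis' canonical values: |log2FC| > 1 for DELs,
    p and q < 0.01 for the LLN, |PCC| > 0.5 with p < 0.01 for co-expression,
    k = 8, 9, 10 for clique percolation, specificity > 0.8, and 1000
    permutations.
    """

    outdir: str = "smlnet_out"
    seed: int = 0
    synth: SynthConfig | None = None
    fc_threshold: float = 1.0
    p_cut: float = 0.01
    q_cut: float = 0.01
    pcc_cut: float = 0.5
    pcc_p_cut: float = 0.01
    k_values: tuple[int, ...] = (8, 9, 10)
    specificity_threshold: float = 0.8
    n_perm: int = 1000
    # optional file inputs; when None the synthetic generator supplies them
    expression_path: str | None = None
    manifest_path: str | None = None
    annotations_path: str | None = None

    def __post_init__(self) -> None:
        if self.synth is None:
            self.synth = SynthConfig(seed=self.seed)
        if self.fc_threshold <= 0:
            raise ValueError("fc_threshold must be > 0")
        for name in ("p_cut", "q_cut", "pcc_p_cut"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0 <= self.pcc_cut <= 1:
            raise ValueError("pcc_cut must be in [0, 1]")
        if any(k < 3 for k in self.k_values):
            raise ValueError("all k values must be >= 3")
        if not 0 <= self.specificity_threshold <= 1:
            raise ValueError("specificity_threshold must be in [0, 1]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    artifacts: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    notices: list[str] = field(default_factory=list)
    summary: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Stage:
    def __init__(self, manifest: RunManifest, name: str):
        self.manifest, self.name = manifest, name

    def __enter__(self):
        logger.info("=== stage: %s ===", self.name)
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        self.manifest.timings[self.name] = round(time.perf_counter() - self.t0, 4)
        if exc is not None:
            logger.error("stage %s failed: %s", self.name, exc)
            raise RuntimeError(f"stage {self.name!r} failed: {exc}") from exc
        return False


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage and return the populated run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")

    cfg_dict = dataclasses.asdict(config)
    manifest = RunManifest(config=cfg_dict, seed=config.seed, version=__version__)
    scfg = config.synth

    with _Stage(manifest, "simulate"):
        if config.expression_path is not None:
            expr = io.read_expression(config.expression_path)
            inst_manifest = io.read_table(config.manifest_path)
            truth = PlantedTruth()  # no planted structure known for file inputs
        else:
            expr, inst_manifest, truth = generate_instances(scfg)
            io.write_truth(truth, outdir)
        io.write_expression(expr, outdir / "expression.tsv")
        io.write_table(inst_manifest, outdir / "instance_manifest.tsv")

    with _Stage(manifest, "dels"):
        associations = associations_from_instances(expr, inst_manifest, config.fc_threshold)
        io.write_associations(associations, outdir / "associations.tsv")
        if not associations:
            manifest.notices.append("no associations called: networks are empty")

    with _Stage(manifest, "network"):
        smln = build_smln(associations)
        io.write_graphml(smln, outdir / "smln.graphml")
        io.write_sif(smln, outdir / "smln.sif")
        summary: dict = {
            "n_nodes": smln.number_of_nodes(),
            "n_drugs": len(side_nodes(smln, "drug")),
            "n_lncrnas": len(side_nodes(smln, "lncrna")),
            "n_edges": smln.number_of_edges(),
        }
        if smln.number_of_edges():
            up, down = sign_counts(smln)
            summary["n_up"], summary["n_down"] = up, down
            summary["giant_component_size"] = len(giant_component(smln))
            for sidename in ("drug", "lncrna"):
                try:
                    fitres = fit_power_law(degree_distribution(smln, sidename))
                    summary[f"{sidename}_powerlaw_slope"] = fitres.slope
                    summary[f"{sidename}_powerlaw_r2"] = fitres.r_squared
                except ValueError as e:
                    manifest.notices.append(f"power-law fit skipped for {sidename}: {e}")
        io.write_table(
            pd.DataFrame([summary]), outdir / "network_summary.tsv"
        )
        manifest.summary.update(summary)

    with _Stage(manifest, "project"):
        ssn_edges = project_ssn(smln)
        io.write_ssn_edges(ssn_edges, outdir / "ssn_edges.tsv")
        ssn_g = nx.Graph((e.drug_a, e.drug_b, {"weight": e.weight}) for e in ssn_edges)
        io.write_graphml(ssn_g, outdir / "ssn.graphml")
        lln_edges = build_lln(smln, config.p_cut, config.q_cut)
        io.write_lln_edges(lln_edges, outdir / "lln_edges.tsv")
        lln_g = lln_graph(lln_edges)
        io.write_graphml(lln_g, outdir / "lln.graphml")
        manifest.summary["n_ssn_edges"] = len(ssn_edges)
        manifest.summary["n_lln_edges"] = len(lln_edges)
        if not lln_edges:
            manifest.notices.append("LLN empty at the configured cutoffs")

    with _Stage(manifest, "pharm"):
        if config.annotations_path is not None:
            annotations = io.read_annotations(config.annotations_path)
        else:
            annotations = generate_drug_annotations(scfg, truth)
        io.write_annotations(annotations, outdir / "drug_annotations.tsv")
        connected = [(e.drug_a, e.drug_b) for e in ssn_edges]
        pharm_rows = []
        if connected:
            for fieldname in ("indications", "targets"):
                res = permutation_test(
                    connected, annotations, fieldname,
                    n_perm=config.n_perm, seed=config.seed,
                )
                pharm_rows.append(
                    {
                        "analysis": f"{fieldname}_sharing",
                        "observed": res.observed,
                        "n_pairs": res.n_pairs,
                        "null_mean": float(np.mean(res.null_counts)),
                        "null_max": int(np.max(res.null_counts)),
                        "p_empirical": res.p_empirical,
                        "p_conservative": res.p_conservative,
                    }
                )
                manifest.summary[f"{fieldname}_p_conservative"] = res.p_conservative
            for metric in ("side_effect_ratio", "tanimoto"):
                cmp_res = compare_connected_vs_rest(connected, annotations, metric)
                pharm_rows.append(
                    {
                        "analysis": f"{metric}_connected_vs_rest",
                        "observed": cmp_res.median_connected,
                        "n_pairs": cmp_res.n_connected,
                        "null_mean": cmp_res.median_rest,
                        "null_max": cmp_res.n_rest,
                        "p_empirical": cmp_res.p_value,
                        "p_conservative": cmp_res.p_value,
                    }
                )
                manifest.summary[f"{metric}_p"] = cmp_res.p_value
        else:
            manifest.notices.append("pharmacology skipped: SSN has no edges")
        io.write_table(pd.DataFrame(pharm_rows), outdir / "pharmacology_report.tsv")

    with _Stage(manifest, "modules"):
        atc_map = {d: a.atc_class for d, a in annotations.items()}
        interface_union: set[str] = set()
        module_rows, iface_rows = [], []
        for k in config.k_values:
            cset = k_clique_communities(lln_g, k)
            report = annotate_interface_atc(interface_nodes(cset), smln, atc_map)
            interface_union |= report.interface_nodes
            manifest.summary[f"n_communities_k{k}"] = len(cset.communities)
            manifest.summary[f"n_interface_k{k}"] = len(report.interface_nodes)
            for i, comm in enumerate(cset.communities):
                module_rows.append(
                    {"k": k, "community_index": i, "members": ";".join(comm)}
                )
            for node in sorted(report.interface_nodes):
                iface_rows.append(
                    {
                        "k": k,
                        "lncrna_id": node,
                        "communities": ";".join(map(str, sorted(report.memberships[node]))),
                        "majority_atc": report.majority_atc.get(node, ""),
                    }
                )
            if not cset.communities:
                manifest.notices.append(f"no k-clique communities at k={k}")
        io.write_table(
            pd.DataFrame(module_rows, columns=["k", "community_index", "members"]),
            outdir / "modules.tsv",
        )
        io.write_table(
            pd.DataFrame(iface_rows, columns=["k", "lncrna_id", "communities", "majority_atc"]),
            outdir / "interface_lncrnas.tsv",
        )

    with _Stage(manifest, "function"):
        mrna_expr, gene_sets = generate_coexpression(scfg, truth, expr)
        io.write_expression(mrna_expr, outdir / "mrna_expression.tsv")
        io.write_gmt(gene_sets, outdir / "gene_sets.gmt")
        io.write_truth(truth, outdir)  # now includes co-expression truth
        # annotate interface lncRNAs when present, otherwise the planted ones
        query_lncs = sorted(interface_union) or sorted(
            {l for l, _, _ in truth.coexpression_links}
        )
        background = [str(g) for g in mrna_expr.index]
        link_rows, enrich_rows = [], []
        for lnc in query_lncs:
            if lnc not in expr.index:
                continue
            links = coexpressed_partners(
                expr.loc[lnc], mrna_expr, config.pcc_cut, config.pcc_p_cut
            )
            partners = [l.mrna_id for l in links]
            link_rows += [
                {"lncrna_id": l.lncrna_id, "mrna_id": l.mrna_id, "pcc": l.pcc, "p_value": l.p_value}
                for l in links
            ]
            if partners:
                for res in ora_enrichment(partners, gene_sets, background):
                    enrich_rows.append(
                        {
                            "lncrna_id": lnc,
                            "gene_set_id": res.gene_set_id,
                            "set_size": res.set_size,
                            "overlap": res.overlap,
                            "p_value": res.p_value,
                            "q_value": res.q_value,
                        }
                    )
        io.write_table(
            pd.DataFrame(link_rows, columns=["lncrna_id", "mrna_id", "pcc", "p_value"]),
            outdir / "coexpression_links.tsv",
        )
        io.write_table(
            pd.DataFrame(
                enrich_rows,
                columns=["lncrna_id", "gene_set_id", "set_size", "overlap", "p_value", "q_value"],
            ),
            outdir / "enrichment.tsv",
        )

    with _Stage(manifest, "tissue"):
        panel, tissue_class = generate_tissue_panel(scfg, truth)
        io.write_expression(panel, outdir / "tissue_panel.tsv")
        io.write_tissue_class(tissue_class, outdir / "tissue_classes.tsv")
        assignments = assign_specific(panel, config.specificity_threshold)
        io.write_assignments(assignments, outdir / "tissue_assignments.tsv")
        manifest.summary["n_tissue_specific"] = sum(a.is_specific for a in assignments)
        jmat = drug_tissue_jaccard_matrix(smln, atc_map, assignments, tissue_class)
        io.write_table(jmat, outdir / "drug_tissue_jaccard.tsv", index=True)
        if not jmat.empty:
            manifest.summary["max_jaccard"] = float(jmat.to_numpy().max())

    for p in sorted(outdir.iterdir()):
        if p.is_file() and p.name != "run_manifest.json":
            manifest.artifacts[p.name] = _sha256(p)
    (outdir / "run_manifest.json").write_text(
        json.dumps(dataclasses.asdict(manifest), indent=2, sort_keys=True, default=str)
    )
    return manifest
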