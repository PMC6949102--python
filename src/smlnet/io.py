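"""Readers and writers for the pipeline's tabular and graph artifacts.

Canonical tabular dialect: TSV with a header row, UTF-8, "." decimal; floats
are serialized with 17 significant digits so a write-then-read roundtrip is
exact.  Graphs go to GraphML and SIF; gene sets to GMT.
"""

from __future__ import annotations

import itertools
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .diffexpr import DrugLncRNAAssociation
from .pharmacology import DrugAnnotation
from .projections import LLNEdge, SSNEdge
from .tissue import SpecificityAssignment

FLOAT_FMT = "%.17g"


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_table(path, index_col=None) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", index_col=index_col, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed TSV {path}: {exc}") from exc


def write_expression(expr: pd.DataFrame, path) -> None:
    write_table(expr, path, index=True)


def read_expression(path) -> pd.DataFrame:
    return read_table(path, index_col=0)


def write_associations(associations: Iterable[DrugLncRNAAssociation], path) -> None:
    rows = [
        {
            "drug_id": a.drug_id,
            "lncrna_id": a.lncrna_id,
            "sign": a.sign,
            "mean_log2fc": a.mean_log2fc,
            "n_supporting_instances": a.n_supporting_instances,
        }
        for a in associations
    ]
    cols = ["drug_id", "lncrna_id", "sign", "mean_log2fc", "n_supporting_instances"]
    write_table(pd.DataFrame(rows, columns=cols), path)


def read_associations(path) -> list[DrugLncRNAAssociation]:
    df = read_table(path)
    return [
        DrugLncRNAAssociation(
            drug_id=r.drug_id,
            lncrna_id=r.lncrna_id,
            sign=r.sign,
            mean_log2fc=float(r.mean_log2fc),
            n_supporting_instances=int(r.n_supporting_instances),
        )
        for r in df.itertuples(index=False)
    ]


def _join(items: Iterable[str]) -> str:
    return ";".join(sorted(items))


def _split(text) -> frozenset[str]:
    if not isinstance(text, str) or not text:
        return frozenset()
    return frozenset(text.split(";"))


def write_annotations(annotations: Mapping[str, DrugAnnotation], path) -> None:
    rows = []
    for d in sorted(annotations):
        a = annotations[d]
        fp = "" if a.fingerprint is None else "".join(str(int(b)) for b in a.fingerprint)
        rows.append(
            {
                "drug_id": a.drug_id,
                "atc_class": a.atc_class,
                "indications": _join(a.indications),
                "targets": _join(a.targets),
                "side_effects": _join(a.side_effects),
                "fingerprint": fp,
            }
        )
    write_table(pd.DataFrame(rows), path)


def read_annotations(path) -> dict[str, DrugAnnotation]:
    df = read_table(path).fillna("")
    out = {}
    for r in df.itertuples(index=False):
        fp = np.array([int(c) for c in str(r.fingerprint)], dtype=np.uint8) if r.fingerprint else None
        out[r.drug_id] = DrugAnnotation(
            drug_id=r.drug_id,
            atc_class=str(r.atc_class),
            indications=_split(r.indications),
            targets=_split(r.targets),
            side_effects=_split(r.side_effects),
            fingerprint=fp,
        )
    return out


def write_ssn_edges(edges: Iterable[SSNEdge], path) -> None:
    rows = [
        {
            "drug_a": e.drug_a,
            "drug_b": e.drug_b,
            "weight": e.weight,
            "shared_lncrnas": _join(e.shared_lncrnas),
        }
        for e in edges
    ]
    write_table(pd.DataFrame(rows, columns=["drug_a", "drug_b", "weight", "shared_lncrnas"]), path)


def read_ssn_edges(path) -> list[SSNEdge]:
    df = read_table(path)
    return [
        SSNEdge(
            drug_a=r.drug_a,
            drug_b=r.drug_b,
            shared_lncrnas=_split(r.shared_lncrnas),
            weight=int(r.weight),
        )
        for r in df.itertuples(index=False)
    ]


def write_lln_edges(edges: Iterable[LLNEdge], path) -> None:
    rows = [
        {
            "lncrna_i": e.lncrna_i,
            "lncrna_j": e.lncrna_j,
            "m": e.m,
            "t": e.t,
            "n": e.n,
            "r": e.r,
            "p_value": e.p_value,
            "q_value": e.q_value,
        }
        for e in edges
    ]
    cols = ["lncrna_i", "lncrna_j", "m", "t", "n", "r", "p_value", "q_value"]
    write_table(pd.DataFrame(rows, columns=cols), path)


def read_lln_edges(path) -> list[LLNEdge]:
    df = read_table(path)
    return [
        LLNEdge(
            lncrna_i=r.lncrna_i,
            lncrna_j=r.lncrna_j,
            m=int(r.m),
            t=int(r.t),
            n=int(r.n),
            r=int(r.r),
            p_value=float(r.p_value),
            q_value=float(r.q_value),
        )
        for r in df.itertuples(index=False)
    ]


def write_assignments(assignments: Iterable[SpecificityAssignment], path) -> None:
    rows = [
        {
            "lncrna_id": a.lncrna_id,
            "best_tissue": a.best_tissue,
            "score": a.score,
            "is_specific": int(a.is_specific),
        }
        for a in assignments
    ]
    write_table(pd.DataFrame(rows, columns=["lncrna_id", "best_tissue", "score", "is_specific"]), path)


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(gene_sets[name])
            fh.write(f"{name}\tna\t{genes}\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = fields[2:]
    return sets


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def write_sif(graph: nx.Graph, path, relation: str = "link") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, data in sorted(graph.edges(data=True)):
            rel = data.get("sign", relation)
            fh.write(f"{u}\t{rel}\t{v}\n")


def write_tissue_class(tissue_class: Mapping[str, str], path) -> None:
    rows = [{"tissue": t, "anatomical_class": c} for t, c in sorted(tissue_class.items())]
    write_table(pd.DataFrame(rows, columns=["tissue", "anatomical_class"]), path)


def read_tissue_class(path) -> dict[str, str]:
    df = read_table(path)
    return dict(zip(df["tissue"], df["anatomical_class"]))


def write_truth(truth, outdir: Path) -> None:
    """Persist the planted ground truth as plain TSV tables."""
    outdir = Path(outdir)
    write_table(
        pd.DataFrame(sorted(truth.effects), columns=["drug_id", "lncrna_id", "sign"]),
        outdir / "truth_effects.tsv",
    )
    write_table(
        pd.DataFrame(
            sorted(truth.tissue_assignments.items()), columns=["lncrna_id", "tissue"]
        ),
        outdir / "truth_tissue_assignments.tsv",
    )
    write_table(
        pd.DataFrame(
            sorted(truth.coexpression_links), columns=["lncrna_id", "mrna_id", "sign"]
        ),
        outdir / "truth_coexpression_links.tsv",
    )
    write_table(
        pd.DataFrame(sorted(truth.enriched_gene_sets), columns=["gene_set_id"]),
        outdir / "truth_enriched_gene_sets.tsv",
    )
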