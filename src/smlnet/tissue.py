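"""Tissue specificity of drug-affected lncRNAs.

Scores each lncRNA's expression concentration in a tissue panel, assigns
tissue-specific lncRNAs (score > 0.8), and relates drug ATC classes to
tissue anatomical classes through Jaccard overlap of affected versus
tissue-specific lncRNA sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .network import side_nodes


@dataclass(frozen=True)
class SpecificityAssignment:
    lncrna_id: str
    best_tissue: str
    score: float
    is_specific: bool


def specificity_score(
    expression_row, tissue_index: int, method: str = "jsd"
) -> float:
    """Specificity of one lncRNA's expression for one tissue, in [0, 1].

    Default ("jsd"): 1 - sqrt(JSD(p, delta_t)) with p the row normalized to
    sum 1, delta_t the point mass on the tissue, and the Jensen-Shannon
    divergence taken with log base 2 — the conventional expression
    tissue-specificity score.  "max_fraction" scores the tissue's share of
    total expression instead.
    """
    row = np.asarray(expression_row, dtype=float)
    if np.any(row < 0):
        raise ValueError("expression must be non-negative")
    total = row.sum()
    if total <= 0:
        raise ValueError("zero-sum expression row")
    if not 0 <= tissue_index < row.size:
        raise IndexError(f"tissue index {tissue_index} out of range")
    p = row / total
    if method == "max_fraction":
        return float(p[tissue_index])
    if method != "jsd":
        raise ValueError(f"unknown method {method!r}")
    delta = np.zeros_like(p)
    delta[tissue_index] = 1.0
    # scipy returns the distance sqrt(JSD); base 2 bounds it in [0, 1]
    return float(1.0 - jensenshannon(p, delta, base=2))


def assign_specific(
    panel: pd.DataFrame, threshold: float = 0.8, method: str = "jsd"
) -> list[SpecificityAssignment]:
    """Best tissue and specificity per lncRNA; specific iff score > threshold.

    Argmax ties are broken toward the lexicographically smallest tissue id.
    """
    tissues = list(panel.columns)
    lex_order = sorted(range(len(tissues)), key=lambda i: tissues[i])
    out = []
    for lnc, row in panel.iterrows():
        scores = [specificity_score(row.to_numpy(), t, method=method) for t in range(len(tissues))]
        # scan in lexicographic tissue order so ties keep the smallest id
        best = max(lex_order, key=lambda i: scores[i])
        s = float(scores[best])
        out.append(
            SpecificityAssignment(
                lncrna_id=str(lnc),
                best_tissue=tissues[best],
                score=s,
                is_specific=bool(s > threshold),
            )
        )
    return out


def jaccard(set_a: Iterable, set_b: Iterable) -> float:
    """Intersection-over-union of two sets; 0 when both are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def drug_tissue_jaccard_matrix(
    smln: nx.Graph,
    atc_map: Mapping[str, str],
    assignments: Iterable[SpecificityAssignment],
    tissue_class: Mapping[str, str],
) -> pd.DataFrame:
    """Jaccard similarity between drug ATC classes and anatomical classes.

    Cell (c, a) compares the union of lncRNAs affected by drugs of ATC class
    c with the union of tissue-specific lncRNAs assigned to tissues of
    anatomical class a.
    """
    drugs = side_nodes(smln, "drug")
    missing = [d for d in drugs if d not in atc_map]
    if missing:
        raise KeyError(f"drugs without ATC class: {missing[:5]}")
    affected: dict[str, set[str]] = {}
    for d in drugs:
        affected.setdefault(atc_map[d], set()).update(smln.neighbors(d))

    specific: dict[str, set[str]] = {}
    for a in assignments:
        if not a.is_specific:
            continue
        if a.best_tissue not in tissue_class:
            raise KeyError(f"tissue {a.best_tissue!r} has no anatomical class")
        specific.setdefault(tissue_class[a.best_tissue], set()).add(a.lncrna_id)

    drug_classes = sorted(affected)
    anat_classes = sorted(set(tissue_class.values()))
    mat = pd.DataFrame(0.0, index=drug_classes, columns=anat_classes)
    for c in drug_classes:
        for a in anat_classes:
            mat.loc[c, a] = jaccard(affected.get(c, set()), specific.get(a, set()))
    mat.index.name = "atc_class"
    mat.columns.name = "anatomical_class"
    return mat
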