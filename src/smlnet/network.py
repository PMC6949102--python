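"""The signed bipartite SMLN and its descriptive topology."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .diffexpr import DrugLncRNAAssociation

DRUG_SIDE = 0
LNCRNA_SIDE = 1


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log10 P(k) on log10 k."""

    slope: float
    r_squared: float
    n_points: int


def build_smln(associations: Iterable[DrugLncRNAAssociation]) -> nx.Graph:
    """Assemble the signed bipartite drug-lncRNA network.

    Nodes carry a ``bipartite`` attribute (0 = drug, 1 = lncRNA); edges carry
    ``sign``, ``mean_log2fc`` and ``n_supporting_instances``.  Only entities
    incident to at least one association appear.  Duplicate (drug, lncRNA)
    pairs are rejected: the upstream merge must deduplicate.
    """
    g = nx.Graph()
    seen: set[tuple[str, str]] = set()
    for a in associations:
        key = (a.drug_id, a.lncrna_id)
        if key in seen:
            raise ValueError(f"duplicate association for {key}")
        seen.add(key)
        g.add_node(a.drug_id, bipartite=DRUG_SIDE)
        g.add_node(a.lncrna_id, bipartite=LNCRNA_SIDE)
        g.add_edge(
            a.drug_id,
            a.lncrna_id,
            sign=a.sign,
            mean_log2fc=a.mean_log2fc,
            n_supporting_instances=a.n_supporting_instances,
        )
    return g


def side_nodes(smln: nx.Graph, side: str) -> list[str]:
    if side not in ("drug", "lncrna"):
        raise ValueError("side must be 'drug' or 'lncrna'")
    want = DRUG_SIDE if side == "drug" else LNCRNA_SIDE
    return sorted(n for n, d in smln.nodes(data=True) if d.get("bipartite") == want)


def sign_counts(smln: nx.Graph) -> tuple[int, int]:
    """(upregulated, downregulated) edge counts."""
    up = sum(1 for _, _, d in smln.edges(data=True) if d.get("sign") == "up")
    return up, smln.number_of_edges() - up


def degree_distribution(smln: nx.Graph, side: str) -> dict[int, float]:
    """Fraction of nodes on one side with each observed degree.

    Fractions sum to 1; only degrees observed on that side appear.
    """
    nodes = side_nodes(smln, side)
    if not nodes:
        raise ValueError(f"no nodes on side {side!r}")
    degrees = [smln.degree(n) for n in nodes]
    counts: dict[int, int] = {}
    for k in degrees:
        counts[k] = counts.get(k, 0) + 1
    n = len(nodes)
    return {k: c / n for k, c in sorted(counts.items())}


def fit_power_law(distribution: Mapping[int, float]) -> PowerLawFit:
    """Ordinary least squares of log10 P(k) on log10 k.

    Uses the raw (unbinned) degree distribution over points with P(k) > 0,
    matching slope-plus-R^2 reporting rather than maximum-likelihood
    exponent estimation.
    """
    pts = [(k, p) for k, p in distribution.items() if p > 0 and k > 0]
    if len({k for k, _ in pts}) < 2:
        raise ValueError("need >= 2 distinct degrees with P(k) > 0")
    x = np.log10([k for k, _ in pts])
    y = np.log10([p for _, p in pts])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PowerLawFit(slope=float(slope), r_squared=float(r2), n_points=len(pts))


def giant_component(smln: nx.Graph) -> set[str]:
    """Largest connected component; ties broken by smallest member node id."""
    if smln.number_of_nodes() == 0:
        raise ValueError("empty network")
    comps = [set(c) for c in nx.connected_components(smln)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps[0]
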