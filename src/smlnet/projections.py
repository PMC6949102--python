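"""Projections of the SMLN: the drug-drug network (SSN) and the
hypergeometric-filtered lncRNA-lncRNA network (LLN).

Two drugs are SSN-connected if they share at least one affected lncRNA.
Two lncRNAs are LLN-connected if the number of drugs they share is larger
than expected by chance under a hypergeometric null:

    p = P(overlap >= r) = 1 - sum_{x=0}^{r-1} C(t,x) C(m-t,n-x) / C(m,n)

with m the total drugs in the SMLN, t and n the drugs affecting each lncRNA
and r their overlap.  p-values are BH-FDR corrected and pairs are kept at
p < 0.01 and q < 0.01 (strict).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .network import side_nodes


@dataclass(frozen=True)
class SSNEdge:
    """Unordered drug pair sharing >= 1 lncRNA; weight = overlap size."""

    drug_a: str
    drug_b: str
    shared_lncrnas: frozenset[str]
    weight: int


@dataclass(frozen=True)
class LLNEdge:
    """lncRNA pair with its hypergeometric parameters and p/q values."""

    lncrna_i: str
    lncrna_j: str
    m: int
    t: int
    n: int
    r: int
    p_value: float
    q_value: float


def project_ssn(smln: nx.Graph) -> list[SSNEdge]:
    """Drug-drug projection: one edge per pair with common lncRNA neighbors.

    Edge signs are ignored; the weight records the number of shared lncRNAs.
    """
    shared: dict[tuple[str, str], set[str]] = {}
    for lnc in side_nodes(smln, "lncrna"):
        drugs = sorted(smln.neighbors(lnc))
        for a, b in itertools.combinations(drugs, 2):
            shared.setdefault((a, b), set()).add(lnc)
    return [
        SSNEdge(drug_a=a, drug_b=b, shared_lncrnas=frozenset(s), weight=len(s))
        for (a, b), s in sorted(shared.items())
    ]


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeometric_pvalue(m: int, t: int, n: int, r: int) -> float:
    """P(overlap >= r) when drawing n of m drugs, t of which are marked.

    Upper-tail hypergeometric probability, summed in log space over the
    feasible range for numerical stability, clamped to [0, 1].  r = 0 gives
    exactly 1 (empty lower sum).
    """
    for name, v in (("m", m), ("t", t), ("n", n), ("r", r)):
        if not isinstance(v, (int, np.integer)) or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if t > m or n > m:
        raise ValueError(f"t={t} and n={n} must be <= m={m}")
    if r > min(t, n):
        raise ValueError(f"r={r} exceeds min(t, n)={min(t, n)}")
    if r == 0:
        return 1.0
    lo = max(r, t + n - m)
    hi = min(t, n)
    xs = np.arange(lo, hi + 1)
    if xs.size == 0:
        return 0.0
    log_terms = _log_binom(t, xs) + _log_binom(m - t, n - xs) - _log_binom(m, n)
    p = float(np.exp(logsumexp(log_terms)))
    return min(1.0, max(0.0, p))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_lln(smln: nx.Graph, p_cut: float = 0.01, q_cut: float = 0.01) -> list[LLNEdge]:
    """Score all lncRNA pairs with non-zero drug overlap and filter.

    The multiple-testing family is exactly the scored pairs (r >= 1; pairs
    with no shared drug have p = 1 and are excluded before BH).  An edge is
    kept iff p < p_cut and q < q_cut, both strict.
    """
    lncs = side_nodes(smln, "lncrna")
    m = len(side_nodes(smln, "drug"))
    neigh = {l: set(smln.neighbors(l)) for l in lncs}
    scored: list[tuple[str, str, int, int, int, float]] = []
    for i, j in itertools.combinations(lncs, 2):
        r = len(neigh[i] & neigh[j])
        if r == 0:
            continue
        t, n = len(neigh[i]), len(neigh[j])
        scored.append((i, j, t, n, r, hypergeometric_pvalue(m, t, n, r)))
    if not scored:
        return []
    q = bh_fdr([s[5] for s in scored])
    return [
        LLNEdge(lncrna_i=i, lncrna_j=j, m=m, t=t, n=n, r=r, p_value=p, q_value=float(qv))
        for (i, j, t, n, r, p), qv in zip(scored, q)
        if p < p_cut and qv < q_cut
    ]


def lln_graph(edges: list[LLNEdge]) -> nx.Graph:
    """Undirected lncRNA-lncRNA graph from filtered LLN edges."""
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.lncrna_i, e.lncrna_j, p_value=e.p_value, q_value=e.q_value, r=e.r)
    return g
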