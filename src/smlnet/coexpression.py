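"""Guilt-by-association functional annotation of lncRNAs.

Correlate a lncRNA's expression with every mRNA across shared samples, keep
partners with |PCC| > 0.5 and p < 0.01 (both strict), and run hypergeometric
gene-set over-representation on the partner list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .projections import bh_fdr, hypergeometric_pvalue


@dataclass(frozen=True)
class CoexpressionLink:
    lncrna_id: str
    mrna_id: str
    pcc: float
    p_value: float


@dataclass(frozen=True)
class EnrichmentResult:
    gene_set_id: str
    set_size: int
    overlap: int
    p_value: float
    q_value: float


def pearson_correlation(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need >= 3 observations")
    xc, yc = x - x.mean(), y - y.mean()
    sx, sy = np.sqrt(np.sum(xc**2)), np.sqrt(np.sum(yc**2))
    if sx == 0 or sy == 0:
        raise ValueError("zero variance")
    return float(np.clip(np.sum(xc * yc) / (sx * sy), -1.0, 1.0))


def pcc_pvalue(pcc: float, n: int) -> float:
    """Two-sided p-value of a Pearson correlation under the null.

    Based on t = pcc * sqrt((n-2) / (1-pcc^2)) with n-2 degrees of freedom;
    |pcc| = 1 is reported as p = 0.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(pcc) > 1:
        raise ValueError("|pcc| must be <= 1")
    if abs(pcc) == 1.0:
        return 0.0
    stat = pcc * np.sqrt((n - 2) / (1.0 - pcc * pcc))
    return float(2.0 * t_dist.sf(abs(stat), n - 2))


def coexpressed_partners(
    lncrna_profile: pd.Series,
    mrna_matrix: pd.DataFrame,
    pcc_cut: float = 0.5,
    p_cut: float = 0.01,
) -> list[CoexpressionLink]:
    """mRNAs co-expressed with one lncRNA: |PCC| > pcc_cut and p < p_cut.

    Correlations are computed over the sample columns shared by the profile
    and the matrix; constant (zero-variance) mRNAs are skipped.
    """
    samples = [s for s in mrna_matrix.columns if s in lncrna_profile.index]
    if len(samples) < 3:
        raise ValueError("need >= 3 shared samples")
    x = lncrna_profile[samples].to_numpy(dtype=float)
    if np.std(x) == 0:
        raise ValueError("lncRNA profile has zero variance")
    mat = mrna_matrix[samples].to_numpy(dtype=float)
    n = len(samples)

    xc = x - x.mean()
    mc = mat - mat.mean(axis=1, keepdims=True)
    sx = np.sqrt(np.sum(xc**2))
    sm = np.sqrt(np.sum(mc**2, axis=1))
    ok = sm > 0
    pcc = np.full(mat.shape[0], np.nan)
    pcc[ok] = np.clip(mc[ok] @ xc / (sm[ok] * sx), -1.0, 1.0)

    links = []
    lnc_id = str(lncrna_profile.name)
    for i, mrna in enumerate(mrna_matrix.index):
        if not ok[i] or abs(pcc[i]) <= pcc_cut:
            continue
        p = pcc_pvalue(float(pcc[i]), n)
        if p < p_cut:
            links.append(
                CoexpressionLink(lncrna_id=lnc_id, mrna_id=str(mrna), pcc=float(pcc[i]), p_value=p)
            )
    return links


def ora_enrichment(
    query_genes: Iterable[str],
    gene_sets: Mapping[str, Sequence[str]],
    background_genes: Iterable[str],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of a gene list in each gene set.

    Each set is intersected with the background before testing; BH q-values
    are computed across all tested sets; results are sorted by (p, set id).
    """
    background = set(background_genes)
    query = set(query_genes)
    if not query or not background:
        raise ValueError("query and background must be non-empty")
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    names, ps, sizes, overlaps = [], [], [], []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & background
        overlap = len(members & query)
        names.append(name)
        sizes.append(len(members))
        overlaps.append(overlap)
        ps.append(hypergeometric_pvalue(len(background), len(members), len(query), overlap))
    qs = bh_fdr(ps)
    results = [
        EnrichmentResult(gene_set_id=nm, set_size=sz, overlap=ov, p_value=p, q_value=float(q))
        for nm, sz, ov, p, q in zip(names, sizes, overlaps, ps, qs)
    ]
    results.sort(key=lambda r: (r.p_value, r.gene_set_id))
    return results
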