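"""Pharmacological similarity of lncRNA-connected drug pairs.

Permutation tests for shared indications/targets, pairwise side-effect
sharing ratios, fingerprint Tanimoto similarity, and rank-sum comparisons of
connected versus unconnected drug pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import mannwhitneyu


@dataclass(frozen=True)
class DrugAnnotation:
    """ATC class, annotation sets, and binary fingerprint of one drug."""

    drug_id: str
    atc_class: str
    indications: frozenset[str] = frozenset()
    targets: frozenset[str] = frozenset()
    side_effects: frozenset[str] = frozenset()
    fingerprint: np.ndarray | None = None


@dataclass
class PermutationResult:
    """Observed pair-sharing count against a resampled null.

    ``p_conservative`` = (#{null >= observed} + 1) / (n_perm + 1) is the
    headline statistic; ``p_empirical`` = #{null >= observed} / n_perm is the
    raw fraction (which can be 0).
    """

    observed: int
    null_counts: np.ndarray
    p_empirical: float
    p_conservative: float
    n_pairs: int


ANNOTATION_FIELDS = ("indications", "targets", "side_effects")


def _normalize_pairs(pairs: Iterable[tuple[str, str]]) -> set[tuple[str, str]]:
    out = set()
    for a, b in pairs:
        if a == b:
            raise ValueError(f"self-pair {a!r}")
        out.add((a, b) if a <= b else (b, a))
    return out


def count_pairs_sharing(
    pairs: Iterable[tuple[str, str]],
    annotations: Mapping[str, DrugAnnotation],
    field_name: str,
) -> int:
    """Number of unordered pairs whose two annotation sets intersect.

    Pairs where either drug has an empty set contribute 0.  Duplicate and
    reordered input pairs are collapsed first.
    """
    if field_name not in ANNOTATION_FIELDS:
        raise ValueError(f"unknown annotation field {field_name!r}")
    count = 0
    for a, b in _normalize_pairs(pairs):
        if a not in annotations or b not in annotations:
            raise KeyError(f"unknown drug id in pair ({a!r}, {b!r})")
        sa = getattr(annotations[a], field_name)
        sb = getattr(annotations[b], field_name)
        if sa & sb:
            count += 1
    return count


def permutation_test(
    connected_pairs: Iterable[tuple[str, str]],
    annotations: Mapping[str, DrugAnnotation],
    field_name: str,
    n_perm: int = 1000,
    seed: int | None = None,
    drug_universe: Sequence[str] | None = None,
) -> PermutationResult:
    """Is the observed number of annotation-sharing connected pairs extreme?

    Each permutation draws the same number of distinct unordered pairs
    uniformly from all pairs of annotated drugs in the universe (default:
    the annotated drugs appearing in the connected pairs).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pairs = _normalize_pairs(connected_pairs)
    if drug_universe is None:
        drug_universe = sorted({d for p in pairs for d in p})
    universe = sorted(d for d in drug_universe if d in annotations and getattr(annotations[d], field_name))
    # restrict to pairs where both drugs are annotated for this field
    eval_pairs = [p for p in pairs if p[0] in set(universe) and p[1] in set(universe)]
    if len(universe) < 2:
        raise ValueError("need >= 2 annotated drugs")
    all_pairs = list(itertools.combinations(universe, 2))
    if len(eval_pairs) > len(all_pairs):
        raise ValueError("more connected pairs than possible pairs in the universe")

    sets = {d: getattr(annotations[d], field_name) for d in universe}
    share = np.fromiter(
        (bool(sets[a] & sets[b]) for a, b in all_pairs), dtype=bool, count=len(all_pairs)
    )
    pair_index = {p: i for i, p in enumerate(all_pairs)}
    observed = int(share[[pair_index[p] for p in eval_pairs]].sum())

    rng = np.random.default_rng(seed)
    k = len(eval_pairs)
    # k distinct uniform pairs per permutation via row-wise argpartition
    u = rng.random((n_perm, len(all_pairs)))
    idx = np.argpartition(u, k - 1, axis=1)[:, :k] if k > 0 else np.empty((n_perm, 0), int)
    null_counts = share[idx].sum(axis=1).astype(int)

    ge = int(np.sum(null_counts >= observed))
    return PermutationResult(
        observed=observed,
        null_counts=null_counts,
        p_empirical=ge / n_perm,
        p_conservative=(ge + 1) / (n_perm + 1),
        n_pairs=k,
    )


def side_effect_sharing_ratio(
    annotation_a: DrugAnnotation, annotation_b: DrugAnnotation
) -> float | None:
    """Jaccard ratio of the two drugs' side-effect sets.

    Returns None (pair skipped) when the union is empty.
    """
    sa, sb = annotation_a.side_effects, annotation_b.side_effects
    union = sa | sb
    if not union:
        return None
    return len(sa & sb) / len(union)


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], alternative: str = "two_sided"
) -> tuple[float, float]:
    """Mann-Whitney U rank-sum test with midranks for ties.

    Exact enumeration when both samples have <= 8 observations and no ties;
    otherwise the normal approximation with tie and continuity correction.
    """
    if alternative not in ("two_sided", "greater"):
        raise ValueError("alternative must be 'two_sided' or 'greater'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and no_ties) else "asymptotic"
    res = mannwhitneyu(
        x, y,
        alternative=alternative.replace("_", "-"),
        method=method,
        use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue)


def tanimoto(fingerprint_a: np.ndarray, fingerprint_b: np.ndarray) -> float:
    """Tanimoto coefficient: shared on-bits over total on-bits.

    Defined as 0 when both fingerprints are all-zero.
    """
    a = np.asarray(fingerprint_a).astype(bool)
    b = np.asarray(fingerprint_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.sum(a | b))
    if union == 0:
        return 0.0
    return int(np.sum(a & b)) / union


@dataclass
class GroupComparison:
    """One-sided rank-sum comparison of a metric between connected pairs and
    all other annotated pairs."""

    metric: str
    n_connected: int
    n_rest: int
    median_connected: float
    median_rest: float
    statistic: float
    p_value: float


def compare_connected_vs_rest(
    connected_pairs: Iterable[tuple[str, str]],
    annotations: Mapping[str, DrugAnnotation],
    metric: str = "side_effect_ratio",
    drug_universe: Sequence[str] | None = None,
) -> GroupComparison:
    """Is the pairwise similarity metric higher among connected drug pairs?

    ``metric`` is "side_effect_ratio" (Jaccard of side-effect sets; pairs
    with an empty union are skipped) or "tanimoto" (fingerprint similarity).
    The rest group is every other unordered pair of annotated drugs in the
    universe.  A one-sided (greater) rank-sum p-value is reported.
    """
    if metric not in ("side_effect_ratio", "tanimoto"):
        raise ValueError(f"unknown metric {metric!r}")
    pairs = _normalize_pairs(connected_pairs)
    if drug_universe is None:
        drug_universe = sorted(annotations)

    def evaluable(d: str) -> bool:
        ann = annotations.get(d)
        if ann is None:
            return False
        return ann.fingerprint is not None if metric == "tanimoto" else bool(ann.side_effects)

    universe = [d for d in sorted(set(drug_universe)) if evaluable(d)]

    def value(a: str, b: str) -> float | None:
        if metric == "tanimoto":
            return tanimoto(annotations[a].fingerprint, annotations[b].fingerprint)
        return side_effect_sharing_ratio(annotations[a], annotations[b])

    connected_vals, rest_vals = [], []
    for a, b in itertools.combinations(universe, 2):
        v = value(a, b)
        if v is None:
            continue
        ((connected_vals if (a, b) in pairs else rest_vals)).append(v)
    if not connected_vals or not rest_vals:
        raise ValueError("need >= 1 evaluable pair in each group")
    stat, p = wilcoxon_rank_sum(connected_vals, rest_vals, alternative="greater")
    return GroupComparison(
        metric=metric,
        n_connected=len(connected_vals),
        n_rest=len(rest_vals),
        median_connected=float(np.median(connected_vals)),
        median_rest=float(np.median(rest_vals)),
        statistic=stat,
        p_value=p,
    )
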