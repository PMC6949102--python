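"""Pharmacological similarity statistics and permutation machinery."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu

from smlnet.pharmacology import (
    DrugAnnotation,
    compare_connected_vs_rest,
    count_pairs_sharing,
    permutation_test,
    side_effect_sharing_ratio,
    tanimoto,
    wilcoxon_rank_sum,
)


def _ann(drug, indications=(), side_effects=(), fingerprint=None, atc="A"):
    return DrugAnnotation(
        drug_id=drug,
        atc_class=atc,
        indications=frozenset(indications),
        side_effects=frozenset(side_effects),
        fingerprint=None if fingerprint is None else np.asarray(fingerprint, dtype=np.uint8),
    )


class TestCountPairsSharing:
    def test_intersection_counts(self):
        ann = {
            "a": _ann("a", indications={"diabetes"}),
            "b": _ann("b", indications={"diabetes", "pain"}),
        }
        assert count_pairs_sharing([("a", "b")], ann, "indications") == 1

    def test_empty_sets_contribute_zero(self):
        ann = {"a": _ann("a"), "b": _ann("b")}
        assert count_pairs_sharing([("a", "b")], ann, "indications") == 0

    def test_duplicate_and_order_invariance(self):
        ann = {
            "a": _ann("a", indications={"x"}),
            "b": _ann("b", indications={"x"}),
            "c": _ann("c", indications={"y"}),
        }
        pairs = [("a", "b"), ("b", "a"), ("a", "b"), ("a", "c")]
        assert count_pairs_sharing(pairs, ann, "indications") == 1

    def test_brute_force_recount(self):
        rng = np.random.default_rng(3)
        ann = {
            f"d{i}": _ann(f"d{i}", indications={f"ind{k}" for k in rng.integers(0, 12, 4)})
            for i in range(20)
        }
        pairs = [tuple(sorted(rng.choice(list(ann), 2, replace=False))) for _ in range(50)]
        pairs = [p for p in pairs if p[0] != p[1]]
        expected = sum(
            1 for a, b in set(pairs) if ann[a].indications & ann[b].indications
        )
        assert count_pairs_sharing(pairs, ann, "indications") == expected

    def test_unknown_drug(self):
        with pytest.raises(KeyError):
            count_pairs_sharing([("a", "zz")], {"a": _ann("a")}, "indications")


class TestPermutationTest:
    def test_universal_annotation_degenerate(self):
        ann = {f"d{i}": _ann(f"d{i}", indications={"everything"}) for i in range(6)}
        pairs = [("d0", "d1"), ("d2", "d3")]
        res = permutation_test(pairs, ann, "indications", n_perm=100, seed=0,
                               drug_universe=sorted(ann))
        assert res.observed == 2
        assert np.all(res.null_counts == 2)
        assert res.p_conservative == 1.0

    def test_conservative_vs_empirical(self):
        rng = np.random.default_rng(1)
        ann = {
            f"d{i}": _ann(f"d{i}", indications={f"i{k}" for k in rng.integers(0, 30, 3)})
            for i in range(15)
        }
        pairs = [("d0", "d1"), ("d2", "d3"), ("d4", "d5")]
        res = permutation_test(pairs, ann, "indications", n_perm=200, seed=2,
                               drug_universe=sorted(ann))
        ge = int(np.sum(res.null_counts >= res.observed))
        assert res.p_empirical == ge / 200
        assert res.p_conservative == (ge + 1) / 201
        assert res.p_conservative >= res.p_empirical

    def test_minimal_universe(self):
        # one connected pair drawn from the single possible pair: p must be 1
        ann = {"a": _ann("a", indications={"x"}), "b": _ann("b", indications={"x"})}
        res = permutation_test([("a", "b")], ann, "indications", n_perm=5,
                               drug_universe=["a", "b"], seed=0)
        assert res.p_conservative == 1.0

    def test_needs_two_annotated_drugs(self):
        ann = {"a": _ann("a", indications={"x"}), "b": _ann("b")}
        with pytest.raises(ValueError):
            permutation_test([("a", "b")], ann, "indications", n_perm=5, seed=0)


class TestSideEffectRatio:
    def test_identical(self):
        a = _ann("a", side_effects={"d", "n"})
        assert side_effect_sharing_ratio(a, a) == 1.0

    def test_disjoint(self):
        a = _ann("a", side_effects={"d"})
        b = _ann("b", side_effects={"n"})
        assert side_effect_sharing_ratio(a, b) == 0.0

    def test_half_overlap(self):
        a = _ann("a", side_effects={"d", "n", "h"})
        b = _ann("b", side_effects={"n", "h", "r"})
        assert side_effect_sharing_ratio(a, b) == 0.5

    def test_empty_union_skipped(self):
        assert side_effect_sharing_ratio(_ann("a"), _ann("b")) is None


class TestWilcoxonRankSum:
    def test_exact_small_sample(self):
        stat, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], "two_sided")
        assert p == pytest.approx(0.1)

    def test_no_separation(self):
        _, p = wilcoxon_rank_sum([5.0], [5.0], "two_sided")
        assert p == pytest.approx(1.0)

    def test_p_decreases_with_shift(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 60)
        other = rng.normal(0, 1, 60)
        ps = [
            wilcoxon_rank_sum(base + shift, other, "greater")[1]
            for shift in (0.0, 0.5, 1.0, 2.0)
        ]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_matches_scipy(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(0, 1, 30), rng.normal(0.4, 1, 25)
        stat, p = wilcoxon_rank_sum(x, y, "greater")
        ref = mannwhitneyu(x, y, alternative="greater", method="asymptotic")
        assert p == pytest.approx(float(ref.pvalue))

    def test_empty_sample(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestTanimoto:
    def test_identical(self):
        fp = np.array([1, 0, 1, 1], dtype=np.uint8)
        assert tanimoto(fp, fp) == 1.0

    def test_disjoint(self):
        assert tanimoto(np.array([1, 0, 0]), np.array([0, 1, 1])) == 0.0

    def test_half(self):
        a = np.zeros(8, dtype=np.uint8)
        b = np.zeros(8, dtype=np.uint8)
        a[[1, 2, 3]] = 1
        b[[2, 3, 4]] = 1
        assert tanimoto(a, b) == 0.5

    def test_all_zero(self):
        z = np.zeros(4, dtype=np.uint8)
        assert tanimoto(z, z) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tanimoto(np.ones(3), np.ones(4))

    @given(st.integers(0, 2**10 - 1), st.integers(0, 2**10 - 1))
    @settings(max_examples=100, deadline=None)
    def test_symmetric_bounded_identity(self, abits, bbits):
        a = np.array([(abits >> i) & 1 for i in range(10)], dtype=np.uint8)
        b = np.array([(bbits >> i) & 1 for i in range(10)], dtype=np.uint8)
        t = tanimoto(a, b)
        assert t == tanimoto(b, a)
        assert 0.0 <= t <= 1.0
        assert (t == 1.0) == (np.array_equal(a, b) and a.sum() > 0)


class TestCompareConnectedVsRest:
    def _annotations(self, rng, n=12):
        return {
            f"d{i}": _ann(
                f"d{i}",
                side_effects={f"se{k}" for k in rng.integers(0, 40, 6)},
                fingerprint=(rng.random(32) < 0.3).astype(np.uint8),
            )
            for i in range(n)
        }

    def test_identical_groups_not_significant(self):
        ann = {f"d{i}": _ann(f"d{i}", side_effects={"s"}) for i in range(8)}
        res = compare_connected_vs_rest([("d0", "d1"), ("d2", "d3")], ann, "side_effect_ratio")
        assert res.p_value >= 0.5  # every pair has ratio 1.0

    def test_partition_oracle(self):
        rng = np.random.default_rng(5)
        ann = self._annotations(rng)
        connected = [("d0", "d1"), ("d2", "d5"), ("d3", "d4")]
        res = compare_connected_vs_rest(connected, ann, "tanimoto")
        total = len(list(itertools.combinations(sorted(ann), 2)))
        assert res.n_connected == 3
        assert res.n_rest == total - 3

    def test_enriched_connected_pairs_score_higher(self):
        from smlnet.synthetic import SynthConfig, generate_drug_annotations, plant_effects

        cfg = SynthConfig(n_drugs=40, n_lncrnas=40, edge_density=0.05,
                          annotation_enrichment=8.0, seed=21)
        truth, _ = plant_effects(cfg)
        ann = generate_drug_annotations(cfg, truth)
        res = compare_connected_vs_rest(
            sorted(truth.connected_drug_pairs()), ann, "side_effect_ratio"
        )
        assert res.median_connected >= res.median_rest
        assert res.p_value < 0.05

    def test_no_evaluable_pairs(self):
        ann = {"a": _ann("a"), "b": _ann("b")}
        with pytest.raises(ValueError):
            compare_connected_vs_rest([("a", "b")], ann, "side_effect_ratio")
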