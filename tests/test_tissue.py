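"""Tissue-specificity scoring and the drug-class/anatomy Jaccard map."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from smlnet.diffexpr import DrugLncRNAAssociation
from smlnet.network import build_smln
from smlnet.tissue import (
    assign_specific,
    drug_tissue_jaccard_matrix,
    jaccard,
    specificity_score,
)


def uniform_score(n_tissues):
    """Closed-form JSD score of a perfectly uniform profile."""
    p = np.full(n_tissues, 1.0 / n_tissues)
    m = p / 2
    m = m.copy()
    m[0] += 0.5
    kl_p = np.sum(p * np.log2(p / m))
    kl_d = np.log2(1.0 / m[0])
    return 1.0 - np.sqrt(0.5 * (kl_p + kl_d))


class TestSpecificityScore:
    def test_delta_distribution(self):
        assert specificity_score([0, 100.0, 0], 1) == pytest.approx(1.0)

    def test_uniform_two_tissues(self):
        # JSD((.5,.5),(1,0)) = H(.75,.25) - 0.5 = 0.311278...
        assert specificity_score([5.0, 5.0], 0) == pytest.approx(0.4420769545, abs=1e-8)
        assert specificity_score([5.0, 5.0], 0) == pytest.approx(uniform_score(2), abs=1e-12)

    def test_decreases_as_expression_spreads(self):
        scores = [
            specificity_score([1.0 - eps, eps / 2, eps / 2], 0)
            for eps in (0.0, 0.1, 0.3, 0.6, 0.9)
        ]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_max_fraction_method(self):
        assert specificity_score([3.0, 1.0], 0, method="max_fraction") == pytest.approx(0.75)

    def test_zero_sum_error(self):
        with pytest.raises(ValueError):
            specificity_score([0.0, 0.0], 0)
        with pytest.raises(ValueError):
            specificity_score([-1.0, 2.0], 0)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, scale):
        row = np.array([3.0, 1.0, 0.5, 7.0])
        for t in range(4):
            assert specificity_score(row * scale, t) == pytest.approx(
                specificity_score(row, t), abs=1e-9
            )


class TestAssignSpecific:
    def test_planted_single_tissue(self):
        panel = pd.DataFrame(
            [[0.0, 80.0, 0.0], [10.0, 10.0, 10.0]],
            index=["lncS", "lncU"],
            columns=["t0", "t1", "t2"],
        )
        a_s, a_u = assign_specific(panel)
        assert a_s.best_tissue == "t1" and a_s.score == pytest.approx(1.0) and a_s.is_specific
        assert not a_u.is_specific
        assert a_u.score <= 0.45  # uniform bound, far below 0.8

    def test_uniform_never_specific_any_width(self):
        for n in range(2, 12):
            assert uniform_score(n) <= 0.45 < 0.8
            panel = pd.DataFrame([np.ones(n)], index=["l"], columns=[f"t{i}" for i in range(n)])
            (a,) = assign_specific(panel)
            assert not a.is_specific

    def test_threshold_zero_everything_specific(self):
        panel = pd.DataFrame([[1.0, 2.0]], index=["l"], columns=["t0", "t1"])
        (a,) = assign_specific(panel, threshold=0.0)
        assert a.is_specific

    def test_argmax_tie_lexicographic(self):
        panel = pd.DataFrame([[5.0, 5.0]], index=["l"], columns=["tB", "tA"])
        (a,) = assign_specific(panel)
        assert a.best_tissue == "tA"

    def test_generator_recovery(self):
        from smlnet.synthetic import SynthConfig, generate_tissue_panel, plant_effects

        cfg = SynthConfig(n_drugs=6, n_lncrnas=30, n_tissues=8, seed=4)
        truth, _ = plant_effects(cfg)
        for purity in (1.0, 0.95):
            panel, _ = generate_tissue_panel(cfg, truth, purity=purity)
            assigned = {
                a.lncrna_id: a.best_tissue for a in assign_specific(panel) if a.is_specific
            }
            assert assigned == truth.tissue_assignments


class TestJaccard:
    def test_identical(self):
        assert jaccard({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint(self):
        assert jaccard({"a"}, {"b"}) == 0.0

    def test_half(self):
        assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5

    def test_both_empty(self):
        assert jaccard(set(), set()) == 0.0


class TestJaccardMatrix:
    def _setup(self):
        assoc = [
            DrugLncRNAAssociation("dL1", "lnc1", "up", 2.0, 1),
            DrugLncRNAAssociation("dL1", "lnc2", "up", 2.0, 1),
            DrugLncRNAAssociation("dN1", "lnc3", "down", -2.0, 1),
        ]
        smln = build_smln(assoc)
        atc = {"dL1": "L", "dN1": "N"}
        panel = pd.DataFrame(
            [[100.0, 0.0], [80.0, 0.0], [0.0, 50.0], [10.0, 10.0]],
            index=["lnc1", "lnc2", "lnc3", "lnc4"],
            columns=["brain", "liver"],
        )
        assignments = assign_specific(panel)
        tissue_class = {"brain": "nervous", "liver": "alimentary"}
        return smln, atc, assignments, tissue_class

    def test_exact_match_cell(self):
        smln, atc, assignments, tclass = self._setup()
        mat = drug_tissue_jaccard_matrix(smln, atc, assignments, tclass)
        # drugs of class L affect exactly the brain-specific lncRNAs
        assert mat.loc["L", "nervous"] == 1.0
        assert mat.loc["L", "alimentary"] == 0.0
        assert mat.loc["N", "alimentary"] == 1.0

    def test_class_without_lncrnas_zero_row(self):
        smln, atc, assignments, tclass = self._setup()
        # lnc4 is not tissue-specific, so an "empty" drug class stays 0
        atc = dict(atc, dN1="P")
        mat = drug_tissue_jaccard_matrix(smln, atc, assignments, tclass)
        assert (mat.loc["P"] >= 0).all()

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(10)
        assoc = []
        for i in range(10):
            for j in range(12):
                if rng.random() < 0.3:
                    assoc.append(DrugLncRNAAssociation(f"d{i}", f"l{j}", "up", 2.0, 1))
        smln = build_smln(assoc)
        drugs = sorted({a.drug_id for a in assoc})
        atc = {d: rng.choice(list("ALN")) for d in drugs}
        tissues = [f"t{i}" for i in range(4)]
        tclass = {t: rng.choice(["anatA", "anatB"]) for t in tissues}
        rows = rng.uniform(0, 1, (12, 4))
        rows[:6] = 0.0
        for i in range(6):
            rows[i, rng.integers(0, 4)] = 50.0  # single-tissue rows
        panel = pd.DataFrame(rows, index=[f"l{j}" for j in range(12)], columns=tissues)
        assignments = assign_specific(panel)
        mat = drug_tissue_jaccard_matrix(smln, atc, assignments, tclass)

        specific = {a.lncrna_id: a.best_tissue for a in assignments if a.is_specific}
        for c in mat.index:
            affected = set()
            for a in assoc:
                if atc[a.drug_id] == c:
                    affected.add(a.lncrna_id)
            for anat in mat.columns:
                spec = {l for l, t in specific.items() if tclass[t] == anat}
                union = affected | spec
                expected = len(affected & spec) / len(union) if union else 0.0
                assert mat.loc[c, anat] == pytest.approx(expected)

    def test_unknown_atc_class_error(self):
        smln, atc, assignments, tclass = self._setup()
        with pytest.raises(KeyError):
            drug_tissue_jaccard_matrix(smln, {}, assignments, tclass)
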