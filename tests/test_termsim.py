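"""The eleven between-term measures: hand-computed toy values, symmetry,
bounds, and the GraSM/MICA relationships."""

import math

import pytest

from ontosim import TermMeasureConfig, UndefinedICError, term_matrix
from ontosim.graph import dca, mica
from ontosim.simulate import TOY_OBO, parse_annotations_text, parse_obo_text
from ontosim.termsim import (
    sim_grasm,
    sim_jc,
    sim_lin,
    sim_rel,
    sim_resnik,
    sim_term,
    sim_wang2007,
    sim_wu2005,
    sim_yu2005,
)

from conftest import random_fixture

ALL_MEASURES = [
    "resnik", "lin", "jc", "rel",
    "resnik_grasm", "lin_grasm", "jc_grasm", "rel_grasm",
    "wu2005", "yu2005", "wang2007",
]
NORMALIZED = ["lin", "jc", "rel", "lin_grasm", "jc_grasm", "rel_grasm",
              "wu2005", "yu2005", "wang2007"]

# hand-derived on the toy ontology: IC(A)=ln(3/2), IC(C)=IC(D)=ln 3
TOY_CD = {
    "resnik": 0.405465,
    "lin": 0.369070,
    "jc": 0.419060,  # 1/(1 + 2 ln 2), d_JC(C,D) = 2 ln 2
    "rel": 0.123023,
    "resnik_grasm": 0.405465,  # single DCA -> collapses to Resnik
    "wu2005": 0.5,
    "yu2005": 1 / 3,
    "wang2007": 0.590164,
}


class TestToyValues:
    @pytest.mark.parametrize("name,expected", sorted(TOY_CD.items()))
    def test_c_vs_d(self, toy, name, expected):
        g, _, ic = toy
        got = sim_term(g, "C", "D", TermMeasureConfig(name), ic)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_resnik_self_and_root_pair(self, toy):
        g, _, ic = toy
        assert sim_resnik(g, ic, "C", "C") == pytest.approx(math.log(3))
        assert sim_resnik(g, ic, "C", "B") == 0.0

    def test_lin_conventions(self, toy):
        g, _, ic = toy
        assert sim_lin(g, ic, "C", "C") == 1.0
        assert sim_lin(g, ic, "R", "R") == 1.0  # 0/0 convention
        assert sim_lin(g, ic, "R", "C") == 0.0

    def test_jc_self_is_one(self, toy):
        g, _, ic = toy
        assert sim_jc(g, ic, "D", "D") == 1.0

    def test_rel_is_lin_discounted_by_mica_probability(self, toy):
        g, _, ic = toy
        assert sim_rel(g, ic, "C", "B") == 0.0  # MICA=root, 1-p(root)=0
        assert sim_rel(g, ic, "C", "C") == pytest.approx(1 - 1 / 3)

    def test_wu2005_degenerate_cases(self, toy):
        g = toy[0]
        assert sim_wu2005(g, "C", "C") == 1.0
        assert sim_wu2005(g, "R", "R") == 1.0
        assert sim_wu2005(g, "C", "B") == 0.0

    def test_yu2005_self_is_one(self, toy):
        assert sim_yu2005(toy[0], "B", "B") == 1.0

    def test_wang_hand_recursion(self, toy):
        g = toy[0]
        # S_C = {C:1, A:.8, R:.64}, SV=2.44; SV(B)=1.8; common(C,B)={R}
        assert sim_wang2007(g, "C", "B") == pytest.approx(0.339623, abs=1e-6)
        assert sim_wang2007(g, "C", "C") == 1.0

    def test_undefined_ic_raises(self, toy):
        g, _, _ = toy
        sparse_ic_corpus = parse_annotations_text("e1\tC\n", g)
        from ontosim import compute_ic
        ic = compute_ic(g, sparse_ic_corpus)
        with pytest.raises(UndefinedICError):
            sim_lin(g, ic, "C", "B")  # IC(B) undefined under this corpus


class TestGrasm:
    def test_two_dca_diamond_uses_mean_share(self):
        """C,D both under A and B (A,B under R): dca={A,B}, share=mean IC."""
        text = (
            TOY_OBO
            .replace("id: C\nname: gamma\nis_a: A", "id: C\nname: gamma\nis_a: A\nis_a: B")
            .replace("id: D\nname: delta\nis_a: A", "id: D\nname: delta\nis_a: A\nis_a: B")
        )
        g = parse_obo_text(text)
        corpus = parse_annotations_text("e1\tC\ne2\tD\ne3\tA\ne4\tB\n", g)
        from ontosim import compute_ic
        ic = compute_ic(g, corpus)
        assert dca(g, "C", "D") == {"A", "B"}
        share = (ic["A"] + ic["B"]) / 2
        assert sim_grasm(g, ic, "C", "D", "resnik") == pytest.approx(share)
        assert ic["A"] == ic["B"] == pytest.approx(math.log(4 / 3))

    def test_rel_grasm_replaces_probability_with_exp_minus_share(self, toy):
        g, _, ic = toy
        share = ic["A"]  # single DCA
        lin = sim_lin(g, ic, "C", "D")
        expected = lin * (1 - math.exp(-share))
        assert sim_grasm(g, ic, "C", "D", "rel") == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(40))
    def test_share_never_exceeds_mica_ic(self, seed):
        """mean over DCA ICs <= max over common-ancestor ICs."""
        g, _, ic = random_fixture(seed)
        terms = sorted(t for t in g.terms if t in ic)
        t1, t2 = terms[seed % len(terms)], terms[(seed * 3 + 2) % len(terms)]
        from ontosim.graph import common_ancestors
        if all(a in ic for a in common_ancestors(g, t1, t2)):
            assert sim_grasm(g, ic, t1, t2, "resnik") <= mica(g, ic, t1, t2)[1] + 1e-12

    @pytest.mark.parametrize("base", ["resnik", "lin", "jc", "rel"])
    @pytest.mark.parametrize("seed", range(25))
    def test_collapses_to_base_when_single_dca_is_mica(self, base, seed):
        g, _, ic = random_fixture(seed)
        terms = sorted(t for t in g.terms if t in ic)
        t1, t2 = terms[seed % len(terms)], terms[(seed * 7 + 5) % len(terms)]
        from ontosim.graph import common_ancestors
        if not all(a in ic for a in common_ancestors(g, t1, t2)):
            return
        d = dca(g, t1, t2)
        # note p(MICA) = exp(-IC(MICA)), so even rel_grasm collapses exactly
        if len(d) == 1 and next(iter(d)) == mica(g, ic, t1, t2)[0]:
            got = sim_grasm(g, ic, t1, t2, base)
            want = sim_term(g, t1, t2, TermMeasureConfig(base), ic)
            assert got == pytest.approx(want)


class TestProperties:
    @pytest.mark.parametrize("name", ALL_MEASURES)
    @pytest.mark.parametrize("seed", range(20))
    def test_symmetric_and_bounded(self, name, seed):
        g, _, ic = random_fixture(seed)
        config = TermMeasureConfig(name)
        terms = sorted(t for t in g.terms if t in ic)
        t1, t2 = terms[(seed * 3) % len(terms)], terms[(seed * 5 + 1) % len(terms)]
        from ontosim.graph import common_ancestors
        if not all(a in ic for a in common_ancestors(g, t1, t2)):
            return
        a = sim_term(g, t1, t2, config, ic)
        b = sim_term(g, t2, t1, config, ic)
        assert a == pytest.approx(b)
        if name in NORMALIZED:
            assert -1e-12 <= a <= 1 + 1e-12

    @pytest.mark.parametrize("name", ["resnik", "lin"])
    @pytest.mark.parametrize("seed", range(15))
    def test_self_similarity_dominates_parent(self, name, seed):
        g, _, ic = random_fixture(seed)
        config = TermMeasureConfig(name)
        for child, parent in sorted(g.traversal.edges()):
            if child in ic and parent in ic:
                self_sim = sim_term(g, child, child, config, ic)
                cross = sim_term(g, child, parent, config, ic)
                assert self_sim >= cross - 1e-12

    def test_normalized_resnik_is_unit_bounded(self, toy):
        g, _, ic = toy
        config = TermMeasureConfig("resnik", normalize_resnik=True)
        assert sim_term(g, "C", "C", config, ic) == pytest.approx(1.0)


class TestTermMatrix:
    def test_toy_matrix_off_diagonal(self, toy):
        g, _, ic = toy
        m = term_matrix(["C", "D"], TermMeasureConfig("lin"), g, ic)
        assert m.loc("C", "D") == pytest.approx(0.369070, abs=1e-6)
        assert m.loc("C", "C") == 1.0

    def test_single_term_matrix_is_self_similarity(self, toy):
        g, _, ic = toy
        m = term_matrix(["C"], TermMeasureConfig("resnik"), g, ic)
        assert m.values.shape == (1, 1)
        assert m.values[0, 0] == pytest.approx(math.log(3))

    @pytest.mark.parametrize("seed", range(10))
    def test_matrix_is_symmetric(self, seed):
        import numpy as np
        g, _, ic = random_fixture(seed)
        terms = sorted(t for t in g.terms if t in ic)[:6]
        m = term_matrix(terms, TermMeasureConfig("lin"), g, ic)
        assert np.allclose(m.values, m.values.T)

    def test_unknown_measure_rejected(self):
        with pytest.raises(ValueError, match="unknown term measure"):
            TermMeasureConfig("bogus")
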