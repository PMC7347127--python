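"""Between-entity measures: pairwise combiners and groupwise set measures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ontosim import (
    EmptyInputError,
    EntityMeasureConfig,
    TermMeasureConfig,
    UnannotatedEntityError,
    entity_matrix,
    pairwise_combine,
    sim_entity,
)
from ontosim.entitysim import ENTITY_MEASURES, PAIRWISE_MODES

from conftest import random_fixture


def config_for(name, term="lin"):
    tc = TermMeasureConfig(term) if name in PAIRWISE_MODES else None
    return EntityMeasureConfig(name, term_config=tc)


class TestPairwiseCombine:
    def test_hand_computed_2x2(self):
        s = np.array([[0.2, 0.8], [0.4, 0.6]])
        assert pairwise_combine(s, "avg") == pytest.approx(0.5)
        assert pairwise_combine(s, "max") == pytest.approx(0.8)
        assert pairwise_combine(s, "bma") == pytest.approx(0.65)
        assert pairwise_combine(s, "rcmax") == pytest.approx(0.7)

    @pytest.mark.parametrize("mode", PAIRWISE_MODES)
    def test_degenerate_1x1_collapses(self, mode):
        assert pairwise_combine(np.array([[0.42]]), mode) == pytest.approx(0.42)

    @pytest.mark.parametrize("mode", PAIRWISE_MODES)
    def test_constant_matrix_returns_constant(self, mode):
        assert pairwise_combine(np.full((3, 4), 0.3), mode) == pytest.approx(0.3)

    def test_empty_matrix_is_an_error(self):
        with pytest.raises(EmptyInputError):
            pairwise_combine(np.empty((0, 0)), "avg")

    @given(arrays(float, st.tuples(st.integers(1, 5), st.integers(1, 5)),
                  elements=st.floats(0, 1)))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_mode_ordering(self, s):
        """avg <= bma <= max and rcmax <= max on every score matrix."""
        avg, mx = pairwise_combine(s, "avg"), pairwise_combine(s, "max")
        bma, rc = pairwise_combine(s, "bma"), pairwise_combine(s, "rcmax")
        assert avg <= bma + 1e-12
        assert bma <= mx + 1e-12
        assert rc <= mx + 1e-12


class TestToyGroupwise:
    """e1 -> {C,A,R}, e2 -> {D,A,R} after propagation; direct universe {B,C,D}."""

    @pytest.mark.parametrize("name,expected", [
        ("to", 2.0),
        ("nto", 2 / 3),
        ("ui", 0.5),
        ("lp", 1.0),
        ("gic", 0.155787),
        ("cosine", 0.0),
        ("kappa", -0.5),
    ])
    def test_e1_vs_e2(self, toy, name, expected):
        _, corpus, ic = toy
        got = sim_entity("e1", "e2", corpus, config_for(name), ic)
        assert got == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("name", ["nto", "ui", "gic", "cosine", "kappa"])
    def test_self_similarity_is_one(self, toy, name):
        _, corpus, ic = toy
        assert sim_entity("e1", "e1", corpus, config_for(name), ic) == pytest.approx(1.0)

    def test_root_only_overlap_gives_zero_gic(self, toy):
        _, corpus, ic = toy
        # e1 (under A) and e3 (under B) share only the root, whose IC is 0
        assert sim_entity("e1", "e3", corpus, config_for("gic"), ic) == 0.0


class TestToyPairwise:
    def test_singleton_sets_collapse_to_term_similarity(self, toy):
        _, corpus, ic = toy
        got = sim_entity("e1", "e2", corpus, config_for("bma", "lin"), ic)
        assert got == pytest.approx(0.369070, abs=1e-6)

    def test_self_max_equals_max_self_term_similarity(self, toy):
        _, corpus, ic = toy
        got = sim_entity("e1", "e1", corpus, config_for("max", "resnik"), ic)
        assert got == pytest.approx(np.log(3))

    def test_unannotated_entity_error_carries_id(self, toy):
        _, corpus, ic = toy
        with pytest.raises(UnannotatedEntityError, match="ghost"):
            sim_entity("e1", "ghost", corpus, config_for("bma"), ic)


class TestProperties:
    @pytest.mark.parametrize("name", ENTITY_MEASURES)
    @pytest.mark.parametrize("seed", range(15))
    def test_symmetry_and_bounds(self, name, seed):
        g, corpus, ic = random_fixture(seed)
        entities = sorted(corpus.entity_universe)
        e1, e2 = entities[seed % len(entities)], entities[(seed * 3 + 1) % len(entities)]
        cfg = config_for(name)
        a = sim_entity(e1, e2, corpus, cfg, ic)
        b = sim_entity(e2, e1, corpus, cfg, ic)
        assert a == pytest.approx(b)
        if name in ("nto", "ui", "gic", "cosine"):
            assert -1e-12 <= a <= 1 + 1e-12
        if name == "kappa":
            assert -1 - 1e-12 <= a <= 1 + 1e-12

    @pytest.mark.parametrize("seed", range(25))
    def test_ui_never_exceeds_nto(self, seed):
        """intersection/union <= intersection/min on every pair."""
        g, corpus, ic = random_fixture(seed)
        entities = sorted(corpus.entity_universe)
        e1, e2 = entities[seed % len(entities)], entities[(seed * 5 + 2) % len(entities)]
        ui = sim_entity(e1, e2, corpus, config_for("ui"))
        nto = sim_entity(e1, e2, corpus, config_for("nto"))
        assert ui <= nto + 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_groupwise_identity_scores(self, seed):
        g, corpus, ic = random_fixture(seed)
        for e in sorted(corpus.entity_universe):
            assert sim_entity(e, e, corpus, config_for("gic"), ic) == pytest.approx(1.0)
            assert sim_entity(e, e, corpus, config_for("ui")) == pytest.approx(1.0)


class TestEntityMatrix:
    def test_toy_ui_matrix(self, toy):
        _, corpus, ic = toy
        m = entity_matrix(["e1", "e2", "e3"], corpus, config_for("ui"), ic)
        # ext(e1)={C,A,R}, ext(e2)={D,A,R}, ext(e3)={B,R}:
        # |∩|/|∪| = 2/4, 1/4, 1/4
        off = sorted(
            m.loc(a, b) for a, b in [("e1", "e2"), ("e1", "e3"), ("e2", "e3")]
        )
        assert off == pytest.approx([0.25, 0.25, 0.5])
        assert all(m.loc(e, e) == 1.0 for e in ("e1", "e2", "e3"))

    def test_unannotated_dropped_unless_strict(self, toy):
        _, corpus, ic = toy
        m = entity_matrix(["e1", "ghost", "e2"], corpus, config_for("ui"), ic)
        assert m.row_labels == ["e1", "e2"]
        with pytest.raises(UnannotatedEntityError):
            entity_matrix(["e1", "ghost"], corpus, config_for("ui"), ic, strict=True)

    @pytest.mark.parametrize("seed", range(5))
    def test_order_permutation_invariance(self, seed):
        g, corpus, ic = random_fixture(seed)
        entities = sorted(corpus.entity_universe)[:5]
        m1 = entity_matrix(entities, corpus, config_for("gic"), ic)
        m2 = entity_matrix(entities[::-1], corpus, config_for("gic"), ic)
        for a in entities:
            for b in entities:
                assert m1.loc(a, b) == pytest.approx(m2.loc(a, b))

    def test_annotation_view_override(self, toy):
        _, corpus, ic = toy
        cfg = EntityMeasureConfig("cosine", annotation_view="extended")
        # extended sets {C,A,R} vs {D,A,R}: cosine = 2/3 instead of 0
        assert sim_entity("e1", "e2", corpus, cfg) == pytest.approx(2 / 3)
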