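"""Invariant engine: HOMFLY skein recursion, Alexander oracle, labels."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from knotscan.invariants import (
    ClosedCurve,
    CrossingCapExceeded,
    DegenerateProjection,
    HomflyPolynomial,
    alexander_oracle,
    braid_diagram,
    homfly,
    homfly_of_curve,
    label_from_polynomial,
    project_to_diagram,
    reference_braid_words,
    reference_homfly_table,
)
from knotscan.invariants import _SkeinEngine, _smooth, _switch
from knotscan.synthetic import torus_knot_curve

# hand skein expansion of the closure of sigma_1^3 under
# l P+ + l^-1 P- + m P0 = 0: switching the middle crossing unknots it,
# smoothing gives the Hopf link, whose own expansion gives
# -(l^-1 + l^-3)/m ... combining: P = -2 l^-2 - l^-4 + l^-2 m^2
TREFOIL_POSITIVE = HomflyPolynomial({(-2, 0): -2, (-4, 0): -1, (-2, 2): 1})


def polynomials(draw_terms=st.dictionaries(
        st.tuples(st.integers(-4, 4), st.integers(-3, 3)),
        st.integers(-5, 5), max_size=5)):
    return draw_terms.map(HomflyPolynomial)


class TestPolynomialAlgebra:
    def test_render_sorted_text(self):
        assert str(TREFOIL_POSITIVE.mirror()) == "-2*l^2 + l^2*m^2 - l^4"
        assert str(HomflyPolynomial.zero()) == "0"
        assert str(HomflyPolynomial.one()) == "1"

    def test_no_zero_terms_stored(self):
        p = HomflyPolynomial({(1, 1): 2, (0, 0): 0})
        assert p.terms == {(1, 1): 2}

    @settings(deadline=None, derandomize=True)
    @given(a=polynomials(), b=polynomials(), c=polynomials())
    def test_ring_laws(self, a, b, c):
        assert a * (b + c) == a * b + a * c
        assert a * b == b * a
        assert a.mirror().mirror() == a
        assert (a * b).mirror() == a.mirror() * b.mirror()


class TestHomflyEngine:
    def test_zero_crossing_unknot_is_one(self):
        square = ClosedCurve(np.array(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float))
        d = project_to_diagram(square, np.array([0.0, 0.0, 1.0]))
        assert d.n_crossings == 0
        assert homfly(d).is_one()

    def test_trefoil_matches_hand_expansion(self):
        d = braid_diagram((1, 1, 1))
        assert homfly(d) == TREFOIL_POSITIVE
        assert homfly(d.mirrored()) == TREFOIL_POSITIVE.mirror()

    def test_split_union_multiplies_by_delta(self):
        loop = ClosedCurve(np.column_stack([
            np.cos(np.linspace(0, 2 * np.pi, 12, endpoint=False)),
            np.sin(np.linspace(0, 2 * np.pi, 12, endpoint=False)),
            np.zeros(12)]))
        upper = ClosedCurve(loop.vertices + np.array([0.1, 0.2, 5.0]))
        d = project_to_diagram([loop, upper], np.array([0.05, 0.03, 1.0]))
        assert d.n_components == 2
        assert homfly(d) == HomflyPolynomial.delta()

    @pytest.mark.parametrize("word", [(1, -2, 1, -2), (1, 1, 1, 2, -1, 2)])
    def test_skein_relation_holds_at_every_crossing(self, word):
        """l P(L+) + l**-1 P(L-) + m P(L0) vanishes for each crossing."""
        d = braid_diagram(word)
        engine = _SkeinEngine()
        for cid, sign in d.signs.items():
            P = engine.eval(d.components, dict(d.signs))
            Psw = engine.eval(*_switch(d.components, dict(d.signs), cid))
            Psm = engine.eval(*_smooth(d.components, dict(d.signs), cid))
            if sign > 0:
                total = P.shift(1, 0) + Psw.shift(-1, 0) + Psm.shift(0, 1)
            else:
                total = Psw.shift(1, 0) + P.shift(-1, 0) + Psm.shift(0, 1)
            assert not total, f"skein relation violated at crossing {cid}"

    def test_composite_is_product_of_factors(self):
        granny = homfly(braid_diagram((1, 1, 1, 2, 2, 2)))
        trefoil = homfly(braid_diagram((1, 1, 1)))
        assert granny == trefoil * trefoil
        square = homfly(braid_diagram((1, 1, 1, -2, -2, -2)))
        assert square == trefoil * trefoil.mirror()

    def test_crossing_cap_raises(self):
        d = braid_diagram((1,) * 7)
        with pytest.raises(CrossingCapExceeded):
            homfly(d, crossing_cap=3)


class TestAlexanderOracle:
    def test_unknot(self):
        square = ClosedCurve(np.array(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float))
        d = project_to_diagram(square, np.array([0.0, 0.0, 1.0]))
        assert alexander_oracle(d) == (1,)

    def test_trefoil_and_figure_eight(self):
        assert alexander_oracle(braid_diagram((1, 1, 1))) == (1, -1, 1)
        assert alexander_oracle(braid_diagram((1, -2, 1, -2))) == (-1, 3, -1)

    def test_reference_braids_validated(self):
        """Every braid word passes the Alexander gate (raises otherwise)."""
        words = reference_braid_words()
        assert set(words) == {
            "3_1", "4_1", "5_1", "5_2", "6_1", "6_2", "6_3",
            "7_1", "7_2", "3_1#3_1",
        }


class TestLabels:
    def test_unit_polynomial_is_unknot(self):
        assert label_from_polynomial(HomflyPolynomial.one()) == "0_1"

    def test_unmatched_polynomial_is_other(self):
        assert label_from_polynomial(HomflyPolynomial({(9, 9): 1})) == "other"

    @pytest.mark.parametrize("name", sorted(reference_braid_words()))
    def test_labels_collapse_chirality(self, name):
        d = braid_diagram(reference_braid_words()[name])
        p = homfly(d)
        assert label_from_polynomial(p) == name
        assert label_from_polynomial(p.mirror()) == name

    def test_amphichiral_knots_have_self_mirror_polynomials(self):
        table = reference_homfly_table()
        for name in ("4_1", "6_3"):
            polys = [p for p, lab in table.items() if lab == name]
            assert len(polys) == 1, f"{name} should be amphichiral"
            assert polys[0].mirror() == polys[0]


class TestProjection:
    def test_projection_invariance_on_trefoil_curve(self):
        curve = torus_knot_curve(2, 3, 120)
        rng = np.random.default_rng(7)
        polys = {homfly_of_curve(curve, rng) for _ in range(8)}
        assert len(polys) == 1
        assert label_from_polynomial(polys.pop()) == "3_1"

    def test_mirror_curve_gives_mirror_polynomial(self):
        curve = torus_knot_curve(2, 3, 120)
        rng = np.random.default_rng(3)
        p = homfly_of_curve(curve, rng)
        pm = homfly_of_curve(curve.mirrored(), rng)
        assert pm == p.mirror()

    def test_in_plane_direction_is_degenerate(self):
        flat = ClosedCurve(np.column_stack([
            np.cos(np.linspace(0, 2 * np.pi, 10, endpoint=False)),
            np.sin(np.linspace(0, 2 * np.pi, 10, endpoint=False)),
            np.zeros(10)]))
        with pytest.raises(DegenerateProjection):
            project_to_diagram(flat, np.array([1.0, 0.0, 0.0]))

    def test_curve_validation(self):
        with pytest.raises(ValueError):
            ClosedCurve(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            ClosedCurve(np.array([[0, 0, 0], [0, 0, 0], [1, 1, 1]], dtype=float))
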