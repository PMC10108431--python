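"""Synthetic-data generator: planted topology, geometry, profiles."""

import numpy as np
import pytest

from knotscan.classification import classify, conservation_summary
from knotscan.detection import dominant_knot
from knotscan.fingerprint import fingerprint, knot_core
from knotscan.invariants import (
    braid_diagram,
    homfly,
    homfly_of_curve,
    label_from_polynomial,
    reference_braid_words,
)
from knotscan.structures_io import parse_backbone
from knotscan.synthetic import (
    BOND_LENGTH,
    MIN_SEPARATION,
    PlddtProfile,
    SyntheticSpec,
    braid_closure_curve,
    make_backbone,
    random_coil,
    torus_knot_curve,
)

from conftest import build_conservation_table


class TestReferenceCurves:
    @pytest.mark.parametrize("pq,expected", [
        ((2, 3), "3_1"), ((2, 5), "5_1"), ((1, 2), "0_1"),
    ])
    def test_torus_knot_types(self, pq, expected):
        curve = torus_knot_curve(*pq, 160)
        rng = np.random.default_rng(1)
        assert label_from_polynomial(homfly_of_curve(curve, rng)) == expected

    def test_torus_knot_validation(self):
        with pytest.raises(ValueError):
            torus_knot_curve(2, 4, 100)      # not coprime
        with pytest.raises(ValueError):
            torus_knot_curve(2, 5, 10)       # undersampled

    @pytest.mark.parametrize("name", ["4_1", "6_3", "3_1#3_1"])
    def test_braid_curves_match_combinatorial_diagrams(self, name):
        """The geometric strand embedding realises the same knot as the
        combinatorial braid closure it was built from."""
        word = reference_braid_words()[name]
        geometric = braid_closure_curve(word, n_vertices_per_crossing=10)
        rng = np.random.default_rng(2)
        geo_label = label_from_polynomial(homfly_of_curve(geometric, rng))
        comb_label = label_from_polynomial(homfly(braid_diagram(word)))
        assert geo_label == comb_label == name

    def test_unvalidated_braid_word_rejected(self):
        with pytest.raises(ValueError, match="validated"):
            braid_closure_curve((1, 2, 1, 2, 1))


class TestBackboneGeometry:
    def test_bond_lengths_and_self_avoidance(self, trefoil_chain):
        bonds = np.linalg.norm(np.diff(trefoil_chain.coords, axis=0), axis=1)
        assert bonds.min() > BOND_LENGTH - 0.7 and bonds.max() < BOND_LENGTH + 0.7
        coords = trefoil_chain.coords
        for i in range(len(coords) - 3):
            d = np.linalg.norm(coords[i + 3:] - coords[i], axis=1)
            assert d.min() >= MIN_SEPARATION - 1e-9

    def test_generation_is_reproducible(self):
        spec = SyntheticSpec.for_knot("3_1", seed=9)
        a = make_backbone(spec)
        b = make_backbone(spec)
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.plddt, b.plddt)

    def test_plddt_profiles(self):
        spec = SyntheticSpec.for_knot("3_1", seed=1,
                                      plddt=PlddtProfile.low_core(40.0, 90.0))
        chain = make_backbone(spec)
        s0, s1 = spec.core_span
        assert chain.plddt[s0 - 1:s1].mean() == pytest.approx(40.0)
        assert chain.plddt[:s0 - 1].mean() == pytest.approx(90.0)

    def test_file_roundtrip(self, fixture_models):
        out, manifest, specs = fixture_models
        for line in manifest.read_text().splitlines()[1:]:
            name = line.split("\t")[0]
            chain = parse_backbone(out / name)
            assert len(chain) >= 3


class TestRandomCoil:
    def test_short_coils_are_unknotted(self):
        unknotted = 0
        for seed in range(20):
            coil = random_coil(100, seed=seed)
            spectrum = dominant_knot(coil, n_closures=50, seed=seed)
            unknotted += spectrum.dominant == "0_1"
        assert unknotted >= 18

    def test_step_lengths_exact(self):
        coil = random_coil(100, seed=0)
        bonds = np.linalg.norm(np.diff(coil.coords, axis=0), axis=1)
        assert np.abs(bonds - BOND_LENGTH).max() < 0.01

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            random_coil(2)


class TestEndToEndVerdicts:
    def test_confident_conserved_trefoil_is_knotted(self, trefoil_chain,
                                                    trefoil_spectrum):
        from knotscan.classification import clash_check

        fp = fingerprint(trefoil_chain, seed=2, full_spectrum=trefoil_spectrum)
        core = knot_core(fp, trefoil_chain)
        clash_ok, _ = clash_check(trefoil_chain, core)
        table = build_conservation_table(100, 12, 100, 3)
        v = classify(trefoil_spectrum, core, clash_ok,
                     conservation_summary(table, "3_1"), "3_1")
        assert v.category == "knotted"

    def test_low_confidence_core_is_artifact(self):
        from knotscan.classification import clash_check

        spec = SyntheticSpec.for_knot("3_1", seed=4,
                                      plddt=PlddtProfile.low_core(40.0, 90.0))
        chain = make_backbone(spec)
        spectrum = dominant_knot(chain, n_closures=100, seed=4)
        fp = fingerprint(chain, seed=4, full_spectrum=spectrum)
        core = knot_core(fp, chain)
        clash_ok, _ = clash_check(chain, core)
        v = classify(spectrum, core, clash_ok, None, None)
        assert core.mean_plddt < 50
        assert v.category == "artifact"
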