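"""Credibility rules, conservation summaries and greedy clustering."""

import itertools

import numpy as np
import pytest

from knotscan.classification import (
    ClassificationConfig,
    HomologTable,
    clash_check,
    classify,
    conservation_summary,
    greedy_cluster,
    read_homolog_table,
)
from knotscan.detection import KnotSpectrum
from knotscan.fingerprint import KnotCore
from knotscan.structures_io import BackboneChain
from knotscan.synthetic import torus_knot_curve

from conftest import build_conservation_table


def spectrum(dominant="3_1", freq=0.9):
    rest = round(1 - freq, 10)
    freqs = {dominant: freq}
    if rest:
        freqs["0_1" if dominant != "0_1" else "3_1"] = rest
    return KnotSpectrum(freqs, 200, dominant if freq >= rest else "0_1", 0)


def core(knot="3_1", plddt=90.0, start=10, end=60, n=80):
    return KnotCore(knot, start, end, n_tail=start - 1, c_tail=n - end,
                    mean_plddt=plddt)


class TestClashCheck:
    def _chain_from_curve(self, verts):
        return BackboneChain("A", np.arange(1, len(verts) + 1), verts,
                             np.full(len(verts), 90.0))

    def test_ideal_trefoil_passes(self):
        verts = torus_knot_curve(2, 3, 60).vertices
        verts = verts * (3.8 / np.linalg.norm(np.diff(verts, axis=0), axis=1).mean())
        chain = self._chain_from_curve(verts)
        ok, offenders = clash_check(chain, core(start=1, end=60, n=60))
        assert ok and offenders == []

    def test_moved_pair_fails_and_is_listed(self):
        verts = torus_knot_curve(2, 3, 60).vertices
        verts = verts * (3.8 / np.linalg.norm(np.diff(verts, axis=0), axis=1).mean())
        verts[30] = verts[10] + np.array([1.0, 0.0, 0.0])
        chain = self._chain_from_curve(verts)
        ok, offenders = clash_check(chain, core(start=1, end=60, n=60))
        assert not ok
        assert any({a, b} == {11, 31} for a, b, _ in offenders)

    def test_synthetic_backbone_passes(self, trefoil_chain):
        ok, _ = clash_check(trefoil_chain, core(start=12, end=70, n=81))
        assert ok


class TestConservationSummary:
    def test_fully_conserved(self):
        table = build_conservation_table(100, 19, 100, 2)
        s = conservation_summary(table, "3_1")
        assert (s.pct_conserved, s.n_homologs) == (100, 19)
        assert (s.pct_close_conserved, s.n_close) == (100, 2)

    def test_empty_table(self):
        s = conservation_summary(HomologTable(()), "3_1")
        assert (s.pct_conserved, s.n_homologs, s.pct_close_conserved, s.n_close) \
            == (0, 0, 0, 0)

    def test_partial_conservation_rounds_to_integer(self):
        table = build_conservation_table(87, 31, 100, 4)
        s = conservation_summary(table, "3_1")
        assert (s.pct_conserved, s.n_homologs) == (87, 31)
        assert s.fraction_conserved == pytest.approx(27 / 31)

    def test_tsv_roundtrip(self, tmp_path):
        path = tmp_path / "hom.tsv"
        path.write_text("homolog_id\tknot_label\tidentity\nh1\t3_1\t0.9\nh2\t0_1\t0.3\n")
        table = read_homolog_table(path)
        s = conservation_summary(table, "3_1")
        assert (s.pct_conserved, s.n_homologs) == (50, 2)
        assert (s.pct_close_conserved, s.n_close) == (100, 1)


class TestGreedyCluster:
    def test_two_blocks(self):
        ids = ["a", "b", "c", "d"]
        mat = np.array([
            [1.0, 0.9, 0.2, 0.2],
            [0.9, 1.0, 0.2, 0.2],
            [0.2, 0.2, 1.0, 0.9],
            [0.2, 0.2, 0.9, 1.0],
        ])
        assign = greedy_cluster(ids, mat, 0.6)
        assert assign["a"] == assign["b"] != assign["c"] == assign["d"]

    def test_all_identical_one_cluster(self):
        assign = greedy_cluster(["x", "y", "z"], np.ones((3, 3)), 0.6)
        assert len(set(assign.values())) == 1

    def test_chain_joins_longest_representative(self):
        """Everything at 0.7 to the longest sequence only: one cluster.

        Brute-force restatement of the greedy rule: the longest id
        founds the cluster, each other id joins because identity to the
        representative (not to other members) clears the threshold.
        """
        ids = ["long", "m1", "m2", "m3"]
        n = len(ids)
        mat = np.full((n, n), 0.1)
        np.fill_diagonal(mat, 1.0)
        mat[0, 1:] = mat[1:, 0] = 0.7
        lengths = {"long": 500, "m1": 100, "m2": 90, "m3": 80}
        assign = greedy_cluster(ids, mat, 0.6, lengths)
        assert set(assign.values()) == {0}
        # brute-force check: without the long representative, singletons
        assign2 = greedy_cluster(ids[1:], mat[1:, 1:], 0.6,
                                 {k: lengths[k] for k in ids[1:]})
        assert len(set(assign2.values())) == 3

    def test_threshold_extremes(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(0.2, 0.8, size=(5, 5))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        ids = list("abcde")
        assert len(set(greedy_cluster(ids, m, 0.0).values())) == 1
        assert len(set(greedy_cluster(ids, m, 1.01).values())) == 5

    def test_asymmetric_matrix_rejected(self):
        m = np.eye(3)
        m[0, 1] = 0.5
        with pytest.raises(ValueError):
            greedy_cluster(list("abc"), m)


class TestClassify:
    def test_high_confidence_conserved_is_knotted(self):
        table = build_conservation_table(100, 19, 100, 2)
        v = classify(spectrum("3_1", 0.9), core(plddt=93.0), True,
                     conservation_summary(table, "3_1"), "3_1")
        assert v.category == "knotted"
        assert v.needs_visual_inspection

    def test_low_core_confidence_is_artifact(self):
        v = classify(spectrum("3_1", 0.9), core(plddt=45.0), True, None, None)
        assert v.category == "artifact"

    def test_low_conservation_is_potentially_knotted(self):
        table = build_conservation_table(32, 19, 75, 4, query_label="6_3")
        v = classify(spectrum("6_3", 0.8), core(knot="6_3", plddt=88.6), True,
                     conservation_summary(table, "6_3"), "3_1")
        assert v.category == "potentially_knotted"

    def test_unavailable_evidence_never_promotes(self):
        v = classify(spectrum("3_1", 0.9), core(plddt=93.0), True, None, None)
        assert v.category == "potentially_knotted"

    def test_trivial_dominant_is_unknotted(self):
        v = classify(spectrum("0_1", 0.99), None, None, None, None)
        assert v.category == "unknotted"

    def test_core_spectrum_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classify(spectrum("3_1", 0.9), core(knot="4_1"), True, None, None)

    def test_verdict_monotonicity(self):
        """Improving any single rule input never demotes the category."""
        order = {"artifact": 0, "potentially_knotted": 1, "knotted": 2}
        table_good = build_conservation_table(100, 10, 100, 2)
        table_bad = build_conservation_table(40, 10, 50, 2)
        plddts = [45.0, 55.0, 93.0]
        clashes = [False, True]
        conservations = [None, conservation_summary(table_bad, "3_1"),
                         conservation_summary(table_good, "3_1")]
        seconds = [None, "0_1", "3_1"]
        axes = [plddts, clashes, conservations, seconds]

        def verdict(p, cl, cons, sec):
            return classify(spectrum("3_1", 0.9), core(plddt=p), cl, cons, sec)

        for combo in itertools.product(*axes):
            base = order[verdict(*combo).category]
            for axis in range(4):
                level = axes[axis].index(combo[axis])
                if level + 1 < len(axes[axis]):
                    better = list(combo)
                    better[axis] = axes[axis][level + 1]
                    assert order[verdict(*better).category] >= base
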