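"""Shared fixtures: synthetic chains and fixture directories are built
once per session because stochastic-closure typing is the dominant cost."""

from __future__ import annotations

import numpy as np
import pytest

from knotscan.classification import HomologTable
from knotscan.detection import dominant_knot
from knotscan.synthetic import PlddtProfile, SyntheticSpec, emit_fixture_set, make_backbone


@pytest.fixture(scope="session")
def trefoil_spec() -> SyntheticSpec:
    return SyntheticSpec.for_knot("3_1", n_tail=10, c_tail=10, seed=2)


@pytest.fixture(scope="session")
def trefoil_chain(trefoil_spec):
    return make_backbone(trefoil_spec)


@pytest.fixture(scope="session")
def trefoil_spectrum(trefoil_chain):
    return dominant_knot(trefoil_chain, n_closures=200, seed=2)


@pytest.fixture(scope="session")
def fixture_models(tmp_path_factory):
    """Directory of mixed synthetic models plus its manifest path."""
    out = tmp_path_factory.mktemp("models")
    specs = [
        SyntheticSpec.for_knot("3_1", seed=1),
        SyntheticSpec.for_knot("3_1", seed=2),
        SyntheticSpec.for_knot("4_1", seed=1),
        SyntheticSpec.for_knot("5_2", seed=1),
        SyntheticSpec.for_knot("0_1", seed=3),
        SyntheticSpec.for_knot("3_1", seed=4, plddt=PlddtProfile.low_core(40.0, 90.0)),
    ]
    manifest = emit_fixture_set(specs, out)
    return out, manifest, specs


def build_conservation_table(pct: int, n: int, pct_close: int, n_close: int,
                             query_label: str = "3_1",
                             other_label: str = "0_1") -> HomologTable:
    """Construct a homolog table whose summary prints the given pairs.

    The close subset (identity 0.8) holds the first ``n_close`` rows;
    the remainder sit at identity 0.3.  Raises if the printed pair is
    not realisable with integer counts — which would mean the target
    percentages were misread.
    """
    m = int(round(pct * n / 100.0))
    m_close = int(round(pct_close * n_close / 100.0))
    if n and int(round(100.0 * m / n)) != pct:
        raise ValueError(f"({pct}, {n}) not realisable")
    if n_close and int(round(100.0 * m_close / n_close)) != pct_close:
        raise ValueError(f"close ({pct_close}, {n_close}) not realisable")
    far_matches = m - m_close
    if far_matches < 0 or far_matches > n - n_close:
        raise ValueError(f"row ({pct}, {n}, {pct_close}, {n_close}) inconsistent")
    rows = []
    for i in range(n_close):
        rows.append((f"close{i}", query_label if i < m_close else other_label, 0.8))
    for i in range(n - n_close):
        rows.append((f"far{i}", query_label if i < far_matches else other_label, 0.3))
    return HomologTable(tuple(rows))
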