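"""Credibility classification of knotted structure models.

A model with a nontrivial dominant knot is *knotted* (credible) only
when every rule passes: the nontrivial closure fraction exceeds the
trivial one, the knot core lies in a confident region (mean pLDDT above
50), the core is free of steric clashes, the same knot type is conserved
in more than 80% of the protein's homologs, and a second, independently
predicted model agrees.  Models failing confidence badly (core pLDDT
below 50) or whose closures favour the unknot are *artifacts*; everything
in between is *potentially knotted*.  The final manual step of visual
inspection is not automatable, so every knotted verdict additionally
carries a needs-visual-inspection flag for human review.

Homolog topology tables are inputs (TSV: homolog_id, knot_label,
identity in [0, 1]); homolog search itself is outside this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .detection import KnotSpectrum, UNKNOT
from .fingerprint import KnotCore
from .structures_io import BackboneChain

__all__ = [
    "HomologTable",
    "ClassificationConfig",
    "ConservationSummary",
    "Verdict",
    "clash_check",
    "conservation_summary",
    "greedy_cluster",
    "classify",
    "read_homolog_table",
]

UNAVAILABLE = "unavailable"


@dataclass(frozen=True)
class HomologTable:
    """Per-homolog knot labels with sequence identity to the query."""

    rows: tuple[tuple[str, str, float], ...]   # (homolog_id, knot_label, identity)

    def __post_init__(self) -> None:
        rows = tuple((str(h), str(k), float(i)) for h, k, i in self.rows)
        ids = [r[0] for r in rows]
        if len(set(ids)) != len(ids):
            raise ValueError("homolog ids must be unique")
        for _, _, ident in rows:
            if not 0.0 <= ident <= 1.0:
                raise ValueError("identities must be within [0, 1]")
        object.__setattr__(self, "rows", rows)

    def __len__(self) -> int:
        return len(self.rows)


def read_homolog_table(path: str | Path) -> HomologTable:
    """Read a homolog-topology TSV (homolog_id, knot_label, identity)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("homolog_id"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"malformed homolog row: {line!r}")
        rows.append((parts[0], parts[1], float(parts[2])))
    return HomologTable(tuple(rows))


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds of the credibility rules.

    Defaults follow the published criteria: knot-core pLDDT above 50,
    topology conserved in more than 80% of homologs, close homologs at
    60% sequence identity; the clash check is a Cα-distance heuristic
    with a 3.0 Å cutoff for non-adjacent pairs.
    """

    plddt_min: float = 50.0
    conservation_min: float = 0.80
    close_identity_min: float = 0.60
    clash_distance: float = 3.0
    min_sequence_span: int = 3      # |i - j| >= this counts as non-adjacent

    def __post_init__(self) -> None:
        if not 0 <= self.plddt_min <= 100:
            raise ValueError("plddt_min must be in [0, 100]")
        for name in ("conservation_min", "close_identity_min"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.clash_distance <= 0:
            raise ValueError("clash_distance must be positive")


@dataclass(frozen=True)
class ConservationSummary:
    """Topology-conservation percentages as printed in report tables."""

    pct_conserved: int
    n_homologs: int
    pct_close_conserved: int
    n_close: int
    fraction_conserved: float
    fraction_close_conserved: float


@dataclass(frozen=True)
class Verdict:
    """Classification of one structure with per-rule outcomes."""

    category: str                            # knotted/potentially_knotted/artifact/unknotted
    rule_flags: Mapping[str, str]            # rule name -> pass/fail/unavailable
    needs_visual_inspection: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "rule_flags", dict(self.rule_flags))
        if self.category not in ("knotted", "potentially_knotted", "artifact", "unknotted"):
            raise ValueError(f"unknown category {self.category!r}")


def clash_check(
    chain: BackboneChain,
    core: KnotCore,
    config: ClassificationConfig | None = None,
) -> tuple[bool, list[tuple[int, int, float]]]:
    """Steric-clash heuristic over the knot-core Cα trace.

    Fails when any pair of core residues at least ``min_sequence_span``
    apart in sequence lies closer than ``clash_distance`` Å; returns the
    offending residue pairs with their distances.
    """
    config = config or ClassificationConfig()
    nums = chain.residue_numbers
    mask = (nums >= core.start) & (nums <= core.end)
    idx = np.nonzero(mask)[0]
    if len(idx) < 3:
        raise ValueError("knot core covers fewer than 3 residues of the chain")
    xyz = chain.coords[idx]
    offenders: list[tuple[int, int, float]] = []
    for a in range(len(idx)):
        for b in range(a + config.min_sequence_span, len(idx)):
            d = float(np.linalg.norm(xyz[a] - xyz[b]))
            if d < config.clash_distance:
                offenders.append((int(nums[idx[a]]), int(nums[idx[b]]), d))
    return (len(offenders) == 0), offenders


def conservation_summary(
    table: HomologTable,
    query_label: str,
    config: ClassificationConfig | None = None,
) -> ConservationSummary:
    """Fraction of homologs (and close homologs) sharing the query topology.

    Percentages are rounded to integers for report parity; the raw
    fractions are kept alongside.  Empty sets report 0 with n = 0.
    """
    config = config or ClassificationConfig()
    n = len(table)
    matches = sum(1 for _, label, _ in table.rows if label == query_label)
    close = [(h, label, i) for h, label, i in table.rows
             if i >= config.close_identity_min]
    n_close = len(close)
    close_matches = sum(1 for _, label, _ in close if label == query_label)
    frac = matches / n if n else 0.0
    frac_close = close_matches / n_close if n_close else 0.0
    return ConservationSummary(
        pct_conserved=int(round(100 * frac)),
        n_homologs=n,
        pct_close_conserved=int(round(100 * frac_close)),
        n_close=n_close,
        fraction_conserved=frac,
        fraction_close_conserved=frac_close,
    )


def greedy_cluster(
    ids: Sequence[str],
    pairwise_identity: np.ndarray,
    threshold: float = 0.60,
    lengths: Mapping[str, int] | None = None,
) -> dict[str, int]:
    """Greedy incremental sequence clustering (CD-hit style).

    Sequences are processed by descending length (ties lexicographic);
    each joins the first existing cluster whose *representative* (its
    founder, the longest member) has identity >= threshold, else founds
    a new cluster.  Returns id -> cluster index, in founding order.
    """
    ids = list(ids)
    mat = np.asarray(pairwise_identity, dtype=float)
    if mat.shape != (len(ids), len(ids)):
        raise ValueError("identity matrix shape must match ids")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("identity matrix must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-9):
        raise ValueError("identity matrix diagonal must be 1")
    pos = {name: k for k, name in enumerate(ids)}
    if lengths is None:
        lengths = {name: 0 for name in ids}
    order = sorted(ids, key=lambda name: (-lengths.get(name, 0), name))
    representatives: list[str] = []
    assignment: dict[str, int] = {}
    for name in order:
        for ci, rep in enumerate(representatives):
            if mat[pos[name], pos[rep]] >= threshold:
                assignment[name] = ci
                break
        else:
            assignment[name] = len(representatives)
            representatives.append(name)
    return assignment


# rule names in Verdict.rule_flags
RULE_NONTRIVIAL = "nontrivial_majority"
RULE_PLDDT = "core_plddt"
RULE_CLASH = "no_clashes"
RULE_CONSERVATION = "homolog_conservation"
RULE_SECOND_MODEL = "second_model_agrees"


def classify(
    spectrum: KnotSpectrum,
    core: KnotCore | None,
    clash_ok: bool | None,
    conservation: ConservationSummary | None,
    second_model_label: str | None,
    config: ClassificationConfig | None = None,
) -> Verdict:
    """Apply the credibility rules to one analysed structure.

    knotted      — every rule passes (visual inspection still flagged);
    artifact     — closures favour the unknot, or the core confidence is
                   below the pLDDT floor;
    potentially_knotted — anything in between (including rules that
                   cannot be evaluated: missing homolog table or second
                   model never promotes to knotted);
    unknotted    — trivial dominant knot type.
    """
    config = config or ClassificationConfig()
    if spectrum.dominant == UNKNOT:
        return Verdict("unknotted", {}, needs_visual_inspection=False)
    if core is None:
        raise ValueError("knotted spectrum requires a knot core")
    if core.knot_type != spectrum.dominant:
        raise ValueError(
            f"core label {core.knot_type} does not match dominant {spectrum.dominant}"
        )

    flags: dict[str, str] = {}
    nontrivial_ok = spectrum.frequency(spectrum.dominant) > spectrum.frequency(UNKNOT)
    flags[RULE_NONTRIVIAL] = "pass" if nontrivial_ok else "fail"
    plddt_ok = core.mean_plddt > config.plddt_min
    flags[RULE_PLDDT] = "pass" if plddt_ok else "fail"
    if clash_ok is None:
        flags[RULE_CLASH] = UNAVAILABLE
    else:
        flags[RULE_CLASH] = "pass" if clash_ok else "fail"
    if conservation is None:
        flags[RULE_CONSERVATION] = UNAVAILABLE
    else:
        conserved = conservation.fraction_conserved > config.conservation_min \
            and conservation.n_homologs > 0
        flags[RULE_CONSERVATION] = "pass" if conserved else "fail"
    if second_model_label is None:
        flags[RULE_SECOND_MODEL] = UNAVAILABLE
    else:
        flags[RULE_SECOND_MODEL] = (
            "pass" if second_model_label == spectrum.dominant else "fail"
        )

    if not nontrivial_ok or (not plddt_ok and core.mean_plddt < config.plddt_min):
        return Verdict("artifact", flags, needs_visual_inspection=False)
    if all(v == "pass" for v in flags.values()):
        return Verdict("knotted", flags, needs_visual_inspection=True)
    return Verdict("potentially_knotted", flags, needs_visual_inspection=False)
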