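"""Knot-core localization by the subchain matrix model.

The knot fingerprint types every subchain on a two-sided trimming grid:
cell (start, end) is the dominant knot of the backbone restricted to
that residue window.  The knot core is the shortest subchain whose
dominant type equals the full chain's; residues outside it are the N-
and C-tails, and a knot with a tail shorter than 5 residues is shallow.
Subchains knotted differently from (or despite) the full chain reveal
slipknot motifs, named K<full-type> <internal-type>.

Cells are evaluated on a coarse grid first (default step 10) and the
boundaries of the minimal knotted cell refined at single-residue
resolution; each cell's closure seed derives deterministically from
(seed, start, end), so coarse, refined and exhaustive evaluations of the
same cell agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .detection import KnotSpectrum, UNKNOT, dominant_knot
from .structures_io import BackboneChain

__all__ = [
    "KnotFingerprint",
    "KnotCore",
    "fingerprint",
    "knot_core",
    "detect_slipknot",
    "write_fingerprint_tsv",
    "SHALLOW_TAIL_LIMIT",
]

#: a knot whose shorter tail is below this many residues is "shallow"
SHALLOW_TAIL_LIMIT = 5

#: subchains shorter than this are not typed (too short to hold a knot)
_MIN_SUBCHAIN = 10

DEFAULT_COARSE_STEP = 10
DEFAULT_CLOSURES_PER_CELL = 50


@dataclass(frozen=True)
class KnotFingerprint:
    """Subchain-to-knot-type matrix of one chain."""

    grid: tuple[tuple[int, int], ...]                 # (start, end) inclusive
    labels: Mapping[tuple[int, int], str]
    frequencies: Mapping[tuple[int, int], float]      # dominant-label frequency
    full_chain_label: str
    full_spectrum: KnotSpectrum
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", dict(self.labels))
        object.__setattr__(self, "frequencies", dict(self.frequencies))
        full = (min(s for s, _ in self.grid), max(e for _, e in self.grid))
        if full not in self.labels:
            raise ValueError("fingerprint grid must include the full chain")


@dataclass(frozen=True)
class KnotCore:
    """Minimal subchain carrying the full-chain knot type."""

    knot_type: str
    start: int                 # residue numbers, inclusive on both ends
    end: int
    n_tail: int
    c_tail: int
    mean_plddt: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("core start must precede core end")

    @property
    def depth_class(self) -> str:
        """"shallow" when the shorter tail is below 5 residues, else "deep"."""
        return "shallow" if min(self.n_tail, self.c_tail) < SHALLOW_TAIL_LIMIT else "deep"


def _cell_seed(seed: int, start: int, end: int) -> int:
    """Deterministic per-cell seed, independent of evaluation order."""
    return (int(seed) * 1_000_003 + start * 10_007 + end * 101) % (2**31)


def fingerprint(
    chain: BackboneChain,
    coarse_step: int = DEFAULT_COARSE_STEP,
    closures_per_cell: int = DEFAULT_CLOSURES_PER_CELL,
    seed: int = 0,
    full_spectrum: KnotSpectrum | None = None,
    n_closures_full: int = 200,
    allow_trivial: bool = False,
) -> KnotFingerprint:
    """Type subchains trimmed from both termini on a coarse-then-fine grid.

    Requires a chain whose dominant knot is nontrivial unless
    ``allow_trivial`` is set (slipknot searches on unknotted chains).
    A precomputed full-chain spectrum may be passed to avoid repeating
    the headline closure run.
    """
    if coarse_step < 1:
        raise ValueError("coarse_step must be >= 1")
    nums = chain.residue_numbers
    first, last = int(nums[0]), int(nums[-1])
    if full_spectrum is None:
        full_spectrum = dominant_knot(chain, n_closures=n_closures_full, seed=seed)
    full_label = full_spectrum.dominant
    if full_label == UNKNOT and not allow_trivial:
        raise ValueError(
            "fingerprint requires a knotted chain (trivial dominant type); "
            "pass allow_trivial=True to search for slipknots anyway"
        )

    labels: dict[tuple[int, int], str] = {}
    freqs: dict[tuple[int, int], float] = {}

    def evaluate(start: int, end: int) -> str:
        cell = (start, end)
        if cell in labels:
            return labels[cell]
        if cell == (first, last):
            spec = full_spectrum
        else:
            sub = chain.subchain(start, end)
            spec = dominant_knot(sub, n_closures=closures_per_cell,
                                 seed=_cell_seed(seed, start, end))
        labels[cell] = spec.dominant
        freqs[cell] = spec.frequency(spec.dominant)
        return spec.dominant

    starts = list(range(first, last - _MIN_SUBCHAIN + 2, coarse_step))
    ends = list(range(last, first + _MIN_SUBCHAIN - 2, -coarse_step))
    for s in starts:
        for e in sorted(ends):
            if e - s + 1 < _MIN_SUBCHAIN:
                continue
            evaluate(s, e)

    # refine the boundaries of the minimal cell carrying the full label
    if full_label != UNKNOT:
        matching = [c for c, lab in labels.items() if lab == full_label]
        if matching:
            bs, be = min(matching, key=lambda c: (c[1] - c[0], c[0]))
            best_s = bs
            for s in range(bs + 1, min(bs + coarse_step, be - _MIN_SUBCHAIN + 2)):
                if evaluate(s, be) == full_label:
                    best_s = s
                else:
                    break
            best_e = be
            for e in range(be - 1, max(be - coarse_step, best_s + _MIN_SUBCHAIN - 2), -1):
                if evaluate(best_s, e) == full_label:
                    best_e = e
                else:
                    break

    grid = tuple(sorted(labels.keys()))
    return KnotFingerprint(grid, labels, freqs, full_label, full_spectrum, int(seed))


def knot_core(fp: KnotFingerprint, chain: BackboneChain) -> KnotCore:
    """Shortest fingerprint cell with the full-chain label (ties: smaller start)."""
    if fp.full_chain_label == UNKNOT:
        raise ValueError("an unknotted chain has no knot core")
    matching = [c for c, lab in fp.labels.items() if lab == fp.full_chain_label]
    if not matching:
        raise ValueError(
            "inconsistent fingerprint: no subchain carries the full-chain label"
        )
    start, end = min(matching, key=lambda c: (c[1] - c[0], c[0]))
    first = int(chain.residue_numbers[0])
    last = int(chain.residue_numbers[-1])
    return KnotCore(
        knot_type=fp.full_chain_label,
        start=start,
        end=end,
        n_tail=start - first,
        c_tail=last - end,
        mean_plddt=chain.mean_plddt(start, end),
    )


def detect_slipknot(fp: KnotFingerprint) -> list[tuple[tuple[int, int], str, str]]:
    """Slipknot motifs: knotted subchains beyond the knot core.

    Returns maximal regions (merged over overlapping cells) whose label
    is nontrivial and either differs from the full-chain label or, when
    it matches, does not contain the knot core (an internal knot that
    vanishes in the whole chain).  Each entry is
    ``(region, internal_label, motif_name)`` with the motif written
    K<full> <internal>.
    """
    full = fp.full_chain_label
    if full != UNKNOT:
        matching = [c for c, lab in fp.labels.items() if lab == full]
        core = min(matching, key=lambda c: (c[1] - c[0], c[0])) if matching else None
    else:
        core = None

    candidates: dict[str, list[tuple[int, int]]] = {}
    for cell, lab in fp.labels.items():
        if lab == UNKNOT or lab == "other":
            continue
        if lab == full and core is not None and \
                cell[0] <= core[0] and cell[1] >= core[1]:
            continue  # expected: the cell contains the knot core
        candidates.setdefault(lab, []).append(cell)

    out: list[tuple[tuple[int, int], str, str]] = []
    for lab, cells in sorted(candidates.items()):
        cells.sort()
        merged: list[list[int]] = []
        for s, e in cells:
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            out.append(((s, e), lab, f"K{full} {lab}"))
    return out


def write_fingerprint_tsv(fp: KnotFingerprint, path: str | Path) -> None:
    """Export the fingerprint matrix as TSV (start, end, label, frequency)."""
    lines = ["start\tend\tlabel\tfrequency"]
    for (s, e) in fp.grid:
        lines.append(f"{s}\t{e}\t{fp.labels[(s, e)]}\t{fp.frequencies[(s, e)]:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")
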