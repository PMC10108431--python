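"""Reading and writing single-chain Cα backbone models.

Input models follow the AlphaFold file conventions: one polymer chain
with the per-residue confidence (pLDDT, 0-100) stored in the B-factor /
isotropic-displacement column.  Both PDB and mmCIF are read through
gemmi; output is a minimal poly-alanine Cα-trace PDB dialect that
round-trips exactly through :func:`parse_backbone`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import gemmi
import numpy as np

__all__ = [
    "BackboneChain",
    "StructureParseError",
    "ChainNotFoundError",
    "MissingCalphaError",
    "parse_backbone",
    "write_synthetic_model",
    "CHAIN_BREAK_DISTANCE",
]

#: consecutive-Cα distance beyond which a chain break is recorded (Å)
CHAIN_BREAK_DISTANCE = 4.5


class StructureParseError(ValueError):
    """The file could not be parsed as a structure model."""


class ChainNotFoundError(StructureParseError):
    """No usable chain (or the requested chain) in the file."""


class MissingCalphaError(StructureParseError):
    """An amino-acid residue in the selected chain has no Cα atom."""


@dataclass(frozen=True)
class BackboneChain:
    """Ordered Cα trace of one protein chain with per-residue confidence.

    ``residue_numbers`` keeps the source numbering (1-based in AlphaFold
    models); knot cores are always reported in this numbering with
    inclusive bounds.
    """

    chain_id: str
    residue_numbers: np.ndarray          # (n,) int
    coords: np.ndarray                   # (n, 3) float, Å
    plddt: np.ndarray                    # (n,) float in [0, 100]
    sequence: str | None = None
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        nums = np.asarray(self.residue_numbers, dtype=int)
        xyz = np.asarray(self.coords, dtype=float)
        conf = np.asarray(self.plddt, dtype=float)
        if xyz.ndim != 2 or xyz.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if not (len(nums) == len(xyz) == len(conf)):
            raise ValueError("residue_numbers, coords and plddt must align")
        if len(nums) < 3:
            raise ValueError("a backbone chain needs at least 3 residues")
        if np.any(np.diff(nums) <= 0):
            raise ValueError("residue numbers must be strictly increasing")
        if not np.all(np.isfinite(xyz)):
            raise ValueError("coordinates must be finite")
        if self.sequence is not None and len(self.sequence) != len(nums):
            raise ValueError("sequence length must match residue count")
        object.__setattr__(self, "residue_numbers", nums)
        object.__setattr__(self, "coords", xyz)
        object.__setattr__(self, "plddt", conf)
        object.__setattr__(self, "warnings", tuple(self.warnings))

    def __len__(self) -> int:
        return len(self.residue_numbers)

    def subchain(self, start: int, end: int) -> "BackboneChain":
        """Residues with source numbers in the inclusive window [start, end]."""
        mask = (self.residue_numbers >= start) & (self.residue_numbers <= end)
        if mask.sum() < 3:
            raise ValueError(f"subchain [{start}, {end}] has fewer than 3 residues")
        seq = None
        if self.sequence is not None:
            seq = "".join(c for c, m in zip(self.sequence, mask) if m)
        return BackboneChain(
            self.chain_id,
            self.residue_numbers[mask],
            self.coords[mask],
            self.plddt[mask],
            sequence=seq,
        )

    def mean_plddt(self, start: int | None = None, end: int | None = None) -> float:
        """Mean confidence over a residue-number window (whole chain by default)."""
        if start is None and end is None:
            return float(self.plddt.mean())
        lo = self.residue_numbers[0] if start is None else start
        hi = self.residue_numbers[-1] if end is None else end
        mask = (self.residue_numbers >= lo) & (self.residue_numbers <= hi)
        if not mask.any():
            raise ValueError(f"no residues in [{lo}, {hi}]")
        return float(self.plddt[mask].mean())


def _pick_ca(residue: gemmi.Residue) -> gemmi.Atom | None:
    """Cα of a residue; altlocs resolved by occupancy, then altloc letter."""
    cands = [a for a in residue if a.name == "CA" and a.element.name != "Ca"]
    if not cands:
        return None
    return min(cands, key=lambda a: (-a.occ, a.altloc))


def _is_amino_acid(residue: gemmi.Residue) -> bool:
    info = gemmi.find_tabulated_residue(residue.name)
    if info is not None and info.is_amino_acid():
        return True
    return residue.het_flag == "A"


def parse_backbone(path: str | Path, chain_selector: str | None = None) -> BackboneChain:
    """Read a single-chain Cα backbone from a PDB or mmCIF file.

    One Cα per amino-acid residue, ordered by residue number; pLDDT is
    taken from the B-factor field.  Non-polymer residues (waters,
    ligands) are ignored.  Chain breaks (consecutive Cα farther apart
    than 4.5 Å) are recorded as warnings, not errors.
    """
    path = Path(path)
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(structure) == 0:
        raise StructureParseError(f"{path} contains no models")
    model = structure[0]

    chain = None
    if chain_selector is not None:
        chain = model.find_chain(chain_selector)
        if chain is None:
            available = [c.name for c in model]
            raise ChainNotFoundError(
                f"chain {chain_selector!r} not in {path} (available: {available})"
            )
    else:
        for cand in model:
            if sum(1 for r in cand if _is_amino_acid(r)) >= 3:
                chain = cand
                break
        if chain is None:
            raise ChainNotFoundError(f"no chain with >=3 amino-acid residues in {path}")

    numbers: list[int] = []
    coords: list[tuple[float, float, float]] = []
    plddt: list[float] = []
    seq: list[str] = []
    for residue in chain:
        if not _is_amino_acid(residue):
            continue
        ca = _pick_ca(residue)
        if ca is None:
            raise MissingCalphaError(
                f"residue {residue.seqid.num} ({residue.name}) in chain "
                f"{chain.name} of {path} has no CA atom"
            )
        numbers.append(residue.seqid.num)
        coords.append((ca.pos.x, ca.pos.y, ca.pos.z))
        plddt.append(ca.b_iso)
        info = gemmi.find_tabulated_residue(residue.name)
        one = info.one_letter_code.upper() if info else "X"
        seq.append(one if one.isalpha() else "X")
    if len(numbers) < 3:
        raise ChainNotFoundError(
            f"chain {chain.name} of {path} has only {len(numbers)} Cα residues"
        )

    order = np.argsort(numbers, kind="stable")
    numbers_arr = np.asarray(numbers)[order]
    coords_arr = np.asarray(coords)[order]
    plddt_arr = np.asarray(plddt)[order]
    seq_str = "".join(seq[i] for i in order)

    warnings: list[str] = []
    gaps = np.linalg.norm(np.diff(coords_arr, axis=0), axis=1)
    for i in np.nonzero(gaps > CHAIN_BREAK_DISTANCE)[0]:
        warnings.append(
            f"chain break between residues {numbers_arr[i]} and "
            f"{numbers_arr[i + 1]} (Cα distance {gaps[i]:.1f} Å)"
        )
    return BackboneChain(
        chain.name, numbers_arr, coords_arr, plddt_arr,
        sequence=seq_str, warnings=tuple(warnings),
    )


def write_synthetic_model(chain: BackboneChain, path: str | Path) -> None:
    """Write a backbone as a minimal poly-alanine Cα-trace PDB file.

    The B-factor column carries pLDDT with two decimals; coordinates are
    written at the standard 3 decimals, so parse(write(x)) reproduces x
    to 1e-3 Å and 1e-2 pLDDT.
    """
    path = Path(path)
    cid = (chain.chain_id or "A")[0]
    lines = []
    for serial, (num, xyz, b) in enumerate(
        zip(chain.residue_numbers, chain.coords, chain.plddt), start=1
    ):
        lines.append(
            f"ATOM  {serial:5d}  CA  ALA {cid}{num:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{b:6.2f}"
            f"{'':10s}C  "
        )
    lines.append(f"TER   {len(chain) + 1:5d}      ALA {cid}{chain.residue_numbers[-1]:4d}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
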