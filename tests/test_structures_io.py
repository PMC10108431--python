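"""Backbone I/O: PDB/mmCIF parsing, pLDDT handling, round trips."""

import gemmi
import numpy as np
import pytest

from knotscan.structures_io import (
    BackboneChain,
    ChainNotFoundError,
    MissingCalphaError,
    StructureParseError,
    parse_backbone,
    write_synthetic_model,
)


def straight_chain(n=10, plddt=90.0, start_num=1):
    return BackboneChain(
        chain_id="A",
        residue_numbers=np.arange(start_num, start_num + n),
        coords=np.column_stack([np.arange(n) * 3.8, np.zeros(n), np.zeros(n)]),
        plddt=np.full(n, plddt),
    )


class TestBackboneChain:
    def test_invariants(self):
        with pytest.raises(ValueError):
            straight_chain(2)
        with pytest.raises(ValueError):
            BackboneChain("A", [3, 2, 1], np.zeros((3, 3)), [90, 90, 90])
        with pytest.raises(ValueError):
            BackboneChain("A", [1, 2, 3], np.full((3, 3), np.nan), [90, 90, 90])

    def test_subchain_uses_residue_numbers(self):
        chain = straight_chain(20, start_num=101)
        sub = chain.subchain(105, 110)
        assert list(sub.residue_numbers) == list(range(105, 111))
        assert sub.coords.shape == (6, 3)

    def test_mean_plddt_window(self):
        chain = straight_chain(10)
        assert chain.mean_plddt() == pytest.approx(90.0)
        assert chain.mean_plddt(3, 5) == pytest.approx(90.0)


class TestRoundTrip:
    def test_write_parse_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        chain = BackboneChain(
            "A", np.arange(1, 31),
            rng.normal(scale=20, size=(30, 3)).cumsum(axis=0) / 3,
            rng.uniform(30, 99, size=30),
        )
        path = tmp_path / "m.pdb"
        write_synthetic_model(chain, path)
        back = parse_backbone(path)
        assert np.abs(back.coords - chain.coords).max() < 1e-3
        assert np.abs(back.plddt - chain.plddt).max() < 1e-2
        assert list(back.residue_numbers) == list(chain.residue_numbers)

    def test_uniform_plddt_mean_exact(self, tmp_path):
        chain = straight_chain(10, plddt=90.0)
        write_synthetic_model(chain, tmp_path / "m.pdb")
        back = parse_backbone(tmp_path / "m.pdb")
        assert back.mean_plddt() == pytest.approx(90.00, abs=1e-9)

    def test_source_numbering_preserved(self, tmp_path):
        chain = straight_chain(10, start_num=42)
        write_synthetic_model(chain, tmp_path / "m.pdb")
        back = parse_backbone(tmp_path / "m.pdb")
        assert back.residue_numbers[0] == 42

    def test_mmcif_roundtrip(self, tmp_path):
        chain = straight_chain(12)
        pdb = tmp_path / "m.pdb"
        write_synthetic_model(chain, pdb)
        st = gemmi.read_structure(str(pdb))
        st.setup_entities()
        cif = tmp_path / "m.cif"
        st.make_mmcif_document().write_file(str(cif))
        back = parse_backbone(cif)
        assert np.abs(back.coords - chain.coords).max() < 1e-3
        assert np.abs(back.plddt - chain.plddt).max() < 1e-2


class TestParsing:
    def test_missing_ca_names_residue(self, tmp_path):
        lines = []
        serial = 1
        for i in range(1, 6):
            if i == 3:  # residue 3 has only a CB atom
                lines.append(
                    f"ATOM  {serial:5d}  CB  ALA A{i:4d}    "
                    f"{i*3.8:8.3f}{0.0:8.3f}{0.0:8.3f}{1.0:6.2f}{90.0:6.2f}"
                )
            else:
                lines.append(
                    f"ATOM  {serial:5d}  CA  ALA A{i:4d}    "
                    f"{i*3.8:8.3f}{0.0:8.3f}{0.0:8.3f}{1.0:6.2f}{90.0:6.2f}"
                )
            serial += 1
        path = tmp_path / "gap.pdb"
        path.write_text("\n".join(lines) + "\nEND\n")
        with pytest.raises(MissingCalphaError, match="residue 3"):
            parse_backbone(path)

    def test_trailing_columns_ignored(self, tmp_path):
        chain = straight_chain(5)
        full = tmp_path / "full.pdb"
        write_synthetic_model(chain, full)
        # truncate every ATOM record right after the B-factor column (66)
        trimmed = tmp_path / "trim.pdb"
        trimmed.write_text("".join(
            line[:66] + "\n" if line.startswith("ATOM") else line + "\n"
            for line in full.read_text().splitlines()
        ))
        a, b = parse_backbone(full), parse_backbone(trimmed)
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.plddt, b.plddt)

    def test_chain_break_warning(self, tmp_path):
        coords = np.column_stack([np.arange(6) * 3.8, np.zeros(6), np.zeros(6)])
        coords[3:] += np.array([30.0, 0, 0])   # 33.8 Å jump between 3 and 4
        chain = BackboneChain("A", np.arange(1, 7), coords, np.full(6, 90.0))
        write_synthetic_model(chain, tmp_path / "b.pdb")
        back = parse_backbone(tmp_path / "b.pdb")
        assert len(back.warnings) == 1
        assert "between residues 3 and 4" in back.warnings[0]

    def test_altloc_highest_occupancy_wins(self, tmp_path):
        lines = []
        for i in range(1, 4):
            lines.append(
                f"ATOM  {i:5d}  CA  ALA A{i:4d}    "
                f"{i*3.8:8.3f}{0.0:8.3f}{0.0:8.3f}{1.0:6.2f}{90.0:6.2f}"
            )
        # residue 4 with two altlocs: B has the higher occupancy
        lines.append(
            "ATOM      4  CA AALA A   4    "
            f"{15.2:8.3f}{0.0:8.3f}{0.0:8.3f}{0.40:6.2f}{10.0:6.2f}"
        )
        lines.append(
            "ATOM      5  CA BALA A   4    "
            f"{15.2:8.3f}{1.0:8.3f}{0.0:8.3f}{0.60:6.2f}{77.0:6.2f}"
        )
        path = tmp_path / "alt.pdb"
        path.write_text("\n".join(lines) + "\nEND\n")
        back = parse_backbone(path)
        assert back.plddt[-1] == pytest.approx(77.0)
        assert back.coords[-1][1] == pytest.approx(1.0)

    def test_missing_chain_and_unparsable(self, tmp_path):
        chain = straight_chain(5)
        write_synthetic_model(chain, tmp_path / "m.pdb")
        with pytest.raises(ChainNotFoundError):
            parse_backbone(tmp_path / "m.pdb", chain_selector="Z")
        bad = tmp_path / "junk.pdb"
        bad.write_text("this is not a structure\n")
        with pytest.raises(StructureParseError):
            parse_backbone(bad)
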