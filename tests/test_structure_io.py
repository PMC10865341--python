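"""Structure container, PDB/GRO round trips, and neighbour counting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cphprep.fixtures import make_water_box
from cphprep.structure import (
    Atom,
    Structure,
    StructureError,
    neighbor_count,
    read_structure,
    write_structure,
)
from conftest import brute_neighbor_count

WATER_PDB = """\
CRYST1   30.000   30.000   30.000  90.00  90.00  90.00 P 1           1
ATOM      1  O   HOH A   1      10.000   2.000   3.000  1.00  0.00           O
ATOM      2  H1  HOH A   1      10.800   2.300   3.000  1.00  0.00           H
ATOM      3  H2  HOH A   1       9.500   2.700   3.100  1.00  0.00           H
END
"""


def _atom(name="X", res="RES", seq=1, chain="A", pos=(0, 0, 0)):
    return Atom(1, name, res, seq, chain, np.array(pos, dtype=float))


class TestReading:
    def test_pdb_single_water(self, tmp_path):
        p = tmp_path / "w.pdb"
        p.write_text(WATER_PDB)
        s = read_structure(p)
        assert s.n_atoms == 3
        assert len(s.residues()) == 1
        # PDB coordinates are Angstrom; internal storage is nm
        assert s.atoms[0].position == pytest.approx([1.0, 0.2, 0.3])
        assert s.box == pytest.approx([3.0, 3.0, 3.0])

    def test_gro_positions_kept_in_nm(self, tmp_path):
        gro = (
            "single water\n    1\n"
            "    1SOL     OW    1   1.000   2.000   3.000\n"
            "  5.00000   5.00000   5.00000\n"
        )
        p = tmp_path / "w.gro"
        p.write_text(gro)
        s = read_structure(p)
        assert s.atoms[0].position == pytest.approx([1.0, 2.0, 3.0])
        # GRO has no chain column -> single synthetic chain
        assert s.atoms[0].chain == "A"

    def test_malformed_pdb_names_line(self, tmp_path):
        bad = WATER_PDB.replace("10.000", "1x.0y0", 1)
        p = tmp_path / "bad.pdb"
        p.write_text(bad)
        with pytest.raises(StructureError, match="line 2"):
            read_structure(p)

    def test_unknown_format_rejected(self, tmp_path):
        p = tmp_path / "w.xyz"
        p.write_text("3\n")
        with pytest.raises(StructureError, match="format"):
            read_structure(p)


class TestWriting:
    @pytest.mark.parametrize("fmt", ["pdb", "gro"])
    def test_round_trip_small(self, tmp_path, fmt):
        s = read_structure(self._write_input(tmp_path))
        out = tmp_path / f"out.{fmt}"
        write_structure(s, out)
        r = read_structure(out)
        assert [a.name for a in r.atoms] == [a.name for a in s.atoms]
        assert [a.residue_seq for a in r.atoms] == [a.residue_seq for a in s.atoms]
        # format precision: GRO 0.001 nm, PDB 0.001 A = 0.0001 nm
        tol = 0.0006 if fmt == "gro" else 0.0001
        assert np.abs(r.coords() - s.coords()).max() < tol

    @staticmethod
    def _write_input(tmp_path):
        p = tmp_path / "in.pdb"
        p.write_text(WATER_PDB)
        return p

    def test_round_trip_large_synthetic_box(self, tmp_path):
        s = make_water_box(15, seed=1)  # 10,125 atoms
        out = tmp_path / "big.gro"
        write_structure(s, out)
        r = read_structure(out)
        assert r.n_atoms == s.n_atoms == 10125
        assert np.abs(r.coords() - s.coords()).max() < 0.0006

    def test_pdb_gro_pdb_coordinates_preserved(self, tmp_path):
        s = make_water_box(4, seed=9)
        write_structure(s, tmp_path / "a.pdb")
        mid = read_structure(tmp_path / "a.pdb")
        write_structure(mid, tmp_path / "b.gro")
        back = read_structure(tmp_path / "b.gro")
        assert np.abs(back.coords() - s.coords()).max() < 0.001

    def test_empty_structure_rejected(self, tmp_path):
        with pytest.raises(StructureError, match="empty"):
            write_structure(Structure(), tmp_path / "x.pdb")

    def test_overlong_atom_name_not_truncated(self, tmp_path):
        s = Structure(atoms=[_atom(name="OXYGEN1")], box=np.ones(3))
        with pytest.raises(StructureError, match="column width"):
            write_structure(s, tmp_path / "x.gro")


class TestStructureInvariants:
    def test_triclinic_box_rejected(self):
        box = np.array([[3.0, 0.5, 0.0], [0.0, 3.0, 0.0], [0.0, 0.0, 3.0]])
        with pytest.raises(StructureError, match="triclinic"):
            Structure(atoms=[_atom()], box=box)

    def test_every_atom_in_exactly_one_residue(self, water_box):
        counts = np.zeros(water_box.n_atoms, dtype=int)
        for res in water_box.residues():
            counts[res.atom_indices] += 1
        assert (counts == 1).all()

    def test_nonfinite_position_rejected(self):
        with pytest.raises(StructureError):
            _atom(pos=(np.nan, 0, 0))


class TestNeighborCount:
    def test_single_atom_at_center(self):
        s = Structure(atoms=[_atom(pos=(1.0, 1.0, 1.0))], box=np.full(3, 3.0))
        assert neighbor_count(s, (1.0, 1.0, 1.0), 0.1) == 1

    def test_exact_tie_counts_as_inside(self):
        s = Structure(atoms=[_atom(pos=(0.5, 0.0, 0.0))], box=np.full(3, 3.0))
        assert neighbor_count(s, (0.0, 0.0, 0.0), 0.5) == 1

    def test_pbc_requires_box(self):
        s = Structure(atoms=[_atom()])
        with pytest.raises(StructureError, match="no box"):
            neighbor_count(s, (0, 0, 0), 0.5, pbc=True)

    def test_pbc_wraps_across_boundary(self):
        s = Structure(
            atoms=[_atom(pos=(0.05, 0.5, 0.5)), _atom(pos=(2.95, 0.5, 0.5))],
            box=np.full(3, 3.0),
        )
        assert neighbor_count(s, (0.0, 0.5, 0.5), 0.2, pbc=True) == 2
        assert neighbor_count(s, (0.0, 0.5, 0.5), 0.2, pbc=False) == 1

    def test_selection_predicate(self, water_box):
        center = water_box.box / 2
        total = neighbor_count(water_box, center, 1.0)
        oxy = neighbor_count(
            water_box, center, 1.0, selection=lambda a: a.name == "OW"
        )
        assert 0 < oxy < total

    @given(seed=st.integers(0, 10_000), pbc=st.booleans())
    def test_matches_brute_force(self, water_box, seed, pbc):
        """Tree-accelerated counting equals the all-pairs scan."""
        rng = np.random.default_rng(seed)
        center = rng.random(3) * water_box.box
        radius = 0.2 + rng.random() * 0.9
        assert neighbor_count(water_box, center, radius, pbc=pbc) == \
            brute_neighbor_count(water_box, center, radius, pbc=pbc)
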