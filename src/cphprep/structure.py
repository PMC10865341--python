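"""Molecular structure container with PDB/GRO I/O and spatial queries.

Coordinates are stored internally in nanometres (the GRO convention);
PDB files are converted from/to Angstrom on read/write.  Only rectangular
(orthorhombic) boxes are supported for periodic distance computations;
triclinic boxes are rejected rather than silently mishandled.

File-level parsing and writing is delegated to :mod:`biotite.structure.io`,
which implements the wwPDB v3.3 and GROMACS fixed-width column layouts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: residue names treated as solvent (water) throughout the package
DEFAULT_SOLVENT_NAMES = frozenset({"SOL", "HOH", "TIP3"})

_ANGSTROM_PER_NM = 10.0


class StructureError(Exception):
    """Raised for malformed structure files or invalid structure operations."""


@dataclass
class Atom:
    """A single atom record.

    ``position`` is a length-3 float array in nm.  ``element`` is derived
    from the atom name when the file does not provide one.
    """

    serial: int
    name: str
    residue_name: str
    residue_seq: int
    chain: str
    position: np.ndarray
    element: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise StructureError(f"atom {self.name}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.name}: non-finite position")
        if not self.name:
            raise StructureError("atom name must be non-empty")
        if self.residue_seq < 0:
            raise StructureError(f"atom {self.name}: negative residue_seq")
        if not self.element:
            self.element = guess_element(self.name)

    def copy(self) -> "Atom":
        return replace(self, position=self.position.copy())


def guess_element(atom_name: str) -> str:
    """Derive the element from an atom name (first alphabetic character;
    a leading digit, as in ``1HH1``, is skipped)."""
    stripped = atom_name.lstrip("0123456789")
    for two in ("CL", "NA", "MG", "BR"):
        if stripped.upper().startswith(two) and len(stripped) <= 2:
            return two.capitalize()
    return stripped[:1].upper() if stripped else "X"


@dataclass
class Residue:
    """A contiguous group of atoms sharing (chain, residue_seq, residue_name)."""

    chain: str
    seq: int
    name: str
    atom_indices: list[int] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seq, self.name)


@dataclass
class Structure:
    """An ordered list of atoms plus an optional rectangular box (nm)."""

    title: str = ""
    atoms: list[Atom] = field(default_factory=list)
    box: np.ndarray | None = None  # 3 box lengths, nm

    def __post_init__(self) -> None:
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape == (3, 3):
                off = self.box - np.diag(np.diag(self.box))
                if np.any(np.abs(off) > 1e-9):
                    raise StructureError(
                        "triclinic boxes are not supported; only rectangular "
                        "(diagonal) box vectors are accepted"
                    )
                self.box = np.diag(self.box).copy()
            if self.box.shape != (3,):
                raise StructureError("box must be 3 lengths or a 3x3 matrix")
            if np.any(self.box <= 0):
                raise StructureError("box lengths must be positive")

    # -- basic queries -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """All positions as an (N, 3) array in nm."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms])

    def residues(self) -> list[Residue]:
        """Group atoms into residues, preserving file order.

        Atoms belong to the same residue while (chain, seq, name) is
        unchanged; a revisited key after an interruption starts a new
        residue (standard PDB semantics).
        """
        out: list[Residue] = []
        last: tuple[str, int, str] | None = None
        for i, a in enumerate(self.atoms):
            key = (a.chain, a.residue_seq, a.residue_name)
            if key != last:
                out.append(Residue(a.chain, a.residue_seq, a.residue_name))
                last = key
            out[-1].atom_indices.append(i)
        return out

    def copy(self) -> "Structure":
        return Structure(
            title=self.title,
            atoms=[a.copy() for a in self.atoms],
            box=None if self.box is None else self.box.copy(),
        )

    def renumber(self) -> None:
        """Reassign atom serials sequentially from 1."""
        for i, a in enumerate(self.atoms, start=1):
            a.serial = i

    def remove_residues(self, keys: Iterable[tuple[str, int, str]]) -> "Structure":
        """Return a copy with all atoms of the given residues removed."""
        drop = set(keys)
        kept = [
            a.copy()
            for a in self.atoms
            if (a.chain, a.residue_seq, a.residue_name) not in drop
        ]
        s = Structure(title=self.title, atoms=kept,
                      box=None if self.box is None else self.box.copy())
        s.renumber()
        return s


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("pdb", "gro"):
        return suffix
    raise StructureError(f"cannot infer structure format from '{path.name}'")


def _first_bad_line(path: Path, fmt: str) -> int | None:
    """Locate the first obviously malformed atom line, for error messages."""
    try:
        lines = path.read_text().splitlines()
    except OSError:
        return None
    for lineno, line in enumerate(lines, start=1):
        if fmt == "pdb" and line.startswith(("ATOM", "HETATM")):
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except (ValueError, IndexError):
                return lineno
    return None


def read_structure(path: str | Path, fmt: str = "auto") -> Structure:
    """Read a PDB or GRO file into a :class:`Structure` (positions in nm).

    PDB coordinates are converted from Angstrom.  Alternate locations other
    than the first are dropped with a warning.  A malformed coordinate line
    raises :class:`StructureError` naming the line number where possible.
    """
    import biotite.structure as struc

    path = Path(path)
    if not path.exists():
        raise StructureError(f"structure file not found: {path}")
    fmt = _infer_format(path, fmt)

    try:
        if fmt == "pdb":
            from biotite.structure.io.pdb import PDBFile

            pfile = PDBFile.read(str(path))
            arr = pfile.get_structure(model=1, altloc="first")
        elif fmt == "gro":
            from biotite.structure.io.gro import GROFile

            gfile = GROFile.read(str(path))
            arr = gfile.get_structure(model=1)
        else:
            raise StructureError(f"unknown structure format '{fmt}'")
    except StructureError:
        raise
    except Exception as exc:  # biotite raises format-specific errors
        lineno = _first_bad_line(path, fmt)
        where = f" (line {lineno})" if lineno else ""
        raise StructureError(f"failed to parse {fmt} file {path}{where}: {exc}") from exc

    coords_nm = np.asarray(arr.coord, dtype=float) / _ANGSTROM_PER_NM
    box = None
    if arr.box is not None:
        box3 = np.asarray(arr.box, dtype=float) / _ANGSTROM_PER_NM
        diag = np.diag(box3)
        if np.any(np.abs(box3 - np.diag(diag)) > 1e-9):
            raise StructureError(f"{path}: triclinic boxes are not supported")
        if np.all(diag > 0):
            box = diag.copy()

    atoms: list[Atom] = []
    for i in range(arr.array_length()):
        chain = str(arr.chain_id[i]).strip()
        atoms.append(
            Atom(
                serial=i + 1,
                name=str(arr.atom_name[i]).strip(),
                residue_name=str(arr.res_name[i]).strip(),
                residue_seq=int(arr.res_id[i]),
                # GRO has no chain column; use a single synthetic chain
                chain=chain or "A",
                position=coords_nm[i],
                element=str(arr.element[i]).strip().capitalize()
                if "element" in arr.get_annotation_categories()
                else "",
            )
        )
    return Structure(title=path.stem, atoms=atoms, box=box)


def write_structure(s: Structure, path: str | Path, fmt: str = "auto") -> Path:
    """Write a structure to PDB or GRO.

    Raises :class:`StructureError` for an empty structure or for atom /
    residue names that do not fit the fixed-width columns (no silent
    truncation).
    """
    import biotite.structure as struc

    path = Path(path)
    if not s.atoms:
        raise StructureError("refusing to write an empty structure")
    fmt = _infer_format(path, fmt)

    max_res = 3 if fmt == "pdb" else 5
    for a in s.atoms:
        if len(a.name) > 4 or len(a.residue_name) > max_res:
            raise StructureError(
                f"atom '{a.name}' / residue '{a.residue_name}' exceeds the "
                f"column width of {fmt} files"
                + ("; 4-character residue names fit GRO" if fmt == "pdb" else "")
            )
        if fmt == "pdb" and len(a.chain) > 1:
            raise StructureError(f"chain id '{a.chain}' too long for PDB")

    n = s.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = (s.coords() * _ANGSTROM_PER_NM).astype(np.float32)
    arr.chain_id = np.array([a.chain[:1] for a in s.atoms], dtype="U4")
    arr.res_id = np.array([a.residue_seq for a in s.atoms], dtype=int)
    arr.res_name = np.array([a.residue_name for a in s.atoms], dtype="U5")
    arr.atom_name = np.array([a.name for a in s.atoms], dtype="U6")
    arr.element = np.array([a.element for a in s.atoms], dtype="U2")
    arr.hetero = np.array(
        [a.residue_name in DEFAULT_SOLVENT_NAMES or a.residue_name in ("NA", "CL", "BUF")
         for a in s.atoms]
    )
    if s.box is not None:
        arr.box = np.diag(s.box * _ANGSTROM_PER_NM).astype(np.float32)
    else:
        arr.box = np.zeros((3, 3), dtype=np.float32)

    if fmt == "pdb":
        from biotite.structure.io.pdb import PDBFile

        f = PDBFile()
        f.set_structure(arr)
        f.write(str(path))
    elif fmt == "gro":
        from biotite.structure.io.gro import GROFile

        f = GROFile()
        f.set_structure(arr)
        f.write(str(path))
    else:
        raise StructureError(f"unknown structure format '{fmt}'")
    return path


# ---------------------------------------------------------------------------
# Spatial queries
# ---------------------------------------------------------------------------

def _wrap(points: np.ndarray, box: np.ndarray) -> np.ndarray:
    return np.mod(points, box)


def minimum_image_distances(
    center: np.ndarray, points: np.ndarray, box: np.ndarray | None
) -> np.ndarray:
    """Distances from ``center`` to each row of ``points``; minimum-image
    convention when a rectangular ``box`` is given."""
    delta = points - np.asarray(center, dtype=float)
    if box is not None:
        delta -= box * np.round(delta / box)
    return np.linalg.norm(delta, axis=1)


def neighbor_count(
    s: Structure,
    center: Sequence[float],
    radius: float,
    selection: Callable[[Atom], bool] | None = None,
    pbc: bool = False,
) -> int:
    """Count selected atoms within ``radius`` (nm) of ``center``.

    A distance exactly equal to ``radius`` counts as inside.  With
    ``pbc=True`` the minimum-image convention is used; this requires a
    rectangular box and ``radius`` below half the smallest box length.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if pbc and s.box is None:
        raise StructureError("periodic neighbor count requested but structure has no box")
    if pbc and radius >= s.box.min() / 2:
        raise StructureError("radius must be smaller than half the smallest box length")

    if selection is None:
        idx = np.arange(s.n_atoms)
    else:
        idx = np.array([i for i, a in enumerate(s.atoms) if selection(a)], dtype=int)
    if idx.size == 0:
        return 0
    pts = s.coords()[idx]
    center = np.asarray(center, dtype=float)

    # cell-list (k-d tree) pruning with an exact distance confirmation so the
    # <= boundary convention holds regardless of backend rounding
    if pbc:
        box = s.box
        tree = cKDTree(_wrap(pts, box), boxsize=box)
        cand = tree.query_ball_point(np.mod(center, box), radius * (1 + 1e-9))
        d = minimum_image_distances(center, pts[cand], box)
    else:
        tree = cKDTree(pts)
        cand = tree.query_ball_point(center, radius * (1 + 1e-9))
        d = minimum_image_distances(center, pts[cand], None)
    return int(np.count_nonzero(d <= radius))
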