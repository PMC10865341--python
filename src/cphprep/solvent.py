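"""Removal of water molecules misplaced inside the solute.

Automated solvation can drop waters into hydrophobic cavities; two
heuristics identify and delete them.  Both operate on the set of candidate
waters near the solute (within ``Rc`` of any non-solvent atom, default
0.5 nm) and score each candidate on the *original* structure in a single
pass, so removals never influence one another:

* density criterion — count water atoms within a sphere of radius ``R``
  (default 1.0 nm) around the candidate's oxygen; bulk water gives counts
  around 400, buried waters far fewer; remove below ``Ncutoff`` (120).
* neighbour criterion — find the ``Nneighbors`` (20) nearest residues and
  remove the candidate if fewer than ``min_water`` (3) of them are waters.

The water reference point is the oxygen atom; residue-residue distance is
the minimum over the candidate oxygen to all atoms of the other residue.
Ions count as non-solvent for the candidate cutoff but never as waters.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .structure import DEFAULT_SOLVENT_NAMES, Residue, Structure

logger = logging.getLogger(__name__)

__all__ = ["candidate_waters", "clean_by_density", "clean_by_neighbors"]


def _water_oxygen_index(s: Structure, res: Residue) -> int:
    for i in res.atom_indices:
        if s.atoms[i].element == "O" or s.atoms[i].name.startswith("O"):
            return i
    return res.atom_indices[0]


def _partition(s: Structure, solvent_names: frozenset[str]):
    residues = s.residues()
    water_res = [r for r in residues if r.name in solvent_names]
    non_solvent_atoms = [
        i for r in residues if r.name not in solvent_names for i in r.atom_indices
    ]
    return residues, water_res, non_solvent_atoms


def candidate_waters(
    s: Structure,
    Rc: float = 0.5,
    solvent_names: frozenset[str] = DEFAULT_SOLVENT_NAMES,
) -> list[Residue]:
    """Waters whose oxygen lies within ``Rc`` (nm) of any non-solvent atom."""
    _, water_res, non_solvent = _partition(s, solvent_names)
    if not water_res:
        logger.warning("structure contains no solvent residues")
        return []
    if not non_solvent:
        return []
    coords = s.coords()
    tree = cKDTree(coords[non_solvent])
    out = []
    for res in water_res:
        o = coords[_water_oxygen_index(s, res)]
        d, _ = tree.query(o)
        if d <= Rc:
            out.append(res)
    return out


def clean_by_density(
    s: Structure,
    Rc: float = 0.5,
    R: float = 1.0,
    Ncutoff: int = 120,
    solvent_names: frozenset[str] = DEFAULT_SOLVENT_NAMES,
) -> tuple[Structure, list[tuple[str, int, str]]]:
    """Remove candidate waters with fewer than ``Ncutoff`` water atoms
    within ``R`` of their oxygen (the candidate's own atoms excluded)."""
    candidates = candidate_waters(s, Rc, solvent_names)
    _, water_res, _ = _partition(s, solvent_names)
    coords = s.coords()
    water_atom_idx = np.array(
        [i for r in water_res for i in r.atom_indices], dtype=int
    )
    removed: list[tuple[str, int, str]] = []
    if candidates and water_atom_idx.size:
        tree = cKDTree(coords[water_atom_idx])
        for res in candidates:
            own = set(res.atom_indices)
            o = coords[_water_oxygen_index(s, res)]
            near = tree.query_ball_point(o, R * (1 + 1e-9))
            global_idx = water_atom_idx[near]
            d = np.linalg.norm(coords[global_idx] - o, axis=1)
            inside = global_idx[d <= R]
            count = sum(1 for i in inside if i not in own)
            if count < Ncutoff:
                removed.append(res.key)
    cleaned = s.remove_residues(removed) if removed else s.copy()
    return cleaned, removed


def clean_by_neighbors(
    s: Structure,
    Rc: float = 0.5,
    Nneighbors: int = 20,
    min_water: int = 3,
    solvent_names: frozenset[str] = DEFAULT_SOLVENT_NAMES,
) -> tuple[Structure, list[tuple[str, int, str]]]:
    """Remove candidate waters with fewer than ``min_water`` waters among
    their ``Nneighbors`` nearest residues.

    Distance to a residue is the minimum over its atoms from the candidate
    oxygen; ties at the cutoff rank are broken toward the lower residue
    index (stable sort).
    """
    residues, _, _ = _partition(s, solvent_names)
    if len(residues) - 1 < Nneighbors:
        raise ValueError(
            f"structure has only {len(residues) - 1} other residues; "
            f"{Nneighbors} neighbours requested"
        )
    candidates = candidate_waters(s, Rc, solvent_names)
    coords = s.coords()
    res_index_of_atom = np.empty(s.n_atoms, dtype=int)
    for ri, r in enumerate(residues):
        res_index_of_atom[r.atom_indices] = ri
    is_water_res = np.array([r.name in solvent_names for r in residues])

    removed: list[tuple[str, int, str]] = []
    for res in candidates:
        o = coords[_water_oxygen_index(s, res)]
        d_atom = np.linalg.norm(coords - o, axis=1)
        d_res = np.full(len(residues), np.inf)
        np.minimum.at(d_res, res_index_of_atom, d_atom)
        probe = res_index_of_atom[res.atom_indices[0]]
        d_res[probe] = np.inf  # exclude the candidate itself
        order = np.argsort(d_res, kind="stable")[:Nneighbors]
        n_water = int(np.count_nonzero(is_water_res[order]))
        if n_water < min_water:
            removed.append(res.key)
    cleaned = s.remove_residues(removed) if removed else s.copy()
    return cleaned, removed
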