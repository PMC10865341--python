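"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cphprep.grouptypes import default_registry
from cphprep.fixtures import make_cavity_system, make_water_box

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# The published single-site and multisite example blocks, as printed
# (including typographic minus signs), reflowed to one key per line.
ASPT_BLOCK = """\
[ ASPT ]
incl = ASP ASP1 ASPH ASPP ASH
atoms = CB CG OD1 OD2 HD2
qqA = −0.21 0.75 −0.55 −0.61 0.44
pKa_1 = 3.65
qqB_1 = −0.28 0.62 −0.76 −0.76 0.00
dvdl_1 = −54.078 −144.280 278.550 −146.030 −554.270 44.621
"""

HSPT_BLOCK = """\
[ HSPT ]
incl = HIS HIS1 HISA HISB HISH HISD HISE HISP HSD HSE HSP
atoms = CB CD2 HD2 CG NE2 HE2 ND1 HD1 CE1 HE1
qqA = 0.00 0.00 0.00 0.00 0.00 0.00 0.00 0.00 0.00 0.00
pKa_1 = 0.0
qqB_1 = −0.05 0.19 0.13 0.19 −0.51 0.44 −0.51 0.44 0.32 0.18
dvdl_1 = −3015.4 −13444.1 −34779.0
pKa_2 = 6.53
qqB_2 = −0.08 −0.05 0.09 0.22 −0.36 0.32 −0.7 0.0 0.25 0.13
dvdl_2 = −1695.49 −8107.68 −22614.3
pKa_3 = 6.92
qqB_3 = −0.09 0.22 0.1 −0.05 −0.7 0.0 −0.36 0.32 0.25 0.13
dvdl_3 = −111.044 −768.566 −9092.12
"""


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def water_box():
    return make_water_box(8, seed=2)


@pytest.fixture(scope="session")
def cavity_system():
    return make_cavity_system(12, n_trapped=2, seed=3)


# ---------------------------------------------------------------------------
# Independent O(N^2) oracles (no k-d trees, no package spatial helpers)
# ---------------------------------------------------------------------------

def brute_neighbor_count(structure, center, radius, pbc=False):
    coords = structure.coords()
    delta = coords - np.asarray(center, dtype=float)
    if pbc:
        delta -= structure.box * np.round(delta / structure.box)
    d = np.sqrt((delta**2).sum(axis=1))
    return int((d <= radius).sum())


def _residue_table(structure, solvent_names=("SOL", "HOH", "TIP3")):
    residues = structure.residues()
    coords = structure.coords()
    waters = [r for r in residues if r.name in solvent_names]
    oxygens = {}
    for r in waters:
        o = next(
            (i for i in r.atom_indices if structure.atoms[i].name.startswith("O")),
            r.atom_indices[0],
        )
        oxygens[r.key] = coords[o]
    return residues, coords, waters, oxygens


def brute_candidates(structure, Rc=0.5):
    residues, coords, waters, oxygens = _residue_table(structure)
    non_solvent = np.array(
        [coords[i] for r in residues if r.name not in ("SOL", "HOH", "TIP3")
         for i in r.atom_indices]
    )
    if non_solvent.size == 0:
        return []
    out = []
    for r in waters:
        d = np.sqrt(((non_solvent - oxygens[r.key]) ** 2).sum(axis=1))
        if d.min() <= Rc:
            out.append(r)
    return out


def brute_clean_density(structure, Rc=0.5, R=1.0, Ncutoff=120):
    residues, coords, waters, oxygens = _residue_table(structure)
    water_atoms = [(r.key, i) for r in waters for i in r.atom_indices]
    wcoords = np.array([coords[i] for _, i in water_atoms])
    wkeys = [k for k, _ in water_atoms]
    removed = []
    for r in brute_candidates(structure, Rc):
        d = np.sqrt(((wcoords - oxygens[r.key]) ** 2).sum(axis=1))
        count = sum(
            1 for dist, key in zip(d, wkeys) if dist <= R and key != r.key
        )
        if count < Ncutoff:
            removed.append(r.key)
    return removed


def brute_clean_neighbors(structure, Rc=0.5, Nneighbors=20, min_water=3):
    residues, coords, waters, oxygens = _residue_table(structure)
    removed = []
    for r in brute_candidates(structure, Rc):
        o = oxygens[r.key]
        dists = []
        for ri, other in enumerate(residues):
            if other.key == r.key:
                continue
            d = min(
                np.sqrt(((coords[i] - o) ** 2).sum()) for i in other.atom_indices
            )
            dists.append((d, ri, other.name))
        dists.sort(key=lambda t: (t[0], t[1]))
        n_water = sum(
            1 for _, _, name in dists[:Nneighbors] if name in ("SOL", "HOH", "TIP3")
        )
        if n_water < min_water:
            removed.append(r.key)
    return removed
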