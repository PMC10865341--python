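"""Neutralizing ions and charge-buffer particles.

The prepared system must be net-neutral for the configured initial
protonation state, and it must stay neutral while sites titrate, which is
what the buffer particles are for: each buffer is a single particle whose
charge interpolates +0.5 <-> -0.5 with its own lambda coordinate (zero
charge at lambda = 0.5).  By default one buffer is added per titratable
site.  Ions and buffers replace solvent molecules, subject to a minimum
placement distance from non-solvent atoms (default 0.6 nm).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .gentopol import TitratableSite
from .grouptypes import GroupTypeRegistry, interpolate_charges
from .structure import DEFAULT_SOLVENT_NAMES, Atom, Structure, StructureError

logger = logging.getLogger(__name__)

__all__ = [
    "NeutralizePlan",
    "system_net_charge",
    "compute_ion_counts",
    "compute_buffer_count",
    "recommended_buffer_range",
    "place_particles",
]

#: molarity of pure water, mol/L; converts ion concentration to pairs/water
WATER_MOLARITY = 55.345

#: maximal buffer particle charge, elementary charge units
BUFFER_MAX_CHARGE = 0.5


@dataclass
class NeutralizePlan:
    """Counts and constraints for one placement pass."""

    n_positive: int = 0
    n_negative: int = 0
    n_buffers: int = 0
    rmin: float = 0.6
    seed: int = 1

    def __post_init__(self) -> None:
        if min(self.n_positive, self.n_negative, self.n_buffers) < 0:
            raise ValueError("particle counts must be non-negative")
        if self.rmin <= 0:
            raise ValueError("rmin must be positive")

    @property
    def total(self) -> int:
        return self.n_positive + self.n_negative + self.n_buffers


def system_net_charge(
    s: Structure,
    registry: GroupTypeRegistry,
    sites: list[TitratableSite],
    per_residue_charges: dict[str, float],
) -> float:
    """Total system charge with titratable sites at their initial lambda.

    ``per_residue_charges`` maps residue name to the residue's charge
    *excluding* the titratable atom set (for non-titratable residues it is
    simply the residue charge).  Each site adds the sum of its interpolated
    atomic charges at its initial lambda coordinates (multisite: common
    charges plus the lambda-weighted state shifts).
    """
    total = 0.0
    for res in s.residues():
        if res.name not in per_residue_charges:
            raise KeyError(
                f"no charge entry for residue '{res.name}' "
                f"({res.chain}:{res.seq})"
            )
        total += per_residue_charges[res.name]
    for site in sites:
        definition = registry.definitions[site.group_type]
        if not site.lambda_coords:
            raise ValueError(
                f"site {site.group_type} {site.chain}:{site.residue_seq} has "
                "no initial lambda; run initialize_lambdas first"
            )
        if definition.multisite:
            q = np.asarray(definition.common_charges, dtype=float)
            for state_index, lam in site.lambda_coords:
                shift = np.asarray(definition.states[state_index].charges) - np.asarray(
                    definition.common_charges
                )
                q = q + lam * shift
            total += float(q.sum())
        else:
            state_index, lam = site.lambda_coords[0]
            total += float(np.sum(interpolate_charges(definition, state_index, lam)))
    return total


def compute_ion_counts(
    net_charge: float, concentration: float, n_waters: int
) -> tuple[int, int]:
    """Numbers of (positive, negative) monovalent ions to add.

    A salt concentration c (mol/L) contributes round(c * n_waters / 55.345)
    ion pairs; the species opposing the rounded net charge is then topped up
    so the final system charge is zero.  A net charge farther than 0.05 e
    from an integer signals a setup bug and raises ``ValueError``.
    """
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    q = round(net_charge)
    if abs(net_charge - q) > 0.05:
        raise ValueError(
            f"system net charge {net_charge:.4f} is not close to an integer; "
            "check the charge table and site states"
        )
    pairs = round(concentration * n_waters / WATER_MOLARITY)
    n_pos = pairs + max(0, -q)
    n_neg = pairs + max(0, q)
    return n_pos, n_neg


def compute_buffer_count(n_sites: int, user_value: int | None = None) -> int:
    """Number of buffer particles: the user's choice, else one per site."""
    if n_sites < 0:
        raise ValueError("n_sites must be non-negative")
    if user_value is not None:
        if user_value < 0:
            raise ValueError("buffer count must be non-negative")
        if user_value > 2 * n_sites:
            logger.warning(
                "%d buffers exceeds twice the number of titratable sites (%d); "
                "large buffer counts alter solvent properties",
                user_value, n_sites,
            )
        return user_value
    if n_sites == 0:
        logger.warning("no titratable sites: nothing to buffer")
    return n_sites


def recommended_buffer_range(n_sites: int) -> tuple[float, float]:
    """Advisory lower/upper bounds on the buffer count.

    Upper bound: the maximal charge fluctuation (all sites flip, 2*n_sites
    in charge-compensation units divided by the 0.5 maximal buffer charge
    is already folded in as 2*n_sites).  Lower bound: this package's own
    advisory estimate sqrt(n_sites)/0.5, treating site charge fluctuations
    as independent.  Advisory only — never used as a default.
    """
    return math.sqrt(n_sites) / BUFFER_MAX_CHARGE, 2.0 * n_sites


def place_particles(
    s: Structure,
    plan: NeutralizePlan,
    solvent_names: frozenset[str] = DEFAULT_SOLVENT_NAMES,
) -> Structure:
    """Replace randomly chosen solvent molecules by ions/buffer particles.

    Eligible waters have their oxygen at least ``plan.rmin`` from every
    non-solvent atom.  Selection is uniform without replacement with a
    seeded RNG; each placed particle immediately counts as non-solvent, so
    later picks keep ``rmin`` from it as well.  Placement order: NA, CL,
    BUF; each replacement removes one 3-site water and adds one particle at
    the former oxygen position.
    """
    residues = s.residues()
    water_res = [r for r in residues if r.name in solvent_names]
    coords = s.coords()
    non_solvent = [
        i for r in residues if r.name not in solvent_names for i in r.atom_indices
    ]

    oxygens = np.array(
        [coords[_oxygen(s, r)] for r in water_res]
    ) if water_res else np.zeros((0, 3))
    if non_solvent:
        tree = cKDTree(coords[non_solvent])
        dmin, _ = tree.query(oxygens) if len(oxygens) else (np.array([]), None)
        eligible = {i for i, d in enumerate(dmin) if d >= plan.rmin}
    else:
        eligible = set(range(len(water_res)))

    if len(eligible) < plan.total:
        raise StructureError(
            f"only {len(eligible)} waters are at least {plan.rmin} nm from "
            f"non-solvent atoms but {plan.total} particles are required; "
            "enlarge the box or reduce rmin"
        )

    rng = np.random.default_rng(plan.seed)
    species = ["NA"] * plan.n_positive + ["CL"] * plan.n_negative + ["BUF"] * plan.n_buffers
    chosen: list[tuple[int, str]] = []
    pool = sorted(eligible)
    for name in species:
        if not pool:
            raise StructureError(
                "ran out of eligible waters during placement; "
                "enlarge the box or reduce rmin"
            )
        pick = pool[rng.integers(len(pool))]
        chosen.append((pick, name))
        pos = oxygens[pick]
        pool = [
            i for i in pool
            if i != pick and np.linalg.norm(oxygens[i] - pos) >= plan.rmin
        ]

    replaced = {water_res[i].key: name for i, name in chosen}
    out_atoms: list[Atom] = []
    max_seq = max((a.residue_seq for a in s.atoms), default=0)
    particles: list[Atom] = []
    for res in residues:
        if res.key in replaced:
            name = replaced[res.key]
            o = coords[_oxygen(s, res)]
            max_seq += 1
            particles.append(
                Atom(
                    serial=0, name=name, residue_name=name,
                    residue_seq=max_seq, chain=s.atoms[res.atom_indices[0]].chain,
                    position=o.copy(),
                )
            )
        else:
            out_atoms.extend(s.atoms[i].copy() for i in res.atom_indices)
    out_atoms.extend(particles)
    result = Structure(
        title=s.title, atoms=out_atoms,
        box=None if s.box is None else s.box.copy(),
    )
    result.renumber()
    return result


def _oxygen(s: Structure, res) -> int:
    for i in res.atom_indices:
        if s.atoms[i].element == "O" or s.atoms[i].name.startswith("O"):
            return i
    return res.atom_indices[0]
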