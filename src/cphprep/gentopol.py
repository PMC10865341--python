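"""Make residues titratable: detection, renaming, hydrogen completion and
initial protonation-coordinate assignment.

The protonation degree of each titratable site is a continuous coordinate
lambda in [0, 1] (lambda-dynamics); lambda = 0 is the reference/protonated
end state and lambda = 1 the deprotonated physical state.  Initial values
are chosen from the simulation pH via Henderson-Hasselbalch and snapped to
the nearer end state, because the wells of the lambda potential sit at the
end states and a fractional start would sit on the barrier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np

from .grouptypes import GroupTypeDefinition, GroupTypeRegistry
from .structure import Atom, Residue, Structure, StructureError

logger = logging.getLogger(__name__)

__all__ = [
    "TitratableSite",
    "detect_titratable",
    "assign_initial_lambda",
    "multisite_initial_lambdas",
    "initialize_lambdas",
    "apply_titratable_forms",
    "write_charge_table_itp",
]

#: bond length used when a missing titratable hydrogen must be placed, nm
HYDROGEN_BOND_LENGTH = 0.10


@dataclass
class TitratableSite:
    """One concrete titratable residue in a structure.

    ``atom_indices`` aligns with the group type's atom-name list; an entry is
    ``None`` while the corresponding (hydrogen) atom is still missing from
    the structure.  ``lambda_coords`` holds (state_index, initial_lambda)
    pairs — one pair for a single-site type, one per physical state for a
    multisite type.
    """

    chain: str
    residue_seq: int
    residue_name: str
    group_type: str
    atom_indices: list[int | None] = field(default_factory=list)
    lambda_coords: list[tuple[int, float]] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain, self.residue_seq)

    def mapped_indices(self) -> list[int]:
        missing = [i for i in self.atom_indices if i is None]
        if missing:
            raise StructureError(
                f"site {self.group_type} {self.chain}:{self.residue_seq} has "
                f"{len(missing)} unmapped atoms"
            )
        return [i for i in self.atom_indices if i is not None]


def detect_titratable(
    s: Structure,
    registry: GroupTypeRegistry,
    selection: Callable[[Residue], bool] | None = None,
) -> list[TitratableSite]:
    """Find residues whose name matches a group-type alias.

    Residues missing a required heavy atom are skipped with a warning
    (missing titratable hydrogens are fine — they are added later by
    :func:`apply_titratable_forms`).
    """
    sites: list[TitratableSite] = []
    for res in s.residues():
        definition = registry.lookup(res.name)
        if definition is None:
            continue
        if definition.name == "BUF":
            continue  # buffer particles are placed, never detected
        if selection is not None and not selection(res):
            continue
        by_name = {s.atoms[i].name: i for i in res.atom_indices}
        missing_heavy = [n for n in definition.heavy_atoms if n not in by_name]
        if missing_heavy:
            logger.warning(
                "skipping %s %s:%d: missing heavy atoms %s",
                res.name, res.chain, res.seq, ",".join(missing_heavy),
            )
            continue
        sites.append(
            TitratableSite(
                chain=res.chain,
                residue_seq=res.seq,
                residue_name=res.name,
                group_type=definition.name,
                atom_indices=[by_name.get(n) for n in definition.atom_names],
            )
        )
    return sites


def assign_initial_lambda(pH: float, pKa: float) -> float:
    """Initial lambda for a single-site group at the given pH.

    The equilibrium deprotonated fraction is f = 1/(1 + 10^(pKa - pH));
    the start value snaps to the nearer end state, with the tie at f = 0.5
    going to the deprotonated state (lambda = 1).
    """
    f = 1.0 / (1.0 + 10.0 ** (pKa - pH))
    return 1.0 if f >= 0.5 else 0.0


def multisite_initial_lambdas(definition: GroupTypeDefinition, pH: float) -> list[float]:
    """Initial lambdas for a multisite group: 1 for the dominant physical
    state, 0 for the rest.

    The first listed physical state is taken as the protonated parent
    (weight 1; its pKa entry in the file is a dummy) and each later state i
    as a single deprotonation of it with microscopic pKa_i, so its relative
    population is 10^(pH - pKa_i).  Ties go to the earlier state in file
    order.
    """
    if not definition.multisite:
        raise ValueError(
            f"[{definition.name}] is single-site; use assign_initial_lambda"
        )
    weights = [1.0] + [
        10.0 ** (pH - st.pKa) for st in definition.states[1:]
    ]
    winner = int(np.argmax(weights))  # argmax takes the first maximum: tie rule
    return [1.0 if i == winner else 0.0 for i in range(len(weights))]


def initialize_lambdas(
    sites: Iterable[TitratableSite],
    registry: GroupTypeRegistry,
    pH: float,
) -> None:
    """Fill ``lambda_coords`` of each site from the simulation pH."""
    for site in sites:
        definition = registry.definitions[site.group_type]
        if definition.multisite:
            lams = multisite_initial_lambdas(definition, pH)
            site.lambda_coords = list(enumerate(lams))
        else:
            lam = assign_initial_lambda(pH, definition.states[0].pKa)
            site.lambda_coords = [(0, lam)]


def _bonded_heavy_atom(
    hydrogen: str, present: dict[str, int], residue_label: str
) -> int:
    """Heavy atom a titratable hydrogen bonds to, found by name suffix
    (HD2 -> OD2/ND2/CD2, HE1 -> CE1/NE1/OE1, ...)."""
    suffix = hydrogen[1:]
    candidates = [
        idx for name, idx in present.items()
        if not name.startswith("H") and name[1:] == suffix
    ]
    if len(candidates) != 1:
        state = "ambiguous" if len(candidates) > 1 else "missing"
        raise StructureError(
            f"{residue_label}: bonded heavy atom for hydrogen '{hydrogen}' "
            f"is {state}"
        )
    return candidates[0]


def apply_titratable_forms(
    s: Structure, sites: list[TitratableSite], registry: GroupTypeRegistry
) -> Structure:
    """Rename detected residues to their titratable form and complete
    missing titratable hydrogens.

    A missing hydrogen is placed 0.10 nm from its bonded heavy atom,
    pointing away from the residue centroid (any placement is relaxed by
    the mandatory energy minimization that precedes production).  Within
    each modified residue the mapped atoms are re-ordered to the group
    type's atom list, after the unmapped (backbone) atoms.
    """
    out = s.copy()
    site_by_key = {site.key: site for site in sites}
    new_atoms: list[Atom] = []
    for res in out.residues():
        site = site_by_key.get((res.chain, res.seq))
        if site is None or registry.lookup(res.name) is None:
            new_atoms.extend(out.atoms[i] for i in res.atom_indices)
            continue
        definition = registry.definitions[site.group_type]
        label = f"{res.name} {res.chain}:{res.seq}"
        res_atoms = [out.atoms[i] for i in res.atom_indices]
        by_name = {a.name: a for a in res_atoms}
        present_idx = {a.name: j for j, a in enumerate(res_atoms)}

        centroid = np.mean(
            [a.position for a in res_atoms if not a.name.startswith("H")], axis=0
        )
        for hname in definition.titratable_hydrogens:
            if hname in by_name:
                continue
            heavy = res_atoms[_bonded_heavy_atom(hname, present_idx, label)]
            direction = heavy.position - centroid
            norm = np.linalg.norm(direction)
            if norm < 1e-9:  # heavy atom at the centroid: pick a fixed axis
                direction, norm = np.array([0.0, 0.0, 1.0]), 1.0
            pos = heavy.position + HYDROGEN_BOND_LENGTH * direction / norm
            by_name[hname] = Atom(
                serial=0, name=hname, residue_name=res.name,
                residue_seq=res.seq, chain=res.chain, position=pos,
            )

        mapped = set(definition.atom_names)
        reordered = [a for a in res_atoms if a.name not in mapped]
        reordered += [by_name[n] for n in definition.atom_names if n in by_name]
        for a in reordered:
            a.residue_name = definition.name
        new_atoms.extend(reordered)

    result = Structure(title=out.title, atoms=new_atoms, box=out.box)
    result.renumber()
    return result


def write_charge_table_itp(
    sites: list[TitratableSite],
    registry: GroupTypeRegistry,
    path,
) -> None:
    """Write a per-site end-state charge table as a GROMACS .itp fragment.

    This records the lambda = 0 and lambda = 1 charge sets per mapped atom;
    full bonded-topology generation is delegated to an external builder.
    """
    from pathlib import Path

    lines = ["; per-site titratable charge table (lambda end states)", ""]
    for site in sites:
        definition = registry.definitions[site.group_type]
        lines.append(f"[ {site.group_type}_{site.chain}_{site.residue_seq} ]")
        lines.append("; atom     q(lambda=0)   q(lambda=1)")
        for atom_name, qA, qB in zip(
            definition.atom_names,
            definition.common_charges,
            definition.states[0].charges,
        ):
            lines.append(f"  {atom_name:<6s} {qA:>12.4f}  {qB:>12.4f}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
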