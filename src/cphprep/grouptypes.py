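"""Titratable group-type definitions (the ``lambdagrouptypes.dat`` dialect).

The file consists of an INI-like preamble of global settings (force-field
name, water model, engine path, ...) followed by ``[ NAME ]`` blocks, each
describing one titratable group type:

    [ ASPT ]
    incl  = ASP ASP1 ASPH ASPP ASH
    atoms = CB CG OD1 OD2 HD2
    qqA   = -0.21 0.75 -0.55 -0.61 0.44
    pKa_1 = 3.65
    qqB_1 = -0.28 0.62 -0.76 -0.76 0.00
    dvdl_1 = -54.078 -144.280 278.550 -146.030 -554.270 44.621

``qqA`` holds the charges of the common (reference) state, ``qqB_i`` the
charges of physical state *i*, ``pKa_i`` its reference pKa, and ``dvdl_i``
the polynomial coefficients of the fitted mean force dV/dlambda along the
protonation coordinate, **highest power first** (6 coefficients = degree-5
polynomial).  A type with more than one physical state uses the multisite
representation (one artificial common state plus N physical states).
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GroupTypeError",
    "PhysicalState",
    "GroupTypeDefinition",
    "GroupTypeRegistry",
    "parse_grouptypes",
    "parse_grouptypes_text",
    "write_grouptypes",
    "format_grouptypes",
    "interpolate_charges",
    "state_charge_shift",
    "default_registry",
]


class GroupTypeError(Exception):
    """Validation or parse failure in a group-type definition file."""


@dataclass
class PhysicalState:
    """One physical protonation state of a group type."""

    pKa: float
    charges: list[float]
    dvdl_coeffs: list[float] = field(default_factory=list)


@dataclass
class GroupTypeDefinition:
    name: str
    aliases: list[str]
    atom_names: list[str]
    common_charges: list[float]
    states: list[PhysicalState]

    @property
    def multisite(self) -> bool:
        return len(self.states) > 1

    @property
    def titratable_hydrogens(self) -> list[str]:
        """Atom names in the type list that are hydrogens (may be absent in
        an input structure and added during topology generation)."""
        return [n for n in self.atom_names if n.startswith("H")]

    @property
    def heavy_atoms(self) -> list[str]:
        return [n for n in self.atom_names if not n.startswith("H")]

    def validate(self) -> None:
        n = len(self.atom_names)
        if len(self.common_charges) != n:
            raise GroupTypeError(
                f"[{self.name}] qqA has {len(self.common_charges)} values "
                f"for {n} atoms"
            )
        if not self.states:
            raise GroupTypeError(f"[{self.name}] defines no physical state")
        for i, st in enumerate(self.states, start=1):
            if len(st.charges) != n:
                raise GroupTypeError(
                    f"[{self.name}] qqB_{i} has {len(st.charges)} values for {n} atoms"
                )


@dataclass
class GroupTypeRegistry:
    """All known group types plus the global settings from the same file."""

    definitions: dict[str, GroupTypeDefinition] = field(default_factory=dict)
    settings: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._alias_map: dict[str, str] = {}
        for d in self.definitions.values():
            self._register_aliases(d)

    def _register_aliases(self, d: GroupTypeDefinition) -> None:
        for alias in [d.name, *d.aliases]:
            owner = self._alias_map.get(alias)
            if owner is not None and owner != d.name:
                raise GroupTypeError(
                    f"alias '{alias}' claimed by both [{owner}] and [{d.name}]"
                )
            self._alias_map[alias] = d.name

    def add(self, d: GroupTypeDefinition) -> None:
        d.validate()
        self._register_aliases(d)
        self.definitions[d.name] = d

    def lookup(self, residue_name: str) -> GroupTypeDefinition | None:
        """Resolve a residue name through the alias table."""
        name = self._alias_map.get(residue_name)
        return self.definitions.get(name) if name else None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GroupTypeRegistry):
            return NotImplemented
        return self.settings == other.settings and _defs_equal(
            self.definitions, other.definitions
        )


def _defs_equal(a: dict, b: dict, tol: float = 1e-6) -> bool:
    if a.keys() != b.keys():
        return False
    for k in a:
        da, db = a[k], b[k]
        if (da.aliases, da.atom_names) != (db.aliases, db.atom_names):
            return False
        if not np.allclose(da.common_charges, db.common_charges, atol=tol):
            return False
        if len(da.states) != len(db.states):
            return False
        for sa, sb in zip(da.states, db.states):
            if abs(sa.pKa - sb.pKa) > tol:
                return False
            if not np.allclose(sa.charges, sb.charges, atol=tol):
                return False
            if len(sa.dvdl_coeffs) != len(sb.dvdl_coeffs):
                return False
            if sa.dvdl_coeffs and not np.allclose(
                sa.dvdl_coeffs, sb.dvdl_coeffs, rtol=1e-9, atol=1e-9
            ):
                return False
    return True


# ---------------------------------------------------------------------------
# Parsing / writing
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(r"^\[\s*(\S+)\s*\]$")
# Unicode minus signs occur in copy-pasted literature blocks
_MINUS = str.maketrans({"−": "-", "–": "-"})


def _floats(value: str, context: str) -> list[float]:
    try:
        return [float(tok) for tok in value.split()]
    except ValueError as exc:
        raise GroupTypeError(f"{context}: cannot parse numeric list '{value}'") from exc


def parse_grouptypes_text(text: str, source: str = "<string>") -> GroupTypeRegistry:
    """Parse group-type definitions from a string (see module docstring)."""
    registry = GroupTypeRegistry()
    block_name: str | None = None
    block: dict[str, str] = {}

    def flush() -> None:
        nonlocal block_name, block
        if block_name is None:
            return
        registry.add(_build_definition(block_name, block))
        block_name, block = None, {}

    for raw in text.translate(_MINUS).splitlines():
        line = raw.split(";")[0].split("#")[0].strip()
        if not line:
            continue
        m = _HEADER_RE.match(line)
        if m:
            flush()
            block_name = m.group(1)
            continue
        if "=" not in line:
            raise GroupTypeError(f"{source}: expected 'key = value', got '{line}'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if block_name is None:
            registry.settings[key] = value
        else:
            if key in block:
                raise GroupTypeError(f"{source} [{block_name}]: duplicate key '{key}'")
            block[key] = value
    flush()
    return registry


def _build_definition(name: str, block: dict[str, str]) -> GroupTypeDefinition:
    ctx = f"[{name}]"
    for required in ("incl", "atoms", "qqA"):
        if required not in block:
            raise GroupTypeError(f"{ctx}: missing required key '{required}'")
    aliases = block["incl"].split()
    atoms = block["atoms"].split()
    qqA = _floats(block["qqA"], ctx + " qqA")

    states: list[PhysicalState] = []
    i = 1
    while f"pKa_{i}" in block or f"qqB_{i}" in block:
        if f"pKa_{i}" not in block or f"qqB_{i}" not in block:
            raise GroupTypeError(f"{ctx}: state {i} needs both pKa_{i} and qqB_{i}")
        states.append(
            PhysicalState(
                pKa=float(block[f"pKa_{i}"].split()[0]),
                charges=_floats(block[f"qqB_{i}"], f"{ctx} qqB_{i}"),
                dvdl_coeffs=_floats(block.get(f"dvdl_{i}", ""), f"{ctx} dvdl_{i}"),
            )
        )
        i += 1

    d = GroupTypeDefinition(
        name=name, aliases=aliases, atom_names=atoms,
        common_charges=qqA, states=states,
    )
    d.validate()
    return d


def parse_grouptypes(path: str | Path) -> GroupTypeRegistry:
    """Parse a group-type definition file."""
    path = Path(path)
    if not path.exists():
        raise GroupTypeError(f"group-type file not found: {path}")
    return parse_grouptypes_text(path.read_text(), source=str(path))


def _fmt_floats(values: list[float]) -> str:
    # %.10g keeps short decimals (printed precision) verbatim and preserves
    # fitted coefficients well beyond the comparison tolerance
    return " ".join(f"{v:.10g}" for v in values)


def format_grouptypes(registry: GroupTypeRegistry) -> str:
    """Serialize a registry back to the definition-file dialect."""
    lines: list[str] = []
    for key, value in registry.settings.items():
        lines.append(f"{key} = {value}")
    if registry.settings:
        lines.append("")
    for d in registry.definitions.values():
        lines.append(f"[ {d.name} ]")
        lines.append(f"incl = {' '.join(d.aliases)}")
        lines.append(f"atoms = {' '.join(d.atom_names)}")
        lines.append(f"qqA = {_fmt_floats(d.common_charges)}")
        for i, st in enumerate(d.states, start=1):
            lines.append(f"pKa_{i} = {st.pKa:.10g}")
            lines.append(f"qqB_{i} = {_fmt_floats(st.charges)}")
            if st.dvdl_coeffs:
                lines.append(f"dvdl_{i} = {_fmt_floats(st.dvdl_coeffs)}")
        lines.append("")
    return "\n".join(lines).rstrip() + "\n"


def write_grouptypes(registry: GroupTypeRegistry, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(format_grouptypes(registry))
    return path


# ---------------------------------------------------------------------------
# Charge arithmetic
# ---------------------------------------------------------------------------

def interpolate_charges(
    definition: GroupTypeDefinition, state_index: int, lam: float
) -> list[float]:
    """Per-atom charges at protonation coordinate ``lam`` for one state.

    q_i(lambda) = (1 - lambda) * qqA_i + lambda * qqB_i.  Values of lambda
    outside [0, 1] extrapolate linearly (used at the ends of the TI grid).
    """
    if not 0 <= state_index < len(definition.states):
        raise GroupTypeError(
            f"[{definition.name}] has no state index {state_index}"
        )
    qqA = np.asarray(definition.common_charges)
    qqB = np.asarray(definition.states[state_index].charges)
    return list((1.0 - lam) * qqA + lam * qqB)


def state_charge_shift(definition: GroupTypeDefinition, state_index: int) -> float:
    """Net charge change from the common state to physical state
    ``state_index`` (sum qqB - sum qqA); -1 for an acid deprotonation."""
    if not 0 <= state_index < len(definition.states):
        raise GroupTypeError(
            f"[{definition.name}] has no state index {state_index}"
        )
    return float(
        np.sum(definition.states[state_index].charges)
        - np.sum(definition.common_charges)
    )


def default_registry() -> GroupTypeRegistry:
    """The group types shipped with the package (Asp, Glu, His, buffer)."""
    ref = importlib.resources.files("cphprep.data").joinpath("lambdagrouptypes.dat")
    return parse_grouptypes_text(ref.read_text(), source="cphprep/data/lambdagrouptypes.dat")
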