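"""Run-parameter (.mdp) and index (.ndx) file generation.

Four simulation phases are emitted: energy minimization (EM), NVT and NPT
equilibration, and constant-pH production (CPHMD).  The constant-pH section
carries the simulation pH, the lambda-particle mass (5 amu) and thermostat
time constant (2.0 ps), the per-group-type reference pKa / charge / dV/dl
data copied verbatim from the group-type registry, per-site initial lambda
values and biasing-barrier height (default 7.5 kJ/mol), and one buffer
block.  During EM/NVT/NPT (and in calibration mode, used for the fixed-
lambda TI runs) the lambda coordinates are held constant.

The actual mdp key spellings of the constant-pH engine may drift between
engine versions, so the logical-name -> mdp-key mapping lives in a JSON
template (``data/mdp_keys.json``) and can be overridden by the caller.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

from .gentopol import TitratableSite
from .grouptypes import GroupTypeRegistry
from .structure import Structure

__all__ = [
    "MDPDocument",
    "IndexDocument",
    "load_key_template",
    "generate_mdp",
    "generate_index",
]

#: lambda-particle mass, atomic units
LAMBDA_MASS = 5.0
#: lambda thermostat time constant, ps
LAMBDA_TAU = 2.0
#: default biasing-potential barrier height, kJ/mol
DEFAULT_BARRIER = 7.5

PHASES = ("EM", "NVT", "NPT", "CPHMD")


@dataclass
class MDPDocument:
    """Ordered ``key = value`` run-parameter document with comments.

    Entries are (key, value) pairs; comment/blank lines are interleaved as
    (None, text).  Keys are unique; serialization round-trips byte-for-byte.
    """

    entries: list[tuple[str | None, str]] = field(default_factory=list)

    def set(self, key: str, value) -> None:
        if key is None:
            raise ValueError("use comment() for comment lines")
        if any(k == key for k, _ in self.entries):
            raise ValueError(f"duplicate mdp key '{key}'")
        self.entries.append((key, str(value)))

    def comment(self, text: str = "") -> None:
        self.entries.append((None, text))

    def get(self, key: str) -> str | None:
        for k, v in self.entries:
            if k == key:
                return v
        return None

    def keys(self) -> list[str]:
        return [k for k, _ in self.entries if k is not None]

    def serialize(self) -> str:
        lines = []
        for k, v in self.entries:
            if k is None:
                lines.append(f"; {v}" if v else "")
            else:
                lines.append(f"{k:<40s} = {v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def parse(cls, text: str) -> "MDPDocument":
        doc = cls()
        for raw in text.splitlines():
            line = raw.rstrip("\n")
            if not line.strip():
                doc.comment("")
            elif line.lstrip().startswith(";"):
                doc.comment(line.lstrip()[1:].strip())
            else:
                key, _, value = line.partition("=")
                doc.set(key.strip(), value.strip())
        return doc

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.serialize())
        return path

    @classmethod
    def read(cls, path: str | Path) -> "MDPDocument":
        return cls.parse(Path(path).read_text())


@dataclass
class IndexDocument:
    """Named groups of 1-based atom indices (GROMACS .ndx)."""

    groups: dict[str, list[int]] = field(default_factory=dict)

    def add(self, name: str, indices: list[int]) -> None:
        if name in self.groups:
            raise ValueError(f"duplicate index group '{name}'")
        self.groups[name] = list(indices)

    def serialize(self) -> str:
        blocks = []
        for name, idx in self.groups.items():
            lines = [f"[ {name} ]"]
            for start in range(0, len(idx), 15):
                lines.append(" ".join(str(i) for i in idx[start:start + 15]))
            blocks.append("\n".join(lines))
        return "\n".join(blocks) + "\n"

    @classmethod
    def parse(cls, text: str) -> "IndexDocument":
        doc = cls()
        name = None
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                name = line[1:-1].strip()
                doc.add(name, [])
            elif name is not None:
                doc.groups[name].extend(int(tok) for tok in line.split())
        return doc

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.serialize())
        return path

    @classmethod
    def read(cls, path: str | Path) -> "IndexDocument":
        return cls.parse(Path(path).read_text())


def load_key_template(path: str | Path | None = None) -> dict[str, str]:
    """Load the logical-name -> mdp-key mapping (shipped default or user file)."""
    if path is None:
        ref = importlib.resources.files("cphprep.data").joinpath("mdp_keys.json")
        return json.loads(ref.read_text())
    return json.loads(Path(path).read_text())


def _thermodynamic_section(doc: MDPDocument, phase: str) -> None:
    """Literal engine settings per phase (never simulated by this package)."""
    doc.comment(f"{phase} phase")
    if phase == "EM":
        doc.set("integrator", "steep")
        doc.set("emtol", "1000")
        doc.set("nsteps", "5000")
    else:
        doc.set("integrator", "md")
        doc.set("dt", "0.002")
        doc.set("nsteps", "5000" if phase in ("NVT", "NPT") else "5000000")
    doc.set("cutoff-scheme", "Verlet")
    doc.set("coulombtype", "PME")
    doc.set("rcoulomb", "1.2")
    doc.set("fourierspacing", "0.14")
    doc.set("vdwtype", "Cut-off")
    doc.set("vdw-modifier", "Force-switch")
    doc.set("rvdw-switch", "1.0")
    doc.set("rvdw", "1.2")
    if phase != "EM":
        doc.set("tcoupl", "v-rescale")
        doc.set("tc-grps", "System")
        doc.set("tau-t", "0.5")
        doc.set("ref-t", "300")
        doc.set("constraints", "h-bonds")
        doc.set("constraint-algorithm", "lincs")
    if phase in ("NPT", "CPHMD"):
        doc.set("pcoupl", "c-rescale")
        doc.set("tau-p", "5.0")
        doc.set("ref-p", "1.0")
        doc.set("compressibility", "4.5e-5")


def generate_mdp(
    phase: str,
    sites: list[TitratableSite],
    registry: GroupTypeRegistry,
    pH: float,
    barrier: float = DEFAULT_BARRIER,
    calibration: bool = False,
    key_template: dict[str, str] | None = None,
) -> MDPDocument:
    """Build the run-parameter document for one phase.

    With no titratable sites the constant-pH master switch is omitted
    entirely.  ``calibration=True`` (or a non-production phase) holds the
    lambda coordinates fixed, as used for minimization/equilibration and
    for the fixed-lambda TI runs of the parametrization grid.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase '{phase}'; expected one of {PHASES}")
    keys = key_template or load_key_template()
    doc = MDPDocument()
    _thermodynamic_section(doc, phase)

    if not sites:
        return doc

    for site in sites:
        if site.group_type not in registry.definitions:
            raise KeyError(f"site references unknown group type '{site.group_type}'")

    type_names = sorted({site.group_type for site in sites})
    hold_constant = calibration or phase != "CPHMD"

    doc.comment()
    doc.comment("constant-pH (lambda-dynamics) section")
    doc.set(keys["master_switch"], "yes")
    doc.set(keys["simulation_ph"], f"{pH:g}")
    doc.set(keys["lambda_mass"], f"{LAMBDA_MASS:g}")
    doc.set(keys["lambda_tau"], f"{LAMBDA_TAU:g}")
    doc.set(keys["charge_constraints"], "yes")
    doc.set(keys["calibration"], "yes" if hold_constant else "no")
    doc.set(keys["n_group_types"], len(type_names) + 1)  # +1 for BUF

    for i, tname in enumerate([*type_names, "BUF"], start=1):
        definition = registry.definitions[tname]
        doc.comment()
        doc.set(keys["type_name"].format(i=i), tname)
        doc.set(keys["type_n_states"].format(i=i), len(definition.states))
        doc.set(
            keys["type_common_charges"].format(i=i),
            " ".join(f"{q:.10g}" for q in definition.common_charges),
        )
        for j, st in enumerate(definition.states, start=1):
            doc.set(keys["type_state_pka"].format(i=i, j=j), f"{st.pKa:.10g}")
            doc.set(
                keys["type_state_charges"].format(i=i, j=j),
                " ".join(f"{q:.10g}" for q in st.charges),
            )
            doc.set(
                keys["type_state_dvdl"].format(i=i, j=j),
                " ".join(f"{c:.10g}" for c in st.dvdl_coeffs),
            )

    doc.comment()
    doc.set(keys["n_atom_sets"], len(sites) + 1)  # +1 for the buffer set
    for k, site in enumerate(sites, start=1):
        if not site.lambda_coords:
            raise ValueError(
                f"site {site.group_type} {site.chain}:{site.residue_seq} has no "
                "initial lambda; run initialize_lambdas first"
            )
        doc.set(keys["set_name"].format(k=k), site.group_type)
        doc.set(
            keys["set_index_group"].format(k=k),
            f"{site.group_type}_{site.chain}_{site.residue_seq}",
        )
        doc.set(
            keys["set_initial_lambda"].format(k=k),
            " ".join(f"{lam:g}" for _, lam in site.lambda_coords),
        )
        doc.set(keys["set_barrier"].format(k=k), f"{barrier:g}")
        doc.set(keys["set_charge_restraint_group"].format(k=k), 1)
    k = len(sites) + 1
    doc.set(keys["set_name"].format(k=k), "BUF")
    doc.set(keys["set_index_group"].format(k=k), "BUFFER")
    doc.set(keys["set_initial_lambda"].format(k=k), "0.5")
    doc.set(keys["set_barrier"].format(k=k), "0")
    doc.set(keys["set_buffer_residue"].format(k=k), "yes")
    doc.set(keys["set_buffer_multiplier"].format(k=k), 1)
    return doc


def generate_index(s: Structure, sites: list[TitratableSite]) -> IndexDocument:
    """Index groups (1-based): System, one group per titratable site, the
    combined titratable group, and the buffer group."""
    doc = IndexDocument()
    doc.add("System", list(range(1, s.n_atoms + 1)))
    combined: list[int] = []
    for site in sites:
        indices = [i + 1 for i in site.mapped_indices()]
        doc.add(f"{site.group_type}_{site.chain}_{site.residue_seq}", indices)
        combined.extend(indices)
    if sites:
        doc.add("TITRATABLE", combined)
    buffer_idx = [
        i + 1 for i, a in enumerate(s.atoms) if a.residue_name == "BUF"
    ]
    if buffer_idx:
        doc.add("BUFFER", buffer_idx)
    for name, idx in doc.groups.items():
        bad = [i for i in idx if not 1 <= i <= s.n_atoms]
        if bad:
            raise ValueError(f"group '{name}' has out-of-range indices {bad[:3]}")
    return doc
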