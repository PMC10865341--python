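"""Synthetic test systems: water boxes, cavity systems, toy proteins, and
exact samplers for lambda trajectories and TI data.

Everything here is generated, deterministic under a fixed seed, and needs
no MD engine or network access.  The lambda sampler draws i.i.d. samples
by inverse-CDF from the Boltzmann distribution of a given energy function:
the distributional claims being tested (histogram flatness, Boltzmann
inversion) do not depend on kinetics, and exact sampling removes
autocorrelation as a confounder.
"""

from __future__ import annotations

import numpy as np

from .parameterize import (
    KB_KJ_PER_MOL_K,
    LAMBDA_DOMAIN,
    CorrectionPotential,
    LambdaTrajectory,
    TISample,
)
from .structure import Atom, Structure

__all__ = [
    "make_water_box",
    "make_cavity_system",
    "make_peptide",
    "synthetic_cardiotoxin",
    "synthetic_barnase_barstar",
    "sample_lambda",
    "sample_dvdl",
]

# rigid 3-site water geometry, nm
_WATER_OH = 0.09572
_WATER_HOH_DEG = 104.52


def _water_atoms(origin: np.ndarray, rotation: np.ndarray) -> list[np.ndarray]:
    half = np.deg2rad(_WATER_HOH_DEG / 2)
    local = np.array(
        [
            [0.0, 0.0, 0.0],
            [_WATER_OH * np.sin(half), _WATER_OH * np.cos(half), 0.0],
            [-_WATER_OH * np.sin(half), _WATER_OH * np.cos(half), 0.0],
        ]
    )
    return [origin + rotation @ p for p in local]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # QR of a Gaussian matrix gives a uniform random orthogonal matrix
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))


def make_water_box(
    n_per_side: int, spacing: float = 0.31, seed: int = 1, jitter: float = 0.01
) -> Structure:
    """Cubic lattice of 3-site waters with seeded positional jitter.

    At the default 0.31 nm spacing the number density is 1/0.31^3 ~ 33.6
    waters/nm^3, matching liquid water closely enough that a 1 nm probe
    sphere in the bulk contains on the order of 400 water atoms.
    """
    if n_per_side < 2:
        raise ValueError("n_per_side must be at least 2")
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    seq = 0
    serial = 0
    for ix in range(n_per_side):
        for iy in range(n_per_side):
            for iz in range(n_per_side):
                seq += 1
                origin = (np.array([ix, iy, iz]) + 0.5) * spacing
                origin = origin + rng.normal(scale=jitter, size=3)
                rot = _random_rotation(rng)
                for name, pos in zip(("OW", "HW1", "HW2"), _water_atoms(origin, rot)):
                    serial += 1
                    atoms.append(
                        Atom(
                            serial=serial, name=name, residue_name="SOL",
                            residue_seq=seq, chain="A", position=pos,
                        )
                    )
    box = np.full(3, n_per_side * spacing)
    return Structure(title=f"water box {n_per_side}^3", atoms=atoms, box=box)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_cavity_system(
    n_per_side: int = 12,
    spacing: float = 0.31,
    shell_radius: float = 1.2,
    n_trapped: int = 2,
    seed: int = 1,
) -> tuple[Structure, list[tuple[str, int, str]]]:
    """Water box with a hollow spherical 'protein' shell and a known number
    of waters deliberately trapped inside it.

    Trapped waters sit 0.30-0.45 nm inside the wall, so they fall inside
    the default candidate cutoff (0.5 nm from non-solvent) while remaining
    isolated from the bulk.  Returns the structure and the residue keys of
    the trapped waters — the ground-truth removal set for the cleanup
    algorithms.  Construction asserts by brute force that each trapped
    water has fewer than 120 water atoms within 1 nm, so the ground truth
    is valid for the density criterion by construction.
    """
    box_len = n_per_side * spacing
    if shell_radius + 0.25 >= box_len / 2:
        raise ValueError("shell radius must be smaller than half the box")
    base = make_water_box(n_per_side, spacing, seed)
    center = np.full(3, box_len / 2)

    residues = base.residues()
    coords = base.coords()
    outside_atoms: list[Atom] = []
    inner: list[tuple[float, object]] = []
    for res in residues:
        o = coords[res.atom_indices[0]]
        d = np.linalg.norm(o - center)
        if d < shell_radius + 0.25:
            # waters inside or clashing with the shell wall
            inner.append((d, res))
        else:
            outside_atoms.extend(base.atoms[i] for i in res.atom_indices)

    # keep trapped waters near (but not clashing with) the wall so they are
    # candidates under the default Rc
    eligible = [res for d, res in inner
                if shell_radius - 0.45 < d < shell_radius - 0.30]
    trapped_res = eligible[:n_trapped]
    if len(trapped_res) < n_trapped:
        raise ValueError(
            f"cavity too small: only {len(trapped_res)} waters fit inside"
        )
    trapped_keys = [r.key for r in trapped_res]

    atoms: list[Atom] = []
    for res in trapped_res:
        atoms.extend(base.atoms[i] for i in res.atom_indices)
    atoms.extend(outside_atoms)

    # dummy protein shell: carbon atoms on a Fibonacci sphere, ~0.2 nm
    # apart; dense enough that a trapped water's nearest residues are
    # dominated by shell atoms, sparse enough that bulk waters just outside
    # still see >= 3 waters among their 20 nearest residues
    n_shell = max(50, int(4 * np.pi * shell_radius**2 / 0.04))
    seq = max(a.residue_seq for a in atoms)
    for k, unit in enumerate(_fibonacci_sphere(n_shell), start=1):
        atoms.append(
            Atom(
                serial=0, name="C", residue_name="SHL",
                residue_seq=seq + k, chain="P",
                position=center + shell_radius * unit,
            )
        )
    s = Structure(title="cavity system", atoms=atoms, box=base.box.copy())
    s.renumber()

    # validate the ground truth by brute force
    all_coords = s.coords()
    water_atoms = np.array(
        [i for r in s.residues() if r.name == "SOL" for i in r.atom_indices]
    )
    for res in s.residues():
        if res.key not in trapped_keys:
            continue
        o = all_coords[res.atom_indices[0]]
        d = np.linalg.norm(all_coords[water_atoms] - o, axis=1)
        count = int(np.count_nonzero(d <= 1.0)) - len(res.atom_indices)
        assert count < 120, "trapped water is not actually isolated"
    return s, trapped_keys


# ---------------------------------------------------------------------------
# Toy proteins
# ---------------------------------------------------------------------------

_SIDECHAINS: dict[str, list[str]] = {
    # heavy sidechain atoms needed for titratable-site detection
    "ASP": ["CB", "CG", "OD1", "OD2"],
    "GLU": ["CB", "CG", "CD", "OE1", "OE2"],
    "HIS": ["CB", "CD2", "CG", "NE2", "ND1", "CE1"],
    "ALA": ["CB"],
    "GLY": [],
    "SER": ["CB", "OG"],
}

_ONE_TO_THREE = {
    "A": "ALA", "G": "GLY", "S": "SER", "D": "ASP", "E": "GLU", "H": "HIS"
}


def make_peptide(sequence: str, chain: str = "A", start_seq: int = 1,
                 origin: np.ndarray | None = None) -> list[Atom]:
    """Build a toy peptide chain from a one-letter sequence.

    Residues are placed 0.38 nm apart along a gentle helix; each has the
    four backbone atoms plus the heavy sidechain atoms its type needs for
    titratable-site detection.  Only coordinates are synthetic — residue
    and atom naming follows PDB conventions.
    """
    atoms: list[Atom] = []
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    for i, letter in enumerate(sequence):
        resname = _ONE_TO_THREE.get(letter.upper())
        if resname is None:
            raise ValueError(f"unsupported residue letter '{letter}'")
        seq = start_seq + i
        t = i * 0.6
        ca = origin + np.array(
            [1.2 * np.cos(t), 1.2 * np.sin(t), 0.15 * i]
        )
        backbone = {
            "N": ca + [-0.12, 0.0, -0.05],
            "CA": ca,
            "C": ca + [0.12, 0.0, 0.05],
            "O": ca + [0.18, 0.1, 0.05],
        }
        for name, pos in backbone.items():
            atoms.append(Atom(0, name, resname, seq, chain, np.asarray(pos)))
        outward = np.array([np.cos(t), np.sin(t), 0.0])
        for j, name in enumerate(_SIDECHAINS[resname]):
            pos = ca + outward * (0.12 * (j + 1)) + np.array([0, 0, 0.03 * (j % 2)])
            atoms.append(Atom(0, name, resname, seq, chain, pos))
    return atoms


def synthetic_cardiotoxin() -> Structure:
    """SYNTHETIC stand-in for cardiotoxin V (62 residues, one chain).

    Coordinates and filler residues are artificial; the titratable content
    matches the real protein as documented: His-4, Glu-17, Asp-42 and
    Asp-59 (four titratable groups).
    """
    seq = list("A" * 62)
    seq[4 - 1] = "H"
    seq[17 - 1] = "E"
    seq[42 - 1] = "D"
    seq[59 - 1] = "D"
    atoms = make_peptide("".join(seq), chain="A")
    s = Structure(title="synthetic cardiotoxin V stand-in", atoms=atoms,
                  box=np.full(3, 8.0))
    s.renumber()
    return s


def synthetic_barnase_barstar() -> Structure:
    """SYNTHETIC stand-in for the two-chain barnase-barstar complex.

    Coordinates and filler residues are artificial; the complex carries 30
    Asp/Glu/His residues in total across the two chains, matching the
    documented titratable content (barnase-like chain A: 110 residues with
    9 Asp, 3 Glu, 2 His; barstar-like chain B: 89 residues with 7 Asp,
    7 Glu, 2 His).
    """
    def scatter(length: int, placements: dict[int, str]) -> str:
        seq = ["A"] * length
        for pos, letter in placements.items():
            seq[pos - 1] = letter
        return "".join(seq)

    chain_a = scatter(110, {
        8: "D", 12: "D", 22: "D", 44: "D", 54: "D", 75: "D", 86: "D",
        93: "D", 101: "D",
        29: "E", 60: "E", 73: "E",
        18: "H", 102: "H",
    })
    chain_b = scatter(89, {
        15: "D", 35: "D", 39: "D", 54: "D", 61: "D", 75: "D", 83: "D",
        23: "E", 28: "E", 46: "E", 52: "E", 57: "E", 68: "E", 80: "E",
        17: "H", 79: "H",
    })
    atoms = make_peptide(chain_a, chain="A")
    atoms += make_peptide(chain_b, chain="B", origin=np.array([4.0, 0.0, 0.0]))
    s = Structure(title="synthetic barnase-barstar stand-in", atoms=atoms,
                  box=np.full(3, 12.0))
    s.renumber()
    return s


# ---------------------------------------------------------------------------
# Lambda / TI samplers
# ---------------------------------------------------------------------------

def sample_lambda(
    energy,
    temperature: float,
    n: int,
    seed: int = 1,
    domain: tuple[float, float] = LAMBDA_DOMAIN,
    grid_points: int = 10_000,
) -> LambdaTrajectory:
    """Draw n i.i.d. samples from p(lambda) ~ exp(-U(lambda)/kT).

    ``energy`` is any callable (kJ/mol) evaluable on the domain, e.g.
    :meth:`CorrectionPotential.potential` or a composite of two.  Sampling
    is by inverse CDF on a dense quadrature grid; samples are packaged as a
    trajectory with 1-ps spacing.
    """
    lo, hi = domain
    grid = np.linspace(lo, hi, grid_points)
    with np.errstate(all="ignore"):
        try:
            u = np.asarray(energy(grid), dtype=float)
            if u.shape != grid.shape:
                raise TypeError
        except (TypeError, ValueError):
            u = np.array([float(energy(x)) for x in grid])
    if not np.all(np.isfinite(u)):
        raise ValueError("energy function is not finite on the lambda domain")
    kT = KB_KJ_PER_MOL_K * temperature
    logp = -(u - u.min()) / kT
    p = np.exp(logp)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    samples = np.interp(rng.random(n), cdf, grid)
    return LambdaTrajectory(np.arange(n, dtype=float), samples, temperature)


def sample_dvdl(
    true_potential: CorrectionPotential,
    lambda_value: float,
    noise_sd: float,
    n: int,
    seed: int = 1,
) -> TISample:
    """Gaussian dV/dlambda samples centred on the analytic derivative of
    ``true_potential`` at ``lambda_value`` (stand-in for a fixed-lambda
    TI run)."""
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    center = float(true_potential.dvdl(lambda_value))
    samples = center + rng.normal(scale=noise_sd, size=n) if noise_sd > 0 \
        else np.full(n, center)
    return TISample(lambda_value, samples)
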