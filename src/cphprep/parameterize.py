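"""Two-step parametrization of the correction potential V^MM.

Each titratable group type needs a correction potential V(lambda) that
compensates the force field's deficient proton affinity; it is stored as
the polynomial coefficients of a fit to the mean force dV/dlambda (the
"dvdl" line of the group-type file, highest power first, degree 5 by
default).  The scheme:

1. **Fast TI fit** — short runs at lambda fixed on a grid from -0.1 to 1.1
   in steps of 0.1 (13 points) record samples of dV/dlambda; a least-
   squares polynomial fit of the per-point means gives an approximate V.

2. **Boltzmann-inversion reweighting** — a long sampling run at pH = pKa
   with zero biasing barrier, under the approximate V, yields the
   distribution p(lambda).  If V were exact, p would be flat; the residual
   free energy is recovered from the histogram as -kB*T*ln p(lambda) (up
   to an irrelevant additive constant), fitted with a polynomial one
   degree higher than the dV/dlambda degree, differentiated analytically,
   and added coefficient-wise to the stored coefficients.  A second
   sampling run under the updated V should then produce a flat histogram.

Trajectory input is two-column whitespace text (time, lambda); lines
starting with ``#`` or ``@`` (XVG headers) are skipped.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .gentopol import TitratableSite, initialize_lambdas
from .genparams import generate_mdp
from .grouptypes import GroupTypeDefinition, GroupTypeRegistry, PhysicalState

__all__ = [
    "KB_KJ_PER_MOL_K",
    "CorrectionPotential",
    "TISample",
    "LambdaTrajectory",
    "read_lambda_xvg",
    "write_lambda_xvg",
    "ti_grid",
    "fit_ti",
    "boltzmann_correction",
    "flatness",
    "scaffold_parameterization",
    "scaffold_titration",
    "protonation_fraction",
    "grouptype_block_from_fit",
]

#: Boltzmann constant, kJ/(mol K)
KB_KJ_PER_MOL_K = 0.008314462618

#: lambda domain covered by the TI grid and the correction fit
LAMBDA_DOMAIN = (-0.1, 1.1)


@dataclass
class CorrectionPotential:
    """Polynomial fit to dV/dlambda (kJ/mol), highest power first."""

    dvdl_coeffs: np.ndarray

    def __post_init__(self) -> None:
        self.dvdl_coeffs = np.atleast_1d(np.asarray(self.dvdl_coeffs, dtype=float))
        if not np.all(np.isfinite(self.dvdl_coeffs)):
            raise ValueError("dvdl coefficients must be finite")

    @property
    def degree(self) -> int:
        return len(self.dvdl_coeffs) - 1

    def dvdl(self, lam) -> np.ndarray | float:
        """Evaluate dV/dlambda."""
        return np.polyval(self.dvdl_coeffs, lam)

    def potential(self, lam) -> np.ndarray | float:
        """Evaluate V(lambda) = integral of the dvdl polynomial (V(0) = 0)."""
        integ = np.polyint(self.dvdl_coeffs)
        return np.polyval(integ, lam) - np.polyval(integ, 0.0)

    def add(self, other: "CorrectionPotential") -> "CorrectionPotential":
        """Coefficient-wise sum (shorter polynomial zero-padded at the
        high-power end)."""
        n = max(len(self.dvdl_coeffs), len(other.dvdl_coeffs))
        a = np.pad(self.dvdl_coeffs, (n - len(self.dvdl_coeffs), 0))
        b = np.pad(other.dvdl_coeffs, (n - len(other.dvdl_coeffs), 0))
        return CorrectionPotential(a + b)

    def __add__(self, other):
        return self.add(other)


@dataclass
class TISample:
    """dV/dlambda samples recorded at one fixed lambda."""

    lambda_value: float
    dvdl_samples: np.ndarray

    def __post_init__(self) -> None:
        self.dvdl_samples = np.atleast_1d(np.asarray(self.dvdl_samples, dtype=float))
        if self.dvdl_samples.size < 1:
            raise ValueError("need at least one dV/dlambda sample per point")


@dataclass
class LambdaTrajectory:
    """A time series of lambda values from a sampling run."""

    times: np.ndarray
    lambdas: np.ndarray
    temperature: float = 300.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if self.times.shape != self.lambdas.shape:
            raise ValueError("times and lambdas must have equal length")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def n(self) -> int:
        return len(self.lambdas)


def read_lambda_xvg(path: str | Path, temperature: float = 300.0) -> LambdaTrajectory:
    """Read a two-column (time, lambda) text file, skipping # and @ lines."""
    times, lams = [], []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "@")):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns")
        times.append(float(parts[0]))
        lams.append(float(parts[1]))
    return LambdaTrajectory(np.array(times), np.array(lams), temperature)


def write_lambda_xvg(traj: LambdaTrajectory, path: str | Path) -> Path:
    path = Path(path)
    lines = ["@ title \"lambda coordinate\"", "@ xaxis label \"time (ps)\""]
    lines += [f"{t:.4f} {l:.8f}" for t, l in zip(traj.times, traj.lambdas)]
    path.write_text("\n".join(lines) + "\n")
    return path


def ti_grid() -> list[float]:
    """The fixed-lambda grid: -0.1 to 1.1 inclusive, step 0.1 (13 points)."""
    return [round(-0.1 + 0.1 * i, 10) for i in range(13)]


def fit_ti(samples: list[TISample], degree: int = 5) -> CorrectionPotential:
    """Least-squares polynomial fit of the per-point mean dV/dlambda."""
    lams = np.array([s.lambda_value for s in samples])
    if len(np.unique(lams)) < degree + 1:
        raise ValueError(
            f"degree-{degree} fit needs at least {degree + 1} distinct lambda "
            f"points, got {len(np.unique(lams))}"
        )
    means = np.array([s.dvdl_samples.mean() for s in samples])
    coeffs = np.polyfit(lams, means, degree)
    return CorrectionPotential(coeffs)


def boltzmann_correction(
    traj: LambdaTrajectory,
    old: CorrectionPotential,
    bins: int = 100,
    degree: int = 5,
) -> CorrectionPotential:
    """Reweight a correction potential from the sampled lambda distribution.

    The histogram p(lambda) over the sampled range gives the residual free
    energy -kB*T*ln p (additive constant irrelevant); it is fitted with a
    degree-(degree+1) polynomial over the non-empty bins, differentiated
    analytically, and the resulting degree-``degree`` dV/dlambda update is
    added coefficient-wise to ``old``.  Over-visited lambda regions thereby
    have their effective energy raised, flattening the distribution on
    resampling.  More than 50% empty bins raises ``ValueError``.
    """
    if traj.n == 0:
        raise ValueError("empty trajectory")
    lo, hi = traj.lambdas.min(), traj.lambdas.max()
    if hi <= lo:
        raise ValueError("trajectory samples a single lambda value")
    counts, edges = np.histogram(traj.lambdas, bins=bins, range=(lo, hi), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    filled = counts > 0
    if np.count_nonzero(filled) < bins / 2:
        raise ValueError(
            f"{bins - np.count_nonzero(filled)} of {bins} histogram bins are "
            "empty; sampling is insufficient for Boltzmann inversion"
        )
    kT = KB_KJ_PER_MOL_K * traj.temperature
    u_corr = -kT * np.log(counts[filled])
    u_fit = np.polyfit(centers[filled], u_corr, degree + 1)
    delta_dvdl = np.polyder(u_fit)
    return old.add(CorrectionPotential(delta_dvdl))


def flatness(traj: LambdaTrajectory, bins: int = 50) -> float:
    """Maximum absolute deviation of the sampled lambda density from the
    uniform density over the sampled range (0 = perfectly flat)."""
    if traj.n == 0:
        raise ValueError("empty trajectory")
    lo, hi = traj.lambdas.min(), traj.lambdas.max()
    if hi <= lo:
        return float("inf")
    density, _ = np.histogram(traj.lambdas, bins=bins, range=(lo, hi), density=True)
    uniform = 1.0 / (hi - lo)
    return float(np.max(np.abs(density - uniform)))


def protonation_fraction(
    traj: LambdaTrajectory, lo: float = 0.2, hi: float = 0.8
) -> float:
    """Deprotonated fraction from end-state dwell counts.

    Samples with lambda > ``hi`` count as deprotonated, lambda < ``lo`` as
    protonated; intermediate (barrier) samples are excluded.
    """
    n_deprot = int(np.count_nonzero(traj.lambdas > hi))
    n_prot = int(np.count_nonzero(traj.lambdas < lo))
    if n_deprot + n_prot == 0:
        raise ValueError("no end-state samples in trajectory")
    return n_deprot / (n_deprot + n_prot)


# ---------------------------------------------------------------------------
# Run-directory scaffolding
# ---------------------------------------------------------------------------

def _prepare_dir(path: Path, overwrite: bool) -> None:
    if path.exists() and any(path.iterdir()):
        if not overwrite:
            raise FileExistsError(f"target directory {path} is not empty")
        shutil.rmtree(path)
    path.mkdir(parents=True, exist_ok=True)


def scaffold_parameterization(
    workdir: str | Path,
    sites: list[TitratableSite],
    registry: GroupTypeRegistry,
    grid: list[float] | None = None,
    overwrite: bool = False,
) -> list[Path]:
    """Create one run directory per fixed-lambda grid point.

    Each directory holds a calibration-mode mdp with the site lambda fixed
    at the grid value; a manifest file lists the runs.
    """
    workdir = Path(workdir)
    grid = ti_grid() if grid is None else grid
    _prepare_dir(workdir, overwrite)
    run_dirs = []
    for lam in grid:
        d = workdir / f"lambda_{lam:+.1f}"
        d.mkdir()
        for site in sites:
            site.lambda_coords = [(i, lam) for i, _ in enumerate(
                registry.definitions[site.group_type].states
            )] if registry.definitions[site.group_type].multisite else [(0, lam)]
        doc = generate_mdp(
            "CPHMD", sites, registry, pH=7.0, barrier=0.0, calibration=True
        )
        doc.write(d / "run.mdp")
        run_dirs.append(d)
    manifest = workdir / "manifest.txt"
    manifest.write_text(
        "\n".join(f"{lam:+.1f} {d.name}" for lam, d in zip(grid, run_dirs)) + "\n"
    )
    return run_dirs


def scaffold_titration(
    workdir: str | Path,
    sites: list[TitratableSite],
    registry: GroupTypeRegistry,
    ph_values: list[float],
    barrier: float = 7.5,
    overwrite: bool = False,
) -> list[Path]:
    """Create one run directory per pH, with initial lambdas re-derived
    from that pH."""
    if not ph_values:
        raise ValueError("need at least one pH value")
    if len(set(ph_values)) != len(ph_values):
        raise ValueError("duplicate pH values in titration list")
    workdir = Path(workdir)
    _prepare_dir(workdir, overwrite)
    run_dirs = []
    for ph in ph_values:
        d = workdir / f"ph_{ph:g}"
        d.mkdir()
        initialize_lambdas(sites, registry, ph)
        doc = generate_mdp("CPHMD", sites, registry, pH=ph, barrier=barrier)
        doc.write(d / "run.mdp")
        run_dirs.append(d)
    manifest = workdir / "manifest.txt"
    manifest.write_text(
        "\n".join(f"{ph:g} {d.name}" for ph, d in zip(ph_values, run_dirs)) + "\n"
    )
    return run_dirs


def grouptype_block_from_fit(
    name: str,
    aliases: list[str],
    atom_names: list[str],
    common_charges: list[float],
    state_charges: list[float],
    pKa: float,
    potential: CorrectionPotential,
) -> str:
    """Format a ready-to-paste single-site group-type block from a fit."""
    from .grouptypes import GroupTypeRegistry, format_grouptypes

    registry = GroupTypeRegistry()
    registry.add(
        GroupTypeDefinition(
            name=name,
            aliases=aliases,
            atom_names=atom_names,
            common_charges=list(common_charges),
            states=[
                PhysicalState(
                    pKa=pKa,
                    charges=list(state_charges),
                    dvdl_coeffs=list(potential.dvdl_coeffs),
                )
            ],
        )
    )
    return format_grouptypes(registry)
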