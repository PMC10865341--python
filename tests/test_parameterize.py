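"""TI fitting, Boltzmann-inversion reweighting, and run scaffolding."""

import numpy as np
import pytest

from cphprep.fixtures import (
    make_peptide,
    sample_dvdl,
    sample_lambda,
)
from cphprep.gentopol import detect_titratable
from cphprep.genparams import MDPDocument, load_key_template
from cphprep.parameterize import (
    KB_KJ_PER_MOL_K,
    CorrectionPotential,
    LambdaTrajectory,
    TISample,
    boltzmann_correction,
    fit_ti,
    flatness,
    grouptype_block_from_fit,
    protonation_fraction,
    read_lambda_xvg,
    scaffold_parameterization,
    scaffold_titration,
    ti_grid,
    write_lambda_xvg,
)
from cphprep.structure import Structure

TRUE_DVDL = np.array([-54.078, -144.280, 278.550, -146.030, -554.270, 44.621])


def _traj(lambdas, T=300.0):
    lambdas = np.asarray(lambdas, dtype=float)
    return LambdaTrajectory(np.arange(lambdas.size, dtype=float), lambdas, T)


class TestTIGrid:
    def test_thirteen_points_from_minus01_to_11(self):
        grid = ti_grid()
        assert len(grid) == 13
        assert grid[0] == pytest.approx(-0.1)
        assert grid[-1] == pytest.approx(1.1)
        assert np.diff(grid) == pytest.approx(np.full(12, 0.1))


class TestFitTI:
    def test_noiseless_recovery_is_exact(self):
        true = CorrectionPotential(TRUE_DVDL)
        samples = [sample_dvdl(true, lam, 0.0, 5, seed=1) for lam in ti_grid()]
        fit = fit_ti(samples)
        assert np.abs(fit.dvdl_coeffs - TRUE_DVDL).max() < 1e-8 * np.abs(TRUE_DVDL).max()

    @pytest.mark.parametrize("degree", [1, 3, 5])
    def test_noiseless_exact_any_degree(self, degree):
        coeffs = np.arange(degree + 1, dtype=float) + 1.0
        true = CorrectionPotential(coeffs)
        samples = [sample_dvdl(true, lam, 0.0, 2, seed=1) for lam in ti_grid()]
        fit = fit_ti(samples, degree=degree)
        assert np.allclose(fit.dvdl_coeffs, coeffs, rtol=1e-9, atol=1e-9)

    def test_noisy_recovery_within_three_standard_errors(self):
        sigma, n_per_point = 20.0, 1000
        true = CorrectionPotential(TRUE_DVDL)
        samples = [
            sample_dvdl(true, lam, sigma, n_per_point, seed=100 + i)
            for i, lam in enumerate(ti_grid())
        ]
        fit = fit_ti(samples)
        X = np.vander(np.array(ti_grid()), 6)
        cov = sigma**2 / n_per_point * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        assert np.all(np.abs(fit.dvdl_coeffs - TRUE_DVDL) <= 3 * se)

    def test_all_zero_samples_give_zero_polynomial(self):
        samples = [TISample(lam, np.zeros(4)) for lam in ti_grid()]
        assert np.allclose(fit_ti(samples).dvdl_coeffs, 0.0, atol=1e-10)

    def test_too_few_points_is_error(self):
        samples = [TISample(lam, [1.0]) for lam in (0.0, 0.5, 1.0)]
        with pytest.raises(ValueError, match="distinct lambda"):
            fit_ti(samples, degree=5)


class TestBoltzmannCorrection:
    def test_exactly_uniform_distribution_is_fixed_point(self):
        # equal counts in every histogram bin: ln p is constant, so the
        # derivative of the fitted correction vanishes identically
        old = CorrectionPotential(TRUE_DVDL)
        edges = np.linspace(-0.1, 1.1, 101)
        centers = 0.5 * (edges[:-1] + edges[1:])
        lambdas = np.repeat(centers, 10)
        lambdas[0], lambdas[-1] = -0.1, 1.1  # pin the sampled range
        new = boltzmann_correction(_traj(lambdas), old, bins=100)
        grid = np.linspace(-0.1, 1.1, 200)
        assert np.abs(new.dvdl(grid) - old.dvdl(grid)).max() < 1e-6

    def test_correction_linear_in_temperature(self):
        rng = np.random.default_rng(12)
        lambdas = rng.beta(2.0, 3.0, size=200_000) * 1.2 - 0.1
        old = CorrectionPotential(np.zeros(6))
        d300 = boltzmann_correction(_traj(lambdas, 300.0), old).dvdl_coeffs
        d600 = boltzmann_correction(_traj(lambdas, 600.0), old).dvdl_coeffs
        assert np.allclose(d600, 2.0 * d300, rtol=1e-9)

    def test_insufficient_sampling_is_error(self):
        lambdas = np.concatenate([
            np.full(500, 0.01) + np.linspace(0, 1e-3, 500),
            np.full(500, 0.99) + np.linspace(0, 1e-3, 500),
        ])
        with pytest.raises(ValueError, match="empty"):
            boltzmann_correction(_traj(lambdas), CorrectionPotential([0.0]))

    def test_closed_loop_flattens(self):
        """One reweighting step turns a skewed distribution flat (the
        two-step parametrization in miniature)."""
        true = CorrectionPotential(TRUE_DVDL)
        perturbation = CorrectionPotential([40.0, -90.0, 55.0, 20.0, -12.0, 2.0])
        misfit = true + perturbation

        def residual(pot):
            return lambda x: true.potential(x) - pot.potential(x)

        first = sample_lambda(residual(misfit), 300.0, 200_000, seed=21)
        corrected = boltzmann_correction(first, misfit)
        second = sample_lambda(residual(corrected), 300.0, 200_000, seed=22)
        assert flatness(second) < flatness(first)
        assert flatness(second) < 0.05

    def test_coefficient_addition_commutes(self):
        base = CorrectionPotential(TRUE_DVDL)
        d1 = CorrectionPotential([1.0, 2.0, 3.0])
        d2 = CorrectionPotential([-0.5, 4.0])
        left = (base + d1) + d2
        right = base + (d1 + d2)
        assert np.allclose(left.dvdl_coeffs, right.dvdl_coeffs)


class TestFlatness:
    def test_uniform_samples_near_zero(self):
        rng = np.random.default_rng(9)
        traj = _traj(rng.random(100_000) * 1.2 - 0.1)
        assert flatness(traj) <= 0.05

    def test_single_cluster_is_maximal(self):
        # nearly all mass in one interior bin, endpoints pin the range
        lambdas = np.concatenate([[0.0, 1.0], np.full(10_000, 0.5)])
        stat = flatness(_traj(lambdas), bins=50)
        assert stat == pytest.approx(49.0, rel=0.02)

    def test_bimodal_end_states_large(self):
        rng = np.random.default_rng(10)
        lambdas = np.concatenate([
            rng.normal(0.02, 0.01, 50_000), rng.normal(0.98, 0.01, 50_000)
        ])
        assert flatness(_traj(lambdas)) > 0.5


class TestProtonationFraction:
    def test_all_deprotonated(self):
        assert protonation_fraction(_traj(np.full(100, 0.95))) == 1.0

    def test_even_split(self):
        lambdas = np.concatenate([np.full(50, 0.05), np.full(50, 0.95)])
        assert protonation_fraction(_traj(lambdas)) == 0.5

    def test_seventy_percent_occupancy(self):
        rng = np.random.default_rng(11)
        n = 100_000
        deprot = rng.random(n) < 0.7
        lambdas = np.where(deprot, 0.9 + 0.08 * rng.random(n),
                           0.02 + 0.08 * rng.random(n))
        assert protonation_fraction(_traj(lambdas)) == pytest.approx(0.70, abs=0.01)

    def test_no_end_state_samples_is_error(self):
        with pytest.raises(ValueError, match="end-state"):
            protonation_fraction(_traj(np.full(10, 0.5)))


class TestTrajectoryIO:
    def test_xvg_round_trip_skips_headers(self, tmp_path):
        traj = _traj(np.linspace(0, 1, 50))
        path = write_lambda_xvg(traj, tmp_path / "lambda.xvg")
        text = path.read_text()
        assert text.startswith("@")
        again = read_lambda_xvg(path)
        assert np.allclose(again.lambdas, traj.lambdas, atol=1e-8)


@pytest.fixture()
def asp_sites(registry):
    s = Structure(atoms=make_peptide("ADA"))
    s.renumber()
    return detect_titratable(s, registry)


class TestScaffolding:
    def test_parameterization_grid_directories(self, tmp_path, registry, asp_sites):
        dirs = scaffold_parameterization(tmp_path / "par", asp_sites, registry)
        assert len(dirs) == 13
        manifest = (tmp_path / "par" / "manifest.txt").read_text().splitlines()
        assert len(manifest) == 13
        assert manifest[0].startswith("-0.1")
        assert manifest[-1].startswith("+1.1")

    def test_scaffold_refuses_nonempty_dir(self, tmp_path, registry, asp_sites):
        scaffold_parameterization(tmp_path / "par", asp_sites, registry)
        with pytest.raises(FileExistsError):
            scaffold_parameterization(tmp_path / "par", asp_sites, registry)
        # identical tree on overwrite
        dirs = scaffold_parameterization(
            tmp_path / "par", asp_sites, registry, overwrite=True
        )
        assert len(dirs) == 13

    def test_calibration_mode_in_grid_mdp(self, tmp_path, registry, asp_sites):
        keys = load_key_template()
        dirs = scaffold_parameterization(tmp_path / "par", asp_sites, registry)
        doc = MDPDocument.read(dirs[0] / "run.mdp")
        assert doc.get(keys["calibration"]) == "yes"

    def test_titration_directories_and_ph(self, tmp_path, registry, asp_sites):
        keys = load_key_template()
        dirs = scaffold_titration(
            tmp_path / "tit", asp_sites, registry, [2.0, 4.0, 6.0]
        )
        assert len(dirs) == 3
        for d, ph in zip(dirs, (2.0, 4.0, 6.0)):
            doc = MDPDocument.read(d / "run.mdp")
            assert doc.get(keys["simulation_ph"]) == f"{ph:g}"
        # the aspartate site flips between pH 2 and pH 6 (pKa 3.65)
        low = MDPDocument.read(dirs[0] / "run.mdp")
        high = MDPDocument.read(dirs[2] / "run.mdp")
        key = keys["set_initial_lambda"].format(k=1)
        assert low.get(key) == "0" and high.get(key) == "1"

    def test_duplicate_ph_rejected(self, tmp_path, registry, asp_sites):
        with pytest.raises(ValueError, match="duplicate"):
            scaffold_titration(tmp_path / "t", asp_sites, registry, [4.0, 4.0])


class TestBlockOutput:
    def test_fit_formats_parseable_block(self):
        pot = CorrectionPotential(TRUE_DVDL)
        block = grouptype_block_from_fit(
            name="ARGT", aliases=["ARG"], atom_names=["NH1"],
            common_charges=[0.0], state_charges=[-1.0], pKa=13.8,
            potential=pot,
        )
        from cphprep.grouptypes import parse_grouptypes_text

        reg = parse_grouptypes_text(block)
        assert np.allclose(
            reg.definitions["ARGT"].states[0].dvdl_coeffs, TRUE_DVDL
        )
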