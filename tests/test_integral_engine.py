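"""Eigenbasis, projection, problem assembly and the per-mode solves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rdintegral as rd
from rdintegral.fixtures import gaussian_profile
from rdintegral.integral_engine import IntegralProblem
from rdintegral.network_model import DomainDef
from rdintegral.validation import relative_l2

from conftest import perturbed_initial


@pytest.fixture(scope="module")
def neumann_basis():
    return rd.make_basis(DomainDef(length=1.0, bc="neumann"), 64)


class TestBasis:
    def test_neumann_frequencies(self):
        basis = rd.make_basis(DomainDef(length=1.0, bc="neumann"), 4)
        assert basis.mu == pytest.approx(np.array([0, 1, 2, 3, 4]) * np.pi)

    def test_dirichlet_excludes_constant_mode(self):
        basis = rd.make_basis(DomainDef(length=2.0, bc="dirichlet"), 3)
        assert basis.ks.tolist() == [1, 2, 3]
        z = np.linspace(0, 2.0, 11)
        assert basis.phi(1, z)[0] == pytest.approx(0.0)
        assert basis.phi(1, z)[-1] == pytest.approx(0.0, abs=1e-14)

    @pytest.mark.parametrize("bc", ["neumann", "dirichlet"])
    def test_orthonormality(self, bc):
        basis = rd.make_basis(DomainDef(length=1.3, bc=bc), 8)
        z = np.linspace(0, 1.3, 2001)
        Phi = basis.eval_matrix(z)
        from scipy.integrate import simpson

        gram = simpson(Phi[:, None, :] * Phi[None, :, :], x=z, axis=-1)
        assert np.allclose(gram, np.eye(basis.n_modes), atol=1e-10)

    def test_eigenfunction_relation(self):
        # -phi'' = mu^2 phi, via central differences
        basis = rd.make_basis(DomainDef(length=1.0, bc="neumann"), 5)
        z = np.linspace(0.01, 0.99, 200)
        h = 1e-5
        for k in (1, 3, 5):
            lap = (basis.phi(k, z + h) - 2 * basis.phi(k, z) + basis.phi(k, z - h)) / h**2
            assert np.allclose(-lap, (k * np.pi) ** 2 * basis.phi(k, z), rtol=1e-4)

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            rd.make_basis(DomainDef(length=1.0, bc="neumann"), 0)


class TestProject:
    def test_constant_profile_hits_only_mode_zero(self, neumann_basis):
        coeffs = rd.project(lambda z: np.full_like(z, 3.0), neumann_basis)
        assert coeffs[0] == pytest.approx(3.0 * np.sqrt(1.0))
        assert np.allclose(coeffs[1:], 0.0, atol=1e-10)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(k=st.integers(min_value=0, max_value=40))
    def test_eigenfunction_projects_to_unit_vector(self, k):
        basis = rd.make_basis(DomainDef(length=1.0, bc="neumann"), 48)
        coeffs = rd.project(lambda z: basis.phi(k, z), basis)
        expected = np.zeros(basis.n_modes)
        expected[k] = 1.0
        assert np.allclose(coeffs, expected, atol=1e-8)

    def test_gaussian_reconstruction_error(self, neumann_basis):
        f = gaussian_profile(1.0, 0.5, 0.1)
        coeffs = rd.project(f, neumann_basis)
        z = np.linspace(0, 1, 501)
        recon = neumann_basis.synthesize(coeffs, z)
        assert relative_l2(recon, f(z)) < 1e-6

    def test_nan_profile_rejected(self, neumann_basis):
        with pytest.raises(ValueError, match="NaN"):
            rd.project(lambda z: np.full_like(z, np.nan), neumann_basis)


class TestAssemble:
    def test_complexform_operators(self, complexform, cert, equilibrium):
        prob = rd.assemble_problem(complexform, cert, equilibrium)
        assert np.allclose(prob.Abar, np.diag([-1.0, -1.0]))
        assert prob.D2 == pytest.approx([0.0, 5e-3])
        assert prob.Gbar == pytest.approx(np.array([[0.0], [1.0]]))

    def test_equilibrium_start_zero_stimulus_zero_solution(
        self, complexform, cert, equilibrium, neumann_basis
    ):
        prob = rd.assemble_problem(complexform, cert, equilibrium)
        z = np.linspace(0, 1, 11)
        assert np.allclose(prob.beta(z), 0.0)
        sol = rd.solve_modes(prob, neumann_basis)
        assert np.allclose(sol.coeffs, 0.0)
        assert np.allclose(sol.evaluate(z), 0.0)

    def test_c1_perturbation_forcing_proportional(
        self, complexform, cert, equilibrium
    ):
        # a bump p(z) on the complex enters both c2 rows with weight
        # -N21 N11^-1 p = (p, p): beta is proportional to p componentwise
        bump = gaussian_profile(0.7, 0.4, 0.08)
        initial = perturbed_initial(complexform, equilibrium, "C", bump)
        prob = rd.assemble_problem(complexform, cert, equilibrium, initial=initial)
        z = np.linspace(0, 1, 101)
        b = prob.beta(z)
        assert np.allclose(b[0], bump(z))
        assert np.allclose(b[1], bump(z))

    def test_unstable_equilibrium_refused(self):
        spec = {
            "species": [{"name": "s", "diffusion": 1.0, "initial": 0.0}],
            "reactions": [
                {"name": "grow", "stoich": {"s": 1}, "kind": "affine",
                 "affine": {"const": 0.0, "coeffs": {"s": 1.0}}}
            ],
            "domain": {"length": 1.0},
        }
        net = rd.build_network(spec)
        cert = rd.check_conditions(net)
        eq = rd.homogeneous_equilibrium(net, guess=np.array([0.0]))
        with pytest.raises(ValueError, match="stable"):
            rd.assemble_problem(net, cert, eq)


def _scalar_problem(length: float, abar: float, d2: float, beta_fn, p_channels=0):
    return IntegralProblem(
        D2=np.array([d2]),
        Abar=np.array([[abar]]),
        Gbar=np.zeros((1, p_channels)),
        beta=lambda z: np.atleast_2d(beta_fn(np.asarray(z, dtype=float))),
        stimulus_integral=lambda z: np.zeros((p_channels, np.asarray(z).size)),
        c2_names=("s",),
        domain=DomainDef(length=length, bc="neumann"),
    )


class TestSolveModes:
    def test_scalar_mode_arithmetic(self):
        # domain length pi puts mode 2 at mu = 2; forcing f_2 = -5 comes from
        # beta = 5 phi_2, and (-1 - 4) a_2 = -5 gives a_2 = 1
        dom = DomainDef(length=np.pi, bc="neumann")
        basis = rd.make_basis(dom, 4)
        prob = _scalar_problem(np.pi, -1.0, 1.0, lambda z: 5.0 * basis.phi(2, z))
        sol = rd.solve_modes(prob, basis)
        assert sol.coeffs[0, 2] == pytest.approx(1.0, rel=1e-10)
        others = np.delete(sol.coeffs[0], 2)
        assert np.allclose(others, 0.0, atol=1e-9)

    def test_ligand_row_matches_filter_formula(
        self, complexform, cert, equilibrium, params
    ):
        # perturbation on the complex: ligand coefficients must equal
        # q_k / (d_L + D_L mu_k^2), the spatial low-pass filter
        bump = gaussian_profile(1.0, 0.5, 0.1)
        initial = perturbed_initial(complexform, equilibrium, "C", bump)
        prob = rd.assemble_problem(complexform, cert, equilibrium, initial=initial)
        basis = rd.make_basis(complexform.domain, 48)
        sol = rd.solve_modes(prob, basis)
        qk = rd.project(bump, basis)
        expected_L = qk / (params.d_L + params.D_L * basis.mu**2)
        expected_R = qk / params.d_R
        assert np.allclose(sol.coeffs[1], expected_L, rtol=1e-10, atol=1e-12)
        assert np.allclose(sol.coeffs[0], expected_R, rtol=1e-10, atol=1e-12)

    def test_mode_solve_residuals(self, complexform, cert, equilibrium):
        bump = gaussian_profile(1.0, 0.5, 0.1)
        initial = perturbed_initial(complexform, equilibrium, "C", bump)
        prob = rd.assemble_problem(complexform, cert, equilibrium, initial=initial)
        basis = rd.make_basis(complexform.domain, 32)
        sol = rd.solve_modes(prob, basis)
        beta_k = rd.project(prob.beta, basis)
        forcing = -beta_k
        for k, mu in enumerate(basis.mu):
            Mk = prob.Abar - mu**2 * np.diag(prob.D2)
            resid = np.linalg.norm(Mk @ sol.coeffs[:, k] - forcing[:, k])
            assert resid <= 1e-12 * max(np.linalg.norm(forcing[:, k]), 1.0)

    def test_singular_mode_matrix_names_mode(self):
        dom = DomainDef(length=1.0, bc="neumann")
        basis = rd.make_basis(dom, 2)
        prob = _scalar_problem(1.0, 0.0, 0.0, lambda z: np.ones_like(z))
        with pytest.raises(np.linalg.LinAlgError, match="k=0"):
            rd.solve_modes(prob, basis)

    def test_truncation_doubling_stability(self, complexform, cert, equilibrium):
        bump = gaussian_profile(1.0, 0.5, 0.1)
        initial = perturbed_initial(complexform, equilibrium, "C", bump)
        prob = rd.assemble_problem(complexform, cert, equilibrium, initial=initial)
        z = np.linspace(0, 1, 301)
        y64 = rd.solve_modes(prob, rd.make_basis(complexform.domain, 64)).evaluate(z)
        y128 = rd.solve_modes(prob, rd.make_basis(complexform.domain, 128)).evaluate(z)
        assert relative_l2(y64, y128) < 1e-3


class TestNilChannels:
    def test_complexform_ligand_influx_nil_for_receptor(
        self, complexform, cert, equilibrium
    ):
        prob = rd.assemble_problem(complexform, cert, equilibrium)
        basis = rd.make_basis(complexform.domain, 32)
        nil = rd.detect_nil_channels(prob, basis)
        i_R = prob.c2_names.index("R")
        assert (0, i_R) in nil
        assert (0, prob.c2_names.index("L")) not in nil

    def test_zero_gbar_row_flagged_for_all_channels(self):
        prob = IntegralProblem(
            D2=np.zeros(2),
            Abar=np.diag([-1.0, -2.0]),
            Gbar=np.array([[0.0, 0.0], [1.0, 2.0]]),
            beta=lambda z: np.zeros((2, np.asarray(z).size)),
            stimulus_integral=lambda z: np.zeros((2, np.asarray(z).size)),
            c2_names=("a", "b"),
            domain=DomainDef(length=1.0, bc="neumann"),
        )
        basis = rd.make_basis(prob.domain, 8)
        nil = rd.detect_nil_channels(prob, basis)
        assert set(nil) == {(0, 0), (1, 0)}

    def test_dense_gbar_gives_no_flags(self):
        rng = np.random.default_rng(5)
        Gbar = rng.uniform(0.5, 1.5, size=(2, 2))
        Abar = np.diag([-1.0, -2.0])
        prob = IntegralProblem(
            D2=np.array([0.1, 0.2]),
            Abar=Abar,
            Gbar=Gbar,
            beta=lambda z: np.zeros((2, np.asarray(z).size)),
            stimulus_integral=lambda z: np.zeros((2, np.asarray(z).size)),
            c2_names=("a", "b"),
            domain=DomainDef(length=1.0, bc="neumann"),
        )
        basis = rd.make_basis(prob.domain, 8)
        assert rd.detect_nil_channels(prob, basis) == []
        # brute-force cross-check: every mode gain entry is nonzero
        for mu in basis.mu:
            gains = np.linalg.solve(Abar - mu**2 * np.diag(prob.D2), Gbar)
            assert np.all(np.abs(gains) > 1e-6)


class TestLinearizedCrossCheck:
    def test_linearized_pde_reproduces_integrals(
        self, complexform, cert, equilibrium, perturbation_bump
    ):
        # the coefficients can equivalently be obtained from the PDE
        # linearized at the equilibrium; for class networks both agree
        initial = perturbed_initial(
            complexform, equilibrium, "C", perturbation_bump
        )
        prob = rd.assemble_problem(complexform, cert, equilibrium, initial=initial)
        basis = rd.make_basis(complexform.domain, 64)
        analytic = rd.solve_modes(prob, basis)
        sys = rd.discretize(complexform, nz=201)
        traj = rd.simulate(
            sys, initial=initial, equilibrium=equilibrium,
            horizon_multiplier=16.0, linearize=True,
        )
        num = rd.numeric_time_integral(traj).profiles[cert.c2_indices, :]
        assert relative_l2(analytic.evaluate(sys.z), num) < 0.01
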