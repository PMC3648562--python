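"""Analytic time-integrals by eigenfunction expansion.

For a network in the C1/C2 class, the time-integral of the c2 species'
deviation from equilibrium,

    y(z) = int_0^inf (c2(z, t) - c2*) dt,

satisfies the linear inhomogeneous boundary-value problem

    0 = D2 y'' + Abar y + beta(z) + Gbar Gint(z),

with Abar = N22 W, Gbar = B2 - N21 N11^-1 B1,
beta(z) = (c2(z,0) - c2*) - N21 N11^-1 (c1(z,0) - c1*), and
Gint(z) = int_0^inf g(z,t) dt the time-integrated stimulus.  Expanding y and
the forcing on the orthonormal Laplacian eigenfunctions phi_k decouples the
problem into one small linear system per spatial mode:

    (Abar - mu_k^2 D2) a_k = -(beta_k + Gbar Gint_k).

The series is exact for the nonlinear dynamics — no linearization is
involved — so it holds for small or large perturbations alike.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable
import warnings

import numpy as np
from scipy.integrate import simpson

from .class_checker import ClassCertificate
from .network_model import (
    DomainDef,
    Equilibrium,
    ReactionNetwork,
    stability_spectrum,
)

__all__ = [
    "EigenBasis",
    "IntegralProblem",
    "TimeIntegralSolution",
    "make_basis",
    "project",
    "assemble_problem",
    "solve_modes",
    "detect_nil_channels",
]

DEFAULT_QUAD_POINTS = 2049  # composite-Simpson grid for projections
_MODE_RESIDUAL_RTOL = 1e-12
_TAIL_WARN = 1e-6


@dataclass(frozen=True)
class EigenBasis:
    """Orthonormal eigenfunctions of the 1-D Laplacian on [0, length].

    Neumann: mu_k = k pi / l for k = 0..K with phi_0 = sqrt(1/l) and
    phi_k = sqrt(2/l) cos(mu_k z).  Dirichlet: k = 1..K with
    phi_k = sqrt(2/l) sin(k pi z / l).  Satisfies -phi_k'' = mu_k^2 phi_k
    and <phi_j, phi_k> = delta_jk.
    """

    bc: str
    length: float
    K: int
    ks: np.ndarray  # mode indices (Neumann 0..K, Dirichlet 1..K)
    mu: np.ndarray  # spatial frequencies k pi / l

    @property
    def n_modes(self) -> int:
        return len(self.ks)

    def phi(self, k: int, z: np.ndarray) -> np.ndarray:
        """Evaluate eigenfunction of mode index ``k`` (the physical k, not position)."""
        z = np.asarray(z, dtype=float)
        l = self.length
        if self.bc == "neumann":
            if k == 0:
                return np.full_like(z, np.sqrt(1.0 / l))
            return np.sqrt(2.0 / l) * np.cos(k * np.pi * z / l)
        return np.sqrt(2.0 / l) * np.sin(k * np.pi * z / l)

    def eval_matrix(self, z: np.ndarray) -> np.ndarray:
        """(n_modes, len(z)) matrix of eigenfunction values."""
        return np.stack([self.phi(int(k), z) for k in self.ks], axis=0)

    def synthesize(self, coeffs: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Evaluate sum_k coeffs[..., k] phi_k(z); coeffs shape (..., n_modes)."""
        return np.asarray(coeffs) @ self.eval_matrix(z)


def make_basis(domain: DomainDef, K: int) -> EigenBasis:
    """Laplacian eigenbasis for ``domain`` truncated at mode index ``K``."""
    if K < 1:
        raise ValueError("truncation order K must be >= 1")
    if domain.bc == "neumann":
        ks = np.arange(0, K + 1)
    elif domain.bc == "dirichlet":
        ks = np.arange(1, K + 1)
    else:  # DomainDef validates, but keep the message local
        raise ValueError(f"unsupported boundary condition {domain.bc!r}")
    mu = ks * np.pi / domain.length
    return EigenBasis(bc=domain.bc, length=domain.length, K=K, ks=ks, mu=mu)


def project(
    f: Callable[[np.ndarray], np.ndarray] | np.ndarray,
    basis: EigenBasis,
    n_points: int = DEFAULT_QUAD_POINTS,
) -> np.ndarray:
    """Expansion coefficients f_k = <f, phi_k> by composite Simpson quadrature.

    ``f`` is a callable on [0, length] returning values of shape
    ``(len(z),)`` or ``(d, len(z))``; the result has shape ``(n_modes,)`` or
    ``(d, n_modes)`` accordingly.
    """
    z = np.linspace(0.0, basis.length, n_points)
    F = np.asarray(f(z) if callable(f) else f, dtype=float)
    if not np.all(np.isfinite(F)):
        raise ValueError("profile evaluates to NaN/inf on the domain")
    Phi = basis.eval_matrix(z)
    # integrand shape (..., n_modes, nz)
    integrand = F[..., None, :] * Phi
    return simpson(integrand, x=z, axis=-1)


@dataclass(frozen=True)
class IntegralProblem:
    """Assembled data of the linear boundary-value problem for the time-integrals.

    ``beta`` and ``stimulus_integral`` are callables on the spatial grid
    returning ``(n2, len(z))`` and ``(p, len(z))`` arrays.
    """

    D2: np.ndarray  # n2 diagonal diffusion coefficients of the c2 species
    Abar: np.ndarray  # n2 x n2, = N22 W
    Gbar: np.ndarray  # n2 x p, = B2 - N21 N11^-1 B1
    beta: Callable[[np.ndarray], np.ndarray]
    stimulus_integral: Callable[[np.ndarray], np.ndarray]
    c2_names: tuple[str, ...]
    domain: DomainDef

    @property
    def n2(self) -> int:
        return len(self.D2)


@dataclass(frozen=True)
class TimeIntegralSolution:
    """Eigenbasis coefficients of the time-integral vector plus an evaluator."""

    coeffs: np.ndarray  # n2 x n_modes
    basis: EigenBasis
    c2_names: tuple[str, ...]
    tail_bound: float

    def evaluate(self, z: np.ndarray) -> np.ndarray:
        """Time-integral profiles on ``z``; shape (n2, len(z))."""
        return self.basis.synthesize(self.coeffs, np.asarray(z, dtype=float))


def assemble_problem(
    net: ReactionNetwork,
    cert: ClassCertificate,
    eq: Equilibrium,
    initial: Callable[[np.ndarray], np.ndarray] | None = None,
    stimulus_integral: Callable[[np.ndarray], np.ndarray] | None = None,
    check_stability: bool = True,
) -> IntegralProblem:
    """Assemble the linear problem for the time-integrals of the c2 species.

    Parameters
    ----------
    initial
        Initial concentration field ``c(z, 0)`` as a callable returning an
        ``(n, len(z))`` array; ``None`` means start at equilibrium.
    stimulus_integral
        Time-integrated stimulus ``Gint(z) = int_0^inf g(z, t) dt`` as a
        callable returning ``(p, len(z))``; ``None`` means no stimulus.
    check_stability
        Verify exponential stability of the homogeneous mode (all eigenvalues
        of the reaction Jacobian have negative real part) before assembling.
    """
    if not cert.passes:
        raise ValueError(
            "network is not in the computable class: " + "; ".join(cert.failures)
        )
    if check_stability:
        spec = stability_spectrum(net, eq, [0.0])
        if not spec.all_negative_real_parts:
            raise ValueError(
                "equilibrium is not exponentially stable at mu=0; "
                "time-integrals may diverge"
            )

    c1, c2 = cert.c1_indices, cert.c2_indices
    N11 = cert.blocks["N11"].astype(float)
    N21 = cert.blocks["N21"].astype(float)
    N22 = cert.blocks["N22"].astype(float)
    W = cert.affine_params["W"]
    Abar = N22 @ W
    # Coupling of c1 into c2 through the eliminated nonlinear rates
    M = N21 @ np.linalg.inv(N11) if len(c1) else np.zeros((len(c2), 0))

    B = net.stimulus.B
    B1, B2 = B[c1, :], B[c2, :]
    Gbar = B2 - M @ B1

    cstar = eq.cstar
    c1star, c2star = cstar[c1], cstar[c2]

    def beta(z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if initial is None:
            return np.zeros((len(c2), z.size))
        c0 = np.asarray(initial(z), dtype=float)
        d2 = c0[c2, :] - c2star[:, None]
        d1 = c0[c1, :] - c1star[:, None]
        return d2 - M @ d1

    p = net.stimulus.n_channels

    def gint(z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if stimulus_integral is None:
            return np.zeros((p, z.size))
        return np.atleast_2d(np.asarray(stimulus_integral(z), dtype=float))

    return IntegralProblem(
        D2=net.diffusion[c2],
        Abar=Abar,
        Gbar=Gbar,
        beta=beta,
        stimulus_integral=gint,
        c2_names=tuple(net.species_names[i] for i in c2),
        domain=net.domain,
    )


def _mode_matrices(prob: IntegralProblem, basis: EigenBasis) -> list[np.ndarray]:
    return [prob.Abar - (mu**2) * np.diag(prob.D2) for mu in basis.mu]


def solve_modes(
    prob: IntegralProblem,
    basis: EigenBasis,
    n_points: int = DEFAULT_QUAD_POINTS,
) -> TimeIntegralSolution:
    """Solve the per-mode linear systems and return the analytic time-integrals.

    Mode k solves ``(Abar - mu_k^2 D2) a_k = f_k`` with forcing
    ``f_k = -(beta_k + Gbar Gint_k)``; the solve is refused (with the mode
    named) if any mode matrix is singular — for the Neumann k = 0 mode this is
    the exponential-stability requirement on Abar.
    """
    beta_k = project(prob.beta, basis, n_points)  # (n2, n_modes)
    gint_k = project(prob.stimulus_integral, basis, n_points)  # (p, n_modes)
    forcing = -(beta_k + prob.Gbar @ gint_k)

    coeffs = np.zeros((prob.n2, basis.n_modes))
    for k, Mk in enumerate(_mode_matrices(prob, basis)):
        fk = forcing[:, k]
        if prob.n2:
            try:
                ak = np.linalg.solve(Mk, fk)
            except np.linalg.LinAlgError:
                raise np.linalg.LinAlgError(
                    f"mode k={int(basis.ks[k])} matrix Abar - mu^2 D2 is "
                    "singular; equilibrium not exponentially stable or "
                    "zero-mode unsolvable"
                ) from None
            resid = np.linalg.norm(Mk @ ak - fk)
            scale = max(np.linalg.norm(fk), 1e-300)
            if np.linalg.norm(fk) > 0 and resid > _MODE_RESIDUAL_RTOL * scale:
                raise ArithmeticError(
                    f"mode k={int(basis.ks[k])} solve residual {resid:.2e} "
                    "exceeds tolerance"
                )
            coeffs[:, k] = ak

    norms = np.linalg.norm(coeffs, axis=0)
    peak = norms.max() if norms.size else 0.0
    tail = float(norms[-1] / peak) if peak > 0 else 0.0
    if tail > _TAIL_WARN:
        warnings.warn(
            f"series tail not converged: |a_K|/max|a_k| = {tail:.2e} "
            f"(K = {basis.K}); increase the truncation order",
            stacklevel=2,
        )
    return TimeIntegralSolution(
        coeffs=coeffs,
        basis=basis,
        c2_names=prob.c2_names,
        tail_bound=tail,
    )


def detect_nil_channels(
    prob: IntegralProblem,
    basis: EigenBasis,
    tol: float = 1e-12,
) -> list[tuple[int, int]]:
    """Input channels whose time-integral contribution to a species is nil.

    Returns pairs ``(channel q, c2 species i)`` such that row i of
    ``(Abar - mu_k^2 D2)^-1 Gbar`` has a (relatively) zero entry in column q
    for every retained mode k: the species' time-integral is structurally
    insensitive to that channel, certifying a waterbed effect up to the
    truncation order.
    """
    if prob.Gbar.shape[1] == 0 or prob.n2 == 0:
        return []
    gains = np.stack(
        [np.linalg.solve(Mk, prob.Gbar) for Mk in _mode_matrices(prob, basis)],
        axis=0,
    )  # (n_modes, n2, p)
    scale = max(np.abs(gains).max(), 1e-300)
    nil = np.all(np.abs(gains) <= tol * scale, axis=0)  # (n2, p)
    return [
        (q, i)
        for i in range(prob.n2)
        for q in range(prob.Gbar.shape[1])
        if nil[i, q]
    ]
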