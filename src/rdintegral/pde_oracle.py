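"""Numerical ground truth: method-of-lines solution of the nonlinear PDE.

The full reaction-diffusion system is discretized on a uniform 1-D grid with
second-order central differences (ghost-point mirror for Neumann boundaries,
clamped boundary nodes for Dirichlet, i.e. concentrations held at their
initial boundary values) and integrated in time with a stiff BDF scheme.
Numeric time-integrals of the deviation from equilibrium are then obtained by
trapezoidal quadrature on a dense time grid.

This module is the independent oracle for the analytic series: it never
reads any output of :mod:`rdintegral.integral_engine`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .class_checker import ClassCertificate
from .network_model import (
    Equilibrium,
    ReactionNetwork,
    evaluate_rates,
    homogeneous_equilibrium,
    reaction_jacobian,
    stability_spectrum,
)

__all__ = [
    "SemiDiscreteSystem",
    "Trajectory",
    "NumericTimeIntegral",
    "discretize",
    "simulate",
    "numeric_time_integral",
    "mass_balance_residual",
]

DEFAULT_NZ = 201
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
DEFAULT_HORIZON_MULTIPLIER = 12.0
SETTLE_RTOL = 1e-6  # settle tolerance relative to ||c*||_inf


@dataclass(frozen=True)
class SemiDiscreteSystem:
    """Spatially discretized network: grid, Laplacian stencil, sparsity."""

    net: ReactionNetwork
    z: np.ndarray  # nz uniform points on [0, length]
    laplacian: np.ndarray  # nz x nz second-difference matrix (unit diffusion)
    jac_sparsity: sp.spmatrix

    @property
    def nz(self) -> int:
        return len(self.z)


@dataclass(frozen=True)
class Trajectory:
    """A simulated space-time solution c(z, t) with settling diagnostics."""

    times: np.ndarray  # (nt,)
    states: np.ndarray  # (nt, n, nz)
    z: np.ndarray
    net: ReactionNetwork
    equilibrium: Equilibrium
    final_deviation: float
    settle_tol: float
    slowest_rate: float
    stimulus: Callable[[np.ndarray, float], np.ndarray] | None
    linearized: bool = False

    @property
    def settled(self) -> bool:
        return self.final_deviation <= self.settle_tol


@dataclass(frozen=True)
class NumericTimeIntegral:
    """Numeric profiles of int (c - c*) dt with an exponential-tail estimate."""

    z: np.ndarray
    profiles: np.ndarray  # (n, nz), one row per species (original order)
    tail_correction: float  # ||c(t_end) - c*||_inf / slowest decay rate
    species_names: tuple[str, ...]


def _laplacian_matrix(nz: int, dz: float, bc: str) -> np.ndarray:
    """Unit-diffusion second-difference matrix with the requested boundaries."""
    L = np.zeros((nz, nz))
    for i in range(1, nz - 1):
        L[i, i - 1 : i + 2] = (1.0, -2.0, 1.0)
    if bc == "neumann":
        # mirror ghost point: u[-1] = u[1] -> u'' ~ 2(u1 - u0)/dz^2
        L[0, 0], L[0, 1] = -2.0, 2.0
        L[-1, -1], L[-1, -2] = -2.0, 2.0
    # dirichlet: boundary rows stay zero (values clamped by the integrator)
    return L / dz**2


def discretize(net: ReactionNetwork, nz: int = DEFAULT_NZ) -> SemiDiscreteSystem:
    """Build the semi-discrete system on ``nz`` uniform grid points (nz >= 41)."""
    if nz < 41:
        raise ValueError("nz must be >= 41 for a trustworthy oracle")
    length, bc = net.domain.length, net.domain.bc
    z = np.linspace(0.0, length, nz)
    dz = z[1] - z[0]
    L = _laplacian_matrix(nz, dz, bc)

    n = net.n_species
    # reaction coupling pattern between species at the same grid point
    S = np.eye(n, dtype=bool)
    for rxn in net.reactions:
        rows = np.flatnonzero(rxn.stoich != 0)
        for i in rows:
            for j in rxn.depends_on:
                S[i, j] = True
    if net.stimulus.n_channels:
        S |= np.diag(np.any(net.stimulus.B != 0.0, axis=1))
    tri = sp.diags(
        [np.ones(nz - 1), np.ones(nz), np.ones(nz - 1)], offsets=(-1, 0, 1)
    )
    sparsity = sp.kron(sp.csr_matrix(S.astype(float)), sp.identity(nz)) + sp.kron(
        sp.identity(n), tri
    )
    return SemiDiscreteSystem(net=net, z=z, laplacian=L, jac_sparsity=sparsity.tocsr())


def _auto_t_end(
    net: ReactionNetwork,
    eq: Equilibrium,
    stimulus,
    multiplier: float,
) -> float:
    mu1 = np.pi / net.domain.length
    spec = stability_spectrum(net, eq, [0.0, mu1])
    if not spec.all_negative_real_parts:
        raise ValueError(
            "equilibrium is not exponentially stable; cannot choose a "
            "settling horizon automatically"
        )
    t_end = multiplier / spec.slowest_rate
    hint = getattr(stimulus, "t_end_hint", 0.0)
    return t_end + float(hint)


def _time_grid(t_end: float, stimulus, n_t: int) -> np.ndarray:
    t = np.linspace(0.0, t_end, n_t)
    t0 = getattr(stimulus, "t0", None)
    sigma_t = getattr(stimulus, "sigma_t", None)
    if t0 is not None and sigma_t is not None:
        # refine around the pulse support for accurate time quadrature
        lo, hi = max(0.0, t0 - 5 * sigma_t), min(t_end, t0 + 5 * sigma_t)
        t = np.union1d(t, np.linspace(lo, hi, n_t // 2))
    return t


def simulate(
    sys: SemiDiscreteSystem,
    initial: Callable[[np.ndarray], np.ndarray] | np.ndarray | None = None,
    stimulus: Callable[[np.ndarray, float], np.ndarray] | None = None,
    t_end: float | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    equilibrium: Equilibrium | None = None,
    horizon_multiplier: float = DEFAULT_HORIZON_MULTIPLIER,
    n_t: int = 4001,
    linearize: bool = False,
) -> Trajectory:
    """Integrate the (nonlinear or equilibrium-linearized) PDE to ``t_end``.

    Parameters
    ----------
    initial
        Initial concentration field: callable ``z -> (n, len(z))``, an
        ``(n, nz)`` array, or ``None`` for the homogeneous equilibrium.
    stimulus
        Spatiotemporal input ``g(z, t) -> (p, len(z))`` for the network's
        stimulus channels; ``None`` for no input.  A ``t_end_hint`` attribute
        on the callable extends the automatic horizon past the pulse.
    t_end
        Final time; ``None`` selects ``horizon_multiplier`` slowest reaction
        time-constants (from the mu = 0 and first-harmonic spectra) plus the
        stimulus duration.
    linearize
        Replace the reaction term by its Jacobian linearization at the
        equilibrium (cross-check mode; the default solves the full
        nonlinear dynamics).
    """
    net = sys.net
    n, nz = net.n_species, sys.nz
    if equilibrium is None:
        equilibrium = homogeneous_equilibrium(net)
    cstar = equilibrium.cstar

    if initial is None:
        u0 = np.tile(cstar[:, None], (1, nz))
    elif callable(initial):
        u0 = np.asarray(initial(sys.z), dtype=float)
    else:
        u0 = np.asarray(initial, dtype=float)
    if u0.shape != (n, nz):
        raise ValueError(f"initial field must have shape {(n, nz)}")

    if t_end is None:
        t_end = _auto_t_end(net, equilibrium, stimulus, horizon_multiplier)

    D = net.diffusion
    B = net.stimulus.B
    has_stim = stimulus is not None and B.shape[1] > 0
    LapT = sys.laplacian.T
    if linearize:
        Jr = reaction_jacobian(net, cstar)

    clamp = net.domain.bc == "dirichlet"

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        u = y.reshape(n, nz)
        if linearize:
            du = Jr @ (u - cstar[:, None])
        else:
            du = net.N @ evaluate_rates(net, u)
        if has_stim:
            g = np.atleast_2d(np.asarray(stimulus(sys.z, t), dtype=float))
            du = du + B @ g
        du = du + D[:, None] * (u @ LapT)
        if clamp:
            du[:, 0] = 0.0
            du[:, -1] = 0.0
        return du.ravel()

    t_eval = _time_grid(t_end, stimulus, n_t)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        u0.ravel(),
        method="BDF",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        jac_sparsity=sys.jac_sparsity,
    )
    if not sol.success:
        raise RuntimeError(f"stiff integrator failed: {sol.message}")

    states = sol.y.T.reshape(len(sol.t), n, nz)
    if states.min() < -100 * atol:
        warnings.warn(
            f"concentration undershoot below -100*atol (min {states.min():.3g}): "
            "model entered a nonphysical regime",
            stacklevel=2,
        )
    final_dev = float(np.max(np.abs(states[-1] - cstar[:, None])))
    settle_tol = SETTLE_RTOL * float(np.max(np.abs(cstar))) if np.any(cstar) else atol
    spec = stability_spectrum(net, equilibrium, [0.0, np.pi / net.domain.length])
    return Trajectory(
        times=sol.t,
        states=states,
        z=sys.z,
        net=net,
        equilibrium=equilibrium,
        final_deviation=final_dev,
        settle_tol=settle_tol,
        slowest_rate=spec.slowest_rate,
        stimulus=stimulus,
        linearized=linearize,
    )


def numeric_time_integral(traj: Trajectory) -> NumericTimeIntegral:
    """Trapezoidal time-quadrature of the deviation from equilibrium.

    Requires a settled trajectory (final deviation at or below the settle
    tolerance); the neglected exponential tail is estimated as the final
    deviation divided by the slowest decay rate and reported separately.
    """
    if not traj.settled:
        raise RuntimeError(
            f"trajectory not settled (final deviation {traj.final_deviation:.3g} "
            f"> tolerance {traj.settle_tol:.3g}); increase t_end"
        )
    dev = traj.states - traj.equilibrium.cstar[None, :, None]
    profiles = np.trapezoid(dev, traj.times, axis=0)
    tail = traj.final_deviation / traj.slowest_rate
    return NumericTimeIntegral(
        z=traj.z,
        profiles=profiles,
        tail_correction=float(tail),
        species_names=traj.net.species_names,
    )


def mass_balance_residual(
    traj: Trajectory, cert: ClassCertificate
) -> np.ndarray:
    """Residual of the integrated balance for x = c2 - N21 N11^-1 c1.

    For each c2 species row the combination's total mass obeys

        d/dt int x_i dz = int [N22 (w + W c2) + Gbar g]_i dz

    under Neumann boundaries (diffusive boundary fluxes vanish).  Returns the
    running residual ``max_i |M_i(t) - M_i(0) - int_0^t predicted dt'|`` on
    the trajectory's time grid; for Dirichlet boundaries the unaccounted
    boundary flux shows up here.
    """
    net = traj.net
    c1, c2 = cert.c1_indices, cert.c2_indices
    N11 = cert.blocks["N11"].astype(float)
    N21 = cert.blocks["N21"].astype(float)
    N22 = cert.blocks["N22"].astype(float)
    w, W = cert.affine_params["w"], cert.affine_params["W"]
    M = N21 @ np.linalg.inv(N11) if len(c1) else np.zeros((len(c2), 0))
    B = net.stimulus.B
    Gbar = B[c2, :] - M @ B[c1, :]

    z, t = traj.z, traj.times
    u1 = traj.states[:, c1, :]  # (nt, n1, nz)
    u2 = traj.states[:, c2, :]
    x = u2 - np.einsum("ij,tjk->tik", M, u1)
    mass = np.trapezoid(x, z, axis=2)  # (nt, n2)

    pred = np.einsum("ij,tjk->tik", N22, w[None, :, None] + np.einsum(
        "ij,tjk->tik", W, u2
    ))
    if traj.stimulus is not None and B.shape[1]:
        g = np.stack(
            [np.atleast_2d(traj.stimulus(z, tk)) for tk in t], axis=0
        )  # (nt, p, nz)
        pred = pred + np.einsum("ij,tjk->tik", Gbar, g)
    rate = np.trapezoid(pred, z, axis=2)  # (nt, n2)

    # higher-order cumulative quadrature so the diagnostic's own error
    # stays below the integrator's
    from scipy.integrate import cumulative_simpson

    cum = cumulative_simpson(rate, x=t, axis=0, initial=0.0)
    return np.max(np.abs(mass - mass[0] - cum), axis=1)
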