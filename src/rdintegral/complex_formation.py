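"""The canonical complex-formation mechanism and its spatial-filter analysis.

An immobile binding partner R (a receptor, or a sequestering inhibitor) binds
a diffusible ligand L to form an immobile complex C:

    dR/dt = b_R - d_R R - v1(R, L, C)
    dL/dt = b_L - d_L L - v1(R, L, C) + g(z, t) + D_L d2L/dz2
    dC/dt = v1(R, L, C)

with net binding rate v1 = h(R, L) - k_r C, where h is a sigmoidal
nonlinearity (Hill in the ligand by default) and k_r the dissociation rate
constant.  R and L are synthesized at constant rates b_R, b_L and degraded
linearly with constants d_R, d_L.  The network satisfies the structural
conditions (C is the only species reacting purely nonlinearly, and there is
exactly one nonlinear reaction), so the time-integrals of R and L are exact:

* an initial bump q(z) on the complex gives y_R(z) = q(z)/d_R — pointwise,
  unfiltered — while y_L is the mode-wise attenuated series
  a_k = q_k / (d_L + D_L mu_k^2);
* a transient ligand influx with time-integral G(z) gives y_R identically
  zero (the waterbed effect: R's excursions above and below equilibrium
  cancel exactly) and y_L with a_k = G_k / (d_L + D_L mu_k^2).

Diffusion of the ligand therefore acts as a spatial low-pass filter with
frequency response H(mu) = d_L / (d_L + D_L mu^2); its cutoff (50%
attenuation) sits at mu_c = sqrt(d_L / D_L), the reciprocal of the ligand's
diffusion length.  All analytic results depend only on the network structure,
not on the functional form of h.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .integral_engine import EigenBasis, make_basis, project
from .network_model import (
    DomainDef,
    Equilibrium,
    ReactionNetwork,
    build_network,
)

__all__ = [
    "ComplexFormParams",
    "FilterSpec",
    "PerturbationIntegrals",
    "InfluxIntegrals",
    "network_spec",
    "make_complexform",
    "closed_form_equilibrium",
    "integral_spatial_perturbation",
    "integral_influx",
    "filter_spec",
    "attenuation_report",
    "default_perturbation_profile",
    "default_influx_pulse",
]


@dataclass(frozen=True)
class ComplexFormParams:
    """Kinetic and geometric parameters of the complex-formation network.

    Rates are in concentration/time (``b_R``, ``b_L``, ``k_on``) or 1/time
    (``d_R``, ``d_L``, ``k_r``); ``D_L`` is the ligand diffusion coefficient
    (length^2/time); ``K`` and ``hill`` shape the sigmoidal binding
    h(R, L) = k_on R L^hill / (K^hill + L^hill); ``length`` is the domain
    size.  Defaults put the dominant harmonics of a sigma = length/10
    Gaussian bump astride the filter cutoff so spatial filtering is visible.
    """

    b_R: float = 1.0
    b_L: float = 1.0
    d_R: float = 1.0
    d_L: float = 1.0
    D_L: float = 5e-3
    k_r: float = 1.0
    k_on: float = 5.0
    K: float = 1.0
    hill: float = 2.0
    length: float = 1.0
    binding_preset: str = "hill_binding"

    def __post_init__(self) -> None:
        for name in ("b_R", "b_L", "d_R", "d_L", "D_L", "k_r", "k_on", "K", "length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be > 0")
        if self.hill < 1:
            raise ValueError("hill exponent must be >= 1")

    def h(self, R: np.ndarray, L: np.ndarray) -> np.ndarray:
        """The sigmoidal binding nonlinearity h(R, L)."""
        L = np.maximum(np.asarray(L, dtype=float), 0.0)
        if self.binding_preset == "mass_action_binding":
            return self.k_on * R * L
        return self.k_on * R * L**self.hill / (self.K**self.hill + L**self.hill)


def network_spec(p: ComplexFormParams) -> dict:
    """The declarative network description for :func:`make_complexform`."""
    binding_params = {
        "k_on": p.k_on, "K": p.K, "hill": p.hill, "k_r": p.k_r,
        "receptor": "R", "ligand": "L", "complex": "C",
    }
    if p.binding_preset == "mass_action_binding":
        binding_params = {
            "k_on": p.k_on, "k_r": p.k_r,
            "receptor": "R", "ligand": "L", "complex": "C",
        }
    eq = closed_form_equilibrium(p)
    return {
        "species": [
            {"name": "R", "diffusion": 0.0, "initial": float(eq.cstar[0])},
            {"name": "L", "diffusion": p.D_L, "initial": float(eq.cstar[1])},
            {"name": "C", "diffusion": 0.0, "initial": float(eq.cstar[2])},
        ],
        "reactions": [
            {
                "name": "binding",
                "stoich": {"R": -1, "L": -1, "C": 1},
                "kind": "nonlinear",
                "nonlinear": {"preset": p.binding_preset, "params": binding_params},
            },
            {
                "name": "turnover_R",
                "stoich": {"R": 1},
                "kind": "affine",
                "affine": {"const": p.b_R, "coeffs": {"R": -p.d_R}},
            },
            {
                "name": "turnover_L",
                "stoich": {"L": 1},
                "kind": "affine",
                "affine": {"const": p.b_L, "coeffs": {"L": -p.d_L}},
            },
        ],
        "stimulus": {"matrix": {"L": [1.0]}, "channels": [{"preset": "none"}]},
        "domain": {"length": p.length, "bc": "neumann"},
    }


def make_complexform(p: ComplexFormParams | None = None) -> ReactionNetwork:
    """Build the three-species complex-formation network (one ligand channel)."""
    return build_network(network_spec(p or ComplexFormParams()))


def closed_form_equilibrium(p: ComplexFormParams) -> Equilibrium:
    """The unique homogeneous equilibrium: R* = b_R/d_R, L* = b_L/d_L, C* = h*/k_r."""
    Rs = p.b_R / p.d_R
    Ls = p.b_L / p.d_L
    Cs = float(p.h(Rs, Ls)) / p.k_r
    return Equilibrium(cstar=np.array([Rs, Ls, Cs]), residual=0.0)


def _filtered_series(
    p: ComplexFormParams,
    source: Callable[[np.ndarray], np.ndarray],
    K: int,
) -> tuple[np.ndarray, EigenBasis, Callable[[np.ndarray], np.ndarray]]:
    basis = make_basis(DomainDef(length=p.length, bc="neumann"), K)
    src_k = project(source, basis)
    coeffs = src_k / (p.d_L + p.D_L * basis.mu**2)

    def y(z: np.ndarray) -> np.ndarray:
        return basis.synthesize(coeffs, np.asarray(z, dtype=float))

    return coeffs, basis, y


@dataclass(frozen=True)
class PerturbationIntegrals:
    """Time-integrals of R and L after an initial bump q(z) on the complex."""

    y_R: Callable[[np.ndarray], np.ndarray]  # q(z)/d_R, pointwise exact
    y_L: Callable[[np.ndarray], np.ndarray]  # filtered series
    ligand_coeffs: np.ndarray
    basis: EigenBasis


@dataclass(frozen=True)
class InfluxIntegrals:
    """Time-integrals of R and L under a transient ligand influx."""

    y_R: Callable[[np.ndarray], np.ndarray]  # identically zero (waterbed)
    y_L: Callable[[np.ndarray], np.ndarray]
    ligand_coeffs: np.ndarray
    basis: EigenBasis


def integral_spatial_perturbation(
    p: ComplexFormParams,
    q: Callable[[np.ndarray], np.ndarray],
    K: int = 64,
) -> PerturbationIntegrals:
    """Closed-form time-integrals for an initial perturbation q(z) on the complex.

    The immobile partner sees the perturbation unfiltered, y_R(z) = q(z)/d_R;
    the ligand's integral is the low-pass-filtered series with coefficients
    q_k / (d_L + D_L mu_k^2).
    """
    coeffs, basis, y_L = _filtered_series(p, q, K)

    def y_R(z: np.ndarray) -> np.ndarray:
        return np.asarray(q(np.asarray(z, dtype=float)), dtype=float) / p.d_R

    return PerturbationIntegrals(y_R=y_R, y_L=y_L, ligand_coeffs=coeffs, basis=basis)


def integral_influx(
    p: ComplexFormParams,
    G: Callable[[np.ndarray], np.ndarray],
    K: int = 64,
) -> InfluxIntegrals:
    """Time-integrals under a transient ligand influx with time-integral G(z).

    The immobile partner's integral is *identically zero at every point* —
    the waterbed effect: any peak of R above equilibrium is exactly
    compensated by a valley below it.  The ligand integral is the filtered
    series G_k / (d_L + D_L mu_k^2).
    """
    coeffs, basis, y_L = _filtered_series(p, G, K)

    def y_R(z: np.ndarray) -> np.ndarray:
        return np.zeros(np.asarray(z, dtype=float).shape)

    return InfluxIntegrals(y_R=y_R, y_L=y_L, ligand_coeffs=coeffs, basis=basis)


@dataclass(frozen=True)
class FilterSpec:
    """The ligand's spatial low-pass filter: response, cutoff, diffusion length."""

    attenuation: Callable[[np.ndarray], np.ndarray]  # H(mu) = d_L/(d_L + D_L mu^2)
    cutoff: float  # mu_c with H(mu_c) = 1/2, = sqrt(d_L/D_L)
    diffusion_length: float  # per the selected lifetime convention
    convention: str


def filter_spec(p: ComplexFormParams, convention: str = "rate") -> FilterSpec:
    """Frequency response of the ligand time-integral filter.

    ``convention`` selects the lifetime entering the diffusion length
    sqrt(D_L * tau): ``"rate"`` uses tau = 1/d_L (so cutoff * length = 1
    exactly), ``"halflife"`` uses tau = ln(2)/d_L.
    """
    if convention not in ("rate", "halflife"):
        raise ValueError("convention must be 'rate' or 'halflife'")

    def H(mu: np.ndarray) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        return p.d_L / (p.d_L + p.D_L * mu**2)

    tau = 1.0 / p.d_L if convention == "rate" else np.log(2.0) / p.d_L
    return FilterSpec(
        attenuation=H,
        cutoff=float(np.sqrt(p.d_L / p.D_L)),
        diffusion_length=float(np.sqrt(p.D_L * tau)),
        convention=convention,
    )


def attenuation_report(
    p: ComplexFormParams, harmonics: list[int] | None = None
) -> pd.DataFrame:
    """Per-harmonic attenuation table for the domain's Neumann modes.

    Columns: harmonic index k, spatial frequency mu_k = k pi / length, the
    filter response H(mu_k), and the percent attenuation 100 (1 - H).
    """
    if harmonics is None:
        harmonics = list(range(0, 9))
    spec = filter_spec(p)
    rows = []
    for k in harmonics:
        mu = k * np.pi / p.length
        H = float(spec.attenuation(mu))
        rows.append(
            {"k": k, "mu": mu, "H": H, "percent_attenuation": 100.0 * (1.0 - H)}
        )
    return pd.DataFrame(rows)


def default_perturbation_profile(p: ComplexFormParams):
    """The stock experiment: a Gaussian bump on the complex, amplitude C*/2."""
    from .fixtures import gaussian_profile

    Cs = closed_form_equilibrium(p).cstar[2]
    return gaussian_profile(a=0.5 * Cs, z0=p.length / 2.0, sigma=p.length / 10.0)


def default_influx_pulse(p: ComplexFormParams):
    """The stock influx: a spatiotemporal Gaussian pulse of ligand, amplitude L*/2.

    Returns ``(g, G)`` — the pulse and its exact time-integral profile.
    """
    from .fixtures import gaussian_pulse

    Ls = closed_form_equilibrium(p).cstar[1]
    sigma_t = 0.5 / p.d_L
    return gaussian_pulse(
        a=0.5 * Ls,
        z0=p.length / 2.0,
        sigma_z=p.length / 10.0,
        t0=3.0 * sigma_t,
        sigma_t=sigma_t,
    )
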