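"""Shared fixtures: the worked example network, scenarios, and cached simulations.

The stiff PDE simulations are session-scoped so the oracle trajectories are
computed once and reused by every test that inspects them.
"""

from __future__ import annotations

import numpy as np
import pytest

import rdintegral as rd
from rdintegral.complex_formation import (
    ComplexFormParams,
    default_influx_pulse,
    default_perturbation_profile,
)
from rdintegral.network_model import ReactionDef, ReactionNetwork, SpeciesDef, StimulusDef


@pytest.fixture(scope="session")
def params() -> ComplexFormParams:
    return ComplexFormParams()


@pytest.fixture(scope="session")
def complexform(params):
    return rd.make_complexform(params)


@pytest.fixture(scope="session")
def cert(complexform):
    return rd.check_conditions(complexform)


@pytest.fixture(scope="session")
def equilibrium(complexform):
    return rd.homogeneous_equilibrium(complexform)


def perturbed_initial(net, eq, species: str, bump):
    """Initial field: equilibrium everywhere plus a bump on one species."""
    idx = net.species_index(species)

    def initial(z):
        z = np.asarray(z, dtype=float)
        u0 = np.tile(eq.cstar[:, None], (1, z.size))
        u0[idx] += bump(z)
        return u0

    return initial


@pytest.fixture(scope="session")
def perturbation_bump(params):
    return default_perturbation_profile(params)


@pytest.fixture(scope="session")
def perturb_traj(complexform, equilibrium, perturbation_bump):
    """Oracle trajectory for the stock Gaussian perturbation on the complex."""
    sys = rd.discretize(complexform, nz=201)
    initial = perturbed_initial(complexform, equilibrium, "C", perturbation_bump)
    return rd.simulate(
        sys, initial=initial, equilibrium=equilibrium, horizon_multiplier=16.0
    )


@pytest.fixture(scope="session")
def perturb_numeric(perturb_traj):
    return rd.numeric_time_integral(perturb_traj)


@pytest.fixture(scope="session")
def influx_pulse(params):
    g1, G1 = default_influx_pulse(params)

    def g(z, t):
        return g1(z, t)

    g.t0 = g1.t0
    g.sigma_t = g1.sigma_t
    g.t_end_hint = g1.t_end_hint
    return g, G1


@pytest.fixture(scope="session")
def influx_traj(complexform, equilibrium, influx_pulse):
    """Oracle trajectory for the stock transient ligand influx."""
    g, _ = influx_pulse
    sys = rd.discretize(complexform, nz=201)
    return rd.simulate(
        sys, stimulus=g, equilibrium=equilibrium, horizon_multiplier=16.0
    )


@pytest.fixture(scope="session")
def influx_numeric(influx_traj):
    return rd.numeric_time_integral(influx_traj)


# ---------------------------------------------------------------------------
# network permutation helper (checker invariance tests)
# ---------------------------------------------------------------------------

def permute_network(net: ReactionNetwork, seed: int) -> ReactionNetwork:
    """Reorder species and reactions with a seeded shuffle, rewiring indices."""
    rng = np.random.default_rng(seed)
    n, m = net.n_species, net.n_reactions
    sperm = rng.permutation(n)  # new position -> old index
    rperm = rng.permutation(m)
    new_of_old = np.empty(n, dtype=int)
    new_of_old[sperm] = np.arange(n)

    species = tuple(net.species[i] for i in sperm)
    reactions = []
    for j in rperm:
        old = net.reactions[j]
        stoich = old.stoich[sperm]
        if old.kind == "affine":
            coeffs = {int(new_of_old[i]): v for i, v in old.affine_coeffs.items()}
            reactions.append(
                ReactionDef(
                    name=old.name, stoich=stoich, kind="affine",
                    affine_const=old.affine_const, affine_coeffs=coeffs,
                )
            )
        else:
            fn = old.rate_fn

            def wrapped(c, _fn=fn, _map=new_of_old.copy()):
                # c is in the new order; _map sends old indices to new ones
                return _fn(np.asarray(c, dtype=float)[_map])

            deps = frozenset(int(new_of_old[i]) for i in old.depends_on)
            reactions.append(
                ReactionDef(
                    name=old.name, stoich=stoich, kind="nonlinear",
                    rate_fn=wrapped, depends_on=deps,
                )
            )
    N = np.stack([r.stoich for r in reactions], axis=1) if reactions else np.zeros(
        (n, 0), dtype=int
    )
    return ReactionNetwork(
        species=species,
        reactions=tuple(reactions),
        N=N,
        stimulus=StimulusDef(B=net.stimulus.B[sperm, :], channels=net.stimulus.channels),
        domain=net.domain,
    )
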