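"""Synthetic inputs: spatial profiles, spatiotemporal pulses, example networks.

Everything here is generated programmatically and deterministically — the
named example networks are fixed, and :func:`randomized_network` is a pure
function of its seed — so test inputs are bit-stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .network_model import (
    Equilibrium,
    NetworkSpecError,
    ReactionNetwork,
    build_network,
)

__all__ = [
    "gaussian_profile",
    "gaussian_pulse",
    "ScenarioSpec",
    "FixtureNetwork",
    "example_networks",
    "randomized_network",
]


def gaussian_profile(
    a: float, z0: float, sigma: float, domain=None
) -> Callable[[np.ndarray], np.ndarray]:
    """Gaussian bump ``a exp(-(z - z0)^2 / (2 sigma^2))`` on the domain.

    The closed-form mass is ``a sigma sqrt(2 pi)`` when the bump's 6-sigma
    support fits inside the domain.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")

    def profile(z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return a * np.exp(-((z - z0) ** 2) / (2.0 * sigma**2))

    profile.mass = a * sigma * np.sqrt(2.0 * np.pi)  # type: ignore[attr-defined]
    return profile


def gaussian_pulse(
    a: float, z0: float, sigma_z: float, t0: float, sigma_t: float
) -> tuple[Callable[[np.ndarray, float], np.ndarray], Callable[[np.ndarray], np.ndarray]]:
    """Spatiotemporal Gaussian pulse and its exact time-integral profile.

    Returns ``(g, G)`` with ``g(z, t) = a exp(-(z-z0)^2/(2 sigma_z^2))
    exp(-(t-t0)^2/(2 sigma_t^2))`` (shape ``(1, len(z))``, a single input
    channel) and ``G(z) = a sigma_t sqrt(2 pi) exp(-(z-z0)^2/(2 sigma_z^2))``.
    Requires ``t0 >= 3 sigma_t`` so the pulse mass at t < 0 is negligible.
    """
    if sigma_t <= 0 or sigma_z <= 0:
        raise ValueError("sigma_z and sigma_t must be > 0")
    if t0 < 3.0 * sigma_t:
        raise ValueError("t0 must be >= 3*sigma_t (transient pulse)")

    space = gaussian_profile(a, z0, sigma_z)

    def g(z: np.ndarray, t: float) -> np.ndarray:
        return space(z)[None, :] * np.exp(-((t - t0) ** 2) / (2.0 * sigma_t**2))

    def G(z: np.ndarray) -> np.ndarray:
        return sigma_t * np.sqrt(2.0 * np.pi) * space(z)

    # hints used by the oracle to extend/refine its time grid
    g.t0 = t0  # type: ignore[attr-defined]
    g.sigma_t = sigma_t  # type: ignore[attr-defined]
    g.t_end_hint = t0 + 6.0 * sigma_t  # type: ignore[attr-defined]
    return g, G


@dataclass(frozen=True)
class ScenarioSpec:
    """A perturbation experiment: who is perturbed and with what profile.

    ``kind = "perturbation"`` applies an initial spatial bump to ``target``
    (a species name) with the other species at equilibrium and no stimulus;
    ``kind = "influx"`` starts everything at equilibrium and drives stimulus
    channel ``channel`` with a transient spatiotemporal pulse.
    """

    kind: str  # "perturbation" | "influx"
    target: str | None = None
    channel: int = 0
    profile: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("perturbation", "influx"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "perturbation" and self.target is None:
            raise ValueError("perturbation scenarios must name a target species")

    def build(self, net: ReactionNetwork, eq: Equilibrium):
        """Materialise ``(initial, stimulus, stimulus_integral)`` for a network."""
        cstar = eq.cstar
        if self.kind == "perturbation":
            idx = net.species_index(self.target)
            bump = gaussian_profile(
                self.profile["a"], self.profile["z0"], self.profile["sigma"]
            )

            def initial(z: np.ndarray) -> np.ndarray:
                z = np.asarray(z, dtype=float)
                u0 = np.tile(cstar[:, None], (1, z.size))
                u0[idx] += bump(z)
                return u0

            return initial, None, None
        g1, G1 = gaussian_pulse(
            self.profile["a"],
            self.profile["z0"],
            self.profile["sigma_z"],
            self.profile["t0"],
            self.profile["sigma_t"],
        )
        p = net.stimulus.n_channels
        q = self.channel
        if not 0 <= q < p:
            raise ValueError(f"channel {q} out of range for {p} channels")

        def g(z: np.ndarray, t: float) -> np.ndarray:
            out = np.zeros((p, np.asarray(z).size))
            out[q] = g1(z, t)[0]
            return out

        g.t0 = g1.t0  # type: ignore[attr-defined]
        g.sigma_t = g1.sigma_t  # type: ignore[attr-defined]
        g.t_end_hint = g1.t_end_hint  # type: ignore[attr-defined]

        def G(z: np.ndarray) -> np.ndarray:
            out = np.zeros((p, np.asarray(z).size))
            out[q] = G1(z)
            return out

        return None, g, G


@dataclass(frozen=True)
class FixtureNetwork:
    """An example network annotated with its expected class verdict.

    ``spec`` is the declarative description when the network is expressible
    in the YAML schema (``None`` for fixtures with programmatic rate
    functions, which cannot be serialized).
    """

    net: ReactionNetwork
    expect_pass: bool
    note: str
    spec: dict | None = None


def _complexform_spec(
    D_C: float = 0.0, extra_reactions: list | None = None
) -> dict:
    # default worked-example parameters; variants mutate the declarative spec
    from .complex_formation import ComplexFormParams, network_spec

    spec = network_spec(ComplexFormParams())
    spec["species"][2]["diffusion"] = D_C
    if extra_reactions:
        spec["reactions"].extend(extra_reactions)
    return spec


def _double_binding_spec() -> dict:
    """One diffusible ligand binding two immobile receptors (two nonlinear rates)."""
    def binding(name, receptor, complex_):
        return {
            "name": name,
            "stoich": {receptor: -1, "L": -1, complex_: 1},
            "kind": "nonlinear",
            "nonlinear": {
                "preset": "hill_binding",
                "params": {
                    "k_on": 2.0, "K": 1.0, "hill": 2.0, "k_r": 1.0,
                    "receptor": receptor, "ligand": "L", "complex": complex_,
                },
            },
        }

    return {
        "species": [
            {"name": "R1", "diffusion": 0.0, "initial": 1.0},
            {"name": "R2", "diffusion": 0.0, "initial": 1.0},
            {"name": "L", "diffusion": 1e-2, "initial": 1.0},
            {"name": "C1", "diffusion": 0.0, "initial": 1.0},
            {"name": "C2", "diffusion": 0.0, "initial": 1.0},
        ],
        "reactions": [
            binding("binding1", "R1", "C1"),
            binding("binding2", "R2", "C2"),
            {"name": "turnover_R1", "stoich": {"R1": 1}, "kind": "affine",
             "affine": {"const": 1.0, "coeffs": {"R1": -1.0}}},
            {"name": "turnover_R2", "stoich": {"R2": 1}, "kind": "affine",
             "affine": {"const": 0.8, "coeffs": {"R2": -0.8}}},
            {"name": "turnover_L", "stoich": {"L": 1}, "kind": "affine",
             "affine": {"const": 1.0, "coeffs": {"L": -1.0}}},
        ],
        "stimulus": {"matrix": {"L": [1.0]}, "channels": [{"preset": "none"}]},
        "domain": {"length": 1.0, "bc": "neumann"},
    }


def example_networks() -> dict[str, FixtureNetwork]:
    """Named fixture networks spanning passing and failing topologies."""
    out: dict[str, FixtureNetwork] = {}

    spec = _complexform_spec()
    out["complexform"] = FixtureNetwork(
        net=build_network(spec),
        expect_pass=True,
        note="immobile receptor + diffusible ligand -> immobile complex; "
        "the canonical passing topology",
        spec=spec,
    )
    spec = _complexform_spec(
        extra_reactions=[
            {
                "name": "deg_C",
                "stoich": {"C": -1},
                "kind": "affine",
                "affine": {"const": 0.0, "coeffs": {"C": 0.5}},
            }
        ]
    )
    out["complexform_complex_degradation"] = FixtureNetwork(
        net=build_network(spec),
        expect_pass=False,
        note="linear degradation of the complex links it to an affine rate: "
        "no species reacts only in nonlinear reactions (C2 fails)",
        spec=spec,
    )
    spec = _complexform_spec(D_C=1e-3)
    out["complexform_diffusing_complex"] = FixtureNetwork(
        net=build_network(spec),
        expect_pass=False,
        note="the complex diffuses: C1 fails",
        spec=spec,
    )
    spec = _double_binding_spec()
    out["double_binding"] = FixtureNetwork(
        net=build_network(spec),
        expect_pass=True,
        note="two nonlinear bindings with two immobile complexes (n1 = m1 = 2)",
        spec=spec,
    )

    shared = _complexform_spec()
    shared["reactions"].append(
        {
            "name": "self_limited_decay_C",
            "stoich": {"C": -1},
            "kind": "nonlinear",
            "nonlinear": {
                "preset": "custom",
                "rate_fn": _saturating_decay,
                "depends_on": ["C"],
            },
        }
    )
    out["double_nonlinear_shared_complex"] = FixtureNetwork(
        net=build_network(shared),
        expect_pass=False,
        note="one immobile complex shared by two nonlinear reactions "
        "(n1 = 1 < m1 = 2): C2 fails",
    )
    return out


def _saturating_decay(c: np.ndarray) -> np.ndarray:
    # saturating self-limited decay of the third species
    x = np.maximum(c[2], 0.0)
    return 0.5 * x**2 / (1.0 + x**2)


def randomized_network(seed: int, n2: int = 3, m2: int | None = None) -> ReactionNetwork:
    """A random network in the computable class *by construction*.

    An affine subnetwork of ``n2`` diffusible species with diagonally dominant
    (hence Hurwitz) first-order kinetics is coupled to one nondiffusive
    species through a single saturating nonlinear reaction, guaranteeing
    C1/C2 with n1 = m1 = 1.
    """
    if m2 is None:
        m2 = n2
    if m2 != n2:
        raise NetworkSpecError(
            "randomized fixtures use one affine turnover reaction per species"
        )
    rng = np.random.default_rng(seed)
    names = [f"s{i}" for i in range(n2)]
    species = [
        {"name": names[i], "diffusion": float(rng.uniform(1e-3, 2e-2)), "initial": 1.0}
        for i in range(n2)
    ]
    species.append({"name": "x", "diffusion": 0.0, "initial": 0.5})

    reactions = []
    d = rng.uniform(0.6, 1.6, size=n2)
    w = rng.uniform(0.5, 1.5, size=n2)
    for i in range(n2):
        coeffs = {names[i]: float(-d[i])}
        for j in range(n2):
            if j != i and rng.random() < 0.5:
                # strictly diagonally dominant rows keep W (and N22 W) Hurwitz
                coeffs[names[j]] = float(
                    rng.uniform(-1.0, 1.0) * d[i] / (2.0 * n2)
                )
        reactions.append(
            {
                "name": f"turnover_{names[i]}",
                "stoich": {names[i]: 1},
                "kind": "affine",
                "affine": {"const": float(w[i]), "coeffs": coeffs},
            }
        )

    a, b = rng.choice(n2, size=2, replace=False)
    k_bind = float(rng.uniform(0.05, 0.15))
    k_x = float(rng.uniform(0.8, 1.2))
    ia, ib = int(a), int(b)

    def bind_rate(c: np.ndarray, _ia=ia, _ib=ib, _k=k_bind, _kx=k_x) -> np.ndarray:
        sa = np.maximum(c[_ia], 0.0)
        sb = np.maximum(c[_ib], 0.0)
        return _k * sa * sb**2 / (1.0 + sb**2) - _kx * c[n2]

    reactions.append(
        {
            "name": "bind_x",
            "stoich": {names[ia]: -1, names[ib]: -1, "x": 1},
            "kind": "nonlinear",
            "nonlinear": {
                "preset": "custom",
                "rate_fn": bind_rate,
                "depends_on": [names[ia], names[ib], "x"],
            },
        }
    )
    spec = {
        "species": species,
        "reactions": reactions,
        "stimulus": {
            "matrix": {names[0]: [1.0]},
            "channels": [{"preset": "none"}],
        },
        "domain": {"length": 1.0, "bc": "neumann"},
    }
    return build_network(spec)
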