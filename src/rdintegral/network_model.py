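"""Reaction-diffusion network model: structure, rates, equilibrium, stability.

A network couples ``n`` species to ``m`` reactions through a stoichiometric
matrix ``N`` (columns are net stoichiometric vectors; reversible reactions are
a single net rate).  The dynamics on a 1-D domain are

    dc/dt = N r(c) + B g(z, t) + D d2c/dz2

with ``r`` the reaction-rate vector, ``B`` an n x p stimulus distribution
matrix, ``g`` the p spatiotemporal input channels and ``D`` the diagonal
matrix of diffusion coefficients.  Rates are either *affine*
(``w_j + sum_i W_ji c_i``, zeroth plus first order) or *nonlinear*
(an arbitrary callable with an explicitly declared dependence set).

Concentrations are unitless; time and length units are implied by the user's
rate constants.  No unit conversion is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "SpeciesDef",
    "ReactionDef",
    "StimulusDef",
    "DomainDef",
    "ReactionNetwork",
    "Equilibrium",
    "NetworkSpecError",
    "RateEvaluationError",
    "EquilibriumError",
    "register_rate_preset",
    "build_network",
    "evaluate_rates",
    "rate_jacobian",
    "reaction_jacobian",
    "homogeneous_equilibrium",
    "stability_spectrum",
    "verify_dependencies",
]


class NetworkSpecError(ValueError):
    """A network description violates the schema or its invariants."""


class RateEvaluationError(RuntimeError):
    """A user-supplied rate function raised during evaluation."""


class EquilibriumError(RuntimeError):
    """The equilibrium solver failed to produce a valid nonnegative root."""


@dataclass(frozen=True)
class SpeciesDef:
    """A chemical species: name, diffusion coefficient, homogeneous initial value."""

    name: str
    diffusion: float = 0.0
    initial: float = 0.0

    def __post_init__(self) -> None:
        if self.diffusion < 0:
            raise NetworkSpecError(
                f"species {self.name!r}: diffusion must be >= 0, got {self.diffusion}"
            )
        if self.initial < 0:
            raise NetworkSpecError(
                f"species {self.name!r}: initial concentration must be >= 0"
            )


@dataclass(frozen=True)
class ReactionDef:
    """A reaction column: net stoichiometry plus an affine or nonlinear net rate.

    For ``kind == "affine"`` the rate is exactly
    ``affine_const + sum_i affine_coeffs[i] * c[i]`` and ``depends_on`` is the
    support of ``affine_coeffs``.  For ``kind == "nonlinear"`` the rate is
    ``rate_fn(c)`` (vectorised over a trailing grid axis) and ``depends_on``
    must be declared explicitly; it is spot-checked by finite differencing.
    """

    name: str
    stoich: np.ndarray  # length-n integer vector
    kind: str  # "affine" | "nonlinear"
    affine_const: float = 0.0
    affine_coeffs: Mapping[int, float] = field(default_factory=dict)
    rate_fn: Callable[[np.ndarray], np.ndarray] | None = None
    depends_on: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in ("affine", "nonlinear"):
            raise NetworkSpecError(
                f"reaction {self.name!r}: kind must be 'affine' or 'nonlinear'"
            )
        if self.kind == "affine":
            support = frozenset(i for i, v in self.affine_coeffs.items() if v != 0.0)
            object.__setattr__(self, "depends_on", support)
        else:
            if self.rate_fn is None:
                raise NetworkSpecError(
                    f"reaction {self.name!r}: nonlinear reactions need a rate_fn"
                )
            object.__setattr__(self, "depends_on", frozenset(self.depends_on))

    def rate(self, c: np.ndarray) -> np.ndarray:
        """Evaluate the net rate at concentrations ``c`` (shape (n,) or (n, nz))."""
        c = np.asarray(c, dtype=float)
        if self.kind == "affine":
            out = np.full(c.shape[1:], self.affine_const, dtype=float)
            for i, v in self.affine_coeffs.items():
                out = out + v * c[i]
            return out
        try:
            return np.asarray(self.rate_fn(c), dtype=float)
        except Exception as exc:  # noqa: BLE001 - reattach context
            raise RateEvaluationError(
                f"rate function of reaction {self.name!r} failed: {exc}"
            ) from exc


@dataclass(frozen=True)
class StimulusDef:
    """Stimulus distribution: ``B`` maps p input channels onto species.

    ``channels[q]`` is either ``None`` (shape only; supplied per scenario) or a
    callable ``g_q(z, t)`` vectorised over the spatial array ``z``.
    """

    B: np.ndarray  # n x p
    channels: tuple[Callable[[np.ndarray, float], np.ndarray] | None, ...] = ()

    def __post_init__(self) -> None:
        B = np.atleast_2d(np.asarray(self.B, dtype=float))
        object.__setattr__(self, "B", B)
        if B.shape[1] and not np.all(np.any(B != 0.0, axis=0)):
            raise NetworkSpecError("stimulus matrix B has an all-zero column")

    @property
    def n_channels(self) -> int:
        return self.B.shape[1]


@dataclass(frozen=True)
class DomainDef:
    """1-D spatial domain [0, length] with homogeneous boundary conditions."""

    length: float
    bc: str = "neumann"  # "neumann" | "dirichlet"

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise NetworkSpecError(f"domain length must be > 0, got {self.length}")
        if self.bc not in ("neumann", "dirichlet"):
            raise NetworkSpecError(f"unsupported boundary condition {self.bc!r}")


@dataclass(frozen=True)
class ReactionNetwork:
    species: tuple[SpeciesDef, ...]
    reactions: tuple[ReactionDef, ...]
    N: np.ndarray  # n x m integer stoichiometric matrix
    stimulus: StimulusDef
    domain: DomainDef

    def __post_init__(self) -> None:
        if not self.species:
            raise NetworkSpecError("network must declare at least one species")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise NetworkSpecError("duplicate species names")
        n, m = len(self.species), len(self.reactions)
        N = np.asarray(self.N)
        if N.shape != (n, m):
            raise NetworkSpecError(f"N must be {n}x{m}, got {N.shape}")
        for j, rxn in enumerate(self.reactions):
            if not np.array_equal(N[:, j], rxn.stoich):
                raise NetworkSpecError(
                    f"column {j} of N disagrees with reaction {rxn.name!r} stoich"
                )
        if self.stimulus.B.shape[0] != n:
            raise NetworkSpecError("stimulus matrix B must have one row per species")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    @property
    def diffusion(self) -> np.ndarray:
        return np.array([s.diffusion for s in self.species])

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise NetworkSpecError(f"unknown species {name!r}") from None


@dataclass(frozen=True)
class Equilibrium:
    """A spatially homogeneous steady state: N r(c*) = 0."""

    cstar: np.ndarray
    residual: float


# --------------------------------------------------------------------------
# Nonlinear rate presets
# --------------------------------------------------------------------------

_RATE_PRESETS: dict[str, Callable] = {}


def register_rate_preset(name: str, factory: Callable) -> None:
    """Register a nonlinear rate preset.

    ``factory(params, species_index)`` must return
    ``(rate_fn, depends_on_names)`` where ``species_index`` maps names to
    indices and ``rate_fn`` accepts a concentration array of shape (n,) or
    (n, nz).
    """
    _RATE_PRESETS[name] = factory


def _hill_binding_factory(params: Mapping, idx: Mapping[str, int]):
    """Net sigmoidal binding: k_on * R * L^h / (K^h + L^h) - k_r * C."""
    i_r = idx[params["receptor"]]
    i_l = idx[params["ligand"]]
    i_c = idx[params["complex"]]
    k_on, K, hill, k_r = (
        float(params["k_on"]),
        float(params["K"]),
        float(params.get("hill", 2.0)),
        float(params["k_r"]),
    )
    if hill < 1:
        raise NetworkSpecError("hill_binding: hill exponent must be >= 1")

    def rate(c: np.ndarray) -> np.ndarray:
        L = np.maximum(c[i_l], 0.0)
        return k_on * c[i_r] * L**hill / (K**hill + L**hill) - k_r * c[i_c]

    return rate, (params["receptor"], params["ligand"], params["complex"])


def _mass_action_binding_factory(params: Mapping, idx: Mapping[str, int]):
    """Net bilinear binding: k_on * R * L - k_r * C."""
    i_r, i_l, i_c = (idx[params[k]] for k in ("receptor", "ligand", "complex"))
    k_on, k_r = float(params["k_on"]), float(params["k_r"])

    def rate(c: np.ndarray) -> np.ndarray:
        return k_on * c[i_r] * c[i_l] - k_r * c[i_c]

    return rate, (params["receptor"], params["ligand"], params["complex"])


register_rate_preset("hill_binding", _hill_binding_factory)
register_rate_preset("mass_action_binding", _mass_action_binding_factory)


# --------------------------------------------------------------------------
# Builder
# --------------------------------------------------------------------------

def build_network(spec: Mapping) -> ReactionNetwork:
    """Assemble and validate a :class:`ReactionNetwork` from a parsed description.

    ``spec`` follows the declarative schema::

        species:   [{name, diffusion, initial}]
        reactions: [{name, stoich: {species: int}, kind,
                     affine: {const, coeffs: {species: real}},
                     nonlinear: {preset, params: {...}, depends_on: [names]}}]
        stimulus:  {matrix: {species: [channel weights]}, channels: [...]}
        domain:    {length, bc}

    Raises :class:`NetworkSpecError` naming the offending field.
    """
    species_spec = spec.get("species") or []
    if not species_spec:
        raise NetworkSpecError("spec declares no species")
    species = tuple(
        SpeciesDef(
            name=str(s["name"]),
            diffusion=float(s.get("diffusion", 0.0)),
            initial=float(s.get("initial", 0.0)),
        )
        for s in species_spec
    )
    names = [s.name for s in species]
    if len(set(names)) != len(names):
        raise NetworkSpecError("duplicate species name in spec")
    idx = {name: i for i, name in enumerate(names)}
    n = len(species)

    def resolve(name: str, where: str) -> int:
        if name not in idx:
            raise NetworkSpecError(f"{where}: unknown species {name!r}")
        return idx[name]

    reactions = []
    for rspec in spec.get("reactions") or []:
        rname = str(rspec["name"])
        stoich = np.zeros(n, dtype=int)
        for sname, coeff in (rspec.get("stoich") or {}).items():
            stoich[resolve(sname, f"reaction {rname!r} stoich")] = int(coeff)
        kind = rspec.get("kind")
        if kind == "affine":
            aff = rspec.get("affine") or {}
            coeffs = {
                resolve(sname, f"reaction {rname!r} affine coeffs"): float(v)
                for sname, v in (aff.get("coeffs") or {}).items()
            }
            reactions.append(
                ReactionDef(
                    name=rname,
                    stoich=stoich,
                    kind="affine",
                    affine_const=float(aff.get("const", 0.0)),
                    affine_coeffs=coeffs,
                )
            )
        elif kind == "nonlinear":
            nl = rspec.get("nonlinear") or {}
            preset = nl.get("preset", "custom")
            if preset == "custom":
                fn = nl.get("rate_fn")
                if fn is None:
                    raise NetworkSpecError(
                        f"reaction {rname!r}: custom nonlinear rate needs a "
                        "programmatically supplied rate_fn"
                    )
                dep_names = nl.get("depends_on") or []
                if not dep_names:
                    raise NetworkSpecError(
                        f"reaction {rname!r}: nonlinear rates must declare depends_on"
                    )
            else:
                if preset not in _RATE_PRESETS:
                    raise NetworkSpecError(
                        f"reaction {rname!r}: unknown nonlinear preset {preset!r}"
                    )
                try:
                    fn, dep_names = _RATE_PRESETS[preset](nl.get("params") or {}, idx)
                except KeyError as exc:
                    raise NetworkSpecError(
                        f"reaction {rname!r}: preset {preset!r} missing parameter {exc}"
                    ) from None
                declared = nl.get("depends_on")
                if declared:
                    dep_names = declared
            deps = frozenset(
                resolve(d, f"reaction {rname!r} depends_on") for d in dep_names
            )
            reactions.append(
                ReactionDef(
                    name=rname, stoich=stoich, kind="nonlinear",
                    rate_fn=fn, depends_on=deps,
                )
            )
        else:
            raise NetworkSpecError(
                f"reaction {rname!r}: kind must be 'affine' or 'nonlinear', got {kind!r}"
            )

    stim_spec = spec.get("stimulus") or {}
    matrix = stim_spec.get("matrix") or {}
    p = max((len(w) for w in matrix.values()), default=0)
    B = np.zeros((n, p))
    for sname, weights in matrix.items():
        B[resolve(sname, "stimulus matrix"), : len(weights)] = weights
    channels: list = []
    for ch in stim_spec.get("channels") or []:
        preset = (ch or {}).get("preset", "none")
        if preset in (None, "none"):
            channels.append(None)
        elif preset == "gaussian_pulse":
            from .fixtures import gaussian_pulse

            g, _ = gaussian_pulse(**(ch.get("params") or {}))
            channels.append(g)
        else:
            raise NetworkSpecError(f"unknown stimulus channel preset {preset!r}")

    dom_spec = spec.get("domain") or {}
    domain = DomainDef(
        length=float(dom_spec.get("length", 1.0)),
        bc=str(dom_spec.get("bc", "neumann")),
    )

    N = (
        np.stack([r.stoich for r in reactions], axis=1)
        if reactions
        else np.zeros((n, 0), dtype=int)
    )
    return ReactionNetwork(
        species=species,
        reactions=tuple(reactions),
        N=N,
        stimulus=StimulusDef(B=B, channels=tuple(channels)),
        domain=domain,
    )


# --------------------------------------------------------------------------
# Rate evaluation and calculus
# --------------------------------------------------------------------------

def evaluate_rates(net: ReactionNetwork, c: np.ndarray) -> np.ndarray:
    """Rate vector r(c); ``c`` of shape (n,) gives (m,), (n, nz) gives (m, nz)."""
    c = np.asarray(c, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ValueError("concentrations must be finite")
    if c.shape[0] != net.n_species:
        raise ValueError(
            f"expected {net.n_species} concentrations, got shape {c.shape}"
        )
    if not net.reactions:
        return np.zeros((0,) + c.shape[1:])
    return np.stack([rxn.rate(c) for rxn in net.reactions], axis=0)


def _fd_step(c: np.ndarray) -> np.ndarray:
    return 1e-6 * (1.0 + np.abs(c))


def rate_jacobian(net: ReactionNetwork, c: np.ndarray) -> np.ndarray:
    """m x n Jacobian dr/dc by central finite differences (step 1e-6*(1+|c|))."""
    c = np.asarray(c, dtype=float)
    h = _fd_step(c)
    J = np.zeros((net.n_reactions, net.n_species))
    for i in range(net.n_species):
        cp, cm = c.copy(), c.copy()
        cp[i] += h[i]
        cm[i] -= h[i]
        J[:, i] = (evaluate_rates(net, cp) - evaluate_rates(net, cm)) / (2 * h[i])
    return J


def reaction_jacobian(net: ReactionNetwork, c: np.ndarray) -> np.ndarray:
    """n x n Jacobian of the reaction term N r(c)."""
    return net.N @ rate_jacobian(net, c)


def verify_dependencies(
    net: ReactionNetwork,
    c: np.ndarray | None = None,
    rtol: float = 1e-6,
) -> list[str]:
    """Spot-check declared ``depends_on`` sets by finite differencing.

    Returns a list of violations (empty when the declarations hold at ``c``):
    a directional derivative above ``rtol`` (relative to the largest rate
    sensitivity) for a species outside a reaction's declared set.
    """
    if c is None:
        c = np.array([max(s.initial, 1.0) for s in net.species])
    J = rate_jacobian(net, c)
    scale = max(np.abs(J).max(), 1.0)
    violations = []
    for j, rxn in enumerate(net.reactions):
        for i in range(net.n_species):
            if i not in rxn.depends_on and abs(J[j, i]) > rtol * scale:
                violations.append(
                    f"reaction {rxn.name!r} depends on undeclared species "
                    f"{net.species[i].name!r} (dr/dc = {J[j, i]:.3g})"
                )
    return violations


# --------------------------------------------------------------------------
# Equilibrium and stability
# --------------------------------------------------------------------------

def homogeneous_equilibrium(
    net: ReactionNetwork,
    guess: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> Equilibrium:
    """Find a nonnegative root of N r(c) = 0 by damped Newton iteration.

    The Newton step is damped by successive halving until the residual
    decreases, and iterates are projected onto the nonnegative orthant.
    """
    n = net.n_species
    if guess is None:
        guess = np.array([max(s.initial, 1.0) for s in net.species])
    c = np.asarray(guess, dtype=float).copy()
    if np.any(c < 0):
        raise EquilibriumError("initial guess must be nonnegative")

    def F(x: np.ndarray) -> np.ndarray:
        return net.N @ evaluate_rates(net, x)

    res = np.max(np.abs(F(c)))
    for _ in range(max_iter):
        if res <= tol:
            break
        J = reaction_jacobian(net, c)
        if not np.all(np.isfinite(J)):
            raise EquilibriumError("Jacobian of N r(c) is not finite")
        try:
            step = np.linalg.solve(J, -F(c))
        except np.linalg.LinAlgError as exc:
            raise EquilibriumError(
                "singular Jacobian in Newton iteration; try a different guess"
            ) from exc
        lam = 1.0
        for _ in range(40):
            trial = np.maximum(c + lam * step, 0.0)
            new_res = np.max(np.abs(F(trial)))
            if new_res < res or new_res <= tol:
                c, res = trial, new_res
                break
            lam *= 0.5
        else:
            raise EquilibriumError(
                "Newton damping stalled; try a different guess"
            )
    if res > tol:
        raise EquilibriumError(
            f"no convergence after {max_iter} iterations (residual {res:.3g}); "
            "try a different guess"
        )
    if np.any(c < 0):
        raise EquilibriumError("converged to negative concentrations")
    return Equilibrium(cstar=c, residual=float(res))


@dataclass(frozen=True)
class StabilitySpectrum:
    """Eigenvalues of J(c*) - mu^2 D for each requested spatial frequency."""

    wavenumbers: np.ndarray
    eigenvalues: tuple[np.ndarray, ...]  # one array per wavenumber
    all_negative_real_parts: bool

    @property
    def slowest_rate(self) -> float:
        """Smallest |Re(lambda)| across all modes — the slowest decay rate."""
        return float(
            min(np.min(np.abs(ev.real)) for ev in self.eigenvalues)
        )


def stability_spectrum(
    net: ReactionNetwork,
    eq: Equilibrium,
    wavenumbers: Sequence[float],
) -> StabilitySpectrum:
    """Dispersion relation at the equilibrium: eig(J(c*) - mu^2 D) per mu.

    The equilibrium is exponentially stable against perturbations of spatial
    frequency mu iff every eigenvalue has negative real part.
    """
    J = reaction_jacobian(net, eq.cstar)
    if not np.all(np.isfinite(J)):
        raise EquilibriumError("Jacobian at equilibrium is not finite")
    D = np.diag(net.diffusion)
    evs = []
    for mu in wavenumbers:
        evs.append(np.linalg.eigvals(J - (mu**2) * D))
    all_neg = all(np.all(ev.real < 0) for ev in evs)
    return StabilitySpectrum(
        wavenumbers=np.asarray(wavenumbers, dtype=float),
        eigenvalues=tuple(evs),
        all_negative_real_parts=all_neg,
    )
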