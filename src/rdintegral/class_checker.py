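"""Species-Reaction graph and the structural test for exact time-integrals.

The Species-Reaction (SR) graph is bipartite: species nodes (S-nodes) and
reaction nodes (R-nodes), with an edge (i, j) whenever the rate of reaction j
depends on species i.  S-nodes are coloured black if the species diffuses and
red otherwise; R-nodes are black for affine rates and red for nonlinear ones.

A network admits exact analytic time-integrals for its "c2" species when:

* C1 — every species that reacts only through nonlinear rates is nondiffusive;
* C2 — the number of such species (n1) equals the number of nonlinear
  reactions (m1);

equivalently, graphically (C*): every S-node not connected to a black R-node
is red, and their number equals the number of red R-nodes.  Under these
conditions the stoichiometric matrix can be permuted to the block-triangular
form [[N11, 0], [N21, N22]] with N11 square (n1 x m1) and nonsingular.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network_model import ReactionNetwork

__all__ = ["SRGraph", "ClassCertificate", "build_sr_graph", "check_conditions",
           "block_decomposition", "to_dot"]

# numeric rank threshold for N11, relative to its largest singular value
_SVD_RTOL = 1e-10


@dataclass(frozen=True)
class SRGraph:
    """Coloured bipartite Species-Reaction graph."""

    graph: nx.Graph
    s_colors: tuple[str, ...]  # per species: "black" (diffusive) | "red"
    r_colors: tuple[str, ...]  # per reaction: "black" (affine) | "red"
    species_names: tuple[str, ...]
    reaction_names: tuple[str, ...]

    def species_neighbors(self, i: int) -> set[int]:
        """Indices of reactions whose rate depends on species ``i``."""
        return {nbr[1] for nbr in self.graph.neighbors(("S", i))}


@dataclass
class ClassCertificate:
    """Outcome of the C1/C2 (C*) test with the induced partition and blocks.

    When ``passes`` is true, species are partitioned into ``c1_indices`` (the
    n1 species reacting only in nonlinear reactions) and ``c2_indices`` (the
    n2 others), reactions into nonlinear ``r1_indices`` and affine
    ``r2_indices``, and ``blocks`` holds N11 (n1 x m1), N21 (n2 x m1) and
    N22 (n2 x m2) of the permuted stoichiometric matrix.  ``affine_params``
    holds the zeroth-order vector w (length m2) and first-order matrix W
    (m2 x n2) restricted to c2 species.
    """

    passes: bool
    c1_indices: list[int]
    c2_indices: list[int]
    r1_indices: list[int]
    r2_indices: list[int]
    failures: list[str] = field(default_factory=list)
    blocks: dict[str, np.ndarray] = field(default_factory=dict)
    affine_params: dict[str, np.ndarray] = field(default_factory=dict)
    n11_condition_number: float | None = None

    @property
    def n1(self) -> int:
        return len(self.c1_indices)

    @property
    def n2(self) -> int:
        return len(self.c2_indices)


def build_sr_graph(net: ReactionNetwork) -> SRGraph:
    """Construct the coloured SR graph from ``depends_on`` sets and colours."""
    g = nx.Graph()
    for i, sp in enumerate(net.species):
        g.add_node(("S", i), bipartite=0, name=sp.name)
    for j, rxn in enumerate(net.reactions):
        g.add_node(("R", j), bipartite=1, name=rxn.name)
        for i in rxn.depends_on:
            g.add_edge(("S", i), ("R", j))
    s_colors = tuple(
        "black" if sp.diffusion > 0 else "red" for sp in net.species
    )
    r_colors = tuple(
        "black" if rxn.kind == "affine" else "red" for rxn in net.reactions
    )
    return SRGraph(
        graph=g,
        s_colors=s_colors,
        r_colors=r_colors,
        species_names=net.species_names,
        reaction_names=tuple(r.name for r in net.reactions),
    )


def _participates(net: ReactionNetwork, i: int) -> bool:
    """Species i takes part in some reaction (stoichiometrically or kinetically)."""
    return bool(np.any(net.N[i, :] != 0)) or any(
        i in rxn.depends_on for rxn in net.reactions
    )


def check_conditions(net: ReactionNetwork) -> ClassCertificate:
    """Run the graphical class test and, on success, the block decomposition.

    Failures are data, not exceptions: each violated clause is appended to
    ``failures`` in words.  Clauses checked:

    a. every c1 candidate (species adjacent to no affine reaction) is
       nondiffusive (C1);
    b. the number of c1 species equals the number of nonlinear reactions (C2);
    c. N11 is numerically nonsingular (smallest singular value above
       1e-10 x largest);
    d. no c1 species appears stoichiometrically in an affine reaction (the
       zero block of the permuted stoichiometric matrix is exactly zero).
    """
    sr = build_sr_graph(net)
    r1 = [j for j, r in enumerate(net.reactions) if r.kind == "nonlinear"]
    r2 = [j for j, r in enumerate(net.reactions) if r.kind == "affine"]

    isolated = [
        i for i in range(net.n_species) if not _participates(net, i)
    ]
    if isolated:
        warnings.warn(
            "species participating in no reaction excluded from the c1 "
            f"candidate set: {[net.species_names[i] for i in isolated]}",
            stacklevel=2,
        )

    affine_set = set(r2)
    c1 = [
        i
        for i in range(net.n_species)
        if i not in isolated and not (sr.species_neighbors(i) & affine_set)
    ]
    c2 = [i for i in range(net.n_species) if i not in c1]

    failures: list[str] = []
    diffusive_c1 = [i for i in c1 if net.species[i].diffusion > 0]
    if diffusive_c1:
        failures.append(
            "C1 violated: species reacting only in nonlinear reactions must "
            f"not diffuse: {[net.species_names[i] for i in diffusive_c1]}"
        )
    if len(c1) != len(r1):
        failures.append(
            f"C2 violated: {len(c1)} species react only in nonlinear "
            f"reactions but there are {len(r1)} nonlinear reactions"
        )
    bad_block = [
        (i, j)
        for i in c1
        for j in r2
        if net.N[i, j] != 0
    ]
    if bad_block:
        failures.append(
            "block-triangular form violated: c1 species appear "
            "stoichiometrically in affine reactions: "
            + ", ".join(
                f"({net.species_names[i]}, {net.reactions[j].name})"
                for i, j in bad_block
            )
        )

    cert = ClassCertificate(
        passes=False,
        c1_indices=c1,
        c2_indices=c2,
        r1_indices=r1,
        r2_indices=r2,
        failures=failures,
    )
    if failures:
        return cert

    # N11 numeric nonsingularity (only meaningful once the counts match)
    N11 = net.N[np.ix_(c1, r1)].astype(float)
    if N11.size:
        sv = np.linalg.svd(N11, compute_uv=False)
        if sv[-1] <= _SVD_RTOL * sv[0]:
            cert.failures.append(
                "N11 is numerically singular (condition C2 holds but the "
                "nonlinear block is rank deficient)"
            )
            return cert
        cert.n11_condition_number = float(sv[0] / sv[-1])
    cert.passes = True
    return block_decomposition(net, cert)


def block_decomposition(
    net: ReactionNetwork, cert: ClassCertificate
) -> ClassCertificate:
    """Fill in the stoichiometric blocks and affine parameters of a passing cert.

    Species order: c1 first then c2, reactions: nonlinear first then affine,
    each preserving original declaration order (reproducible block matrices).
    """
    if not cert.passes:
        raise ValueError("block decomposition requires a passing certificate")
    c1, c2, r1, r2 = (
        cert.c1_indices,
        cert.c2_indices,
        cert.r1_indices,
        cert.r2_indices,
    )
    N = net.N
    N12 = N[np.ix_(c1, r2)]
    if np.any(N12 != 0):  # guarded in check_conditions; internal consistency
        raise AssertionError(
            "internal consistency error: upper-right stoichiometric block "
            "nonzero for a passing certificate"
        )
    cert.blocks = {
        "N11": N[np.ix_(c1, r1)].copy(),
        "N21": N[np.ix_(c2, r1)].copy(),
        "N22": N[np.ix_(c2, r2)].copy(),
    }
    m2, n2 = len(r2), len(c2)
    w = np.zeros(m2)
    W = np.zeros((m2, n2))
    col_of = {i: k for k, i in enumerate(c2)}
    for row, j in enumerate(r2):
        rxn = net.reactions[j]
        w[row] = rxn.affine_const
        for i, v in rxn.affine_coeffs.items():
            # affine rates cannot touch c1 species (their defining property)
            W[row, col_of[i]] = v
    cert.affine_params = {"w": w, "W": W}
    return cert


def to_dot(g: SRGraph) -> str:
    """Graphviz DOT text: S-nodes as circles, R-nodes as boxes, red/black."""
    lines = ["graph sr_graph {"]
    for i, name in enumerate(g.species_names):
        lines.append(
            f'  "S_{name}" [shape=circle, color={g.s_colors[i]}, label="{name}"];'
        )
    for j, name in enumerate(g.reaction_names):
        lines.append(
            f'  "R_{name}" [shape=box, color={g.r_colors[j]}, label="{name}"];'
        )
    for (kind_a, a), (kind_b, b) in g.graph.edges():
        if kind_a == "R":  # normalise edge direction S -- R
            (kind_a, a), (kind_b, b) = (kind_b, b), (kind_a, a)
        lines.append(
            f'  "S_{g.species_names[a]}" -- "R_{g.reaction_names[b]}";'
        )
    lines.append("}")
    return "\n".join(lines)
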