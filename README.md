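# rdintegral

Exact time-integrals of transient responses in nonlinear reaction–diffusion
networks.

## The problem

Cells convert spatiotemporal concentration signals into responses, and a
natural scalar measure of how much signal a species accumulates is the
time-integral of its deviation from steady state,

    y_i(z) = ∫₀^∞ (c_i(z, t) − c_i*) dt,

for a reaction–diffusion system on a 1-D domain,

    ∂c/∂t = N r(c) + B g(z, t) + D ∂²c/∂z².

Here `c` is the vector of n species concentrations, `N` the n×m
stoichiometric matrix, `r(c)` the reaction rates, `B g(z, t)` transient
influx/efflux stimuli and `D` the diagonal diffusion matrix.  For general
nonlinear kinetics neither the PDE nor the integral has a closed form — but
for a structurally characterized class of networks the time-integral does,
**exactly**, with no linearization and for arbitrarily large perturbations.

The class is defined by two conditions on the partition of species into
`c1` (species that react *only* through nonlinear rates) and `c2` (the
rest), with rates split into m₁ nonlinear and m₂ affine
(`r₂ = w + W c₂`):

* **C1** — the `c1` species do not diffuse (receptors, scaffold-anchored or
  membrane-bound molecules);
* **C2** — the number of `c1` species equals the number of nonlinear
  reactions (n₁ = m₁), making the nonlinear stoichiometric block `N11`
  square (and, at a stable equilibrium, invertible).

Both conditions are read off a colored **Species–Reaction graph**: species
nodes colored by diffusivity, reaction nodes by linearity, with an edge
where a rate depends on a species.  The network passes iff every S-node not
touching a black (affine) R-node is red (nondiffusive) and their number
equals the number of red (nonlinear) R-nodes.

When the test passes, eliminating the nonlinear rates shows that
`y₂(z) = ∫ (c₂ − c₂*) dt` solves the *linear* boundary-value problem

    0 = D₂ y₂'' + Ā y₂ + β(z) + Ḡ ∫₀^∞ g dt,

with `Ā = N22 W`, `Ḡ = B₂ − N21 N11⁻¹ B₁` and
`β = (c₂(z,0) − c₂*) − N21 N11⁻¹ (c₁(z,0) − c₁*)`.  Expanding on the
orthonormal Laplacian eigenfunctions φ_k (cosines for Neumann boundaries)
decouples this into one small linear solve per spatial mode:

    (Ā − μ_k² D₂) a_k = −(β_k + Ḡ G_k),    y₂(z) = Σ_k a_k φ_k(z).

The package implements the graph test, the per-mode solver, a
method-of-lines simulator of the full nonlinear PDE (the independent ground
truth every analytic result is validated against), and the worked
complex-formation example: an immobile receptor binding a diffusible ligand
into an immobile complex.  There the formulae show that ligand diffusion
acts as a **spatial low-pass filter** with response
`H(μ) = d_L/(d_L + D_L μ²)`, cutoff `μ_c = √(d_L/D_L)` (the reciprocal of
the ligand's diffusion length), and that a transient ligand influx forces a
**waterbed effect**: the receptor's time-integral is identically zero — its
transient valley below equilibrium exactly cancels its later peak.

## Who it is for

Systems/synthetic biologists and modelers who want parameter-explicit,
simulation-free expressions for cumulative signal transmission in
reaction–diffusion models (ligand–receptor systems, protein sequestration,
calcium buffering), and a structural test for when such expressions exist.

## Worked example

`examples/waterbed_influx.py` drives the complex-formation network (default
parameters: b_R = b_L = d_R = d_L = k_r = 1, D_L = 5·10⁻³, Hill binding
with k_on = 5, K = 1, hill = 2 on a unit Neumann domain) from equilibrium
with a transient Gaussian pulse of ligand, and prints:

```
nil (channel, species) pairs: [(0, 'R')]
analytic y_R on grid: [0. 0. 0. 0. 0.]  (identically zero)
analytic y_L peak   : 0.4749
oracle: max |int (R - R*) dt| = 6.84e-07
        as % of peak ligand integral: 0.00014%  (< 1%)
R transient at z = 1/2: valley 0.9269 < R* = 1.0 < peak 1.0138  (areas cancel)
```

The first line is the structural certificate (ligand channel 0 yields a nil
time-integral for R); the oracle lines confirm it numerically from the full
nonlinear PDE, and the last line shows the valley/peak cancellation that
produces it.  `examples/spatial_filter.py` prints the companion experiment —
a Gaussian bump on the complex whose R-integral passes through unfiltered
(`y_R = q(z)/d_R`) while the ligand integral is mode-wise attenuated — with
the per-harmonic attenuation table and a 6·10⁻⁵ relative L2 agreement
between series and oracle.  `examples/check_network.py` and
`examples/random_class_network.py` show the graph test and the pipeline on
a randomized in-class network.

A thin CLI wraps the same functions:

```bash
rdintegral fixtures emit complexform --out net.yaml
rdintegral check net.yaml --dot graph.dot
rdintegral integrate net.yaml --scenario scen.yaml --out integrals.csv
rdintegral compare net.yaml --scenario scen.yaml --out compare.csv
rdintegral filter --harmonics 8
```

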