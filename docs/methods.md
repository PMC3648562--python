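# Methods

## Model and scope

The package models networks of n chemical species coupled by m reactions on
a 1-D spatial domain [0, ℓ] with homogeneous boundary conditions shared by
all species:

    ∂c/∂t = N r(c) + B g(z, t) + D ∂²c/∂z²,

where N is the stoichiometric matrix (one net column per reaction;
reversible reactions are a single net rate), r(c) the rate vector, B an
n×p matrix distributing p transient input channels g(z, t), and D a
diagonal matrix of constant diffusion coefficients.  Rates are either
*affine* (w_j + Σ_i W_ji c_i) or *nonlinear* (arbitrary callables with an
explicitly declared dependence set, spot-checked by finite differencing).
Concentrations are unitless; time and length scales are implied by the rate
constants supplied.  2-D/3-D geometries, spatially varying diffusion,
per-species boundary conditions and stochastic kinetics are out of scope.

The analysis assumes the network relaxes to a unique spatially homogeneous,
exponentially stable equilibrium c* once the stimulus has passed; this is
what makes the time-integral of the deviation finite.  Stability is checked
(not assumed) through the dispersion relation eig(J(c*) − μ²D).

## The computable class and its graph test

Species are partitioned into c1 (participating only in nonlinear
reactions — via rate dependence or stoichiometry) and c2 (the rest);
reactions into m₁ nonlinear and m₂ affine.  The class conditions are
C1: c1 species do not diffuse, and C2: n₁ = m₁ with the nonlinear block
N11 invertible.  The checker works on the colored Species–Reaction graph
and reports every violated clause in words rather than raising; it also
verifies directly that the permuted stoichiometric matrix has its
upper-right block exactly zero, so the certificate is sound even for
adversarial declarations (a species whose rate-dependence set avoids affine
reactions but whose stoichiometry touches one is rejected with a named
failure instead of corrupting the decomposition).

N11 invertibility is tested numerically (smallest singular value above
1e−10 times the largest) so the checker needs no equilibrium; the condition
number is reported on passing certificates.  Species participating in no
reaction are excluded from the c1 candidate set with a warning.  Within c1
and c2 the original declaration order is preserved, making the block
matrices reproducible.

## The integral equation and its eigenfunction solution

Eliminating the m₁ nonlinear rates through N11⁻¹ and integrating the
dynamics of x = c₂ − N21 N11⁻¹ c₁ from 0 to ∞ yields the linear
boundary-value problem for y(z) = ∫ (c₂ − c₂*) dt:

    0 = D₂ y'' + Ā y + β(z) + Ḡ Gint(z),

    Ā = N22 W,   Ḡ = B₂ − N21 N11⁻¹ B₁,
    β = (c₂(z,0) − c₂*) − N21 N11⁻¹ (c₁(z,0) − c₁*),
    Gint(z) = ∫₀^∞ g(z, t) dt.

The sign convention above is the one under which the worked example's
closed forms come out with their physical signs (a positive bump on the
complex yields positive receptor and ligand integrals, q(z)/d_R and the
filtered series); it is additionally pinned by the PDE-oracle equivalence
tests, which would detect any sign error at the 100% level rather than 1%.

Projecting on the orthonormal Laplacian eigenbasis — Neumann:
φ₀ = √(1/ℓ), φ_k = √(2/ℓ)cos(kπz/ℓ); Dirichlet: φ_k = √(2/ℓ)sin(kπz/ℓ),
k ≥ 1 — decouples the problem into per-mode n₂×n₂ solves
(Ā − μ_k²D₂)a_k = −(β_k + Ḡ G_k).  Each solve's residual must stay below
1e−12 relative or the engine raises.  A singular mode matrix is refused
with the mode named; for the Neumann k = 0 mode this coincides with the
exponential-stability requirement on Ā.  Dirichlet boundaries are
interpreted as concentrations clamped at the equilibrium value (deviations
vanish at the boundary), the only homogeneous-Dirichlet reading compatible
with a nonzero homogeneous equilibrium.

Numerical choices: projections use composite Simpson quadrature on a
uniform 2049-point grid (the integrands are smooth products of Gaussians
and low-order trigonometric functions; spectral quadrature is
unnecessary).  Default truncation is K = 64 with a tail warning when
‖a_K‖/max_k‖a_k‖ > 1e−6; doubling K changes the evaluated series by
< 0.1% for the smooth forcings used throughout, which the tests assert.

Nil-channel detection reports the (channel, species) pairs for which row i
of (Ā − μ_k²D₂)⁻¹Ḡ has a zero entry in column q for every retained mode —
a certificate, up to truncation K, that the species' time-integral is
structurally insensitive to that input (the waterbed effect).

## The PDE oracle

The ground truth is a method-of-lines solver: second-order central
differences on a uniform grid (default nz = 201), ghost-point mirrors for
Neumann boundaries (preserving second-order accuracy and exact zero row
sums), clamped boundary rows for Dirichlet.  Time integration uses SciPy's
BDF with rtol 1e−8 / atol 1e−10 and a supplied Jacobian sparsity pattern
(reaction coupling ⊗ identity plus tridiagonal diffusion), which keeps a
601-state stiff solve under a second.  The horizon defaults to 12 slowest
time-constants (from the μ = 0 and first-harmonic spectra) plus the
stimulus duration; the validation pipeline and large-amplitude tests use
16–20 time-constants so the settle check (final deviation ≤ 1e−6·‖c*‖∞)
passes with margin.  Dense output is evaluated on a ~4000-point time grid,
refined around the stimulus pulse, and time-integrals are trapezoidal sums
on that grid, with the neglected exponential tail estimated as the final
deviation over the slowest decay rate and reported separately.  The oracle
never reads any output of the analytic engine.

A mass-balance diagnostic integrates the affine closed form of
d/dt ∫ x dz for the c1-eliminating combinations and compares it (via
cumulative Simpson quadrature, so the diagnostic's own error sits below the
integrator's) against the simulated mass; under Dirichlet boundaries the
unaccounted boundary flux deliberately shows up in this residual, and a
test asserts that it is detected.

## The worked example

The complex-formation mechanism (immobile partner R, diffusible ligand L,
immobile complex C; net binding rate h(R, L) − k_r C) uses a Hill-in-ligand
sigmoid h = k_on R L^hill/(K^hill + L^hill) by default.  All analytic
results depend only on the network structure, never on the form of h, so a
bilinear mass-action variant ships as well and the oracle tests run both.
Default parameters — ℓ = 1, D_L = 5e−3, b_R = b_L = d_R = d_L = k_r = 1,
k_on = 5, K = 1, hill = 2 — put the dominant harmonics of a σ = ℓ/10
Gaussian bump astride the filter cutoff μ_c = √(d_L/D_L) ≈ 14.1 (between
harmonics 4 and 5), so spatial filtering is visible but not total.

Stock scenarios: a Gaussian bump on the complex with amplitude C*/2
(z₀ = ℓ/2, σ = ℓ/10), and a spatiotemporal Gaussian ligand pulse with
amplitude L*/2, σ_t = 0.5/d_L, t₀ = 3σ_t.  The t₀ = 3σ_t transient cut-off
leaves ~0.13% of the pulse mass before t = 0, which is the dominant term in
the ~0.1% analytic-vs-oracle discrepancy of the influx scenario and well
inside the 1% validation band.

The diffusion length is exposed under two lifetime conventions:
`rate` (τ = 1/d_L, under which cutoff × length = 1 exactly) and
`halflife` (τ = ln 2/d_L); the cutoff identity H(μ_c) = 1/2 holds exactly
under either.  The waterbed certificate is issued for the species the
method computes (the immobile partner R, a c2 species); the complex's own
integral is not claimed analytically.

## Synthetic fixtures and what the tests show

The fixture suite contains the canonical passing topology, failing variants
(linear complex degradation → C2 fails; diffusing complex → C1 fails; a
complex shared by two nonlinear reactions → count mismatch; duplicated
nonlinear columns → singular N11), a two-nonlinear-reaction passing
topology (one ligand, two receptors), and a seeded generator of random
in-class networks (diagonally dominant Hurwitz affine part plus one
saturating nonlinear coupling to an immobile species).  All fixtures are
deterministic functions of their seeds.

These are clean, smooth, noiseless inputs: the validation demonstrates the
exactness of the series against the same PDE the theory assumes (including
perturbation amplitudes of 200–500% of equilibrium, where a linearized
solution would fail), not robustness to measurement noise, parameter
uncertainty, non-Hill kinetics outside the declared rate class, or
geometries beyond a 1-D interval.

## Known limitations

* Only time-integrals are analytic; transient features (peaks, response
  times) require the simulator.
* The series is exact for the PDE, but the package's guarantee is numeric:
  validation is at the 1% level set by spatial/temporal discretization of
  the oracle, not by the series.
* Networks whose nonlinear rates fail their declared dependence sets are
  caught only at finite-difference spot checks, not symbolically.
* The equilibrium solver is a local damped Newton; multistable networks
  need a good initial guess, and uniqueness is the user's modeling
  assumption.
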