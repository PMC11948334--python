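# Methods

`polimage` computes electrostatic interactions between charged polarizable
(dielectric) spheres with the image-charge method, and evaluates closed-form
critical conditions for like-charge attraction (LCA). This note records the
model, the numerical choices, and the known limits of each component.

## Model and units

Each sphere *i* has radius *a<sub>i</sub>*, relative permittivity
ε<sub>i</sub>, and a point charge *Q<sub>i</sub>* at its center; the spheres
sit in a homogeneous medium of permittivity ε<sub>out</sub> with
center-to-center distance *R* ≥ *a*₁ + *a*₂, both centers on the z axis.
Internally everything is in reduced units — lengths in nm, charges in *e*,
energies in *e*²/(4πε₀·nm) ≈ 1.4400 eV — so the Coulomb energy of two
charges is simply *q*₁*q*₂/(ε<sub>out</sub>*r*) and ε₀ never appears.
Conversion to eV happens only at the I/O layer (`--units si-ev`).

Two dimensionless combinations control all of the physics:

- dielectric contrast *k* = (ε<sub>in</sub> − ε<sub>out</sub>)/(ε<sub>in</sub> + ε<sub>out</sub>),
  with *k* = 1 a perfect conductor, *k* = 0 index matching, *k* < 0 a cavity;
- line-image exponent *g* = ε<sub>out</sub>/(ε<sub>in</sub> + ε<sub>out</sub>)
  (so *k* + 2*g* = 1), which tends to 0 in the conductor limit;

together with the contact parameters *t<sub>i</sub>* = *a<sub>i</sub>*/*R*
(contact at *t*₁ + *t*₂ = 1, i.e. *t* = 1/2 for equal spheres). All results
are scale invariant: (a, R) → (λa, λR) changes nothing dimensionless.

## Single sphere: Neumann images and the three-point resummation

A charge *Q* at distance *R* from a sphere's center polarizes it; the exact
exterior response is a Kelvin image *Q*<sub>K</sub> = −*kQa*/*R* at the
inversion point *a*²/*R* plus a line density
*q*<sub>line</sub>(*r*) = (*kQg*/*a*)(*r*/*r*<sub>K</sub>)<sup>*g*−1</sup>
from the center to the Kelvin point, which integrates to −*Q*<sub>K</sub>
(the sphere stays neutral). The polarization energy is half the interaction
of *Q* with its own images.

Two independent evaluations are implemented:

- **Adaptive quadrature** (`pol_energy_quadrature`): the integrable
  *r*<sup>*g*−1</sup> endpoint singularity is split off analytically and the
  remainder handled by QUADPACK's algebraic-weight rule; the Kelvin term and
  the line's center-of-mass term are combined in closed form
  (−*kQa*³/[*R*²(*R*²−*a*²)]) to avoid subtractive cancellation at large *R*.
- **Incomplete-beta closed form** (`pol_energy_beta`, `three_point_energy`):
  substituting u = r·R/a² and t = a/R turns the line integral into
  B<sub>t²</sub>(g, 0) = Σ<sub>n≥0</sub> t^(2n+2g)/(n+g), giving
  E<sub>pol</sub> = −(kQ²/2ε<sub>out</sub>a)·Σ<sub>n≥1</sub> t^(2n+2)·n/(n+g).
  Series are truncated at a relative term < 1e−15 (cap 10⁵ terms, error if
  the cap is hit with t² > 0.999, i.e. essentially at contact).

The two routes agree to ~1e−12 relative over R/a ∈ [1.01, 10³] and
ε<sub>in</sub> ∈ [2, 10⁶]; the conductor limit reproduces
−Q²a³/[2R²(R²−a²)] and the far field reproduces the Clausius–Mossotti
coefficient −(Q²a³/2)(ε<sub>in</sub>−ε<sub>out</sub>)/[ε<sub>out</sub>(ε<sub>in</sub>+2ε<sub>out</sub>)].

Partial fractions on n/(n+g) rearrange the response into exactly **three
images at fixed positions**: charges ∓*Qk*/2 at the two axial surface points
(negative on the source side) and a central dipole

p(t) = Q·k·a·g·Σ<sub>n≥0</sub> t^(2n)/(n+g),  p → Q·k·a as t → 0,

oriented toward the source. This three-point set reproduces the polarization
*potential at the source location* identically — hence the single-sphere
energy exactly — but not the response field elsewhere (its multipole moments
differ from the true ones). Two consequences worth stating explicitly:

- The *energies* of the exact and leading-order (p ≈ Qka) versions do **not**
  converge to each other at large R: the ±Qk/2 pair cancels the O(t²) part of
  the dipole potential, both energies scale as t⁴, and their relative gap
  tends to the constant *g* (≈ 4.8% at ε = 20), the leading form slightly
  overestimating the attraction. Only the dipole strengths converge.
- Iterating the three-point formula between two spheres is an approximation
  beyond the first reflection (next section).

## Two spheres: image reflections

The mutual polarization is built by reflecting images: level 1 is each
sphere's response to the other's central charge; level n + 1 is the response
to the other sphere's level-n images. Strength decays like |k₁k₂|·t₁t₂ per
round, so the recursion converges geometrically away from contact. The total
energy is

E = Q₁Q₂/(ε<sub>out</sub>R) + ½·[Q₁·Φ<sub>img,2</sub>(x₁) + Q₂·Φ<sub>img,1</sub>(x₂)],

bare Coulomb plus half the image potentials evaluated at the *other* central
charge. (The potential at a sphere's center due to external sources equals
their plain Coulomb potential there — the n = 0 transmission coefficient is
unity — which is what makes this closed form correct level by level.)

**Neumann solver** (`reflect_neumann`, the reference): every source charge
maps to its Kelvin image plus a line image discretized by Gauss–Legendre
nodes under the substitution r = r<sub>K</sub>·s^(1/g), which removes the
endpoint singularity and equidistributes the line charge (16 nodes by
default). Since each reflection multiplies the image count by n_nodes + 1,
the per-level clouds — which occupy a narrow band below each Kelvin point —
are compacted by positional binning (8192 bins over the band), separately
for positive and negative charge so that each occupied bin keeps its exact
monopole and dipole moment; the residual error is of quadrupole order,
(bin width/distance)² per level. Convergence: per-level energy increment
below an absolute tolerance (default 1e−12) or a detected discretization
noise floor (increments no longer decaying while < 1e−6 of the energy);
exceeding max_level (default 200) raises with the increment history.
Cross-validated during development against an independent spectral
(Legendre-multipole) solution: agreement ~1e−11 relative even at gap
d = 0.2 nm for the reference system below.

**Three-point solver** (`reflect_three_point`): the state per sphere is just
(q<sub>near</sub>, q<sub>far</sub>, dipole) and each reflection maps the
other sphere's new point sources to fresh three-point strengths, using the
exact p(t) series (mode `exact`) or p ≈ Qka (mode `leading`). Dipole sources
reflect, by default, through the transfer coefficient obtained by
differentiating the exact response with respect to source position and
point-matching at the source: P(t) = k·Σ<sub>n≥1</sub> n(n+1)/(n+g)·t^(2n+1)
(leading term 2k·t³/(1+g), the classical mutual-dipole image). The
alternative of differentiating the already-compressed three-point response
(`dipole_reflection="derivative"`) is kept as a cross-check; it loses the
dipole–dipole channel entirely in the conductor limit and is not the
default. Because the compressed sets are re-reflected and evaluated away
from their matching points, level 1 is exact but the converged three-point
energy is a controlled approximation: on the reference system below it
deviates from the Neumann solver by 0.4% of the total energy (≈ 0.6% of the
polarization part) at d = 0.2 nm, and by up to ~15% of the polarization part
at intermediate gaps (where polarization is itself a small correction, so
the total-energy error stays at the few-percent level). It is the fast method for force-field-style
tabulation; quantitative validation uses the Neumann solver.

Forces are F = −∂E/∂R (> 0 repulsive), by Richardson-extrapolated central
differences with step 1e−5·R (halved as needed near contact); the
first-level force is analytic. Finite differences sit on top of the solver
noise floor, so converged forces carry ~1e−5 relative noise — irrelevant at
the 1% validation scale. `level_decomposition` differentiates the per-level
energies: the level forces alternate in sign and decay to zero; with
strongly asymmetric charges the decay is monotone over level *pairs*
(|F<sub>i+2</sub>| < |F<sub>i</sub>|) rather than step by step, the odd and
even levels forming two interleaved geometric sequences.

## Critical conditions for like-charge attraction

Keeping one reflection with p ≈ Qka gives the closed-form energy

E = (1/ε<sub>out</sub>)·[Q₁Q₂/R − k₁Q₂²a₁³/(2R²(R²−a₁²)) − k₂Q₁²a₂³/(2R²(R²−a₂²))]

whose force zero, divided by the Coulomb force, is the dimensionless
critical condition

k₁(Q₂/Q₁)·h(t₁) + k₂(Q₁/Q₂)·h(t₂) = 1,  h(t) = t³(2−t²)/(1−t²)².

h is strictly increasing on (0, 1), so there is at most one root R<sub>c</sub>;
attraction holds for all R < R<sub>c</sub>. Because the level forces
alternate and decay (pairwise), a first-level force that is repulsive
everywhere implies a converged force that is repulsive everywhere — the
first level is a *necessary-condition* predictor, verified numerically in
the tests. Specializations:

- **Equal sizes**: χ·h(t) = 1 with χ = k₁(Q₂/Q₁) + k₂(Q₁/Q₂). Since
  h(1/2) = 7/18 exactly, LCA requires χ > 18/7 ≈ 2.571; equal charges give
  χ = k₁ + k₂ ≤ 2, so equal-size, equally charged spheres never attract.
  In a medium more polarizable than the spheres (k < 0) the condition has
  no root: no LCA.
- **Equal charges and permittivities**: k·[h(t₁) + h(t₂)] = 1; attraction is
  driven by size asymmetry, maximal for conductors (k = 1), and the
  attraction region collapses to a point as k → 0.

`solve_rc` scans the residual uniformly in contact parameter (512 points,
best conditioned near contact), brackets sign changes, and polishes with
Brent to ~1e−12, reporting the outermost root; "no root up to
R = 10³(a₁+a₂)" is the valid no-LCA outcome (beyond that the Coulomb term
dominates by the t → 0 asymptotics). `solve_rc_numeric` finds the converged
solver's force zero the same way, seeded by the theory root.
`phase_diagram` traces the zero sets per abscissa by inverting h (Brent on
(0, 1)), masking the nonphysical region t₁ + t₂ > 1.

**Accuracy of the closed-form R<sub>c</sub>.** On the package's reference
validation sweep (equal radii with Q₂/Q₁ ∈ {4, 7, 10} and ε ∈ {10, 20, 50,
200} in vacuum; unequal radii a₂/a₁ ∈ {2, 4, 8} with equal charges and
k ∈ {0.6, 0.8, 1.0}; 20 of the 21 systems exhibit LCA), the first-level
R<sub>c</sub> always lies slightly *outside* the converged one — consistent
with the leading-order dipole overestimating attraction by the O(g)
fraction above — with a relative discrepancy from < 0.1% in the
conductor-like cases up to 2.4% in the least polarizable ones (ε = 10,
large charge ratio). The discrepancy decreases systematically with
polarizability; sub-1% accuracy holds for ε ≳ 50 (k ≳ 0.96). The full
per-case table is printed by `scripts/acceptance.py`.

## What the deterministic sweeps do and do not show

The validation sweeps generate ideal two-sphere systems exactly obeying the
model: central point charges, sharp dielectric boundaries, no electrolyte
screening, no surface charge distributions, no external field, and only two
bodies. Passing them shows the closed-form theory tracks the exact
continuum-electrostatics solution of *this model*; it says nothing about
charge regulation, ionic screening or many-body effects in real colloidal
or biomolecular systems, which are outside the model's scope.

## Degenerate inputs and edge behavior

- ε<sub>in</sub> = ε<sub>out</sub> (k = 0): all image strengths vanish;
  solvers return bare Coulomb at level 0.
- Conductor-grade spheres are represented as ε<sub>in</sub> = 10⁸
  (g ≈ 5e−9); the substituted line nodes underflow to the center, exactly
  the classical neutral-conductor image pair.
- R at contact: reflection solvers require a positive gap; the critical
  condition itself is evaluated *at* contact for thresholds.
- Q = 0 on one sphere: that sphere still polarizes; with k = 0 on the other
  sphere the converged energy reduces exactly to the single-sphere
  polarization energy (regression-tested).
- Opposite-sign charges are accepted by the force machinery (Coulomb
  attraction plus polarization); the critical condition, which divides by
  Q₁Q₂, rejects them.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `tol` | 1e−12 (reduced energy) | per-level increment threshold for convergence |
| `n_nodes` | 16 | Gauss–Legendre points per line image (oracle); 16 → ~1e−7 energy accuracy, 32 → ~1e−11 |
| `n_bins` | 8192 | positional compaction resolution of per-level image clouds |
| `max_level` | 200 | reflection cap; ~30–60 levels suffice except very near contact |
| `h_rel` | 1e−5 | finite-difference step, relative to R |
| mode | `exact` | three-point dipole series vs leading term (`leading`) |

The validation sweep uses radius 1 nm (equal-size family) and vacuum
ε<sub>out</sub> = 1 throughout; all quantities being scale invariant, the
choice of nm-scale radii matches the worked example's colloidal/nanoparticle
regime without loss of generality.
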