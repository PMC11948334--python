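# polimage

Image-charge electrostatics for charged polarizable spheres, and
quantitative critical conditions for **like-charge attraction (LCA)**.

Coulomb's law says like charges repel — but at short range two dielectric
spheres polarize each other, and the induced surface charge can overwhelm
the bare repulsion. This matters wherever charged, polarizable particles
meet: colloidal self-assembly and crystallization, ion pairing, aerosol and
dust charging, protein–surface interactions. `polimage` is for researchers
who need either (a) accurate pair energies/forces for the polarizable-sphere
model, e.g. to tabulate pair potentials for Monte Carlo / molecular dynamics,
or (b) a fast, closed-form answer to the question *"will these two
like-charged spheres attract, and inside what distance?"*.

## The model and the theory

Each sphere has radius *a*, relative permittivity ε<sub>in</sub> and a
central charge *Q* (in units of *e*), immersed in a medium ε<sub>out</sub>
at center distance *R*. Two dimensionless numbers control everything:
the dielectric contrast *k* = (ε<sub>in</sub>−ε<sub>out</sub>)/(ε<sub>in</sub>+ε<sub>out</sub>)
and the contact parameter *t* = *a*/*R*.

* **Single sphere (exact):** the polarization response is a Kelvin image
  −*kQa*/*R* plus a Neumann line-image density ∝ *r*^(*g*−1) with
  *g* = ε<sub>out</sub>/(ε<sub>in</sub>+ε<sub>out</sub>). Resumming the line
  image through the incomplete beta function B<sub>t²</sub>(g, 0) condenses
  it into **three images at fixed points**: charges ∓*Qk*/2 at the axial
  surface points and a central dipole p = *Qkag*·Σ<sub>n≥0</sub> t²ⁿ/(n+g).
* **Two spheres (converged):** iterative image reflections, either with the
  full Kelvin + line machinery (the accurate reference solver) or with the
  three-point bookkeeping (fast, percent-level).
* **Critical condition (closed form):** one reflection level with p ≈ *Qka*
  gives the force zero as

  k₁(Q₂/Q₁)·h(t₁) + k₂(Q₁/Q₂)·h(t₂) = 1,  h(t) = t³(2−t²)/(1−t²)²,

  with a unique root R<sub>c</sub>: attraction for every R < R<sub>c</sub>.
  For equal sizes this reads χ·h(t) = 1 with
  χ = k₁(Q₂/Q₁) + k₂(Q₁/Q₂), and since h(1/2) = 7/18, LCA requires
  **χ > 18/7**: equal-size spheres with equal charges (χ = k₁+k₂ ≤ 2) can
  never attract, and no LCA is possible in a medium more polarizable than
  the spheres. For equal charges, k·[h(t₁)+h(t₂)] = 1 — attraction driven
  by size asymmetry, maximal for conductors.

Units are reduced throughout: nm, *e*, energies in e²/(4πε₀·nm) ≈ 1.44 eV.

## Worked example

The benchmark system: two *a* = 1.25 nm spheres in vacuum, ε₁ = ε₂ = 20,
charges Q₁ = −1e and Q₂ = −7e — like-charged, strongly polarizable,
charge-asymmetric.

```bash
polimage rc --a1 1.25 --a2 1.25 --q1 -1 --q2 -7 \
            --eps1 20 --eps2 20 --eps-out 1 --validate
```

prints

```json
{
  "lca_occurs": true,
  "R_c_nm": 3.19184995383011,
  "t_c": [0.3916224189987512, 0.3916224189987512],
  "residual": 3.5388358909926865e-16,
  "method": "eq_general",
  "numeric_Rc_nm": 3.1495317024511036,
  "rel_discrepancy": 0.013436363045995834
}
```

Reading: the closed-form theory predicts a critical center distance
R<sub>c</sub> ≈ 3.192 nm (surface gap ≈ 0.69 nm); inside it the two
negative spheres *attract*. The converged image-reflection solver puts the
actual force zero at 3.150 nm — the closed form is off by 1.3% here, and by
0.02–2.4% across the validation sweep (accuracy improves with
polarizability; see `docs/methods.md`).

The force curve behind that number:

```bash
polimage force-curve --a1 1.25 --a2 1.25 --q1 -1 --q2 -7 \
    --eps1 20 --eps2 20 --eps-out 1 \
    --d 0.1:2:8 --method coulomb,first_level,three_point --out forces.csv
```

```text
d_nm,R_nm,E_coulomb,F_coulomb,E_first_level,F_first_level,E_three_point,F_three_point
0.1,2.6,2.69230769231,1.03550295858,1.43493750179,-1.18967986647,1.49967147914,-0.395688529392
0.642857142857,3.14285714286,2.22727272727,0.70867768595,1.68938683471,-0.0402250375465,1.65006291204,-0.0526246438047
0.914285714286,3.41428571429,2.05020920502,0.600479683479,1.67480002047,0.12663244342,1.64223491149,0.096107444694
2,4.5,1.55555555556,0.345679012346,1.43881328905,0.237569860313,1.42914033628,0.226693129963
```

(abridged). The bare Coulomb force is repulsive everywhere (F > 0); the
polarized forces turn negative — attractive — below d ≈ 0.65 nm, with a
single sign change.

Phase diagrams and larger validation sweeps:

```bash
polimage phase-diagram --mode equal_size --out chi_curve.csv
polimage phase-diagram --mode equal_charge --k-values 0.01,0.1,0.5,1.0 --out size_curves.csv
polimage validate-sweep --n 12 --seed 1 --out sweep.csv
```

The same machinery is available as a library
(`polimage.solve_rc`, `polimage.force`, `polimage.reflect_neumann`, ...);
parameters can also be given in a flat TOML file via `--config`.

## Layout

```
src/polimage/
  model.py         domain types, units, dimensionless parameters
  single_sphere.py Neumann images, incomplete-beta resummation
  three_point.py   three-point image formula, dipole strengths
  two_sphere.py    reflection solvers, forces, level decomposition
  critical.py      critical conditions, R_c solvers, phase diagrams
  cli.py           polimage CLI, TOML config, CSV/JSON output, sweeps
docs/methods.md    model details, numerics, accuracy characterization
scripts/acceptance.py  the validation sweep above
```
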