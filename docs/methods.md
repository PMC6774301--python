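# Methods

## Scope and model assumptions

`pbforce` models the electrostatics of two-partner recognition under three
simplifying assumptions:

* **Rigid bodies.** Both partners keep their bound-state conformation at
  every separation; only partner B is translated.
* **Straight-line trajectory.** Separation proceeds along a single axis,
  the normalized mean of the cross-interface atom-pair vectors, roughly
  perpendicular to the binding interface. Complexes for which this is
  geometrically unsound are removed by the pruning filters rather than
  treated specially.
* **Linear, salt-free continuum solvent.** The potential solves
  ∇·(ε∇φ) = −4πC ρ with zero ionic strength. No Debye term is included:
  all profile-shape and category conclusions are about the salt-free
  dielectric response. Nonpolar and van der Waals terms are out of scope.

Units: lengths in Å, charges in e, potentials in kT/e, energies in kT,
forces in kT/Å. The Coulomb constant C = e²/(4πε₀·kT·1 Å) ≈ 560.46 kT·Å/e²
is computed from CODATA constants at T = 298.15 K.

## Separation geometry and pruning

Interface pairs are all cross-partner atom pairs with d_ij strictly below
the 5 Å cutoff (hydrogens included; a flag restricts to heavy atoms). The
axis is A⃗ = (Σ U⃗_ij)/n, normalized; its sign is flipped if needed so that
moving B by +d increases the centroid separation. A mean-vector magnitude
below 1e-6 Å (fully interlocked interfaces) is a hard error.

Three filters, with the boundary conventions made explicit:

| filter | rule | boundary |
|---|---|---|
| 1-Å overlap | fraction of pair distances that grew after a 1 Å separation must exceed 0.80 | strict > |
| 10-Å clash | no cross-partner pair below 4 Å once separated by 10 Å | reject on < 4 |
| slope | least-squares slope of mean pair distance vs imposed separation ≥ 0.8 | inclusive ≥ |

The pair list for the overlap and slope filters is frozen at the bound
state, and the slope fit includes d = 0. A perfectly detected axis on a
flat interface gives slope 1; for interfaces with diagonal contacts the
slope settles slightly below 1 (0.95 on the contact-gap slab fixture).

Note that the overlap filter only rejects an axis when an appreciable
fraction of pair vectors is *anti-aligned* with it: a lateral shift of
magnitude t increases any perpendicular pair distance by √(d²+t²)−d > 0.
Sliding geometries are therefore detected through their anti-aligned
diagonal contacts, which dense interfaces supply naturally.

## Dielectric models

**Two-dielectric.** ε_in (default 2) inside the probe-closed molecular
volume, ε_out (default 80) elsewhere. The closed volume is computed in
three steps: nodes inside any van der Waals sphere are solute; nodes
farther than R_i + r_probe from every atom are solvent-accessible; the
remaining contact-shell nodes are solute unless they lie within r_probe
(default 1.4 Å) of an accessible node (distance via a Euclidean distance
transform of the accessible mask). With r_probe = 0 this reduces exactly to
the van der Waals union. The probe closing is essential: it is what fills a
sub-water-sized inter-partner gap with ε_in and thereby produces the
desolvation signature at 2–4 Å separation.

**Gaussian smooth.** ρ_i(r) = exp(−r_i²/(σ²R_i²)),
ρ_mol = 1 − Π_i(1−ρ_i), ε(r) = ρ_mol ε_in + (1−ρ_mol) ε_out. σ is the
dimensionless width multiplier (σ = 0.96 and σ = 0.7 are the two values
exercised throughout). Per-atom contributions are truncated where
ρ_i < 1e-6, bounding the density error by 1e-6 per atom. Larger σ extends
the low-dielectric halo, effectively enlarging the molecule.

ε values, probe radius, and σ are all configurable; the defaults follow
common continuum-electrostatics practice since the underlying physics does
not fix them.

## Grid solver

Node-centered regular grids; the box is sized so the solute (including
radii) fills at most 70% of each axis, and grids are non-cubic when the
solute is. The 7-point flux stencil uses the harmonic mean of the two
adjacent node ε values on each edge — the choice that keeps the normal flux
continuous across a sharp dielectric jump. Atomic charges are spread over
their 8 surrounding nodes with trilinear weights (total charge conserved to
machine precision; atoms must sit ≥ 2 nodes from the boundary). Dirichlet
boundary values are the screened Coulomb sum Σ C q_i/(ε_out r_i) (or zero,
configurable).

The resulting system is symmetric positive definite and is solved with
Jacobi-preconditioned conjugate gradients to a relative-residual tolerance
(default 1e-8), with the residual re-checked independently after the
solve; an SOR path exists as a cross-check. Iteration order is
deterministic, so reruns are bit-identical per platform. Potentials are
interpolated trilinearly; fields are central-difference gradients of the
node potential, interpolated per component (exact for linear fields).

Grid energy is ½ Σ q_node φ_node, which includes the grid self-energy of
every charge; it is only ever used in differences between systems gridded
identically.

## Forces

**F_int (field force).** The source partner's charges are gridded, the
dielectric map is built *from the source partner alone*, and the force on
the target is Σ q_j E(r_j), projected on the separation axis with
negative = attractive. Treating the target as test charges makes the qE sum
exactly the negative gradient of the screened interaction energy
Σ q_j φ_src(r_j) — the package computes no dielectric-boundary (Maxwell
stress) force, and with the target's uncharged cavity in the map the qE sum
alone would inherit the cavity's field enhancement (up to ~2× on flat
slabs) without the boundary-pressure term that cancels it. The test-charge
convention also matches how a single source potential map is reused to
evaluate forces along an approach trajectory in field-force tools. The
two-cavity variant remains available (`include_target_cavity=True`) for
studying that enhancement.

**F_ene (energy-gradient force).** ΔE_ele(d) = E_complex(d) − E_A − E_B(d)
with every system gridded on one fixed GridSpec spanning the bound state
and the 10 Å configuration, so grid self-energies cancel. Under the
two-dielectric model, E_total = analytic Coulomb in ε_in + polar solvation,
the latter as ½ Σ q_i[φ_solvated − φ_uniform](r_i) from two solves on the
same grid (solvated map vs uniform ε_in). Under the Gaussian model,
E_total is the grid energy of a single solve. F_ene = −dΔE/dd with central
differences at interior distances and second-order one-sided stencils at
d = 0 and d = 10.

When the separation axis is aligned with a grid axis and the spacing
divides the 1 Å step (the profile computations use h = 0.5 Å), partner B
occupies identical sub-grid offsets at every distance, so its
self-discretization errors cancel exactly along the profile. This matters:
ΔE is a ~5 kT difference between ~10² kT totals, and non-commensurate
spacing leaves visible noise in the numerical derivative.

At d = 10 Å the desolvation gradient is negligible and F_int ≈ F_ene; the
shipped fixtures agree to 2–7% (or < 0.02 kT/Å absolute for the weakest
profile). The residual difference is physical in origin — ΔE retains the
target-cavity dielectric terms that the test-charge F_int excludes — and
grows with the interface dipole strength.

## Profile classification

Given f(d) sampled at d = 0…10 with tolerance tol (default 0.01 kT/Å,
absorbing solver noise around zero):

1. f > −tol everywhere → REPULSIVE;
2. else if argmin f = 0 (ties toward smaller d) → MAX_AT_BOUND;
3. else if f(0) > +tol → SOFT_LANDING;
4. else → MAX_AT_DISTANCE.

The rules are an explicit operationalization of categories that are
recognized visually in practice; they are total and mutually exclusive
(property-tested), and widening tol can only move profiles toward
REPULSIVE, never conjure SOFT_LANDING from MAX_AT_BOUND.

## Synthetic complexes

The generator builds each partner as two parallel m×m layers of
pseudo-atoms (uniform radius 1.8 Å, lattice 3 Å by default): an interface
layer carrying the requested interface charge and a back layer absorbing
the remainder of the net charge. This gives exact, independent control of
net and interface polarity — including the dipolar combination (same-sign
nets, opposite-sign interfaces). An optional *interface motif* concentrates
charge on the four central facing atoms (compensated on the outer ring, so
interface totals are unchanged); like-signed motifs on both partners
emulate the specific short-range pairwise repulsion that turns the
bound-state force repulsive. The interlocked variant threads an uncharged
arm of B through A, creating the persistent 10 Å clash the pruning filter
exists to catch.

Shipped fixtures and their designed behaviour (F_int, two-dielectric):

| fixture | nets (e) | interfaces (e) | motif | gap (Å) | category |
|---|---|---|---|---|---|
| attract_bound | −3 / +3 | −3 / +3 | — | 3.6 | MAX_AT_BOUND |
| repulsive_pair | +3 / +3 | +1 / +1 | — | 4.0 | REPULSIVE |
| dipolar_interface | +1 / +1 | −3 / +3 | +1.5 / +1.5 | 4.0 | SOFT_LANDING |
| distant_attractor | −3 / +3 | −2 / +2 | +1.5 / +1.5 | 4.0 | MAX_AT_DISTANCE |
| interlocked | −3 / +3 | −2 / +2 | — | 4.0 | rejected (clash) |

`attract_bound` places the interface layers at 3.6 Å — two van der Waals
radii, i.e. atomic contact. That close contact is what produces the
textbook two-dielectric F_ene shape: strong attraction at contact, a
repulsive desolvation maximum at d = 2 (inside the 2–4 Å window where the
closing gap expels water), attraction beyond — while the Gaussian σ = 0.7
profile stays smooth, and the σ = 0.96 F_ene is repulsive at the bound
state (the larger effective molecular size increases the desolvation
penalty). With the wider 4 Å gap the desolvation gradient dominates all the
way to contact and the F_ene peak sits at d = 0–1 instead: the bump's
interior position is a genuine close-contact effect, not a free parameter.

What the slabs do **not** emulate: real residue chemistry, interface
roughness and water channels, conformational response, and charge
magnitudes beyond a few e. Passing tests on these fixtures validates the
machinery and the qualitative model contrasts; they say nothing about
category frequencies in real complexes, which require a curated structural
dataset.

## Problem sizes and tolerances

The test suite and the acceptance script use: a 65³ node grid (0.8 Å) for
the Coulomb-limit check; 17³ for the dense-solve comparison; 0.5 Å
commensurate grids (≈ 37×37×69 nodes) for all fixture profiles; solver
tolerance 1e-8 (1e-13 for the dense comparison). The full suite runs in
about two minutes on one CPU.

## Known limitations

* F_int omits dielectric-boundary and ionic force components; zero salt
  removes the latter by construction, and the former is excluded together
  with the target cavity (see Forces above).
* Absolute energies inherit grid self-energy and boundary-placement
  effects; only differences on identical grids, and force projections, are
  quantitative.
* The Coulombic Dirichlet boundary at 70% fill is adequate for desk-scale
  systems but biases weak long-range forces by a few hundredths of kT/Å;
  enlarging the box shifts absolute profile values while leaving profile
  shapes and category calls unchanged.
* Temperature enters only through C; comparative results (shapes,
  orderings, categories) are invariant to the kT convention.
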