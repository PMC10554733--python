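# Methods

This note documents the models, numerical choices and limitations behind
`rcem`: what is computed, which knobs matter, and what the synthetic-data
validation does and does not demonstrate.

## Structures and parameterization

PDB files are read with gemmi.  Alternate conformers are resolved per atom:
`dark` keeps the highest-occupancy conformer; `photoactivated` keeps the
lowest-occupancy conformer with occupancy ≥ 0.2 where alternates exist (the
partial-occupancy photoactivated population of time-resolved refinements,
nominally 30%), else the highest.  Crystallographic waters are stripped by
default — solvent is treated implicitly by the continuum model — with a
`keep_waters` flag for explicit retention.

Charges and radii come from whitespace-delimited tables
(`residue_name atom_name charge radius`).  The shipped amino-acid table is a
simplified polar-group set: charges sit on backbone amides, carbonyls and
side-chain polar/charged groups and sum exactly to each residue's formal
charge; nonpolar CH_n hydrogens are implicit.  Radii are PARSE-like (C 1.7,
N 1.5, O 1.4, S 1.85, H 1.0 Å).  The table is a config input, so a
CHARMM22-parameterized file can be substituted without code changes — and
should be, for publication-grade protein runs.  Cofactors take per-residue
override tables (two per redox couple, one per charge state); hydrogens of a
cofactor not listed in its override are treated as nonpolar CH hydrogens at
+0.09 e, the standard convention for phytol/isoprene tails.

Hydrogen placement uses ideal-geometry templates for polar hydrogens only:
the backbone amide H (N–H 1.01 Å along the bisector of the C(prev)–N and
CA–N directions; skipped for proline and chain-initial residues) and the
side-chain polar hydrogens of Ser, Thr, Cys, Tyr, Lys, Arg, Asn, Gln, His
and Trp from bond/angle/dihedral templates.  His defaults to the Nε-H
tautomer; the site config can override per residue.  Placement is
deterministic and idempotent.  This replaces force-field hydrogen
optimization deliberately: Em values here are dominated by heavy-atom
charges and the continuum response, and the template module is swappable.

Titratable sites (Asp, Glu, His, Cys, Tyr, Lys, Arg, N-/C-termini) carry two
side-chain charge vectors that supersede the base table on the member atoms.
State conventions: state 1 = deprotonated for acids (Δq = −1), protonated
for bases (Δq = +1), reduced for redox couples (Δq = −1).  Reference
midpoint potentials for the shipped redox templates: BChl b −665 mV,
BPheo b −429 mV, menaquinone −256 mV vs NHE (one-electron couples).

## Finite-difference linear Poisson–Boltzmann solver

Seven-point stencil on a cubic grid; potentials in kcal/(mol·e), Coulomb
constant 332.0636 kcal·Å/(mol·e²), 1 eV = 23.061 kcal/mol.  Numerical
choices, all exposed as arguments:

- **Dielectric boundary**: van der Waals union of atom spheres.  Each grid
  edge gets the harmonic mean of ε_protein and ε_solvent weighted by the
  fraction of the edge inside the union, estimated from 24 subsegment
  samples.  Harmonic averaging makes the Born-ion error decrease smoothly
  and monotonically with grid refinement (relative error 2.6% → 0.5% → 0.1%
  at 1.0/0.5/0.25 Å) and keeps half-grid translations below 2%.
- **Screening**: κ² from the ionic strength (Debye length ≈ 9.7 Å at
  100 mM, ε 80, 300 K), zero inside the solute plus a 2.0 Å Stern layer.
- **Charges**: trilinear spreading to the eight surrounding nodes.  The
  grid self-energy is never needed explicitly: solvation energies are
  differences between a heterogeneous and a uniform-ε solve on the
  identical grid and charge spreading, so it cancels by construction.
- **Boundary condition**: Debye–Hückel potential superposed per source
  charge, exp(−κ(r−a))/(ε_w r (1+κa)) with a the solute's effective
  ion-exclusion radius.  Per-charge superposition (rather than a single
  total-charge monopole) keeps the discrete operator exactly linear in the
  charges, which the superposition tests rely on.
- **Focusing**: the coarsest level is a cube enclosing the structure
  (atom spheres included) plus a 15 Å margin; finer levels default to 65³
  nodes centered on the region of interest and take Dirichlet values
  interpolated from the previous level.  A finer level that would poke out
  of its parent is shrunk and re-centered to fit.  Default schedule
  2.5/1.0/0.3 Å; the validation suite uses 1.0/0.5/0.25 Å against the Born
  oracle.
- **Solver**: Jacobi-preconditioned conjugate gradients, relative residual
  ≤ 10⁻⁶ enforced (target 10⁻⁸), max 10 000 iterations; non-convergence
  raises with the residual.

## Microstate model and Monte Carlo

E(x) = Σ xᵢhᵢ + Σ_{i<j} xᵢxⱼW_ij with hᵢ the state-1 energy: intrinsic term
(desolvation + background) plus ln10·RT·(pKa−pH) for acids,
ln10·RT·(pH−pKa) for bases, and +c·bias (c = 23.061 cal/(mol·mV)) for redox
sites.  The sign conventions are pinned by tests: an uncoupled acid titrates
as 1/(1+10^(pKa−pH)), and adding a positive fixed charge near a redox site
never lowers its Em.

Sampling: exact Boltzmann enumeration up to 20 sites (the oracle), and
Metropolis MC — one sweep = N single-site flips in random order plus a
double flip for every pair with |W| > 2 kcal/mol (rescues strongly coupled
pairs from single-flip traps), 10% burn-in, numba kernel, bit-reproducible
for a fixed seed.  10⁵ sweeps reproduce exact populations of random 12-site
systems to < 0.01.

Em search: bisection on the bias over ±2 V to 1 mV, with the midpoint
condition (reduced population 0.5 ± 0.01) asserted on every result; the
bias method agrees with the midpoint of a directly scanned titration curve
to well under 2 mV on coupled toys.

Decomposition: an EmRecord splits Em − Em_ref into desolvation, background
and titration-shift components (the last defined as the remainder, so the
identity Em = Em_ref + Σ components is exact by construction and checked to
1 mV).  Per-residue contributions are the residue's charges — at their
most-probable protonation at pH 7 with the cofactor oxidized — dotted into
the potential of the site's difference charges, signed so that stabilizing
the reduced state is positive.  Pair differences follow
[L→site_L] + [M→site_L] − [L→site_M] − [M→site_M], sorted by magnitude.
Time courses report ΔEm against the first (dark) structure, which is zero
by construction.

## NSD

The 24-atom core (4 N, 8 Cα, 8 Cβ, 4 meso C; canonical order
NA C1A C2A C3A C4A CHB … CHA) is extracted by atom name with a configurable
mapping, covering both bacteriochlorophyll- and bacteriopheophytin-type
naming; metal and substituents are ignored.  Superposition is closed-form
Kabsch/SVD, mass-unweighted.

The mode basis is constructed at import from an idealized planar D4h
macrocycle (bond lengths 1.36–1.44 Å): a z-displacement harmonic model with
unit springs on bonded pairs, rigid z-translation and x/y tilts projected
out, eigenvectors classified by C4v projection operators (out-of-plane
parity reduces D4h to C4v on z-patterns) and the lowest mode taken per
symmetry: B2u saddling (β-carbons, meso in-plane), B1u ruffling
(meso-alternating), A2u doming, Eg waving pair (aligned so waving-y is the
quarter-turn image of waving-x), A1u propellering.  Modes are unit-norm,
mutually orthogonal to < 10⁻¹⁰ and sign-fixed by the first significant
canonical atom displacing in +z.  The basis serializes to a versioned text
file so published NSD eigenvectors can be substituted.

Amplitudes follow the projection formula above; Σd² + residual² equals the
total out-of-plane power to 10⁻⁹ (Parseval).  Real chlorins are not D4h
(one saturated ring), so projections onto this ideal basis carry a nonzero
residual — reported, never hidden.  Time courses flag |Δd| ≤ 0.03 Å as
"practically unchanged".

## Synthetic data

The generators emulate the *statistical and geometric structure* the
analysis assumes, not realistic proteins: Born spheres with closed-form
transfer energies; point-charge titration systems (linear/shell/mirror-pair
geometries, Coulomb couplings at ε 4, random intrinsic energies of scale
1.5 kcal/mol — large enough to produce couplings above the 2 kcal/mol
double-flip threshold at 15 Å shell radius) with exact-enumeration
expectations attached; mirror-branch redox pairs inside a 10 Å
low-dielectric sphere with an optional ±0.5 e dipole as the minimal model
of branch asymmetry; and basis-built deformed macrocycles under random
rigid motions.  All generators are seed-deterministic and attach their
ground truth.  Passing these tests demonstrates correct electrostatics,
sampling and projection machinery; it does not validate force-field
charges, conformer handling of real refinements, or XFEL-specific artifacts
— applying the pipeline to deposited structures additionally needs
RESP-quality cofactor charge files and a protein-grade charge table.

## Problem sizes and defaults

The validation suite runs on one CPU in a few minutes: 65³ focusing grids
(the Born check uses 1.0/0.5/0.25 Å levels), 12-site MC systems at 10⁵
sweeps × 5 seeds, 100-case NSD round trips.  Whole-protein runs with the
default 2.5/1.0/0.3 Å schedule and one focused solve per site pair scale as
O(N_sites²) LPB solves and are hours-scale per structure; the module
boundaries let a user cache the SiteEnergyTable (TSV serialization) between
the expensive electrostatics and the cheap titration/analysis stages.

## Known limitations

- Nonlinear PB, membrane-slab dielectrics and periodic boundaries are out
  of scope; no molecular-surface option beyond the sphere union yet
  (a probe-based surface would shift desolvation terms; the boundary
  builder is the single place to change).
- The shipped amino-acid charges are a documented simplification, not
  CHARMM22; absolute Em values from them are not publication-grade.
- Conformational relaxation and coupled proton-transfer pathways are not
  modeled; protonation states respond to the redox state only through the
  rigid-geometry microstate model.
- The D4h reference basis is an idealized-model construction; published NSD
  eigenvector sets can be dropped in via the basis file but are not
  bundled.
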