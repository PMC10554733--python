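# rcem

Continuum-electrostatics redox titration and chlorin-ring distortion
analysis for photosynthetic reaction-center structures.

`rcem` is aimed at structural biologists and computational biophysicists who
want to ask, for a series of (e.g. time-resolved) reaction-center structures:
*what are the redox midpoint potentials (Em) of the electron-transfer
cofactors in each structure, which residues are responsible for branch
asymmetry, and how are the chlorin macrocycles deformed?*  It implements the
standard FDPB/Monte-Carlo workflow for protein electrostatics plus a
normal-coordinate structural decomposition (NSD) of macrocycle out-of-plane
distortion, with a synthetic-data module so every stage can be validated
against closed-form oracles without downloading any structures.

## What it computes

**Em by continuum electrostatics.**  The electrostatic potential obeys the
linear Poisson–Boltzmann equation

    ∇·ε(r)∇φ(r) − ε_w κ² φ(r) = −4π k_e ρ(r),

solved by finite differences on a cubic grid with a three-step focusing
schedule (default resolutions 2.5, 1.0, 0.3 Å), ε = 4 in the protein
interior and 80 in water, Debye screening κ from the ionic strength (100 mM)
outside a 2 Å Stern layer.  For each redox site the intrinsic reduction
energy combines a desolvation term (reaction-field difference between the
protein and the isolated cofactor in water) and a background term (fixed
protein charges in the potential of the site's reduced-minus-oxidized
difference charges).  Titratable residues (Asp, Glu, Arg, Lys, His, Tyr,
Cys, chain termini) couple to the cofactors through a site–site interaction
matrix W; the protonation/redox microstate ensemble

    E(x) = Σᵢ xᵢ hᵢ + Σ_{i<j} xᵢxⱼ W_ij

is sampled by Metropolis Monte Carlo (with exact 2^N enumeration as the
small-system oracle).  A bias potential applied to the redox site is tuned
by bisection until both redox states are equally populated — the Nernst
midpoint condition — and

    Em = Em(reference) + bias*,

with reference midpoints Em(BChl b) = −665 mV, Em(BPheo b) = −429 mV and
Em(menaquinone) = −256 mV vs NHE.  Per-residue contributions to Em, L/M
branch pair differences

    Δ = [L→Em(site_L)] + [M→Em(site_L)] − [L→Em(site_M)] − [M→Em(site_M)],

and ΔEm time courses relative to a dark-state structure round out the
analysis.

**NSD.**  The 24-atom macrocycle core (4 N + 20 C) is superposed on a planar
D4h reference by least squares (Kabsch), and the out-of-plane displacement
is projected on the six lowest-frequency out-of-plane modes,

    d_Γ = Σᵢ Δzᵢ (n_z^Γ)ᵢ,   Γ ∈ {saddling B2u, ruffling B1u, doming A2u,
                                   waving Eg(x)/Eg(y), propellering A1u},

the minimal-basis approximation; distortion outside the six-mode span is
reported as a residual.

## Worked example

A symmetric two-branch toy system (two one-electron cofactors at mirror
positions inside a low-dielectric sphere) with a +0.5/−0.5 dipole placed
near the L branch:

```python
import numpy as np
from rcem import synthetic, pb, em_analysis, nsd
from rcem.structure import PhysicalConditions

cond = PhysicalConditions(ionic_strength=0.0)
st, analytic = synthetic.make_born_system(2.0, 1.0)
dg = pb.reaction_field_energy(st, cond, schedule=[1.0, 0.5, 0.25])
print(f"Born transfer energy: {dg:.2f} kcal/mol (analytic {analytic:.2f})")

cond = PhysicalConditions(ionic_strength=0.1)
st, sites = synthetic.make_mirror_branch_system(
    asymmetric_dipole={"charge": 0.5, "position": (6.5, 0, 2.5),
                       "separation": 1.0})
for rec in em_analysis.compute_em_profile(st, sites, cond,
                                          schedule=[1.0, 0.5]):
    print(f"{rec.site_id}: Em = {rec.em:7.1f} mV  "
          f"(desolvation {rec.desolvation:+.1f}, "
          f"background {rec.background:+.1f}, "
          f"titration {rec.titration_shift:+.1f})")

mac, truth = synthetic.make_deformed_macrocycle(
    np.array([0.20, -0.10, 0.05, 0.0, 0.0, 0.08]), rigid_motion_seed=11)
res = nsd.analyze_macrocycle(mac)
print({k: round(v, 3) for k, v in res.d.items()})
```

prints

```
Born transfer energy: -19.74 kcal/mol (analytic -19.72)
RD-L: Em = -1266.4 mV  (desolvation -951.7, background +114.6, titration -0.2)
RD-M: Em = -1369.9 mV  (desolvation -951.7, background +10.8, titration -0.0)
{'sad': 0.2, 'ruf': -0.1, 'dom': 0.05, 'wav_x': -0.0, 'wav_y': -0.0, 'pro': 0.08}
```

The FDPB solver reproduces the Born solvation energy to ~0.1%; both
branches lose ~950 mV to burial in the low-dielectric cavity (identically,
by symmetry); the dipole's +q pole facing the L branch stabilizes the
reduced state there and splits the branches by ~100 mV, the sign Coulomb's
law predicts; and the NSD round trip returns exactly the mode amplitudes the
deformation was built from, despite the random rigid motion.

## Command line

```sh
rcem em  --config run.toml --out out/   # em_profile/contributions/pair_differences/timecourse.csv
rcem nsd --config nsd.toml --out out/   # nsd_timecourse.csv
rcem selftest                           # desk-scale property suite
rcem synth --out fixtures/              # synthetic fixtures with ground truth
```

Configs are TOML; every CSV carries a header with the package version,
config hash and seed, so identical configs reproduce identical files.
Applying the pipeline to deposited reaction-center structures additionally
requires cofactor charge sets (RESP-quality, supplied as
`charges_state0`/`charges_state1` parameter files per cofactor) which are
not shipped.

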