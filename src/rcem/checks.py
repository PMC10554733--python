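"""Desk-scale verification suite.

Each check runs a piece of the pipeline on a system with a closed-form or
exactly enumerable reference and reports the computed value, the reference,
and a pass/fail at the documented tolerance.  The CLI ``selftest`` command
and the reproduction script both drive these functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nsd, pb, synthetic
from .constants import K_COULOMB, MV_TO_KCAL, debye_kappa2, debye_length
from .em_analysis import pair_difference_table
from .structure import PhysicalConditions
from .titration import (SiteEnergyTable, curve_midpoint, enumerate_exact,
                        find_em, mc_sample, titration_curve)


@dataclass
class CheckResult:
    name: str
    value: float
    reference: float
    tolerance: float
    relative: bool = False

    @property
    def deviation(self) -> float:
        if self.relative:
            return abs(self.value - self.reference) / abs(self.reference)
        return abs(self.value - self.reference)

    @property
    def passed(self) -> bool:
        return bool(self.deviation <= self.tolerance)


def born_ion(spacings=(1.0, 0.5, 0.25), radius: float = 2.0,
             charge: float = 1.0, npoints_fine: int = 65,
             coulomb_constant: float | None = None) -> CheckResult:
    """FDPB Born transfer energy for a 2 A, +1 e sphere, eps 4 -> 80.

    *coulomb_constant* exists only for the selftest's sensitivity debug
    mode (perturbing it must break this check).
    """
    conditions = PhysicalConditions(ionic_strength=0.0)
    st, analytic = synthetic.make_born_system(radius, charge, conditions)
    if coulomb_constant is not None:
        analytic *= coulomb_constant / K_COULOMB
    value = pb.reaction_field_energy(st, conditions, schedule=list(spacings),
                                     npoints_fine=npoints_fine)
    return CheckResult("born_ion_transfer_energy", value, analytic,
                       tolerance=0.02, relative=True)


def screened_coulomb(r_eval: float = 10.0, radius: float = 2.0,
                     ionic_strength: float = 0.1) -> CheckResult:
    """Potential of +1 e at 10 A in eps=80, I=0.1 M vs the Debye-Hueckel
    closed form exp(-kappa (r-a)) / (eps r (1 + kappa a))."""
    conditions = PhysicalConditions(ionic_strength=ionic_strength,
                                    eps_protein=80.0, eps_solvent=80.0)
    st, _ = synthetic.make_born_system(radius, 1.0, conditions)
    grid = pb.GridSpec((0.0, 0.0, 0.0), 81, 0.5)
    model = pb.build_dielectric_model(st, grid, conditions)
    phi = pb.solve_lpb(model, boundary="analytic_debye",
                       source_coords=st.coords, source_charges=st.charges)
    value = float(phi.sample([[r_eval, 0.0, 0.0]])[0])
    kappa = math.sqrt(debye_kappa2(ionic_strength, 80.0, 300.0))
    a = radius + pb.STERN_LAYER
    analytic = (K_COULOMB * math.exp(-kappa * (r_eval - a))
                / (80.0 * r_eval * (1.0 + kappa * a)))
    return CheckResult("screened_coulomb_potential", value, analytic,
                       tolerance=0.02, relative=True)


def debye_length_check() -> CheckResult:
    """Debye length at 100 mM, eps 80, 300 K (~9.7 A)."""
    value = debye_length(0.1, 80.0, 300.0)
    analytic = 1.0 / math.sqrt(debye_kappa2(0.1, 80.0, 300.0))
    return CheckResult("debye_length_100mM", value, analytic, tolerance=1e-12)


def mc_vs_enumeration(seeds=(1, 2, 3, 4, 5), n_sites: int = 12,
                      n_sweeps: int = 100_000) -> CheckResult:
    """Max population deviation, Metropolis MC vs exact enumeration, over
    random 12-site systems."""
    conditions = PhysicalConditions()
    worst = 0.0
    for seed in seeds:
        spec = synthetic.ToySystemSpec(n_sites=n_sites, geometry="shell",
                                       seed=seed)
        _, table, exact = synthetic.make_toy_titration(spec)
        mc = mc_sample(table, conditions, n_sweeps=n_sweeps, seed=seed)
        worst = max(worst, float(np.max(np.abs(mc.populations
                                               - exact.populations))))
    return CheckResult("mc_vs_exact_max_population_dev", worst, 0.0,
                       tolerance=0.01)


def henderson_hasselbalch(pka: float = 7.0, n_sweeps: int = 100_000,
                          seed: int = 11) -> CheckResult:
    """Uncoupled-acid titration curve vs 1/(1+10^(pKa-pH)) at 7 pH points."""
    spec = synthetic.ToySystemSpec(n_sites=1, geometry="linear", seed=0,
                                   kinds=["acid"], model_pkas=[pka],
                                   g_intr_scale=0.0)
    _, table, _ = synthetic.make_toy_titration(spec)
    worst = 0.0
    for i, ph in enumerate(np.linspace(pka - 3, pka + 3, 7)):
        conditions = PhysicalConditions(pH=float(ph))
        r = mc_sample(table, conditions, n_sweeps=n_sweeps, seed=seed + i)
        expect = 1.0 / (1.0 + 10.0 ** (pka - ph))
        worst = max(worst, abs(float(r.populations[0]) - expect))
    return CheckResult("henderson_hasselbalch_max_dev", worst, 0.0,
                       tolerance=0.01)


def _coupled_redox_table(seed: int = 3) -> SiteEnergyTable:
    spec = synthetic.ToySystemSpec(
        n_sites=4, geometry="shell", seed=seed,
        kinds=["redox", "acid", "base", "acid"],
        model_pkas=[0.0, 6.5, 7.5, 7.0], em_refs=[-429.0] * 4)
    _, table, _ = synthetic.make_toy_titration(spec)
    return table


def em_bias_vs_midpoint(seed: int = 3) -> CheckResult:
    """Bias-potential Em vs the midpoint of a direct titration curve on a
    coupled toy system (agreement within 2 mV)."""
    conditions = PhysicalConditions()
    table = _coupled_redox_table(seed)
    site_id = table.sites[0].site_id
    res = find_em(site_id, table, conditions, sampler="exact", tol_mv=0.5)
    em_bias = res.em[site_id]
    grid_mv = np.linspace(res.bias_applied[site_id] - 40,
                          res.bias_applied[site_id] + 40, 33)
    curve = titration_curve(table, conditions, site_id, grid_mv, sampler="exact")
    em_curve = table.sites[0].em_ref + curve_midpoint(grid_mv, curve)
    return CheckResult("em_bias_vs_curve_midpoint_dev_mV",
                       abs(em_bias - em_curve), 0.0, tolerance=2.0)


def reference_em_recovery() -> CheckResult:
    """Isolated cofactor with zero desolvation/background/interactions must
    recover its reference midpoint potential (-429 mV)."""
    spec = synthetic.ToySystemSpec(n_sites=1, geometry="linear",
                                   kinds=["redox"], em_refs=[-429.0],
                                   g_intr_scale=0.0)
    _, table, _ = synthetic.make_toy_titration(spec)
    res = find_em(table.sites[0].site_id, table, PhysicalConditions(),
                  sampler="exact", tol_mv=0.5)
    return CheckResult("isolated_reference_em_mV",
                       res.em[table.sites[0].site_id], -429.0, tolerance=1.0)


def nsd_roundtrip(n_cases: int = 100, seed: int = 0,
                  max_amplitude: float = 0.6) -> tuple[CheckResult, CheckResult]:
    """Mode amplitudes recovered under random rigid motions, plus the
    Parseval identity sum(d^2) + residual^2 = sum(dz^2)."""
    rng = np.random.RandomState(seed)
    basis = nsd.default_basis()
    worst = 0.0
    worst_parseval = 0.0
    for case in range(n_cases):
        amps = rng.uniform(-max_amplitude, max_amplitude, size=6)
        mac, truth = synthetic.make_deformed_macrocycle(
            amps, rigid_motion_seed=(seed * 100_003 + case) % (2**31), basis=basis)
        res = nsd.analyze_macrocycle(mac, basis)
        worst = max(worst, float(np.max(np.abs(res.as_array() - amps))))
        aligned, _ = nsd.superpose(mac, basis)
        dz2 = float(np.sum((aligned[:, 2] - basis.ref_coords[:, 2]) ** 2))
        lhs = float(np.sum(res.as_array() ** 2) + res.residual ** 2)
        worst_parseval = max(worst_parseval, abs(lhs - dz2))
    return (CheckResult("nsd_roundtrip_max_error_A", worst, 0.0, tolerance=1e-6),
            CheckResult("nsd_parseval_max_violation", worst_parseval, 0.0,
                        tolerance=1e-9))


#: printed L/M pair contributions (mV) for the strongest accessory-BChl pair:
#: (L->Em(B_L), L->Em(B_M), M->Em(B_L), M->Em(B_M)) and the published
#: difference
PAIR_CONTRIBUTIONS_PHE_TYR = (0.0, 17.0, 39.0, -3.0)
PAIR_DIFFERENCE_PHE_TYR = 25.0


def pair_difference_arithmetic() -> CheckResult:
    """Pair-difference formula on the printed Phe/Tyr contributions."""
    cl_l, cl_m, cm_l, cm_m = PAIR_CONTRIBUTIONS_PHE_TYR
    rows = pair_difference_table(
        [("Phe-L181", "Tyr-M208")],
        {("Phe-L181", "L"): cl_l, ("Phe-L181", "M"): cl_m,
         ("Tyr-M208", "L"): cm_l, ("Tyr-M208", "M"): cm_m})
    return CheckResult("pair_difference_mV", rows[0].difference,
                       PAIR_DIFFERENCE_PHE_TYR, tolerance=1e-12)


def run_all(fast: bool = False, coulomb_constant: float | None = None
            ) -> list[CheckResult]:
    """The full desk-scale suite (ordered, deterministic)."""
    results = [
        born_ion(spacings=(1.0, 0.5) if fast else (1.0, 0.5, 0.25),
                 coulomb_constant=coulomb_constant),
        screened_coulomb(),
        debye_length_check(),
        mc_vs_enumeration(seeds=(1, 2) if fast else (1, 2, 3, 4, 5)),
        henderson_hasselbalch(),
        em_bias_vs_midpoint(),
        reference_em_recovery(),
    ]
    results.extend(nsd_roundtrip(n_cases=20 if fast else 100))
    results.append(pair_difference_arithmetic())
    return results
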