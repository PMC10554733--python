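"""Full-system Em assembly, per-residue decomposition and time courses.

Builds the site-energy table of a parameterized structure (intrinsic
energies from desolvation and background terms via the FDPB solver, plus the
site-site interaction matrix), determines each redox cofactor's midpoint
potential with the bias-potential method, decomposes Em into per-residue
electrostatic contributions, forms L/M-branch pair differences, and tracks
Em shifts across an ordered structure series relative to the dark state.

Sign conventions: a residue contribution is positive when the residue's
charges stabilize the reduced cofactor (raise Em); the pair difference is
[L-residue to Em(site_L)] + [M-residue to Em(site_L)] - [L-residue to
Em(site_M)] - [M-residue to Em(site_M)].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .constants import MV_TO_KCAL
from . import pb
from .structure import PhysicalConditions, SiteDefinition, Structure
from .titration import SiteEnergyTable, enumerate_exact, find_em


@dataclass
class EmRecord:
    """Computed midpoint potential of one redox site, with its breakdown."""

    structure_id: str
    site_id: str
    em: float  # mV vs NHE
    em_ref: float
    desolvation: float  # mV
    background: float  # mV
    titration_shift: float  # mV

    @property
    def components(self) -> dict[str, float]:
        return {"desolvation": self.desolvation, "background": self.background,
                "titration_shift": self.titration_shift}


@dataclass
class PairDifferenceRow:
    residue_L: str
    residue_M: str
    c_L_to_siteL: float
    c_L_to_siteM: float
    c_M_to_siteL: float
    c_M_to_siteM: float

    @property
    def difference(self) -> float:
        return (self.c_L_to_siteL + self.c_M_to_siteL
                - self.c_L_to_siteM - self.c_M_to_siteM)


def _site_charge_vector(structure: Structure, site: SiteDefinition,
                        state: int) -> np.ndarray:
    q = np.zeros(len(structure))
    vec = site.charges_state1 if state else site.charges_state0
    q[site.atom_indices] = vec
    return q


def _delta_charge_vector(structure: Structure, site: SiteDefinition) -> np.ndarray:
    q = np.zeros(len(structure))
    q[site.atom_indices] = site.delta_charges
    return q


def _background_charges(structure: Structure, sites: Sequence[SiteDefinition],
                        exclude: SiteDefinition) -> np.ndarray:
    """Fixed charges seen by *exclude*: all non-site atoms at their assigned
    charges and every other site's atoms at state-0 charges (other sites'
    titration enters through the interaction matrix instead)."""
    q = structure.charges.copy()
    for s in sites:
        q[s.atom_indices] = s.charges_state0
    q[exclude.atom_indices] = 0.0
    return q


def _model_structure(structure: Structure, site: SiteDefinition) -> Structure:
    """The reference model compound: the site's atoms alone in solvent."""
    atoms = [structure.atoms[i] for i in site.atom_indices]
    return Structure([a for a in atoms], id=f"{structure.id}:{site.site_id}:model")


def intrinsic_energy(site: SiteDefinition, structure: Structure,
                     sites: Sequence[SiteDefinition],
                     conditions: PhysicalConditions,
                     schedule: Sequence[float] = pb.DEFAULT_SCHEDULE,
                     npoints_fine: int = 65, margin: float = 15.0
                     ) -> tuple[float, float]:
    """Desolvation and background terms of a site's intrinsic energy.

    Desolvation: the state-1-vs-state-0 reaction-field energy difference in
    the protein minus the same in the isolated model compound,
    (q1+q0)G(q1-q0)/2 per environment by linearity.  Background: interaction
    of the site's difference charges with the fixed charges.  Both kcal/mol.
    """
    dq = _delta_charge_vector(structure, site)
    qsum = _site_charge_vector(structure, site, 0) + _site_charge_vector(structure, site, 1)
    site_pts = structure.coords[site.atom_indices]
    focus = site_pts.mean(axis=0)
    kw = dict(schedule=schedule, npoints_fine=npoints_fine, margin=margin)

    def rf_cross(st: Structure, dq_v, qsum_v) -> float:
        # (1/2) qsum^T G dq via two focused solves (hetero minus uniform)
        sel = np.nonzero(qsum_v)[0]
        pts = st.coords[sel]
        phi_env = pb.focusing_solve(st, conditions, charges=dq_v,
                                    target_points=pts, focus=focus, **kw)
        phi_ref = pb.focusing_solve(st, conditions, charges=dq_v,
                                    target_points=pts, focus=focus,
                                    uniform_eps=conditions.eps_protein, **kw)
        dphi = phi_env.sample(pts) - phi_ref.sample(pts)
        return float(0.5 * qsum_v[sel] @ dphi)

    rf_protein = rf_cross(structure, dq, qsum)
    model = _model_structure(structure, site)
    nmodel = len(model)
    dq_m = dq[site.atom_indices]
    qsum_m = qsum[site.atom_indices]
    rf_model = rf_cross(model, dq_m, qsum_m)
    desolv = rf_protein - rf_model

    qbg = _background_charges(structure, sites, site)
    sel = np.nonzero(qbg)[0]
    if len(sel):
        phi = pb.site_potential(site, structure, conditions,
                                structure.coords[sel], schedule=schedule,
                                npoints_fine=npoints_fine, margin=margin)
        background = float(qbg[sel] @ phi)
    else:
        background = 0.0
    return desolv, background


def build_site_energy_table(structure: Structure, sites: Sequence[SiteDefinition],
                            conditions: PhysicalConditions,
                            schedule: Sequence[float] = pb.DEFAULT_SCHEDULE,
                            npoints_fine: int = 65, margin: float = 15.0
                            ) -> tuple[SiteEnergyTable, dict[str, tuple[float, float]]]:
    """Intrinsic energies + interaction matrix for all sites.

    Returns the table and a per-site (desolvation, background) breakdown in
    kcal/mol.
    """
    n = len(sites)
    g = np.zeros(n)
    parts: dict[str, tuple[float, float]] = {}
    for i, s in enumerate(sites):
        desolv, backg = intrinsic_energy(s, structure, sites, conditions,
                                         schedule=schedule,
                                         npoints_fine=npoints_fine, margin=margin)
        g[i] = desolv + backg
        parts[s.site_id] = (desolv, backg)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            wij = pb.interaction_energy(sites[i], sites[j], structure, conditions,
                                        schedule=schedule,
                                        npoints_fine=npoints_fine, margin=margin)
            w[i, j] = w[j, i] = wij
    return SiteEnergyTable(sites=list(sites), g_intr=g, W=w), parts


def compute_em_profile(structure: Structure, sites: Sequence[SiteDefinition],
                       conditions: PhysicalConditions,
                       sampler: Literal["exact", "mc"] = "exact",
                       schedule: Sequence[float] = pb.DEFAULT_SCHEDULE,
                       npoints_fine: int = 65, margin: float = 15.0,
                       seed: int = 0,
                       table: SiteEnergyTable | None = None,
                       parts: dict[str, tuple[float, float]] | None = None
                       ) -> list[EmRecord]:
    """One EmRecord per redox site, all titratable sites equilibrated."""
    if table is None:
        table, parts = build_site_energy_table(structure, sites, conditions,
                                               schedule=schedule,
                                               npoints_fine=npoints_fine,
                                               margin=margin)
    records = []
    for i in table.redox_indices():
        s = table.sites[i]
        res = find_em(s.site_id, table, conditions, sampler=sampler, seed=seed)
        em = res.em[s.site_id]
        desolv_mv = -parts[s.site_id][0] / MV_TO_KCAL
        backg_mv = -parts[s.site_id][1] / MV_TO_KCAL
        records.append(EmRecord(
            structure_id=structure.id, site_id=s.site_id, em=em,
            em_ref=s.em_ref, desolvation=desolv_mv, background=backg_mv,
            titration_shift=em - s.em_ref - desolv_mv - backg_mv))
    return records


# ---------------------------------------------------------------------------
# per-residue decomposition

def equilibrium_protonation(table: SiteEnergyTable, conditions: PhysicalConditions
                            ) -> np.ndarray:
    """Most-probable site state vector at the given conditions (oxidized
    redox sites: their population is rounded like any other)."""
    res = enumerate_exact(table, conditions)
    return (res.populations >= 0.5).astype(float)


def residue_contribution(site: SiteDefinition, residue_atoms: Sequence[int],
                         structure: Structure, conditions: PhysicalConditions,
                         charges: np.ndarray | None = None,
                         schedule: Sequence[float] = pb.DEFAULT_SCHEDULE,
                         npoints_fine: int = 65, margin: float = 15.0) -> float:
    """Contribution (mV) of a residue's charges to the site's Em.

    The residue charges (at their equilibrium protonation, passed via
    *charges* or taken from the structure) interact with the site's
    difference-charge potential in the protein dielectric; stabilization of
    the reduced state counts positive.
    """
    overlap = set(residue_atoms) & set(site.atom_indices)
    if overlap:
        raise ValueError(f"residue atoms overlap site {site.site_id}")
    q = structure.charges if charges is None else np.asarray(charges, float)
    qres = q[list(residue_atoms)]
    if not np.any(qres):
        return 0.0
    pts = structure.coords[list(residue_atoms)]
    phi = pb.site_potential(site, structure, conditions, pts, schedule=schedule,
                            npoints_fine=npoints_fine, margin=margin)
    interaction = float(qres @ phi)  # kcal/mol, with reduction difference charges
    return -interaction / MV_TO_KCAL


def pair_difference_table(pairs: Sequence[tuple[str, str]],
                          contributions: dict[tuple[str, str], float]
                          ) -> list[PairDifferenceRow]:
    """Assemble L/M pair-difference rows from residue-to-site contributions.

    *contributions* maps (residue_id, site_role) with site_role in
    {"L", "M"} to the contribution (mV); rows are sorted by |difference|
    descending.
    """
    rows = []
    for res_l, res_m in pairs:
        rows.append(PairDifferenceRow(
            residue_L=res_l, residue_M=res_m,
            c_L_to_siteL=contributions[(res_l, "L")],
            c_L_to_siteM=contributions[(res_l, "M")],
            c_M_to_siteL=contributions[(res_m, "L")],
            c_M_to_siteM=contributions[(res_m, "M")]))
    rows.sort(key=lambda r: abs(r.difference), reverse=True)
    return rows


def pair_difference_frame(rows: Sequence[PairDifferenceRow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "residue_L": r.residue_L, "residue_M": r.residue_M,
        "c_L_to_siteL": r.c_L_to_siteL, "c_M_to_siteL": r.c_M_to_siteL,
        "c_L_to_siteM": r.c_L_to_siteM, "c_M_to_siteM": r.c_M_to_siteM,
        "difference": r.difference} for r in rows])


# ---------------------------------------------------------------------------
# time courses

def run_timecourse(structures: Sequence[tuple[str, Structure]],
                   site_builder, conditions: PhysicalConditions,
                   sampler: Literal["exact", "mc"] = "exact",
                   schedule: Sequence[float] = pb.DEFAULT_SCHEDULE,
                   npoints_fine: int = 65, margin: float = 15.0,
                   seed: int = 0) -> pd.DataFrame:
    """Em shift of every redox site relative to the first (dark) structure.

    *site_builder* maps a Structure to its SiteDefinitions (site ids must be
    consistent across the series).  Returns a DataFrame with columns time,
    site_id, em_mV, delta_em_mV; the dark rows are zero by construction.
    """
    rows = []
    dark_em: dict[str, float] = {}
    dark_ids: set[str] | None = None
    for label, st in structures:
        sites = site_builder(st)
        ids = {s.site_id for s in sites}
        if dark_ids is None:
            dark_ids = ids
        elif ids != dark_ids:
            raise ValueError(f"site definitions inconsistent at {label!r}: "
                             f"{sorted(ids ^ dark_ids)}")
        records = compute_em_profile(st, sites, conditions, sampler=sampler,
                                     schedule=schedule,
                                     npoints_fine=npoints_fine, margin=margin,
                                     seed=seed)
        for rec in records:
            if rec.site_id not in dark_em:
                dark_em[rec.site_id] = rec.em
            rows.append({"time": label, "site_id": rec.site_id,
                         "em_mV": rec.em,
                         "delta_em_mV": rec.em - dark_em[rec.site_id]})
    return pd.DataFrame(rows)


def top_shifting_residues(structure_t0: Structure, structure_t1: Structure,
                          site_id: str, site_builder, residues_of,
                          conditions: PhysicalConditions, k: int = 5,
                          schedule: Sequence[float] = pb.DEFAULT_SCHEDULE,
                          npoints_fine: int = 65, margin: float = 15.0
                          ) -> pd.DataFrame:
    """Residues whose contribution to the site's Em shifts most between two
    structures; top-k by |shift|, both signs reported.

    *residues_of* maps a Structure to {residue_id: atom index list}.
    """
    shifts = []
    per_struct = []
    for st in (structure_t0, structure_t1):
        sites = site_builder(st)
        try:
            site = next(s for s in sites if s.site_id == site_id)
        except StopIteration:
            raise KeyError(f"site {site_id} not defined in structure {st.id}")
        contribs = {}
        for rid, atom_idx in residues_of(st).items():
            if set(atom_idx) & set(site.atom_indices):
                continue
            contribs[rid] = residue_contribution(site, atom_idx, st, conditions,
                                                 schedule=schedule,
                                                 npoints_fine=npoints_fine,
                                                 margin=margin)
        per_struct.append(contribs)
    c0, c1 = per_struct
    common = sorted(set(c0) & set(c1))
    if set(c0) != set(c1):
        raise ValueError(f"residue numbering mismatch: {sorted(set(c0) ^ set(c1))}")
    for rid in common:
        shifts.append({"residue_id": rid, "contribution_t0_mV": c0[rid],
                       "contribution_t1_mV": c1[rid],
                       "shift_mV": c1[rid] - c0[rid]})
    df = pd.DataFrame(shifts)
    df = df.reindex(df["shift_mV"].abs().sort_values(ascending=False).index)
    return df.head(k).reset_index(drop=True)
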