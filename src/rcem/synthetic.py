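"""Synthetic toy systems with known ground truth.

Every generator is seed-deterministic and attaches machine-readable
expectations (closed-form energies, exact Boltzmann populations, or
construction amplitudes) so each pipeline stage can be tested without
external structure downloads.  Toy "protein" interiors are modeled as a
low-dielectric sphere (one large neutral atom) enclosing the sites, which
keeps Coulomb/Born cross-checks closed-form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import K_COULOMB
from .nsd import Macrocycle, ReferenceModeBasis, default_basis
from .structure import Atom, PhysicalConditions, SiteDefinition, Structure
from .titration import SiteEnergyTable, TitrationResult, enumerate_exact


def _atom(serial: int, name: str, resname: str, chain: str, seq: int,
          xyz, charge: float = 0.0, radius: float = 1.5,
          element: str = "C") -> Atom:
    return Atom(serial, name, "", resname, chain, seq, np.asarray(xyz, float),
                1.0, element, charge=charge, radius=radius)


def born_transfer_energy(radius: float, charge: float,
                         conditions: PhysicalConditions) -> float:
    """Closed-form Born energy of moving a charged sphere from eps_protein
    into eps_solvent embedding: -k_e q^2 (1/eps_p - 1/eps_w) / (2 R)."""
    return (-K_COULOMB * charge**2
            * (1.0 / conditions.eps_protein - 1.0 / conditions.eps_solvent)
            / (2.0 * radius))


def make_born_system(radius: float, charge: float,
                     conditions: PhysicalConditions | None = None
                     ) -> tuple[Structure, float]:
    """Single charged sphere at the origin plus its analytic reaction-field
    (Born transfer) energy for the configured dielectrics."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    conditions = conditions or PhysicalConditions(ionic_strength=0.0)
    st = Structure([_atom(1, "Q", "ION", "X", 1, (0.0, 0.0, 0.0),
                          charge=charge, radius=radius)],
                   id=f"born:r{radius}:q{charge}")
    return st, born_transfer_energy(radius, charge, conditions)


# ---------------------------------------------------------------------------
# toy titration systems

@dataclass
class ToySystemSpec:
    """Recipe for a deterministic point-site titration system."""

    n_sites: int = 4
    geometry: str = "shell"  # linear | shell | mirror-pair
    seed: int = 0
    spacing: float = 10.0  # A, linear geometry
    shell_radius: float = 15.0  # A
    kinds: list[str] = field(default_factory=list)  # acid/base/redox per site
    model_pkas: list[float] = field(default_factory=list)
    em_refs: list[float] = field(default_factory=list)
    g_intr_scale: float = 1.5  # kcal/mol, random intrinsic-energy spread
    eps_interior: float = 4.0  # dielectric used for analytic couplings


def _site_positions(spec: ToySystemSpec, rng: np.random.RandomState) -> np.ndarray:
    n = spec.n_sites
    if spec.geometry == "linear":
        return np.column_stack([spec.spacing * np.arange(n),
                                np.zeros(n), np.zeros(n)])
    if spec.geometry == "shell":
        # rejection-sample until all pairs are >= 2 A apart (deterministic:
        # the RNG state advances the same way for a given seed)
        for _ in range(100):
            v = rng.normal(size=(n, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            pos = spec.shell_radius * v
            d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
            if np.all(d[np.triu_indices(n, 1)] >= 2.0):
                return pos
        raise ValueError("could not place non-overlapping shell sites")
    if spec.geometry == "mirror-pair":
        if n != 2:
            raise ValueError("mirror-pair geometry needs n_sites=2")
        return np.array([[spec.spacing / 2, 0, 0], [-spec.spacing / 2, 0, 0]])
    raise ValueError(f"unknown geometry {spec.geometry!r}")


def make_toy_titration(spec: ToySystemSpec
                       ) -> tuple[Structure, SiteEnergyTable, TitrationResult]:
    """Point-charge sites at the requested geometry with analytic Coulomb
    couplings; the attached expectation is the exact Boltzmann titration
    at default conditions."""
    if spec.n_sites > 20:
        raise ValueError("at most 20 sites (exact expectations required)")
    rng = np.random.RandomState(spec.seed)
    pos = _site_positions(spec, rng)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    if np.any(d[np.triu_indices(spec.n_sites, 1)] < 2.0):
        raise ValueError("site positions overlap")

    kinds = list(spec.kinds) or [
        ("acid", "base", "redox")[rng.randint(3)] for _ in range(spec.n_sites)]
    pkas = list(spec.model_pkas) or [float(rng.uniform(3.0, 11.0))
                                     for _ in range(spec.n_sites)]
    emrefs = list(spec.em_refs) or [-429.0] * spec.n_sites

    atoms = []
    sites = []
    dq_sign = {"acid": -1.0, "base": +1.0, "redox": -1.0}
    for i, kind in enumerate(kinds):
        atoms.append(_atom(i + 1, "Q", "TOY", "X", i + 1, pos[i], 0.0, 1.5))
        sites.append(SiteDefinition(
            site_id=f"{kind}-{i + 1}", kind=kind, atom_indices=[i],
            charges_state0=np.array([0.0]),
            charges_state1=np.array([dq_sign[kind]]),
            model_pka=None if kind == "redox" else pkas[i],
            em_ref=emrefs[i] if kind == "redox" else None))
    st = Structure(atoms, id=f"toy:{spec.geometry}:n{spec.n_sites}:s{spec.seed}")

    n = spec.n_sites
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dq_i, dq_j = dq_sign[kinds[i]], dq_sign[kinds[j]]
            w[i, j] = w[j, i] = K_COULOMB * dq_i * dq_j / (spec.eps_interior * d[i, j])
    g = rng.normal(scale=spec.g_intr_scale, size=n) if spec.g_intr_scale else np.zeros(n)
    table = SiteEnergyTable(sites=sites, g_intr=g, W=w)
    expectation = enumerate_exact(table, PhysicalConditions())
    return st, table, expectation


# ---------------------------------------------------------------------------
# mirror-branch system for pair decomposition

def make_mirror_branch_system(asymmetric_dipole: dict | None = None,
                              branch_offset: float = 4.0,
                              cavity_radius: float = 10.0
                              ) -> tuple[Structure, list[SiteDefinition]]:
    """Two redox analogs at mirror positions inside a low-dielectric sphere.

    *asymmetric_dipole*, if given, is {"charge": q, "position": (x, y, z),
    "separation": s}: a +q/-q atom pair placed at position (the +q pole
    nearer whichever branch the position is on), breaking the L/M symmetry.
    Branch L sits at +x, branch M at -x.
    """
    atoms = [_atom(1, "CAV", "CAV", "X", 1, (0, 0, 0), 0.0, cavity_radius)]
    atoms.append(_atom(2, "Q", "RDL", "L", 1, (branch_offset, 0, 0), 0.0, 1.5))
    atoms.append(_atom(3, "Q", "RDM", "M", 1, (-branch_offset, 0, 0), 0.0, 1.5))
    serial = 3
    if asymmetric_dipole is not None:
        q = float(asymmetric_dipole["charge"])
        p = np.asarray(asymmetric_dipole["position"], float)
        s = float(asymmetric_dipole.get("separation", 1.0))
        # dipole axis along x, +q pole facing the nearer branch
        sign = 1.0 if p[0] >= 0 else -1.0
        serial += 1
        atoms.append(_atom(serial, "DP", "DIP", "X", 2,
                           p - sign * np.array([s / 2, 0, 0]), +q, 1.0))
        serial += 1
        atoms.append(_atom(serial, "DM", "DIP", "X", 2,
                           p + sign * np.array([s / 2, 0, 0]), -q, 1.0))
    st = Structure(atoms, id="mirror-branch" + ("" if asymmetric_dipole is None
                                                else ":dipole"))
    sites = [
        SiteDefinition(site_id="RD-L", kind="redox", atom_indices=[1],
                       charges_state0=np.array([0.0]),
                       charges_state1=np.array([-1.0]), em_ref=-429.0),
        SiteDefinition(site_id="RD-M", kind="redox", atom_indices=[2],
                       charges_state0=np.array([0.0]),
                       charges_state1=np.array([-1.0]), em_ref=-429.0),
    ]
    return st, sites


# ---------------------------------------------------------------------------
# deformed macrocycles

def make_deformed_macrocycle(amplitudes, rigid_motion_seed: int = 0,
                             basis: ReferenceModeBasis | None = None
                             ) -> tuple[Macrocycle, dict[str, float]]:
    """Reference macrocycle plus sum(a_mode * n_mode) in z, then a random
    rigid rotation/translation; ground-truth amplitudes attached."""
    if basis is None:
        basis = default_basis()
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.shape != (6,):
        raise ValueError("need six mode amplitudes")
    if np.any(np.abs(amplitudes) > 1.0):
        raise ValueError("amplitudes limited to |a| <= 1 A")
    coords = basis.ref_coords.copy()
    coords[:, 2] += amplitudes @ basis.modes

    rng = np.random.RandomState(rigid_motion_seed)
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.uniform(-20, 20, size=3)
    moved = coords @ q.T + t
    truth = dict(zip(("sad", "ruf", "dom", "wav_x", "wav_y", "pro"),
                     amplitudes.tolist()))
    return Macrocycle(coords=moved, cofactor_id="synthetic"), truth


def macrocycle_structure(mac: Macrocycle, resname: str = "BPB",
                         chain: str = "L", seq: int = 1) -> Structure:
    """Wrap a macrocycle in a Structure (canonical atom names) so the
    extraction/IO path can run on generated data."""
    from .nsd import CANONICAL_ATOMS

    atoms = [_atom(i + 1, name, resname, chain, seq, xyz,
                   0.0, 1.7, element=name[0])
             for i, (name, xyz) in enumerate(zip(CANONICAL_ATOMS, mac.coords))]
    return Structure(atoms, id=f"macrocycle:{resname}")
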