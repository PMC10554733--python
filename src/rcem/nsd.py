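"""Normal-coordinate structural decomposition (NSD) of chlorin macrocycles.

Out-of-plane distortion of the 24-atom macrocycle core (4 N + 20 C) is
quantified by least-squares superposition onto an idealized planar D4h
reference followed by projection of the z-displacements onto the six
lowest-frequency out-of-plane normal modes,

    d_Gamma = sum_i dz_i (n_z^Gamma)_i,

the minimal-basis approximation: saddling (B2u), ruffling (B1u), doming
(A2u), waving x/y (Eg) and propellering (A1u).

The mode basis is built at import time from a harmonic z-displacement model
of the idealized macrocycle (unit springs on bonded atom pairs), with rigid
z-translation and x/y-tilt patterns projected out and the eigenvectors
symmetry-classified by C4v projection operators (out-of-plane parity makes
the full D4h group act as C4v on z-displacement patterns).  Since real
chlorins are not D4h (one saturated ring), the part of the distortion
outside the 6-mode span is reported as a residual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structure import Structure, StructureError

N_ATOMS = 24

#: canonical atom order: ring A..D as (N, C-alpha, C-beta, C-beta, C-alpha)
#: followed by the bridging meso carbon to the next ring
CANONICAL_ATOMS = [
    "NA", "C1A", "C2A", "C3A", "C4A", "CHB",
    "NB", "C1B", "C2B", "C3B", "C4B", "CHC",
    "NC", "C1C", "C2C", "C3C", "C4C", "CHD",
    "ND", "C1D", "C2D", "C3D", "C4D", "CHA",
]

MODE_LABELS = ["sad", "ruf", "dom", "wav_x", "wav_y", "pro"]
MODE_SYMMETRY = {"sad": "B2u", "ruf": "B1u", "dom": "A2u",
                 "wav_x": "Eg(x)", "wav_y": "Eg(y)", "pro": "A1u"}


def _reference_coords() -> np.ndarray:
    """Idealized planar D4h macrocycle, z = 0 (bond lengths ~1.36-1.44 A)."""
    # one pyrrole ring on the +x axis, local (x, y) positions
    n_pos = (2.054, 0.0)
    ca_pos = [(2.845, 1.106), (2.845, -1.106)]
    cb_pos = [(4.193, 0.682), (4.193, -0.682)]
    meso_r = 3.42
    coords = np.zeros((N_ATOMS, 3))
    for ring in range(4):
        th = math.pi / 2 * ring
        c, s = math.cos(th), math.sin(th)
        rot = np.array([[c, -s], [s, c]])
        base = 6 * ring
        coords[base, :2] = rot @ n_pos                     # N
        coords[base + 1, :2] = rot @ ca_pos[0]             # C1 (alpha)
        coords[base + 2, :2] = rot @ cb_pos[0]             # C2 (beta)
        coords[base + 3, :2] = rot @ cb_pos[1]             # C3 (beta)
        coords[base + 4, :2] = rot @ ca_pos[1]             # C4 (alpha)
        mth = th + math.pi / 4
        coords[base + 5, :2] = (meso_r * math.cos(mth), meso_r * math.sin(mth))
    return coords


def _bond_list() -> list[tuple[int, int]]:
    """Bonded pairs of the 24-atom core."""
    bonds = []
    for ring in range(4):
        b = 6 * ring
        nxt = (6 * (ring + 1)) % N_ATOMS
        bonds += [(b, b + 1), (b + 1, b + 2), (b + 2, b + 3), (b + 3, b + 4),
                  (b + 4, b), (b + 4, b + 5), (b + 5, nxt + 1)]
    return bonds


def _c4_permutation() -> np.ndarray:
    """Atom permutation of a 90-degree rotation (ring A -> B -> C -> D)."""
    perm = np.zeros(N_ATOMS, dtype=int)
    for i in range(N_ATOMS):
        perm[(i + 6) % N_ATOMS] = i
    return perm


def _sigma_x_permutation() -> np.ndarray:
    """Mirror through the x axis (contains ring A and ring C nitrogens)."""
    ref = _reference_coords()
    mirrored = ref.copy()
    mirrored[:, 1] *= -1
    perm = np.zeros(N_ATOMS, dtype=int)
    for i, m in enumerate(mirrored):
        d = np.linalg.norm(ref[:, :2] - m[:2], axis=1)
        j = int(np.argmin(d))
        if d[j] > 1e-6:
            raise RuntimeError("reference geometry is not mirror-symmetric")
        perm[i] = j
    return perm


def _perm_matrix(perm: np.ndarray) -> np.ndarray:
    p = np.zeros((N_ATOMS, N_ATOMS))
    p[perm, np.arange(N_ATOMS)] = 1.0
    return p


@dataclass
class ReferenceModeBasis:
    """Planar reference coordinates and six orthonormal out-of-plane modes."""

    ref_coords: np.ndarray  # (24, 3), z = 0
    modes: np.ndarray  # (6, 24) z-components, orthonormal
    labels: tuple[str, ...] = tuple(MODE_LABELS)

    def mode(self, label: str) -> np.ndarray:
        return self.modes[self.labels.index(label)]


def _build_basis() -> ReferenceModeBasis:
    ref = _reference_coords()
    # z-displacement stiffness: unit springs on bonded pairs (graph Laplacian)
    lap = np.zeros((N_ATOMS, N_ATOMS))
    for i, j in _bond_list():
        lap[i, i] += 1.0
        lap[j, j] += 1.0
        lap[i, j] -= 1.0
        lap[j, i] -= 1.0
    # project out rigid z-translation and x/y tilts (z ~ 1, x, y patterns)
    rigid = np.column_stack([np.ones(N_ATOMS), ref[:, 0], ref[:, 1]])
    q, _ = np.linalg.qr(rigid)
    proj = np.eye(N_ATOMS) - q @ q.T
    k = proj @ lap @ proj

    c4 = _perm_matrix(_c4_permutation())
    sx = _perm_matrix(_sigma_x_permutation())
    sd = c4 @ sx  # diagonal mirror

    # C4v projection operators acting on z-patterns
    ops = {
        "E": np.eye(N_ATOMS), "C4": c4, "C4^3": c4.T, "C2": c4 @ c4,
        "sv": sx, "sv'": c4 @ c4 @ sx, "sd": sd, "sd'": c4 @ c4 @ sd,
    }
    chars = {
        # irrep: characters for E, 2C4, C2, 2sigma_v, 2sigma_d
        "A1": {"E": 1, "C4": 1, "C4^3": 1, "C2": 1, "sv": 1, "sv'": 1, "sd": 1, "sd'": 1},
        "A2": {"E": 1, "C4": 1, "C4^3": 1, "C2": 1, "sv": -1, "sv'": -1, "sd": -1, "sd'": -1},
        "B1": {"E": 1, "C4": -1, "C4^3": -1, "C2": 1, "sv": 1, "sv'": 1, "sd": -1, "sd'": -1},
        "B2": {"E": 1, "C4": -1, "C4^3": -1, "C2": 1, "sv": -1, "sv'": -1, "sd": 1, "sd'": 1},
        "E2d": {"E": 2, "C4": 0, "C4^3": 0, "C2": -2, "sv": 0, "sv'": 0, "sd": 0, "sd'": 0},
    }

    def lowest_mode(irrep: str, nvec: int = 1) -> np.ndarray:
        p = sum(chars[irrep][g] * m for g, m in ops.items())
        p = (chars[irrep]["E"] / len(ops)) * p
        # orthonormal basis of the irrep subspace (excluding rigid patterns)
        u, s, _ = np.linalg.svd(proj @ p)
        basis = u[:, s > 1e-8]
        if basis.shape[1] < nvec:
            raise RuntimeError(f"irrep {irrep}: subspace too small")
        ksub = basis.T @ k @ basis
        w, v = np.linalg.eigh(ksub)
        return basis @ v[:, :nvec]

    dom = lowest_mode("A1")[:, 0]
    pro = lowest_mode("A2")[:, 0]
    m_b1 = lowest_mode("B1")[:, 0]
    m_b2 = lowest_mode("B2")[:, 0]
    # ruffling is meso-dominated, saddling beta-carbon-dominated
    meso = [5, 11, 17, 23]
    if np.sum(m_b1[meso] ** 2) >= np.sum(m_b2[meso] ** 2):
        ruf, sad = m_b1, m_b2
    else:
        ruf, sad = m_b2, m_b1
    epair = lowest_mode("E2d", nvec=2)
    # align the degenerate pair: wav_x symmetric under the x-axis mirror,
    # wav_y = C4-rotated wav_x (fixes the 90-degree-rotation mapping)
    sym = 0.5 * (epair + sx @ epair)
    u, s, _ = np.linalg.svd(sym)
    wav_x = u[:, 0]
    wav_y = c4 @ wav_x

    modes = []
    for v in (sad, ruf, dom, wav_x, wav_y, pro):
        v = v / np.linalg.norm(v)
        modes.append(v)
    modes = np.array(modes)
    # sign convention: the first canonical atom with a significant component
    # displaces in +z (wav_y inherits its sign from wav_x via C4)
    for i, label in enumerate(MODE_LABELS):
        if label == "wav_y":
            continue
        v = modes[i]
        j = int(np.argmax(np.abs(v) > 0.25 * np.max(np.abs(v))))
        if v[j] < 0:
            modes[i] = -v
            if label == "wav_x":
                modes[MODE_LABELS.index("wav_y")] = -modes[MODE_LABELS.index("wav_y")]
    return ReferenceModeBasis(ref_coords=ref, modes=modes)


_DEFAULT_BASIS: ReferenceModeBasis | None = None


def default_basis() -> ReferenceModeBasis:
    global _DEFAULT_BASIS
    if _DEFAULT_BASIS is None:
        _DEFAULT_BASIS = _build_basis()
    return _DEFAULT_BASIS


def write_basis(basis: ReferenceModeBasis, path: str | Path) -> None:
    """Text dump: atom label, x, y, z_ref, six mode components."""
    lines = ["# atom x y z " + " ".join(MODE_LABELS)]
    for i, name in enumerate(CANONICAL_ATOMS):
        row = [name] + [f"{v:.8f}" for v in basis.ref_coords[i]]
        row += [f"{basis.modes[m, i]:.8f}" for m in range(6)]
        lines.append(" ".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_basis(path: str | Path) -> ReferenceModeBasis:
    ref = np.zeros((N_ATOMS, 3))
    modes = np.zeros((6, N_ATOMS))
    rows = [l.split() for l in Path(path).read_text().splitlines()
            if l.strip() and not l.startswith("#")]
    if len(rows) != N_ATOMS:
        raise ValueError(f"basis file must have {N_ATOMS} atom rows")
    for i, parts in enumerate(rows):
        if parts[0] != CANONICAL_ATOMS[i]:
            raise ValueError(f"row {i}: expected atom {CANONICAL_ATOMS[i]}")
        ref[i] = [float(v) for v in parts[1:4]]
        modes[:, i] = [float(v) for v in parts[4:10]]
    return ReferenceModeBasis(ref_coords=ref, modes=modes)


# ---------------------------------------------------------------------------
# extraction, superposition, projection

@dataclass
class Macrocycle:
    """24 core atoms in canonical order."""

    coords: np.ndarray  # (24, 3)
    cofactor_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (N_ATOMS, 3):
            raise ValueError(f"macrocycle needs {N_ATOMS}x3 coordinates")


@dataclass
class NSDResult:
    """Six out-of-plane mode amplitudes (A) plus residual diagnostics."""

    d: dict[str, float]
    total_oop: float
    residual: float
    rmsd: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.d[k] for k in MODE_LABELS])


def extract_macrocycle(structure: Structure, cofactor_id: tuple[str, int] | str,
                       name_map: dict[str, str] | None = None) -> Macrocycle:
    """Pull the 24 canonical macrocycle atoms of one cofactor.

    *cofactor_id* is (chain, residue_seq) or "chain:seq"; *name_map*
    translates canonical atom names to the structure's naming if it deviates
    from the standard chlorin convention (NA/C1A/.../CHA).  Central metal
    and all substituents are ignored.
    """
    if isinstance(cofactor_id, str):
        chain, seq = cofactor_id.split(":")
        cofactor_id = (chain, int(seq))
    chain, seq = cofactor_id
    name_map = name_map or {}
    index = {a.name.upper(): a for a in structure
             if a.chain == chain and a.residue_seq == seq}
    if not index:
        raise StructureError(f"no cofactor at {chain}:{seq}")
    coords = np.zeros((N_ATOMS, 3))
    missing = []
    for i, canon in enumerate(CANONICAL_ATOMS):
        name = name_map.get(canon, canon).upper()
        if name not in index:
            missing.append(canon)
            continue
        coords[i] = index[name].coords
    if missing:
        raise StructureError(
            f"cofactor {chain}:{seq}: missing macrocycle atom(s) {missing}")
    return Macrocycle(coords=coords, cofactor_id=f"{chain}:{seq}")


def superpose(mac: Macrocycle, basis: ReferenceModeBasis | None = None
              ) -> tuple[np.ndarray, float]:
    """Least-squares rigid superposition onto the reference (Kabsch/SVD).

    Returns coordinates expressed in the reference frame (mean plane z ~ 0)
    and the RMSD of the fit.
    """
    if basis is None:
        basis = default_basis()
    x = mac.coords - mac.coords.mean(axis=0)
    y = basis.ref_coords - basis.ref_coords.mean(axis=0)
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10:
        raise ValueError("degenerate (collinear) macrocycle coordinates")
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    aligned = x @ rot + basis.ref_coords.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - basis.ref_coords) ** 2, axis=1))))
    return aligned, rmsd


def project_modes(aligned: np.ndarray, basis: ReferenceModeBasis | None = None,
                  rmsd: float = 0.0) -> NSDResult:
    """Project out-of-plane displacement onto the six-mode minimal basis."""
    if basis is None:
        basis = default_basis()
    dz = np.asarray(aligned)[:, 2] - basis.ref_coords[:, 2]
    d = basis.modes @ dz
    total = float(np.sqrt(np.sum(dz**2)))
    residual = float(np.sqrt(max(np.sum(dz**2) - np.sum(d**2), 0.0)))
    return NSDResult(d=dict(zip(MODE_LABELS, d.tolist())), total_oop=total,
                     residual=residual, rmsd=rmsd)


def analyze_macrocycle(mac: Macrocycle,
                       basis: ReferenceModeBasis | None = None) -> NSDResult:
    if basis is None:
        basis = default_basis()
    aligned, rmsd = superpose(mac, basis)
    return project_modes(aligned, basis, rmsd=rmsd)


#: |delta d| below which a mode change is flagged as practically unchanged, A
UNCHANGED_THRESHOLD = 0.03


def nsd_timecourse(structures: list[tuple[str, Structure]],
                   cofactor_ids: dict[str, tuple[str, int] | str],
                   name_map: dict[str, str] | None = None,
                   basis: ReferenceModeBasis | None = None):
    """Six mode amplitudes per cofactor per (time-labelled) structure.

    Returns a pandas DataFrame with columns time, cofactor, the six modes,
    residual, and a per-mode changed flag relative to the first (dark)
    structure (|delta d| > 0.03 A).
    """
    import pandas as pd

    if basis is None:
        basis = default_basis()
    rows = []
    first: dict[str, NSDResult] = {}
    for label, st in structures:
        for cof_name, cof_id in cofactor_ids.items():
            mac = extract_macrocycle(st, cof_id, name_map)
            res = analyze_macrocycle(mac, basis)
            if cof_name not in first:
                first[cof_name] = res
            row = {"time": label, "cofactor": cof_name, **res.d,
                   "residual": res.residual}
            for m in MODE_LABELS:
                row[f"changed_{m}"] = bool(
                    abs(res.d[m] - first[cof_name].d[m]) > UNCHANGED_THRESHOLD)
            rows.append(row)
    return pd.DataFrame(rows)
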