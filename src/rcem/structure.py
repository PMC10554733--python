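"""Structure input, parameterization and titratable/redox site definition.

Reads PDB files (via :mod:`gemmi`), resolves alternate conformers according to
the time-resolved refinement convention (dark state: highest occupancy;
photoactivated state: the low-occupancy conformer, nominally 30%, where
present), assigns partial charges and radii from whitespace-delimited
parameter tables, places polar hydrogens at ideal geometry, and builds
:class:`SiteDefinition` objects for titratable residues and redox cofactors.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

_DATA_DIR = Path(__file__).parent / "data"

WATER_NAMES = {"HOH", "WAT", "TIP", "TIP3", "SOL", "DOD"}

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


class StructureError(ValueError):
    """Raised for unreadable, empty or inconsistent structures."""


class ParameterError(ValueError):
    """Raised when atoms cannot be matched to charge/radius parameters."""


@dataclass
class Atom:
    """One atom with optional charge/radius parameterization."""

    serial: int
    name: str
    altloc: str
    residue_name: str
    chain: str
    residue_seq: int
    coords: np.ndarray
    occupancy: float = 1.0
    element: str = ""
    charge: float | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coords must be a finite 3-vector")
        if not (0.0 <= self.occupancy <= 1.0):
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def residue_id(self) -> tuple[str, int]:
        return (self.chain, self.residue_seq)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_seq, self.name)


class Structure:
    """An ordered collection of atoms with unique (chain, seq, name) keys."""

    def __init__(self, atoms: Iterable[Atom], id: str = ""):
        self.atoms: list[Atom] = list(atoms)
        self.id = id
        if not self.atoms:
            raise StructureError("structure has no atoms")
        seen: set[tuple[str, int, str, str]] = set()
        for a in self.atoms:
            k = (a.chain, a.residue_seq, a.name, a.altloc)
            if k in seen:
                raise StructureError(f"duplicate atom identifier {k}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([0.0 if a.charge is None else a.charge for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([0.0 if a.radius is None else a.radius for a in self.atoms])

    @property
    def is_parameterized(self) -> bool:
        return all(a.charge is not None and a.radius is not None for a in self.atoms)

    def copy(self, id: str | None = None) -> "Structure":
        return Structure([replace(a, coords=a.coords.copy()) for a in self.atoms],
                         id=self.id if id is None else id)

    def residues(self) -> dict[tuple[str, int, str], list[int]]:
        """Group atom indices by (chain, residue_seq, residue_name)."""
        out: dict[tuple[str, int, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault((a.chain, a.residue_seq, a.residue_name), []).append(i)
        return out

    def find(self, chain: str, residue_seq: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.chain == chain and a.residue_seq == residue_seq and a.name == name:
                return i
        raise KeyError(f"atom {chain}/{residue_seq}/{name} not found")

    def validate_geometry(self, min_separation: float = 0.5) -> None:
        """Check no two atoms sit closer than *min_separation* A."""
        from scipy.spatial import cKDTree

        xyz = self.coords
        tree = cKDTree(xyz)
        pairs = tree.query_pairs(min_separation)
        if pairs:
            i, j = sorted(pairs)[0]
            raise StructureError(
                f"atoms {self.atoms[i].key} and {self.atoms[j].key} closer than "
                f"{min_separation} A")


@dataclass(frozen=True)
class PhysicalConditions:
    """Thermodynamic and dielectric conditions of the calculation.

    Defaults are the standard continuum-electrostatics conditions for
    reaction-center titrations: 300 K, pH 7, 100 mM ionic strength,
    eps = 4 for the protein interior and 80 for water.
    """

    temperature: float = 300.0
    pH: float = 7.0
    ionic_strength: float = 0.100
    eps_protein: float = 4.0
    eps_solvent: float = 80.0

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.ionic_strength < 0:
            raise ValueError("invalid physical conditions")
        if self.eps_protein <= 0 or self.eps_solvent <= 0:
            raise ValueError("dielectric constants must be positive")


@dataclass
class SiteDefinition:
    """A titratable residue or redox cofactor with two charge states.

    Conventions: state 1 means deprotonated for acids, protonated for bases
    and reduced for redox sites, so that sum(state1 - state0) is -1 for
    acids, +1 for bases and -1 for one-electron reductions.
    """

    site_id: str
    kind: str  # acid | base | redox
    atom_indices: list[int]
    charges_state0: np.ndarray
    charges_state1: np.ndarray
    model_pka: float | None = None
    em_ref: float | None = None  # mV vs NHE
    n_electrons: int = 1

    def __post_init__(self) -> None:
        self.charges_state0 = np.asarray(self.charges_state0, dtype=float)
        self.charges_state1 = np.asarray(self.charges_state1, dtype=float)
        n = len(self.atom_indices)
        if self.charges_state0.shape != (n,) or self.charges_state1.shape != (n,):
            raise ValueError(f"site {self.site_id}: charge vectors must cover the "
                             "same atoms as atom_indices")
        if self.kind not in ("acid", "base", "redox"):
            raise ValueError(f"site {self.site_id}: unknown kind {self.kind!r}")
        dq = float(self.charges_state1.sum() - self.charges_state0.sum())
        want = {"acid": -1.0, "base": +1.0, "redox": -float(self.n_electrons)}[self.kind]
        if abs(dq - want) > 1e-6:
            raise ValueError(f"site {self.site_id}: state1-state0 charge sum {dq:+.6f}, "
                             f"expected {want:+.0f}")
        if self.kind == "redox":
            if self.em_ref is None:
                raise ValueError(f"redox site {self.site_id} needs em_ref")
            if self.n_electrons != 1:
                raise ValueError("only one-electron couples are supported")
        elif self.model_pka is None:
            raise ValueError(f"site {self.site_id} needs model_pka")

    @property
    def delta_charges(self) -> np.ndarray:
        return self.charges_state1 - self.charges_state0


# ---------------------------------------------------------------------------
# PDB reading and conformer resolution


def _resolve_conformers(variants: list[Atom], state_mode: str) -> Atom:
    if len(variants) == 1:
        return variants[0]
    by_occ = sorted(variants, key=lambda a: (a.occupancy, a.altloc))
    if state_mode == "photoactivated":
        # lowest-occupancy conformer above 0.2 (the nominally-30% photoactivated
        # population); fall back to highest occupancy
        low = [a for a in by_occ if a.occupancy >= 0.2]
        chosen = low[0] if low else by_occ[-1]
    else:
        chosen = by_occ[-1]
    return replace(chosen, altloc="")


def read_pdb(path: str | Path, state_mode: str = "dark",
             keep_waters: bool = False, id: str | None = None) -> Structure:
    """Read a PDB file, resolving altlocs for the requested state.

    state_mode "dark" keeps the highest-occupancy conformer of each atom;
    "photoactivated" keeps the lowest-occupancy conformer with occupancy
    >= 0.2 where alternates exist (the partial-occupancy photoactivated
    population of time-resolved refinements), else the highest.
    Crystallographic waters are removed unless *keep_waters* is set.
    """
    import gemmi

    if state_mode not in ("dark", "photoactivated"):
        raise ValueError(f"unknown state_mode {state_mode!r}")
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:
        raise StructureError(f"cannot read PDB file {path}: {exc}") from exc

    groups: dict[tuple[str, int, str], list[Atom]] = {}
    order: list[tuple[str, int, str]] = []
    serial = 0
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[0]
    for chain in model:
        for res in chain:
            if not keep_waters and res.name.strip() in WATER_NAMES:
                continue
            for at in res:
                serial += 1
                alt = at.altloc if at.altloc not in ("\x00", "\0", " ") else ""
                atom = Atom(
                    serial=serial,
                    name=at.name.strip(),
                    altloc=alt,
                    residue_name=res.name.strip(),
                    chain=chain.name.strip(),
                    residue_seq=res.seqid.num,
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=min(max(at.occ, 0.0), 1.0),
                    element=at.element.name,
                )
                key = atom.key
                if key not in groups:
                    order.append(key)
                groups.setdefault(key, []).append(atom)

    atoms = [_resolve_conformers(groups[k], state_mode) for k in order]
    if not atoms:
        raise StructureError(f"{path}: zero atoms after filtering")
    label = id if id is not None else f"{path.stem}:{state_mode}"
    return Structure(atoms, id=label)


# ---------------------------------------------------------------------------
# Parameter tables


def load_parameter_file(path: str | Path) -> dict[tuple[str, str], tuple[float, float]]:
    """Parse a whitespace-delimited table: residue_name atom_name charge radius.

    Lines starting with '#' are comments.  A residue name of '*' matches any
    residue (used e.g. for terminal OXT).
    """
    table: dict[tuple[str, str], tuple[float, float]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ParameterError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
        res, name, q, r = parts
        radius = float(r)
        if radius <= 0:
            raise ParameterError(f"{path}:{lineno}: radius must be positive")
        table[(res.upper(), name.upper())] = (float(q), radius)
    return table


def default_parameter_table() -> dict[tuple[str, str], tuple[float, float]]:
    return load_parameter_file(_DATA_DIR / "aminoacids.prm")


#: Fallback radii by element, A (PARSE-like)
ELEMENT_RADII = {"H": 1.0, "C": 1.7, "N": 1.5, "O": 1.4, "S": 1.85,
                 "P": 1.9, "MG": 1.45, "FE": 1.3}

NONPOLAR_H_CHARGE = 0.09


def assign_parameters(structure: Structure,
                      params: dict[tuple[str, str], tuple[float, float]] | None = None,
                      overrides: dict[str, dict[str, tuple[float, float]]] | None = None,
                      check_residue_sums: bool = True) -> Structure:
    """Assign charge and radius to every atom; returns a new Structure.

    *params* maps (residue_name, atom_name) to (charge, radius); *overrides*
    maps a cofactor residue name to its own atom table.  Hydrogen atoms of a
    cofactor that are not listed in its override table are treated as
    nonpolar CH_n hydrogens and given +0.09 e.  Unmatched atoms raise
    :class:`ParameterError` naming the residue and atom.
    """
    if params is None:
        params = default_parameter_table()
    overrides = overrides or {}

    new_atoms: list[Atom] = []
    missing: list[str] = []
    for a in structure:
        res = a.residue_name.upper()
        name = a.name.upper()
        if res in overrides:
            tab = overrides[res]
            if name in tab:
                q, r = tab[name]
            elif (a.element.upper() == "H" or name.startswith("H")):
                q = NONPOLAR_H_CHARGE
                r = ELEMENT_RADII["H"]
            else:
                missing.append(f"{res} {a.chain}{a.residue_seq} atom {a.name}")
                continue
        elif (res, name) in params:
            q, r = params[(res, name)]
        elif ("*", name) in params:
            q, r = params[("*", name)]
        else:
            missing.append(f"{res} {a.chain}{a.residue_seq} atom {a.name}")
            continue
        new_atoms.append(replace(a, charge=q, radius=r, coords=a.coords.copy()))

    if missing:
        shown = ", ".join(missing[:10])
        raise ParameterError(
            f"no charge/radius parameters for {len(missing)} atom(s): {shown}"
            + ("..." if len(missing) > 10 else ""))

    out = Structure(new_atoms, id=structure.id)
    if check_residue_sums:
        _check_residue_charge_sums(out, overrides)
    return out


def _check_residue_charge_sums(structure: Structure,
                               overrides: dict[str, dict[str, tuple[float, float]]],
                               tol: float = 1e-6) -> None:
    """Per-residue charge sums must equal the residue's formal charge.

    Only complete standard residues are checked (a residue is complete when
    it carries every atom of its parameter entry that is not a hydrogen we
    may not have placed); cofactors with override tables are checked against
    the integer nearest their table sum.
    """
    params = default_parameter_table()
    expected: dict[str, float] = {}
    counts: dict[str, int] = {}
    for (res, _name), (q, _r) in params.items():
        if res == "*":
            continue
        expected[res] = expected.get(res, 0.0) + q
        counts[res] = counts.get(res, 0) + 1
    for (chain, seq, resname), idx in structure.residues().items():
        res = resname.upper()
        if res in overrides or res not in expected:
            continue
        if len(idx) != counts[res]:
            continue  # incomplete residue (missing hydrogens/terminal atoms)
        total = sum(structure.atoms[i].charge for i in idx)
        formal = round(expected[res])
        if abs(total - formal) > tol:
            raise ParameterError(
                f"residue {res} {chain}{seq}: charge sum {total:+.4f} != formal "
                f"{formal:+d}")


# ---------------------------------------------------------------------------
# Hydrogen placement (ideal geometry)

def _place_internal(a1: np.ndarray, a2: np.ndarray, a3: np.ndarray,
                    bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place an atom from internal coordinates against anchors a3-a2-a1.

    Returns the position at distance *bond* from a1, angle (new,a1,a2) =
    *angle_deg* and dihedral (new,a1,a2,a3) = *dihedral_deg*.
    """
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    b1 = a1 - a2
    b2 = a2 - a3
    n1 = np.cross(b2, b1)
    if np.linalg.norm(n1) < 1e-8 or np.linalg.norm(b1) < 1e-8:
        raise StructureError("degenerate anchor geometry for hydrogen placement")
    e1 = b1 / np.linalg.norm(b1)
    en = n1 / np.linalg.norm(n1)
    em = np.cross(en, e1)
    d = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(dih),
        bond * math.sin(ang) * math.sin(dih),
    ])
    return a1 + d[0] * e1 + d[1] * em + d[2] * en


# side-chain polar hydrogens: name -> (anchor1, anchor2, anchor3, bond, angle, dihedral)
_SIDECHAIN_H: dict[str, list[tuple[str, str, str, str, float, float, float]]] = {
    "SER": [("HG", "OG", "CB", "CA", 0.96, 109.5, 180.0)],
    "THR": [("HG1", "OG1", "CB", "CA", 0.96, 109.5, 180.0)],
    "CYS": [("HG", "SG", "CB", "CA", 1.33, 96.0, 180.0)],
    "TYR": [("HH", "OH", "CZ", "CE1", 0.96, 109.5, 180.0)],
    "LYS": [("HZ1", "NZ", "CE", "CD", 1.01, 109.5, 60.0),
            ("HZ2", "NZ", "CE", "CD", 1.01, 109.5, 180.0),
            ("HZ3", "NZ", "CE", "CD", 1.01, 109.5, -60.0)],
    "ARG": [("HE", "NE", "CZ", "NH1", 1.01, 120.0, 180.0),
            ("HH11", "NH1", "CZ", "NE", 1.01, 120.0, 0.0),
            ("HH12", "NH1", "CZ", "NE", 1.01, 120.0, 180.0),
            ("HH21", "NH2", "CZ", "NE", 1.01, 120.0, 0.0),
            ("HH22", "NH2", "CZ", "NE", 1.01, 120.0, 180.0)],
    "ASN": [("HD21", "ND2", "CG", "OD1", 1.01, 120.0, 0.0),
            ("HD22", "ND2", "CG", "OD1", 1.01, 120.0, 180.0)],
    "GLN": [("HE21", "NE2", "CD", "OE1", 1.01, 120.0, 0.0),
            ("HE22", "NE2", "CD", "OE1", 1.01, 120.0, 180.0)],
    "HIS": [("HE2", "NE2", "CE1", "ND1", 1.01, 125.0, 180.0)],
    "TRP": [("HE1", "NE1", "CE2", "CD2", 1.01, 125.0, 180.0)],
}


def add_hydrogens(structure: Structure) -> Structure:
    """Place polar hydrogens at ideal geometry; heavy atoms are untouched.

    The documented template places, per standard residue: the backbone amide
    H (except proline and chain-initial residues) and the side-chain polar
    hydrogens of Ser, Thr, Cys, Tyr, Lys, Arg, Asn, Gln, His (Neps tautomer)
    and Trp.  Nonpolar CH hydrogens are not placed (their charges are folded
    into the heavy-atom table).  Idempotent: hydrogens already present are
    kept as-is.  Raises if a required heavy-atom anchor is missing.
    """
    residues = structure.residues()
    index = {a.key: i for i, a in enumerate(structure.atoms)}
    # previous residue's C per chain, for the amide H
    by_chain: dict[str, list[tuple[int, tuple[str, int, str]]]] = {}
    for (chain, seq, resname) in residues:
        by_chain.setdefault(chain, []).append((seq, (chain, seq, resname)))
    prev_c: dict[tuple[str, int], np.ndarray] = {}
    first_res: set[tuple[str, int]] = set()
    for chain, lst in by_chain.items():
        lst.sort()
        first_res.add((chain, lst[0][0]))
        for (seq_prev, key_prev), (seq, _key) in zip(lst, lst[1:]):
            ck = (chain, seq_prev, "C")
            if ck in index and seq == seq_prev + 1:
                prev_c[(chain, seq)] = structure.atoms[index[ck]].coords

    new_atoms = [replace(a, coords=a.coords.copy()) for a in structure.atoms]
    serial = max(a.serial for a in structure.atoms)
    appended: list[Atom] = []

    def has(chain: str, seq: int, name: str) -> bool:
        return (chain, seq, name) in index

    def get(chain: str, seq: int, name: str, resname: str) -> np.ndarray:
        try:
            return structure.atoms[index[(chain, seq, name)]].coords
        except KeyError:
            raise StructureError(
                f"residue {resname} {chain}{seq}: missing heavy-atom anchor {name}")

    for (chain, seq, resname), idx in residues.items():
        res = resname.upper()
        if res not in STANDARD_AMINO_ACIDS:
            continue
        # backbone amide H
        if res != "PRO" and (chain, seq) not in first_res and not has(chain, seq, "H"):
            if not has(chain, seq, "N"):
                raise StructureError(f"residue {res} {chain}{seq}: missing backbone N")
            npos = get(chain, seq, "N", res)
            ca = get(chain, seq, "CA", res)
            cprev = prev_c.get((chain, seq))
            if cprev is not None:
                u = npos - cprev
                v = npos - ca
                direction = u / np.linalg.norm(u) + v / np.linalg.norm(v)
                direction /= np.linalg.norm(direction)
                serial += 1
                appended.append(Atom(serial, "H", "", res, chain, seq,
                                     npos + 1.01 * direction, 1.0, "H"))
        for (hname, a1, a2, a3, bond, angle, dih) in _SIDECHAIN_H.get(res, []):
            if has(chain, seq, hname):
                continue
            try:
                pos = _place_internal(get(chain, seq, a1, res), get(chain, seq, a2, res),
                                      get(chain, seq, a3, res), bond, angle, dih)
            except StructureError:
                raise
            serial += 1
            appended.append(Atom(serial, hname, "", res, chain, seq, pos, 1.0, "H"))

    if not appended:
        return structure
    return Structure(new_atoms + appended, id=structure.id)


# ---------------------------------------------------------------------------
# Site definitions

def load_site_config(path: str | Path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def default_site_config() -> dict:
    return load_site_config(_DATA_DIR / "sites_default.toml")


_NTR = {"kind": "base", "model_pka": 8.0, "atoms": ["N"],
        "state0": [-0.40], "state1": [0.60]}
_CTR = {"kind": "acid", "model_pka": 3.8, "atoms": ["C", "O", "OXT"],
        "state0": [0.55, -0.55, 0.0], "state1": [0.10, -0.55, -0.55]}


def define_sites(structure: Structure, site_config: dict | None = None,
                 include_termini: bool = True) -> list[SiteDefinition]:
    """Build one SiteDefinition per titratable residue and redox cofactor.

    *site_config* follows the shipped TOML layout: ``[titratable.<RES>]``
    tables with kind/model_pka/atoms/state0/state1 and ``[redox.<RES>]``
    tables with em_ref and either inline atoms/state0/state1 or
    charges_state0/charges_state1 file paths in the parameter-table dialect.
    Raises if a configured redox cofactor is absent from the structure.
    """
    if site_config is None:
        site_config = default_site_config()
    titratable = {k.upper(): v for k, v in site_config.get("titratable", {}).items()}
    redox = {k.upper(): v for k, v in site_config.get("redox", {}).items()}

    sites: list[SiteDefinition] = []
    residues = structure.residues()
    index = {a.key: i for i, a in enumerate(structure.atoms)}
    seen_redox: set[str] = set()

    by_chain: dict[str, list[int]] = {}
    for (chain, seq, resname) in residues:
        if resname.upper() in STANDARD_AMINO_ACIDS:
            by_chain.setdefault(chain, []).append(seq)

    for (chain, seq, resname), idx in sorted(residues.items(),
                                             key=lambda kv: (kv[0][0], kv[0][1])):
        res = resname.upper()
        if res in titratable:
            cfg = titratable[res]
            ids = _site_atom_indices(index, chain, seq, cfg["atoms"], res,
                                     required=True)
            sites.append(SiteDefinition(
                site_id=f"{res}-{chain}{seq}", kind=cfg["kind"],
                atom_indices=ids,
                charges_state0=np.asarray(cfg["state0"], dtype=float),
                charges_state1=np.asarray(cfg["state1"], dtype=float),
                model_pka=float(cfg["model_pka"])))
        if res in redox:
            cfg = redox[res]
            names, q0, q1 = _redox_charge_vectors(cfg, res)
            ids = _site_atom_indices(index, chain, seq, names, res, required=True)
            sites.append(SiteDefinition(
                site_id=f"{res}-{chain}{seq}", kind="redox",
                atom_indices=ids, charges_state0=q0, charges_state1=q1,
                em_ref=float(cfg["em_ref"])))
            seen_redox.add(res)

    if include_termini:
        for chain, seqs in by_chain.items():
            nseq, cseq = min(seqs), max(seqs)
            nres = next(r for (c, s, r) in residues if c == chain and s == nseq)
            if nres.upper() != "PRO" and (chain, nseq, "N") in index:
                sites.append(SiteDefinition(
                    site_id=f"NTR-{chain}{nseq}", kind="base",
                    atom_indices=[index[(chain, nseq, "N")]],
                    charges_state0=np.array(_NTR["state0"]),
                    charges_state1=np.array(_NTR["state1"]),
                    model_pka=_NTR["model_pka"]))
            if (chain, cseq, "OXT") in index:
                ids = [index[(chain, cseq, n)] for n in _CTR["atoms"]]
                sites.append(SiteDefinition(
                    site_id=f"CTR-{chain}{cseq}", kind="acid",
                    atom_indices=ids,
                    charges_state0=np.array(_CTR["state0"]),
                    charges_state1=np.array(_CTR["state1"]),
                    model_pka=_CTR["model_pka"]))

    missing_cofactors = {r for r in set(redox) - seen_redox
                         if redox[r].get("required", True)}
    if missing_cofactors:
        raise StructureError(
            f"configured redox cofactor(s) absent from structure: "
            f"{sorted(missing_cofactors)}")
    return sites


def _site_atom_indices(index: dict, chain: str, seq: int, names: Sequence[str],
                       res: str, required: bool) -> list[int]:
    ids = []
    for n in names:
        key = (chain, seq, n)
        if key not in index:
            if required:
                raise StructureError(f"site {res} {chain}{seq}: missing atom {n}")
            continue
        ids.append(index[key])
    return ids


def _redox_charge_vectors(cfg: dict, res: str):
    if "atoms" in cfg:
        return (list(cfg["atoms"]), np.asarray(cfg["state0"], dtype=float),
                np.asarray(cfg["state1"], dtype=float))
    f0, f1 = cfg.get("charges_state0"), cfg.get("charges_state1")
    if not f0 or not f1:
        raise ParameterError(
            f"redox cofactor {res}: needs inline atoms/state0/state1 or "
            "charges_state0/charges_state1 file paths")
    t0 = load_parameter_file(f0)
    t1 = load_parameter_file(f1)
    names = [name for (r, name) in t0 if r == res]
    if set(names) != {name for (r, name) in t1 if r == res}:
        raise ParameterError(f"redox cofactor {res}: state files cover different atoms")
    q0 = np.array([t0[(res, n)][0] for n in names])
    q1 = np.array([t1[(res, n)][0] for n in names])
    return names, q0, q1


# ---------------------------------------------------------------------------
# PQR / PDB output

def write_pqr(structure: Structure, path: str | Path) -> None:
    """Write the parameterized structure in standard PQR columns."""
    if not structure.is_parameterized:
        raise ParameterError("structure is not parameterized; run assign_parameters")
    lines = []
    for i, a in enumerate(structure, 1):
        x, y, z = a.coords
        lines.append(
            f"ATOM  {i:5d} {a.name:<4s} {a.residue_name:<4s} {a.chain:1s} "
            f"{a.residue_seq:4d} {x:10.4f} {y:10.4f} {z:10.4f} "
            f"{a.charge:8.4f} {a.radius:7.4f}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pqr(path: str | Path, id: str = "") -> Structure:
    """Read back the PQR written by :func:`write_pqr`."""
    atoms = []
    for line in Path(path).read_text().splitlines():
        if not line.startswith(("ATOM", "HETATM")):
            continue
        parts = line.split()
        _rec, serial, name, resname, chain, seq = parts[:6]
        x, y, z, q, r = (float(v) for v in parts[6:11])
        atoms.append(Atom(int(serial), name, "", resname, chain, int(seq),
                          np.array([x, y, z]), 1.0,
                          name[0] if name else "", charge=q, radius=r))
    return Structure(atoms, id=id)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write atoms in minimal PDB format (HETATM for non-standard residues)."""
    lines = []
    for i, a in enumerate(structure, 1):
        rec = "ATOM  " if a.residue_name.upper() in STANDARD_AMINO_ACIDS else "HETATM"
        x, y, z = a.coords
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"{rec}{i:5d} {name:<4s}{a.altloc or ' '}{a.residue_name:<3s} "
            f"{a.chain:1s}{a.residue_seq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
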