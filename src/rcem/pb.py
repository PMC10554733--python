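"""Finite-difference linear Poisson-Boltzmann solver with grid focusing.

The LPB equation div(eps grad phi) - eps_w kappa^2 phi = -4 pi k_e rho is
discretized on a cubic lattice with a 7-point stencil.  Dielectric values
live on grid edges; an edge crossing the solute boundary gets the harmonic
mean of protein and solvent dielectric weighted by the fraction of the edge
inside the atom-sphere union (estimated by fixed subsegment sampling).
Debye screening applies outside the solute plus a Stern (ion-exclusion)
layer.  Charges are spread to the eight surrounding nodes by trilinear
interpolation.  The discrete system is solved by Jacobi-preconditioned
conjugate gradients; coarse-level boundary potentials come from the analytic
Debye-Hueckel monopole, and each finer focusing level takes its boundary from
the previous solution.

Potentials are in kcal/(mol e), energies in kcal/mol, lengths in A.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import LinearOperator, cg

from .constants import K_COULOMB, debye_kappa2
from .structure import PhysicalConditions, SiteDefinition, Structure

FOUR_PI = 4.0 * math.pi

#: default three-step focusing resolutions, A
DEFAULT_SCHEDULE = (2.5, 1.0, 0.3)

#: ion-exclusion (Stern) layer width, A
STERN_LAYER = 2.0


class SolverError(RuntimeError):
    """Non-convergence or ill-posed grid setup."""


@dataclass(frozen=True)
class GridSpec:
    """A cubic grid: *npoints* nodes per axis (odd), *spacing* A apart."""

    center: tuple[float, float, float]
    npoints: int
    spacing: float

    def __post_init__(self) -> None:
        if self.npoints < 33 or self.npoints % 2 == 0:
            raise ValueError("npoints must be odd and >= 33")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def extent(self) -> float:
        return (self.npoints - 1) * self.spacing

    @property
    def origin(self) -> np.ndarray:
        return np.asarray(self.center) - 0.5 * self.extent

    def axis(self, i: int) -> np.ndarray:
        return self.origin[i] + self.spacing * np.arange(self.npoints)

    def node_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.axis(0), self.axis(1), self.axis(2)

    def contains(self, points: np.ndarray, margin: float = 0.0) -> bool:
        points = np.atleast_2d(points)
        lo = self.origin + margin
        hi = self.origin + self.extent - margin
        return bool(np.all(points >= lo) and np.all(points <= hi))


class DielectricModel:
    """Per-edge dielectric, per-node screening and charge maps for one grid."""

    def __init__(self, grid: GridSpec, eps_edges: tuple[np.ndarray, np.ndarray, np.ndarray],
                 kappa2eps: np.ndarray, rho: np.ndarray,
                 eps_boundary: float, kappa: float, a_eff: float):
        self.grid = grid
        self.eps_edges = eps_edges
        self.kappa2eps = kappa2eps
        self.rho = rho  # charge (e) spread per node
        self.eps_boundary = eps_boundary
        self.kappa = kappa
        self.a_eff = a_eff


@dataclass
class PotentialGrid:
    """A solved potential phi (kcal/(mol e)) on a grid."""

    grid: GridSpec
    phi: np.ndarray
    residual: float = 0.0

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of phi at Cartesian *points*."""
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(self.grid.node_coords(), self.phi,
                                         method="linear", bounds_error=True)
        return interp(np.atleast_2d(points))


# ---------------------------------------------------------------------------
# model construction

def _mark_inside(flags: np.ndarray, xs: np.ndarray, ys: np.ndarray, zs: np.ndarray,
                 centers: np.ndarray, radii: np.ndarray) -> None:
    """Set flags True for lattice points inside any sphere (local-block loop)."""
    for (cx, cy, cz), r in zip(centers, radii):
        if r <= 0:
            continue
        ix = np.searchsorted(xs, (cx - r, cx + r))
        iy = np.searchsorted(ys, (cy - r, cy + r))
        iz = np.searchsorted(zs, (cz - r, cz + r))
        if ix[0] >= ix[1] or iy[0] >= iy[1] or iz[0] >= iz[1]:
            continue
        dx2 = (xs[ix[0]:ix[1]] - cx) ** 2
        dy2 = (ys[iy[0]:iy[1]] - cy) ** 2
        dz2 = (zs[iz[0]:iz[1]] - cz) ** 2
        block = (dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]) < r * r
        flags[ix[0]:ix[1], iy[0]:iy[1], iz[0]:iz[1]] |= block


def _edge_eps(grid: GridSpec, axis: int, centers: np.ndarray, radii: np.ndarray,
              eps_in: float, eps_out: float, nsub: int = 24) -> np.ndarray:
    """Harmonic-mean dielectric for all edges along *axis*."""
    n, h = grid.npoints, grid.spacing
    axes = [grid.axis(0), grid.axis(1), grid.axis(2)]
    # subsample points along the edge direction
    sub = axes[axis][:-1, None] + (np.arange(nsub)[None, :] + 0.5) * (h / nsub)
    fine = sub.ravel()  # sorted, length (n-1)*nsub
    shape = [n, n, n]
    shape[axis] = (n - 1) * nsub
    flags = np.zeros(shape, dtype=bool)
    coords = [axes[0], axes[1], axes[2]]
    coords[axis] = fine
    _mark_inside(flags, coords[0], coords[1], coords[2], centers, radii)
    # average the nsub subsamples back onto each edge -> fraction inside
    newshape = list(flags.shape)
    newshape[axis : axis + 1] = [n - 1, nsub]
    frac = flags.reshape(newshape).mean(axis=axis + 1)
    with np.errstate(divide="ignore"):
        eps = 1.0 / (frac / eps_in + (1.0 - frac) / eps_out)
    return eps


def _spread_charges(grid: GridSpec, coords: np.ndarray, charges: np.ndarray) -> np.ndarray:
    """Trilinear charge spreading onto grid nodes; returns charge (e) per node."""
    n, h = grid.npoints, grid.spacing
    rho = np.zeros((n, n, n))
    if len(coords) == 0:
        return rho
    t = (np.atleast_2d(coords) - grid.origin) / h
    i0 = np.floor(t).astype(int)
    if np.any(i0 < 0) or np.any(i0 >= n - 1):
        raise SolverError("charge outside grid")
    f = t - i0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (np.where(dx, f[:, 0], 1 - f[:, 0])
                     * np.where(dy, f[:, 1], 1 - f[:, 1])
                     * np.where(dz, f[:, 2], 1 - f[:, 2]))
                np.add.at(rho, (i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz),
                          w * charges)
    return rho


def build_dielectric_model(structure: Structure, grid: GridSpec,
                           conditions: PhysicalConditions,
                           charges: np.ndarray | None = None,
                           uniform_eps: float | None = None,
                           stern: float = STERN_LAYER,
                           nsub: int = 24) -> DielectricModel:
    """Build dielectric/screening/charge maps for one grid level.

    *charges* defaults to the structure's assigned charges; pass a custom
    vector to solve for a charge subset (e.g. site difference charges).
    With *uniform_eps* the whole grid gets one dielectric and no screening
    (the homogeneous reference used for reaction-field energies).
    """
    coords = structure.coords
    radii = structure.radii
    if charges is None:
        charges = structure.charges
    charges = np.asarray(charges, dtype=float)
    if not grid.contains(coords[np.nonzero(charges)[0]] if np.any(charges) else coords[:1]):
        raise SolverError("grid does not enclose the charged atoms")

    n = grid.npoints
    rho = _spread_charges(grid, coords, charges)

    if uniform_eps is not None:
        eps_x = np.full((n - 1, n, n), uniform_eps)
        eps_y = np.full((n, n - 1, n), uniform_eps)
        eps_z = np.full((n, n, n - 1), uniform_eps)
        kappa2eps = np.zeros((n, n, n))
        return DielectricModel(grid, (eps_x, eps_y, eps_z), kappa2eps, rho,
                               eps_boundary=uniform_eps, kappa=0.0, a_eff=0.0)

    eps_in, eps_out = conditions.eps_protein, conditions.eps_solvent
    if np.any(radii <= 0):
        raise SolverError("structure has atoms without radii; run assign_parameters")
    eps_x = _edge_eps(grid, 0, coords, radii, eps_in, eps_out, nsub)
    eps_y = _edge_eps(grid, 1, coords, radii, eps_in, eps_out, nsub)
    eps_z = _edge_eps(grid, 2, coords, radii, eps_in, eps_out, nsub)

    kappa2 = debye_kappa2(conditions.ionic_strength, eps_out, conditions.temperature)
    kappa2eps = np.full((n, n, n), kappa2 * eps_out)
    if kappa2 > 0:
        ion_excluded = np.zeros((n, n, n), dtype=bool)
        xs, ys, zs = grid.node_coords()
        _mark_inside(ion_excluded, xs, ys, zs, coords, radii + stern)
        kappa2eps[ion_excluded] = 0.0
    else:
        kappa2eps[:] = 0.0

    center = coords.mean(axis=0)
    a_eff = float(np.max(np.linalg.norm(coords - center, axis=1) + radii) + stern)
    return DielectricModel(grid, (eps_x, eps_y, eps_z), kappa2eps, rho,
                           eps_boundary=eps_out, kappa=math.sqrt(kappa2), a_eff=a_eff)


def _charge_center(coords: np.ndarray, charges: np.ndarray) -> np.ndarray:
    w = np.abs(charges)
    if w.sum() == 0:
        return coords.mean(axis=0)
    return (coords * w[:, None]).sum(axis=0) / w.sum()


# ---------------------------------------------------------------------------
# boundary conditions and solve

def _analytic_boundary(model: DielectricModel, coords: np.ndarray,
                       charges: np.ndarray) -> np.ndarray:
    """Debye-Hueckel boundary potential, superposed per source charge.

    phi(r) = sum_s k_e q_s exp(-kappa (|r - r_s| - a)) /
             (eps |r - r_s| (1 + kappa a))
    with a the solute's effective ion-exclusion radius (geometry only, so
    the boundary is exactly linear in the charges); reduces to Coulomb's
    law at zero ionic strength.  Evaluated on boundary nodes only.
    """
    grid = model.grid
    n = grid.npoints
    phi = np.zeros((n, n, n))
    sel = np.nonzero(np.asarray(charges))[0]
    if len(sel) == 0:
        return phi
    mask = np.zeros((n, n, n), dtype=bool)
    mask[[0, -1], :, :] = True
    mask[:, [0, -1], :] = True
    mask[:, :, [0, -1]] = True
    xs, ys, zs = grid.node_coords()
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([gx[mask], gy[mask], gz[mask]])
    kappa, a = model.kappa, model.a_eff
    vals = np.zeros(len(pts))
    for s in sel:
        r = np.linalg.norm(pts - np.asarray(coords)[s], axis=1)
        r = np.maximum(r, 0.5 * grid.spacing)
        screen = np.exp(-kappa * np.maximum(r - a, 0.0)) / (1.0 + kappa * a)
        vals += K_COULOMB * float(charges[s]) * screen / (model.eps_boundary * r)
    phi[mask] = vals
    return phi


def solve_lpb(model: DielectricModel, boundary="analytic_debye",
              source_coords: np.ndarray | None = None,
              source_charges: np.ndarray | None = None,
              rtol: float = 1e-8, maxiter: int = 10000) -> PotentialGrid:
    """Solve the discrete LPB system for one grid level.

    *boundary* is "analytic_debye", "zero", or a full-grid array whose
    boundary layer supplies Dirichlet values (the focusing path).  The
    analytic boundary needs the physical source charges; they default to the
    model's spread charges.
    """
    grid = model.grid
    n, h = grid.npoints, grid.spacing

    if isinstance(boundary, str):
        if boundary == "zero":
            phi_b = np.zeros((n, n, n))
        elif boundary == "analytic_debye":
            if source_coords is None:
                # fall back to grid-node positions of the spread charge
                xs, ys, zs = grid.node_coords()
                nz = np.nonzero(model.rho)
                source_coords = np.column_stack([xs[nz[0]], ys[nz[1]], zs[nz[2]]])
                source_charges = model.rho[nz]
            phi_b = _analytic_boundary(model, source_coords, source_charges)
        else:
            raise ValueError(f"unknown boundary {boundary!r}")
    else:
        phi_b = np.asarray(boundary, dtype=float)
        if phi_b.shape != (n, n, n):
            raise ValueError("boundary array shape mismatch")

    eps_x, eps_y, eps_z = model.eps_edges
    inv_h2 = 1.0 / (h * h)

    interior = np.zeros((n, n, n), dtype=bool)
    interior[1:-1, 1:-1, 1:-1] = True
    ni = int(interior.sum())
    imap = -np.ones((n, n, n), dtype=np.int64)
    imap[interior] = np.arange(ni)

    diag = np.zeros((n, n, n))
    diag[1:-1, 1:-1, 1:-1] = model.kappa2eps[1:-1, 1:-1, 1:-1]
    b = FOUR_PI * K_COULOMB * model.rho / h**3

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    bvec = b[interior].copy()

    def couple(eps_arr, shift_axis):
        # edges along shift_axis couple node p and p+1 along that axis
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[shift_axis] = slice(0, n - 1)
        sl_hi[shift_axis] = slice(1, n)
        w = eps_arr * inv_h2
        p_lo = imap[tuple(sl_lo)]
        p_hi = imap[tuple(sl_hi)]
        phib_lo = phi_b[tuple(sl_lo)]
        phib_hi = phi_b[tuple(sl_hi)]
        # accumulate diagonal for both endpoints
        np.add.at(diag, tuple(sl_lo), w)
        np.add.at(diag, tuple(sl_hi), w)
        both = (p_lo >= 0) & (p_hi >= 0)
        rows.append(p_lo[both]); cols.append(p_hi[both]); vals.append(-w[both])
        rows.append(p_hi[both]); cols.append(p_lo[both]); vals.append(-w[both])
        lo_only = (p_lo >= 0) & (p_hi < 0)
        np.add.at(bvec, p_lo[lo_only], w[lo_only] * phib_hi[lo_only])
        hi_only = (p_hi >= 0) & (p_lo < 0)
        np.add.at(bvec, p_hi[hi_only], w[hi_only] * phib_lo[hi_only])

    couple(eps_x, 0)
    couple(eps_y, 1)
    couple(eps_z, 2)

    dvec = diag[interior]
    rows.append(np.arange(ni)); cols.append(np.arange(ni)); vals.append(dvec)
    A = csr_matrix((np.concatenate(vals),
                    (np.concatenate(rows), np.concatenate(cols))), shape=(ni, ni))

    M = LinearOperator((ni, ni), matvec=lambda x: x / dvec)
    x, info = cg(A, bvec, rtol=rtol, atol=0.0, maxiter=maxiter, M=M)
    res = float(np.linalg.norm(A @ x - bvec) / max(np.linalg.norm(bvec), 1e-300))
    if info != 0 or res > 1e-6:
        raise SolverError(f"LPB solver did not converge (info={info}, "
                          f"relative residual {res:.2e})")

    phi = phi_b.copy()
    phi[interior] = x
    return PotentialGrid(grid, phi, residual=res)


# ---------------------------------------------------------------------------
# focusing

def _level_grid(structure: Structure, spacing: float, margin: float,
                focus: np.ndarray, npoints_fine: int,
                prev: GridSpec | None) -> GridSpec:
    if prev is None:
        coords = structure.coords
        radii = structure.radii
        lo = (coords - radii[:, None]).min(axis=0)
        hi = (coords + radii[:, None]).max(axis=0)
        center = 0.5 * (lo + hi)
        extent = float(np.max(hi - lo)) + 2 * margin
        npts = int(math.ceil(extent / spacing)) + 1
        npts = max(npts + (npts + 1) % 2, 33)
        return GridSpec(tuple(center), npts, spacing)
    # finer level: shrink and shift so it stays inside the previous grid
    npts = npoints_fine
    max_extent = prev.extent - 2 * prev.spacing
    while (npts - 1) * spacing > max_extent and npts > 33:
        npts -= 2
    if (npts - 1) * spacing > max_extent:
        raise SolverError("focusing level does not fit inside the previous grid")
    extent = (npts - 1) * spacing
    lo = prev.origin + prev.spacing + 0.5 * extent
    hi = prev.origin + prev.extent - prev.spacing - 0.5 * extent
    center = np.clip(np.asarray(focus, float), lo, hi)
    return GridSpec(tuple(center), npts, spacing)


def focusing_solve(structure: Structure, conditions: PhysicalConditions,
                   charges: np.ndarray | None = None,
                   target_points: np.ndarray | None = None,
                   schedule: Sequence[float] = DEFAULT_SCHEDULE,
                   uniform_eps: float | None = None,
                   npoints_fine: int = 65, margin: float = 15.0,
                   focus: np.ndarray | None = None,
                   stern: float = STERN_LAYER) -> PotentialGrid:
    """Solve with a multi-level focusing schedule; returns the finest level.

    The coarsest level is a cube enclosing the structure plus *margin* with
    analytic Debye-Hueckel boundary values; each finer level has
    *npoints_fine* nodes centered on *focus* (default: centroid of
    *target_points*, else of the charges) and takes its boundary by
    interpolation from the previous level.
    """
    schedule = list(schedule)
    if any(b >= a for a, b in zip(schedule, schedule[1:])):
        raise ValueError("focusing schedule must be strictly decreasing")
    charges_arr = structure.charges if charges is None else np.asarray(charges, float)
    if focus is None:
        if target_points is not None:
            focus = np.atleast_2d(target_points).mean(axis=0)
        else:
            focus = _charge_center(structure.coords, charges_arr)

    phi_prev: PotentialGrid | None = None
    for lvl, spacing in enumerate(schedule):
        grid = _level_grid(structure, spacing, margin, focus, npoints_fine,
                           prev=None if phi_prev is None else phi_prev.grid)
        if target_points is not None and lvl == len(schedule) - 1:
            if not grid.contains(np.atleast_2d(target_points), margin=grid.spacing):
                raise SolverError("target atoms outside finest focusing grid")
        model = build_dielectric_model(structure, grid, conditions,
                                       charges=charges_arr,
                                       uniform_eps=uniform_eps, stern=stern)
        if phi_prev is None:
            phi = solve_lpb(model, boundary="analytic_debye",
                            source_coords=structure.coords,
                            source_charges=charges_arr)
        else:
            xs, ys, zs = grid.node_coords()
            pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)
            bvals = phi_prev.sample(pts.reshape(-1, 3)).reshape(pts.shape[:3])
            phi = solve_lpb(model, boundary=bvals)
        phi_prev = phi
    return phi_prev


def reaction_field_energy(structure: Structure, conditions: PhysicalConditions,
                          charges: np.ndarray | None = None,
                          schedule: Sequence[float] = DEFAULT_SCHEDULE,
                          npoints_fine: int = 65, margin: float = 15.0,
                          focus: np.ndarray | None = None,
                          stern: float = STERN_LAYER) -> float:
    """Reaction-field (solvation) energy, kcal/mol.

    dG_rf = 1/2 sum_a q_a [phi_env(r_a) - phi_ref(r_a)] with phi_env the
    heterogeneous-dielectric solution and phi_ref the uniform eps_protein
    solution on the identical grids, so the grid self-energy cancels.
    """
    charges_arr = structure.charges if charges is None else np.asarray(charges, float)
    sel = np.nonzero(charges_arr)[0]
    if len(sel) == 0:
        return 0.0
    pts = structure.coords[sel]
    kw = dict(charges=charges_arr, target_points=pts, schedule=schedule,
              npoints_fine=npoints_fine, margin=margin, focus=focus, stern=stern)
    phi_env = focusing_solve(structure, conditions, **kw)
    phi_ref = focusing_solve(structure, conditions, uniform_eps=conditions.eps_protein,
                             **kw)
    dphi = phi_env.sample(pts) - phi_ref.sample(pts)
    return float(0.5 * np.dot(charges_arr[sel], dphi))


def site_potential(site: SiteDefinition, structure: Structure,
                   conditions: PhysicalConditions,
                   eval_points: np.ndarray,
                   schedule: Sequence[float] = DEFAULT_SCHEDULE,
                   npoints_fine: int = 65, margin: float = 15.0,
                   stern: float = STERN_LAYER) -> np.ndarray:
    """Potential of a site's difference charges in the protein environment,
    evaluated at *eval_points* (focus centered to cover sources and targets)."""
    charges = np.zeros(len(structure))
    for idx, dq in zip(site.atom_indices, site.delta_charges):
        charges[idx] = dq
    src = structure.coords[site.atom_indices]
    pts = np.vstack([src, np.atleast_2d(eval_points)])
    focus = pts.mean(axis=0)
    phi = focusing_solve(structure, conditions, charges=charges,
                         target_points=pts, schedule=schedule,
                         npoints_fine=npoints_fine, margin=margin,
                         focus=focus, stern=stern)
    return phi.sample(np.atleast_2d(eval_points))


def interaction_energy(site_i: SiteDefinition, site_j: SiteDefinition,
                       structure: Structure, conditions: PhysicalConditions,
                       schedule: Sequence[float] = DEFAULT_SCHEDULE,
                       npoints_fine: int = 65, margin: float = 15.0,
                       stern: float = STERN_LAYER) -> float:
    """Site-site interaction W_ij (kcal/mol): difference charges of j in the
    potential of i's difference charges, in the protein environment."""
    if set(site_i.atom_indices) & set(site_j.atom_indices):
        raise ValueError(f"sites {site_i.site_id} and {site_j.site_id} share atoms")
    pts = structure.coords[site_j.atom_indices]
    phi = site_potential(site_i, structure, conditions, pts, schedule=schedule,
                        npoints_fine=npoints_fine, margin=margin, stern=stern)
    return float(np.dot(site_j.delta_charges, phi))


def write_opendx(pot: PotentialGrid, path) -> None:
    """Dump a potential grid in OpenDX scalar format (text)."""
    g = pot.grid
    n = g.npoints
    o = g.origin
    lines = [
        f"object 1 class gridpositions counts {n} {n} {n}",
        f"origin {o[0]:.6g} {o[1]:.6g} {o[2]:.6g}",
        f"delta {g.spacing:.6g} 0 0",
        f"delta 0 {g.spacing:.6g} 0",
        f"delta 0 0 {g.spacing:.6g}",
        f"object 2 class gridconnections counts {n} {n} {n}",
        f"object 3 class array type double rank 0 items {n**3} data follows",
    ]
    flat = pot.phi.ravel()
    for i in range(0, len(flat), 3):
        lines.append(" ".join(f"{v:.6e}" for v in flat[i:i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "regular positions regular connections" class field')
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
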