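"""Protonation/redox microstate sampling and midpoint-potential search.

The microstate model is the standard continuum-electrostatics energy
function: binary state vector x over sites, per-site state-1 free energy
(intrinsic term + pH or bias term) and a symmetric pairwise interaction
matrix W,

    E(x) = sum_i x_i h_i + sum_{i<j} x_i x_j W_ij   [kcal/mol].

Conventions (pinned by the Henderson-Hasselbalch and monotonicity tests):
x = 1 means deprotonated for acids, protonated for bases, reduced for redox
sites; for acids h includes ln10*RT*(pKa - pH), for bases ln10*RT*(pH - pKa);
for redox sites h includes +c*bias with c = 23.061 cal/(mol mV), so a more
positive bias (solution potential above the reference) disfavors the reduced
state.  The midpoint bias, where the reduced population is 1/2, gives
Em = em_ref + bias*.

Populations come either from exact Boltzmann enumeration (<= 20 sites; the
oracle) or from Metropolis Monte Carlo with single-site moves plus double
moves for strongly coupled pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .constants import MV_TO_KCAL, R_GAS
from .structure import PhysicalConditions, SiteDefinition

LN10 = math.log(10.0)

#: |W| threshold (kcal/mol) above which a site pair also gets double moves
STRONG_COUPLING = 2.0


@dataclass
class SiteEnergyTable:
    """Intrinsic energies and interaction matrix for a set of sites."""

    sites: list[SiteDefinition]
    g_intr: np.ndarray  # kcal/mol, state1 - state0 at reference conditions
    W: np.ndarray  # kcal/mol, symmetric, zero diagonal

    def __post_init__(self) -> None:
        n = len(self.sites)
        self.g_intr = np.asarray(self.g_intr, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if self.g_intr.shape != (n,) or self.W.shape != (n, n):
            raise ValueError("table dimensions disagree with number of sites")
        if not np.all(np.isfinite(self.g_intr)) or not np.all(np.isfinite(self.W)):
            raise ValueError("non-finite energies in table")
        if np.max(np.abs(self.W - self.W.T), initial=0.0) > 0.05:
            raise ValueError("interaction matrix not symmetric within 0.05 kcal/mol")
        if np.max(np.abs(np.diag(self.W)), initial=0.0) > 1e-12:
            raise ValueError("interaction matrix diagonal must be zero")
        # symmetrize the residual numerical asymmetry
        self.W = 0.5 * (self.W + self.W.T)

    def __len__(self) -> int:
        return len(self.sites)

    def redox_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.sites) if s.kind == "redox"]

    def state1_terms(self, conditions: PhysicalConditions,
                     bias: dict[str, float] | float | None = None) -> np.ndarray:
        """Per-site state-1 energy h_i at the given conditions and bias (mV)."""
        rt = R_GAS * conditions.temperature
        h = self.g_intr.copy()
        for i, s in enumerate(self.sites):
            if s.kind == "acid":
                h[i] += LN10 * rt * (s.model_pka - conditions.pH)
            elif s.kind == "base":
                h[i] += LN10 * rt * (conditions.pH - s.model_pka)
            else:
                b = _bias_for(s.site_id, bias)
                h[i] += MV_TO_KCAL * b
        return h

    def to_tsv(self, path: str | Path) -> None:
        """Serialize sites + g_intr and the W matrix to a TSV file."""
        lines = ["# site_id\tkind\tg_intr_kcal"]
        for s, g in zip(self.sites, self.g_intr):
            lines.append(f"{s.site_id}\t{s.kind}\t{g:.6f}")
        lines.append("# W (kcal/mol, square)")
        for row in self.W:
            lines.append("\t".join(f"{v:.6f}" for v in row))
        Path(path).write_text("\n".join(lines) + "\n")


def _bias_for(site_id: str, bias) -> float:
    if bias is None:
        return 0.0
    if isinstance(bias, (int, float)):
        return float(bias)
    return float(bias.get(site_id, 0.0))


@dataclass
class TitrationResult:
    """Microstate-averaged populations and sampling diagnostics."""

    populations: np.ndarray  # per-site mean of x, in [0, 1]
    method: str
    bias_applied: dict[str, float] = field(default_factory=dict)
    em: dict[str, float] = field(default_factory=dict)  # mV, filled by find_em
    acceptance_rate: float | None = None
    n_sweeps: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.populations = np.asarray(self.populations, dtype=float)
        if np.any(self.populations < -1e-12) or np.any(self.populations > 1 + 1e-12):
            raise ValueError("populations outside [0, 1]")


def microstate_energy(x: Sequence[int], table: SiteEnergyTable,
                      conditions: PhysicalConditions,
                      bias: dict[str, float] | float | None = None) -> float:
    """Energy (kcal/mol) of one microstate; E(all zeros) = 0 by construction."""
    x = np.asarray(x, dtype=float)
    if x.shape != (len(table),):
        raise ValueError("microstate length disagrees with table")
    h = table.state1_terms(conditions, bias)
    return float(x @ h + 0.5 * x @ table.W @ x)


def enumerate_exact(table: SiteEnergyTable, conditions: PhysicalConditions,
                    bias: dict[str, float] | float | None = None,
                    max_sites: int = 20) -> TitrationResult:
    """Boltzmann-exact populations by summation over all 2^N microstates."""
    n = len(table)
    if n > max_sites:
        raise ValueError(f"{n} sites exceed exact-enumeration limit {max_sites}")
    beta = 1.0 / (R_GAS * conditions.temperature)
    h = table.state1_terms(conditions, bias)

    pops = np.zeros(n)
    log_z_parts = []
    # chunked enumeration keeps the 2^N x N bit matrix small
    chunk = 1 << min(n, 16)
    states = np.arange(1 << n, dtype=np.int64)
    bit_cols = np.arange(n)
    from scipy.special import logsumexp

    weighted = np.zeros(n)
    log_z = -np.inf
    for start in range(0, len(states), chunk):
        s = states[start:start + chunk]
        bits = ((s[:, None] >> bit_cols[None, :]) & 1).astype(float)
        e = bits @ h + 0.5 * np.einsum("si,ij,sj->s", bits, table.W, bits)
        logw = -beta * e
        lz = logsumexp(logw)
        w = np.exp(logw - lz)
        part = w @ bits
        # merge running normalized sums
        if log_z == -np.inf:
            log_z, weighted = lz, part
        else:
            m = max(log_z, lz)
            a = math.exp(log_z - m)
            bfac = math.exp(lz - m)
            weighted = (a * weighted + bfac * part) / (a + bfac)
            log_z = m + math.log(a + bfac)
    pops = weighted
    return TitrationResult(populations=pops, method="exact",
                           bias_applied=_bias_dict(table, bias))


def _bias_dict(table: SiteEnergyTable, bias) -> dict[str, float]:
    return {s.site_id: _bias_for(s.site_id, bias)
            for s in table.sites if s.kind == "redox"}


# ---------------------------------------------------------------------------
# Metropolis Monte Carlo

def _mc_kernel_py(h, W, pairs, beta, n_sweeps, burn, seed):  # pragma: no cover
    """Pure-python fallback, same algorithm as the numba kernel."""
    rng = np.random.RandomState(seed)
    n = len(h)
    x = (rng.random_sample(n) < 0.5).astype(np.float64)
    mean = np.zeros(n)
    acc = 0
    tot = 0
    for sweep in range(n_sweeps):
        order = rng.permutation(n)
        for i in order:
            de = (1.0 - 2.0 * x[i]) * (h[i] + W[i] @ x)
            tot += 1
            if de <= 0 or rng.random_sample() < math.exp(-beta * de):
                x[i] = 1.0 - x[i]
                acc += 1
        for (i, j) in pairs:
            xi, xj = 1.0 - x[i], 1.0 - x[j]
            de = ((xi - x[i]) * (h[i] + W[i] @ x) + (xj - x[j]) * (h[j] + W[j] @ x)
                  + W[i, j] * (xi * xj - x[i] * x[j]
                               - (xi - x[i]) * x[j] - (xj - x[j]) * x[i]))
            tot += 1
            if de <= 0 or rng.random_sample() < math.exp(-beta * de):
                x[i], x[j] = xi, xj
                acc += 1
        if sweep >= burn:
            mean += x
    return mean / max(n_sweeps - burn, 1), acc / max(tot, 1)


try:
    from numba import njit

    @njit(cache=False)
    def _mc_kernel(h, W, pairs, beta, n_sweeps, burn, seed):
        np.random.seed(seed)
        n = h.shape[0]
        x = np.zeros(n)
        for i in range(n):
            if np.random.random() < 0.5:
                x[i] = 1.0
        mean = np.zeros(n)
        acc = 0
        tot = 0
        for sweep in range(n_sweeps):
            order = np.random.permutation(n)
            for k in range(n):
                i = order[k]
                field = h[i]
                for j in range(n):
                    field += W[i, j] * x[j]
                de = (1.0 - 2.0 * x[i]) * field
                tot += 1
                if de <= 0.0 or np.random.random() < math.exp(-beta * de):
                    x[i] = 1.0 - x[i]
                    acc += 1
            for p in range(pairs.shape[0]):
                i = pairs[p, 0]
                j = pairs[p, 1]
                xi = 1.0 - x[i]
                xj = 1.0 - x[j]
                fi = h[i]
                fj = h[j]
                for m in range(n):
                    fi += W[i, m] * x[m]
                    fj += W[j, m] * x[m]
                # subtract each site's own coupling to the other, then add the
                # joint term explicitly
                fi -= W[i, j] * x[j]
                fj -= W[j, i] * x[i]
                de = ((xi - x[i]) * fi + (xj - x[j]) * fj
                      + W[i, j] * (xi * xj - x[i] * x[j]))
                tot += 1
                if de <= 0.0 or np.random.random() < math.exp(-beta * de):
                    x[i] = xi
                    x[j] = xj
                    acc += 1
            if sweep >= burn:
                for i in range(n):
                    mean[i] += x[i]
        denom = n_sweeps - burn
        if denom < 1:
            denom = 1
        return mean / denom, acc / max(tot, 1)

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def mc_sample(table: SiteEnergyTable, conditions: PhysicalConditions,
              bias: dict[str, float] | float | None = None,
              n_sweeps: int = 100_000, seed: int = 0,
              burn_in_fraction: float = 0.1) -> TitrationResult:
    """Metropolis sampling of the microstate ensemble.

    One sweep = N single-site flips in random order plus a double flip for
    every site pair with |W_ij| > 2 kcal/mol; the first 10% of sweeps are
    discarded as burn-in.  Deterministic for a fixed seed.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    n = len(table)
    beta = 1.0 / (R_GAS * conditions.temperature)
    h = table.state1_terms(conditions, bias)
    ii, jj = np.nonzero(np.triu(np.abs(table.W) > STRONG_COUPLING, k=1))
    pairs = np.column_stack([ii, jj]).astype(np.int64)
    if pairs.size == 0:
        pairs = np.empty((0, 2), dtype=np.int64)
    burn = int(burn_in_fraction * n_sweeps)
    kern = _mc_kernel if _HAVE_NUMBA else _mc_kernel_py
    mean, acc = kern(h.astype(np.float64), table.W.astype(np.float64),
                     pairs, beta, n_sweeps, burn, seed)
    return TitrationResult(populations=np.asarray(mean), method="mc",
                           bias_applied=_bias_dict(table, bias),
                           acceptance_rate=float(acc), n_sweeps=n_sweeps,
                           seed=seed)


# ---------------------------------------------------------------------------
# midpoint-potential search

def titrate(table: SiteEnergyTable, conditions: PhysicalConditions,
            bias: dict[str, float] | float | None,
            sampler: Literal["exact", "mc"], n_sweeps: int = 100_000,
            seed: int = 0) -> TitrationResult:
    if sampler == "exact":
        return enumerate_exact(table, conditions, bias)
    if sampler == "mc":
        return mc_sample(table, conditions, bias, n_sweeps=n_sweeps, seed=seed)
    raise ValueError(f"unknown sampler {sampler!r}")


def find_em(site_id: str, table: SiteEnergyTable, conditions: PhysicalConditions,
            sampler: Literal["exact", "mc"] = "exact",
            bias_range: tuple[float, float] = (-2000.0, 2000.0),
            tol_mv: float = 1.0, n_sweeps: int = 100_000,
            seed: int = 0,
            extra_bias: dict[str, float] | None = None) -> TitrationResult:
    """Redox midpoint potential by bisection on the bias potential.

    Finds the bias (mV) at which the site's reduced population is 1/2 while
    all other sites equilibrate, then reports Em = em_ref + bias*.  The
    population is a decreasing function of the bias under the model's sign
    convention, so bisection over *bias_range* converges to *tol_mv*.
    """
    try:
        k = next(i for i, s in enumerate(table.sites) if s.site_id == site_id)
    except StopIteration:
        raise KeyError(f"no site {site_id!r} in table")
    site = table.sites[k]
    if site.kind != "redox":
        raise ValueError(f"site {site_id} is not a redox site")

    def pop(bias_mv: float) -> tuple[float, TitrationResult]:
        bias = dict(extra_bias or {})
        bias[site_id] = bias_mv
        r = titrate(table, conditions, bias, sampler, n_sweeps=n_sweeps, seed=seed)
        return float(r.populations[k]), r

    lo, hi = bias_range
    p_lo, _ = pop(lo)
    p_hi, _ = pop(hi)
    if not (p_lo >= 0.5 >= p_hi):
        raise RuntimeError(
            f"bias bracket failure for {site_id}: population {p_lo:.3f} at "
            f"{lo:+.0f} mV, {p_hi:.3f} at {hi:+.0f} mV")
    while hi - lo > tol_mv:
        mid = 0.5 * (lo + hi)
        p_mid, _ = pop(mid)
        if p_mid >= 0.5:
            lo = mid
        else:
            hi = mid
    bias_star = 0.5 * (lo + hi)
    p_star, result = pop(bias_star)
    if abs(p_star - 0.5) > 0.01:
        raise RuntimeError(
            f"midpoint condition violated for {site_id}: population "
            f"{p_star:.4f} at bias {bias_star:+.1f} mV")
    result.em = {site_id: site.em_ref + bias_star}
    result.bias_applied[site_id] = bias_star
    return result


def titration_curve(table: SiteEnergyTable, conditions: PhysicalConditions,
                    site_id: str, bias_grid: np.ndarray,
                    sampler: Literal["exact", "mc"] = "exact",
                    n_sweeps: int = 100_000, seed: int = 0) -> np.ndarray:
    """Reduced population of *site_id* at each bias in *bias_grid* (mV)."""
    k = next(i for i, s in enumerate(table.sites) if s.site_id == site_id)
    pops = []
    for b in np.asarray(bias_grid, dtype=float):
        r = titrate(table, conditions, {site_id: float(b)}, sampler,
                    n_sweeps=n_sweeps, seed=seed)
        pops.append(float(r.populations[k]))
    return np.asarray(pops)


def curve_midpoint(bias_grid: np.ndarray, populations: np.ndarray) -> float:
    """Interpolated bias at which a monotone titration curve crosses 1/2."""
    b = np.asarray(bias_grid, dtype=float)
    p = np.asarray(populations, dtype=float)
    if p[0] < 0.5 or p[-1] > 0.5:
        raise ValueError("curve does not bracket the midpoint")
    for i in range(len(b) - 1):
        if p[i] >= 0.5 >= p[i + 1]:
            if p[i] == p[i + 1]:
                return 0.5 * (b[i] + b[i + 1])
            t = (p[i] - 0.5) / (p[i] - p[i + 1])
            return float(b[i] + t * (b[i + 1] - b[i]))
    raise ValueError("no crossing found")
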