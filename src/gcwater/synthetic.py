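"""Synthetic host cages, ligand series, and exact grand-canonical oracles.

The generator builds rigid "cage" hosts in which each designed hydration site
is created by a triad of partial charges (two pseudo-donors, one acceptor
carrying the balancing charge) placed around the requested site position; the
triad charge magnitude is tuned by bisection until a rigid water bound at the
site reaches the requested well depth.  Ligand "compounds" are site sets that
sequentially occlude designed sites with neutral LJ bodies and can add
hydrogen-bond-like polar contacts that strengthen named surviving sites --
the statistical structure of a congeneric series that displaces waters from
a pocket network one by one.

For verification, :func:`grid_grand_partition_oracle` evaluates the grand
partition function of a small box exactly (to quadrature error) by Riemann
sums over a position grid and a fixed orientation set:

    Xi(B) = sum_N e^{B N} Z_N / N!,   Z_N = <e^{-beta U}>_(uniform box)^N,

with the same Adams normalisation as the sampling engine, so titration
curves, occupancy distributions and network binding free energies from the
two routes are directly comparable.  Enumeration is supported for N <= 3.

Because a designed site must out-compete bulk water (mu'_hyd = -6.2 kcal/mol
plus the entropy cost of confinement), stably bound sites need host-water
well depths of roughly -12 to -14 kcal/mol; the presets use that regime, and
the weak-site preset (about -4 kcal/mol) gives a fluctuating, partially
occupied box useful for distribution-level checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from scipy.special import gammaln, logsumexp

from .energy import EnergyParams, switching_factor, water_host_energy
from .model import (
    HostStructure,
    ParticleSite,
    SimulationRegion,
    WaterModel,
    gcmc_box_from_waters,
    rotation_from_axis_angle,
)

__all__ = [
    "LigandSpec",
    "SyntheticSystemSpec",
    "OracleResult",
    "make_cage_host",
    "make_ligand_series",
    "make_region",
    "grid_grand_partition_oracle",
    "planted_trajectory",
    "one_site_cage",
    "two_site_cage",
    "weak_site_cage",
    "network_series",
    "cycle_pair",
    "site_well_depth",
]

# triad construction constants
_TRIAD_CONE_DEG = 55.0
_TRIAD_SIGMA = 2.9
_TRIAD_EPSILON = 0.12
_OCCLUDER_SIGMA = 3.2
_OCCLUDER_EPSILON = 0.15
_CONTACT_DISTANCE = 2.85
_COMPENSATOR_EXTRA = 1.5

# enumeration guards for the oracle
_MAX_STATES = 400_000  # pair-stage single-particle states before pruning
_MAX_Z1_STATES = 6_000_000  # single-particle quadrature (no pair matrix)
_MAX_KEPT = 7500


@dataclass(frozen=True)
class LigandSpec:
    """One compound: which designed sites it occludes, and optional polar
    contacts {site index: charge magnitude in e} to surviving sites."""

    blocked_sites: tuple = ()
    polar_contacts: dict = field(default_factory=dict)


@dataclass
class SyntheticSystemSpec:
    """A toy cavity: designed water sites, their well depths, and a nested
    compound series."""

    site_positions: np.ndarray  # (n, 3), >= 3 A apart
    well_depths: np.ndarray  # (n,), kcal/mol, negative
    ligand_series: list = field(default_factory=list)
    triad_distance: float = 2.8
    seed: int = 0

    def __post_init__(self):
        self.site_positions = np.atleast_2d(np.asarray(self.site_positions, dtype=float))
        self.well_depths = np.atleast_1d(np.asarray(self.well_depths, dtype=float))
        n = len(self.site_positions)
        if not 1 <= n <= 7:
            raise ValueError("between 1 and 7 designed sites supported")
        if len(self.well_depths) != n:
            raise ValueError("need one well depth per site")
        if np.any(self.well_depths >= 0):
            raise ValueError("well depths must be negative (binding sites)")
        if n > 1:
            d = cdist(self.site_positions, self.site_positions)
            np.fill_diagonal(d, np.inf)
            if d.min() < 3.0:
                raise ValueError("designed sites must be >= 3 A apart")
        prev: set = set()
        for lig in self.ligand_series:
            blocked = set(lig.blocked_sites)
            if not blocked <= set(range(n)):
                raise ValueError("occlusion of a nonexistent site")
            if not prev <= blocked:
                raise ValueError("occlusion specs must be nested along the series")
            if set(lig.polar_contacts) & blocked:
                raise ValueError("polar contacts must target surviving sites")
            if not set(lig.polar_contacts) <= set(range(n)):
                raise ValueError("polar contact on a nonexistent site")
            prev = blocked

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)


def _orientation_set(n: int) -> np.ndarray:
    """Deterministic set of n rotation matrices, uniform on SO(3).

    Drawn once from a fixed internal stream; used for orientation scans in
    the cage builder (not for quadrature -- see _orientation_quadrature).
    """
    rng = np.random.default_rng(20240517)
    qs = rng.standard_normal((n, 4))
    qs /= np.linalg.norm(qs, axis=1, keepdims=True)
    w, x, y, z = qs.T
    R = np.empty((n, 3, 3))
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (x * y - w * z)
    R[:, 0, 2] = 2 * (x * z + w * y)
    R[:, 1, 0] = 2 * (x * y + w * z)
    R[:, 1, 1] = 1 - 2 * (x * x + z * z)
    R[:, 1, 2] = 2 * (y * z - w * x)
    R[:, 2, 0] = 2 * (x * z - w * y)
    R[:, 2, 1] = 2 * (y * z + w * x)
    R[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return R


def _orientation_quadrature(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Product quadrature over SO(3) in ZYZ Euler angles.

    Uniform (trapezoid) grids in the periodic angles alpha and gamma --
    spectrally accurate for smooth periodic integrands -- and Gauss-Legendre
    nodes in cos(beta), with Haar weights dR = dalpha d(cos beta) dgamma /
    (8 pi^2).  Returns (rotations, weights) with weights summing to 1; the
    node count is the closest product shape to ``n``.
    """
    n_b = max(2, int(round((n / 4.0) ** (1.0 / 3.0))))
    n_a = n_c = 2 * n_b
    alpha = 2 * np.pi * np.arange(n_a) / n_a
    gamma = 2 * np.pi * np.arange(n_c) / n_c
    x_b, w_b = np.polynomial.legendre.leggauss(n_b)  # cos(beta) in [-1, 1]
    beta = np.arccos(x_b)
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    cg, sg = np.cos(gamma), np.sin(gamma)

    def rz(c, s):
        out = np.zeros((len(c), 3, 3))
        out[:, 0, 0] = c
        out[:, 0, 1] = -s
        out[:, 1, 0] = s
        out[:, 1, 1] = c
        out[:, 2, 2] = 1.0
        return out

    def ry(c, s):
        out = np.zeros((len(c), 3, 3))
        out[:, 0, 0] = c
        out[:, 0, 2] = s
        out[:, 2, 0] = -s
        out[:, 2, 2] = c
        out[:, 1, 1] = 1.0
        return out

    Ra, Rb, Rg = rz(ca, sa), ry(cb, sb), rz(cg, sg)
    R = np.einsum("aij,bjk,ckl->abcil", Ra, Rb, Rg).reshape(-1, 3, 3)
    w = np.einsum("a,b,c->abc", np.full(n_a, 1.0 / n_a), w_b / 2.0, np.full(n_c, 1.0 / n_c))
    return R, w.ravel()


def _frame(axis: np.ndarray):
    a = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    b = np.cross(a, helper)
    b /= np.linalg.norm(b)
    c = np.cross(a, b)
    return a, b, c


def _triad_axis(i: int, positions: np.ndarray) -> np.ndarray:
    """Direction the triad extends from site i: away from the other sites,
    falling back to alternating +/-z for degenerate layouts."""
    fallback = np.array([0.0, 0.0, 1.0 if i % 2 == 0 else -1.0])
    if len(positions) == 1:
        return fallback
    away = positions[i] - np.delete(positions, i, axis=0).mean(axis=0)
    # prefer a direction perpendicular to the cage so triads do not block
    # neighbouring sites; project out the strongest inter-site direction
    if np.linalg.norm(away) < 0.5:
        return fallback
    away /= np.linalg.norm(away)
    perp = fallback - (fallback @ away) * away
    if np.linalg.norm(perp) > 0.3:
        return perp / np.linalg.norm(perp)
    return away


def _triad_sites(center, axis, distance, q, label, polarity: int = 1):
    """Three charged LJ particles around a site.  ``polarity`` +1 gives two
    pseudo-donors and one acceptor; -1 the mirror pattern.  Alternating
    polarity along a chain of sites lets neighbouring bound waters adopt
    hydrogen-bond-compatible orientations (cooperative network)."""
    a, b, c = _frame(axis)
    theta = np.deg2rad(_TRIAD_CONE_DEG)
    out = []
    charges = (polarity * q, polarity * q, -2.0 * polarity * q)
    for j, qq in enumerate(charges):
        phi = 2 * np.pi * j / 3
        u = np.cos(theta) * a + np.sin(theta) * (np.cos(phi) * b + np.sin(phi) * c)
        out.append(
            ParticleSite(
                center + distance * u,
                lj_sigma=_TRIAD_SIGMA,
                lj_epsilon=_TRIAD_EPSILON,
                charge=qq,
                label=f"{label}_p{j}",
            )
        )
    return out


def _minimize_water(
    host: HostStructure,
    start: np.ndarray,
    model: WaterModel,
    params: EnergyParams,
    n_orient: int = 60,
) -> tuple[float, np.ndarray]:
    """Local minimum of the host-water energy near ``start``; returns
    (energy, oxygen position)."""
    rots = _orientation_set(n_orient)
    sites_all = start + np.einsum("sk,njk->nsj", model.site_offsets, rots)
    e0 = np.array(
        [water_host_energy(start, sites_all[k], host, model, params) for k in range(n_orient)]
    )
    best = int(np.argmin(e0))
    R0 = rots[best]

    def f(x):
        o = start + x[:3]
        R = rotation_from_axis_angle(x[3:6], np.linalg.norm(x[3:6])) @ R0 \
            if np.linalg.norm(x[3:6]) > 1e-12 else R0
        s = o + model.site_offsets @ R.T
        e = water_host_energy(o, s, host, model, params)
        return e if np.isfinite(e) else 1e6

    x0 = np.zeros(6)
    simplex = np.vstack([x0] + [x0 + 0.15 * np.eye(6)[k] for k in range(6)])
    res = minimize(
        f, x0, method="Nelder-Mead",
        options={"initial_simplex": simplex, "maxiter": 1200, "xatol": 1e-4, "fatol": 1e-6},
    )
    return float(res.fun), start + res.x[:3]


def site_well_depth(
    host: HostStructure, site: np.ndarray, model=None, params=None
) -> tuple[float, np.ndarray]:
    """Minimised host-water energy near a designed site position."""
    model = model or WaterModel.tip4p()
    params = params or EnergyParams()
    return _minimize_water(host, np.asarray(site, dtype=float), model, params)


def make_cage_host(
    spec: SyntheticSystemSpec,
    model: Optional[WaterModel] = None,
    params: Optional[EnergyParams] = None,
    depth_tolerance: float = 0.2,
) -> HostStructure:
    """Deterministic cage host whose designed sites hit the requested well
    depths (tuned by bisection on the triad charge) and hold a local minimum
    within 0.5 A of each requested position (verified at build time)."""
    model = model or WaterModel.tip4p()
    params = params or EnergyParams()
    positions = spec.site_positions
    charges = []
    for i, (p, target) in enumerate(zip(positions, spec.well_depths)):
        axis = _triad_axis(i, positions)
        polarity = 1  # uniform polarity: alternating fields create off-site minima

        def depth_of(q: float) -> float:
            triad = _triad_sites(p, axis, spec.triad_distance, q, f"site{i}", polarity)
            e, _ = _minimize_water(HostStructure(triad), p, model, params, n_orient=40)
            return e

        lo, hi = 0.0, 2.0
        d_lo = depth_of(lo)
        if target > d_lo:
            raise ValueError(
                f"site {i}: requested depth {target} shallower than the LJ-only cage "
                f"({d_lo:.2f} kcal/mol)"
            )
        if depth_of(hi) > target:
            raise ValueError(f"site {i}: depth {target} out of reach for the triad design")
        q = 0.5 * (lo + hi)
        for _ in range(40):
            q = 0.5 * (lo + hi)
            d = depth_of(q)
            if abs(d - target) <= depth_tolerance:
                break
            if d > target:  # too shallow, need more charge
                lo = q
            else:
                hi = q
        else:
            raise RuntimeError(f"site {i}: bisection did not reach depth {target}")
        charges.append(q)

    def assemble(centers):
        sites = []
        for i, (c, q) in enumerate(zip(centers, charges)):
            axis = _triad_axis(i, positions)
            polarity = 1  # uniform polarity: alternating fields create off-site minima
            sites.extend(_triad_sites(c, axis, spec.triad_distance, q, f"site{i}", polarity))
        return HostStructure(sites, crystal_water_oxygens=positions.copy())

    # cross-talk between neighbouring triads shifts the minima; re-center
    # each triad so the full-host minimum sits on the designed position
    centers = positions.copy()
    host = assemble(centers)
    for _ in range(4):
        minima = np.array([_minimize_water(host, p, model, params)[1] for p in positions])
        drift = minima - positions
        if np.linalg.norm(drift, axis=1).max() <= 0.35:
            break
        centers = centers - drift
        host = assemble(centers)
    # build-time verification: each designed site holds a nearby minimum
    for i, p in enumerate(positions):
        e, pos = _minimize_water(host, p, model, params)
        if np.linalg.norm(pos - p) > 0.5:
            raise RuntimeError(
                f"site {i}: energy minimum drifted {np.linalg.norm(pos - p):.2f} A "
                "from the designed position"
            )
    return host


def make_ligand_series(
    spec: SyntheticSystemSpec,
) -> list[list[ParticleSite]]:
    """Ligand site-sets for each compound in the series.

    Compound k occludes ``blocked_sites`` with neutral LJ bodies at the site
    positions; polar contacts place a negative charge (plus a farther
    compensating positive charge, keeping the compound neutral) pointing at a
    surviving site, strengthening water binding there.
    """
    out = []
    positions = spec.site_positions
    for ci, lig in enumerate(spec.ligand_series):
        sites: list[ParticleSite] = []
        for b in lig.blocked_sites:
            sites.append(
                ParticleSite(
                    positions[b],
                    lj_sigma=_OCCLUDER_SIGMA,
                    lj_epsilon=_OCCLUDER_EPSILON,
                    charge=0.0,
                    label=f"c{ci}_occl{b}",
                )
            )
        for s, qc in lig.polar_contacts.items():
            if lig.blocked_sites:
                ref = positions[list(lig.blocked_sites)]
                nearest = ref[np.argmin(np.linalg.norm(ref - positions[s], axis=1))]
                direction = nearest - positions[s]
            else:
                direction = positions.mean(axis=0) - positions[s]
            nrm = np.linalg.norm(direction)
            direction = direction / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
            contact = positions[s] + _CONTACT_DISTANCE * direction
            compens = positions[s] + (_CONTACT_DISTANCE + _COMPENSATOR_EXTRA) * direction
            # pseudo-donor (+q) facing the bound water's open acceptor side;
            # the far compensating charge keeps the compound neutral
            sites.append(
                ParticleSite(contact, lj_sigma=_TRIAD_SIGMA, lj_epsilon=0.1,
                             charge=+qc, label=f"c{ci}_hb{s}")
            )
            sites.append(
                ParticleSite(compens, lj_sigma=0.0, lj_epsilon=0.0,
                             charge=-qc, label=f"c{ci}_hbx{s}")
            )
        out.append(sites)
    return out


def make_region(
    spec: SyntheticSystemSpec,
    padding: float = 1.0,
    droplet_radius: float = 15.0,
    restraint_k: float = 1.5,
) -> SimulationRegion:
    """GCMC box around the designed sites with the standard 1 A padding."""
    return gcmc_box_from_waters(
        spec.site_positions, padding,
        droplet_center=spec.site_positions.mean(axis=0),
        droplet_radius=droplet_radius, restraint_k=restraint_k,
    )


# ---------------------------------------------------------------------------
# exact grid oracle


@dataclass
class OracleResult:
    """Exact (to quadrature) grand-canonical reference for a small box."""

    b_grid: np.ndarray
    mean_n: np.ndarray  # exact <N>(B) on b_grid
    ln_xi: np.ndarray  # ln Xi(B) on b_grid
    log_z: np.ndarray  # ln Z_N for N = 0..max_n (Z_0 = 1)
    max_n: int
    n_states_total: int
    n_kept: int
    spatial_step: float
    n_orientations: int
    kT: float

    def _log_terms(self, b: float) -> np.ndarray:
        n = np.arange(self.max_n + 1)
        return b * n + self.log_z - gammaln(n + 1)

    def ln_xi_at(self, b: float) -> float:
        return float(logsumexp(self._log_terms(b)))

    def mean_n_at(self, b: float) -> float:
        t = self._log_terms(b)
        p = np.exp(t - logsumexp(t))
        return float(p @ np.arange(self.max_n + 1))

    def occupancy_distribution(self, b: float) -> np.ndarray:
        """Exact P(N), N = 0..max_n, at chemical potential b."""
        t = self._log_terms(b)
        return np.exp(t - logsumexp(t))

    def network_dg(self, b_equil: float, target_n: Optional[int] = None) -> float:
        """Exact network binding free energy relative to bulk, kcal/mol.

        With ``target_n`` unset: -kT ln Xi(B_equil) (empty-limit reference),
        the quantity GCI estimates from the titration curve.  With
        ``target_n`` = n: -kT ln(Z_n/n!) - n kT B_equil, the fixed-size
        network free energy used by cycle legs.
        """
        if target_n is None:
            return -self.kT * self.ln_xi_at(b_equil)
        if not 0 <= target_n <= self.max_n:
            raise ValueError("target_n exceeds the enumerated maximum")
        n = int(target_n)
        return -self.kT * float(self.log_z[n] - gammaln(n + 1)) - n * self.kT * b_equil


def _host_energy_orientations(p, offsets_lab, host, model, params):
    """Host-water energy for one oxygen position and all orientations."""
    if host is None:
        return np.zeros(len(offsets_lab))
    d = host.positions - p
    r2 = np.einsum("ij,ij->i", d, d)
    mask = r2 < params.cutoff**2
    n_or = len(offsets_lab)
    if not np.any(mask):
        return np.zeros(n_or)
    r = np.sqrt(r2[mask])
    sw = switching_factor(r, params)
    sigma = 0.5 * (model.oxygen_lj_sigma + host.lj_sigma[mask])
    eps = np.sqrt(model.oxygen_lj_epsilon * host.lj_epsilon[mask])
    with np.errstate(divide="ignore", over="ignore"):
        x = (sigma / r) ** 6
    lj = np.where(eps > 0, 4.0 * eps * (x * x - x), 0.0)
    sites = p + offsets_lab  # (n_or, S, 3)
    dd = host.positions[mask][None, :, None, :] - sites[:, None, :, :]
    dist = np.sqrt(np.einsum("nmsk,nmsk->nms", dd, dd))
    dist = np.maximum(dist, 1e-12)
    qq = host.charges[mask][:, None] * model.site_charges[None, :]
    coul = params.coulomb_constant * (qq[None] / dist).sum(axis=2)  # (n_or, m)
    e = (sw[None, :] * (lj[None, :] + coul)).sum(axis=1)
    e[np.any(dist < 0.05, axis=(1, 2))] = np.inf
    return e


def _sq_dist(A, B):
    """Squared distance matrix via GEMM (fast for large S)."""
    d2 = (
        np.einsum("ik,ik->i", A, A)[:, None]
        + np.einsum("ik,ik->i", B, B)[None, :]
        - 2.0 * (A @ B.T)
    )
    return np.maximum(d2, 0.0)


def _pair_matrix(pos, sites, model, params):
    """Water-water pair energies between all kept single-particle states."""
    D2 = _sq_dist(pos, pos)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        D = np.sqrt(D2)
        sw = switching_factor(D, params)  # molecular O-O switching
        x = (model.oxygen_lj_sigma**2 / D2) ** 3
        lj = 4.0 * model.oxygen_lj_epsilon * (x * x - x)
        coul = np.zeros_like(D)
        overlap = D2 < 0.0025  # includes the state-with-itself diagonal
        q = model.site_charges
        contig = [np.ascontiguousarray(sites[:, a, :]) for a in range(model.n_sites)]
        for a in range(model.n_sites):
            for b in range(model.n_sites):
                if q[a] == 0.0 or q[b] == 0.0:
                    continue
                d2 = _sq_dist(contig[a], contig[b])
                overlap |= d2 < 0.0025
                np.sqrt(d2, out=d2)
                coul += (params.coulomb_constant * q[a] * q[b]) / d2
        w = sw * (lj + coul)
    w[overlap] = np.inf
    np.nan_to_num(w, copy=False, nan=np.inf, posinf=np.inf, neginf=-np.inf)
    return w


def _box_grid(region, step):
    """Midpoint grid whose cells tile the box exactly: the requested step is
    snapped per axis so an integer number of cells covers each edge.
    Returns (points, per-axis cell sizes)."""
    axes, steps = [], np.empty(3)
    for k, (lo, hi) in enumerate(zip(region.box_min, region.box_max)):
        n = max(1, int(np.ceil((hi - lo) / step)))
        h = (hi - lo) / n
        axes.append(lo + (np.arange(n) + 0.5) * h)
        steps[k] = h
    return np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T, steps


def _host_energy_block(P, offsets_lab, host, model, params):
    """Host-water energies for a block of oxygen positions x all
    orientations; returns (len(P), n_or)."""
    n_or = len(offsets_lab)
    if host is None:
        return np.zeros((len(P), n_or))
    d = P[:, None, :] - host.positions[None, :, :]  # (B, M, 3)
    r2 = np.einsum("bmk,bmk->bm", d, d)
    r = np.sqrt(r2)
    within = r < params.cutoff
    sw = np.where(within, switching_factor(r, params), 0.0)
    sigma = 0.5 * (model.oxygen_lj_sigma + host.lj_sigma)[None, :]
    eps = np.sqrt(model.oxygen_lj_epsilon * host.lj_epsilon)[None, :]
    with np.errstate(divide="ignore", over="ignore"):
        x = (sigma / np.maximum(r, 1e-12)) ** 6
    lj = np.where(eps > 0, 4.0 * eps * (x * x - x), 0.0)
    sites = P[:, None, None, :] + offsets_lab[None, :, :, :]  # (B, n_or, S, 3)
    dd = host.positions[None, None, :, None, :] - sites[:, :, None, :, :]
    dist = np.sqrt(np.einsum("bnmsk,bnmsk->bnms", dd, dd))
    qq = host.charges[:, None] * model.site_charges[None, :]  # (M, S)
    coul = (qq[None, None] / np.maximum(dist, 1e-12)).sum(axis=3)  # (B, n_or, M)
    coul *= params.coulomb_constant
    e = (sw[:, None, :] * (lj[:, None, :] + coul)).sum(axis=2)  # (B, n_or)
    bad = np.any(dist < 0.05, axis=(2, 3)) | np.any(within & (r < 0.05), axis=1)[:, None]
    e[bad] = np.inf
    return e


def _single_particle_u(pts, rots, host, model, params, block: int = 48):
    offsets_lab = np.einsum("sk,njk->nsj", model.site_offsets, rots)
    u = np.empty((len(pts), len(rots)))
    # block size keeps the (B, n_or, M, S, 3) intermediate below ~100 MB
    block = max(1, min(block, int(4e6 / max(1, len(rots) * (len(host.positions) if host else 1)))))
    for lo in range(0, len(pts), block):
        u[lo : lo + block] = _host_energy_block(pts[lo : lo + block], offsets_lab, host, model, params)
    return u, offsets_lab


def grid_grand_partition_oracle(
    host: Optional[HostStructure],
    region: SimulationRegion,
    b_grid: Sequence[float],
    max_n: int = 2,
    spatial_step: float = 0.35,
    n_orientations: int = 64,
    model: Optional[WaterModel] = None,
    params: Optional[EnergyParams] = None,
    keep_window_kt: float = 15.0,
    z1_refine: int = 3,
    z1_orientation_factor: int = 8,
    basin_window_kt: float = 10.0,
) -> OracleResult:
    """Exact grand partition function of the GCMC box by grid enumeration.

    Riemann (midpoint) sums over a position grid x a deterministic rotation
    set give the configurational integrals Z_N for N = 0..max_n (<= 3); the
    normalisation matches the sampling engine, so <N>(B), P(N) and network
    free energies are directly comparable.

    The Boltzmann factor of a hydrogen-bonded site is sharply peaked in both
    position and orientation, so the quadrature is adaptive: cells of the
    base grid whose best orientation lies within ``basin_window_kt`` kT of
    the global minimum are re-evaluated on a ``z1_refine``-times finer
    sub-grid with ``z1_orientation_factor`` more orientations, and each
    coarse cell's Boltzmann weight is rescaled by the refined/coarse ratio.
    The same per-cell factors rescale the pair/triple sums (valid because
    water-water interactions vary on the inter-site length scale, much
    coarser than a cell).  States more than ``keep_window_kt`` kT above the
    minimum are pruned from pair enumeration (negligible weight at every
    relevant B).  Convergence is checked by re-running refined, not assumed.
    """
    if max_n > 3:
        raise ValueError("enumeration supported for max_n <= 3")
    model = model or WaterModel.tip4p()
    params = params or EnergyParams()
    beta = params.beta
    b_grid = np.asarray(sorted(float(b) for b in b_grid))

    # coarse pass over the whole box
    pts, cell_steps = _box_grid(region, spatial_step)
    rots, w_or = _orientation_quadrature(n_orientations)
    n_or = len(rots)
    n_states = len(pts) * n_or
    if n_states > _MAX_STATES:
        raise ValueError(
            f"{n_states} single-particle states exceeds the enumeration guard; "
            "coarsen the grid or shrink the box"
        )
    u2d, offsets_lab = _single_particle_u(pts, rots, host, model, params)
    cell_min = u2d.min(axis=1)
    umin = float(cell_min.min())

    # per-cell refinement factors for basin cells (finer positions and a
    # denser orientation quadrature where the Boltzmann weight concentrates)
    cell_factor = np.ones(len(pts))
    refine = max(int(z1_refine), 1)
    n_or_f = n_or * max(int(z1_orientation_factor), 1)
    basin = np.flatnonzero(cell_min < umin + basin_window_kt * params.kT)
    if len(basin) and (refine > 1 or n_or_f > n_or):
        subs = [(np.arange(refine) - (refine - 1) / 2.0) * (h / refine) for h in cell_steps]
        sub_offsets = np.array(np.meshgrid(*subs, indexing="ij")).reshape(3, -1).T
        while len(basin) * len(sub_offsets) * n_or_f > _MAX_Z1_STATES and n_or_f > n_or:
            n_or_f //= 2
        rots_f, w_or_f = _orientation_quadrature(n_or_f)
        coarse_cell = np.exp(-beta * (u2d[basin] - umin)) @ w_or
        pts_f = (pts[basin][:, None, :] + sub_offsets[None, :, :]).reshape(-1, 3)
        u_f, _ = _single_particle_u(pts_f, rots_f, host, model, params)
        fine_cell = (
            np.exp(-beta * (u_f - umin)).reshape(len(basin), len(sub_offsets), len(rots_f))
            @ w_or_f
        ).mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(coarse_cell > 0, fine_cell / coarse_cell, 1.0)
        cell_factor[basin] = f

    log_z = np.full(max_n + 1, -np.inf)
    log_z[0] = 0.0
    cell_mean = (np.exp(-beta * (u2d - umin)) @ w_or) * cell_factor
    if max_n >= 1:
        log_z[1] = -beta * umin + np.log(cell_mean.mean())

    # pruned state set for pair/triple enumeration; each state carries its
    # full quadrature weight (cell volume fraction x orientation weight x
    # refinement factor), so the weighted sums are the Riemann integrals
    u = u2d.ravel()
    keep = u < umin + keep_window_kt * params.kT
    if max_n >= 2 and keep.sum() > _MAX_KEPT:
        # Boltzmann truncation: retain the _MAX_KEPT lowest-energy states;
        # only an error if that cuts into the thermally relevant window
        order = np.argsort(u, kind="stable")[:_MAX_KEPT]
        cut_u = float(u[order[-1]])
        if cut_u < umin + 6.0 * params.kT:
            raise ValueError(
                f"{int(keep.sum())} kept states exceeds the pair-enumeration "
                "guard inside the thermal window; coarsen the grid or shrink the box"
            )
        keep = np.zeros(len(u), dtype=bool)
        keep[order] = True
    omega = (np.tile(w_or, len(pts)) * np.repeat(cell_factor, n_or))[keep] / len(pts)
    a = np.exp(-beta * (u[keep] - umin)) * omega
    kept_pos = np.repeat(pts, n_or, axis=0)[keep]
    kept_sites = kept_pos[:, None, :] + np.tile(offsets_lab, (len(pts), 1, 1))[keep]
    if max_n >= 2:
        w = _pair_matrix(kept_pos, kept_sites, model, params)
        P = np.exp(-beta * np.where(np.isfinite(w), w, np.inf))
        P[~np.isfinite(w)] = 0.0
        z2_ord = float(a @ (P @ a))
        if z2_ord > 0:
            log_z[2] = -2 * beta * umin + np.log(z2_ord)
    if max_n >= 3:
        T = (P * a[None, :]) @ P.T
        z3_ord = float(np.einsum("i,ij,ij,j->", a, P, T, a))
        if z3_ord > 0:
            log_z[3] = -3 * beta * umin + np.log(z3_ord)

    result = OracleResult(
        b_grid=b_grid,
        mean_n=np.zeros(len(b_grid)),
        ln_xi=np.zeros(len(b_grid)),
        log_z=log_z,
        max_n=max_n,
        n_states_total=n_states,
        n_kept=int(keep.sum()),
        spatial_step=spatial_step,
        n_orientations=n_orientations,
        kT=params.kT,
    )
    result.mean_n = np.array([result.mean_n_at(b) for b in b_grid])
    result.ln_xi = np.array([result.ln_xi_at(b) for b in b_grid])
    return result


# ---------------------------------------------------------------------------
# planted fixtures and presets


def planted_trajectory(
    sites: np.ndarray,
    occupancies: Sequence[float],
    jitter: float,
    n_frames: int,
    seed: int,
) -> list[np.ndarray]:
    """Per-frame oxygen sets: each site appears independently per frame with
    its stated probability, displaced by isotropic Gaussian jitter."""
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    occ = np.asarray(occupancies, dtype=float)
    if np.any((occ < 0) | (occ > 1)):
        raise ValueError("occupancies must lie in [0, 1]")
    if len(occ) != len(sites):
        raise ValueError("need one occupancy per site")
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        present = rng.random(len(sites)) < occ
        noise = rng.normal(0.0, jitter, size=sites.shape) if jitter > 0 else 0.0
        frames.append((sites + noise)[present])
    return frames


def one_site_cage(seed: int = 0) -> SyntheticSystemSpec:
    """Single deep site: the minimal GCI-vs-oracle benchmark."""
    return SyntheticSystemSpec(
        site_positions=[[0.0, 0.0, 0.0]],
        well_depths=[-13.0],
        seed=seed,
    )


def two_site_cage(seed: int = 0) -> SyntheticSystemSpec:
    """Two cooperating sites with distinct depths (sequential filling)."""
    return SyntheticSystemSpec(
        site_positions=[[0.0, 0.0, 0.0], [4.2, 0.0, 0.0]],
        well_depths=[-13.5, -12.5],
        seed=seed,
    )


def weak_site_cage(seed: int = 0) -> SyntheticSystemSpec:
    """A weak single site: strongly fluctuating N, for distribution tests."""
    return SyntheticSystemSpec(
        site_positions=[[0.0, 0.0, 0.0]],
        well_depths=[-4.0],
        seed=seed,
    )


def cycle_pair(seed: int = 0, contact_charge: float = 0.3) -> SyntheticSystemSpec:
    """Two sites and a compound pair for the standard free-energy cycle.

    Site 0 is shallow (unoccupied at equilibrium on its own), site 1 deep, so
    the retained water's basin is unambiguous in every lambda window and the
    cycle legs sample one consistent model.  Compound A is the null ligand;
    compound B occludes site 0 and adds a polar contact to the surviving
    site 1.
    """
    return SyntheticSystemSpec(
        site_positions=[[0.0, 0.0, 0.0], [4.2, 0.0, 0.0]],
        well_depths=[-10.0, -13.0],
        ligand_series=[
            LigandSpec(),
            LigandSpec(blocked_sites=(0,), polar_contacts={1: contact_charge}),
        ],
        seed=seed,
    )


def network_series(seed: int = 0, contact_charge: float = 0.6) -> SyntheticSystemSpec:
    """Three-site network with a four-compound occlusion series.

    The arc mirrors a water-displacement ligand series: compound 1 leaves the
    network intact; compound 2 occludes the first site (destabilising the
    remaining pair); compound 3 occludes two sites but adds a polar contact
    to the survivor (net stabilisation); compound 4 occludes everything.
    """
    return SyntheticSystemSpec(
        site_positions=[[0.0, 0.0, 0.0], [5.0, 0.0, 0.0], [10.0, 0.0, 0.0]],
        well_depths=[-13.5, -10.0, -12.0],
        ligand_series=[
            LigandSpec(),
            LigandSpec(blocked_sites=(0,)),
            LigandSpec(blocked_sites=(0, 1), polar_contacts={2: contact_charge}),
            LigandSpec(blocked_sites=(0, 1, 2)),
        ],
        seed=seed,
    )
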