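"""Nonbonded energetics: LJ + Coulomb with a switched cutoff, and the droplet
restraint.

Conventions
-----------
* Lorentz-Berthelot combination rules (sigma arithmetic, epsilon geometric).
* The cutoff acts per molecule pair on the oxygen-oxygen (water-water) or
  oxygen-site (host-water) distance, so all sites of a water switch together
  and a dipole is never split across the cutoff.
* Switching: CHARMM-style energy switching over the last ``switch_width`` A,
  S(r) = (rc^2 - r^2)^2 (rc^2 + 2 r^2 - 3 ron^2) / (rc^2 - ron^2)^3,
  C1-continuous at both joins.
* Droplet restraint: half-harmonic U = k/2 (d - R)^2 outside the sphere.
* Energies in kcal/mol, distances in A, charges in e.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import HostStructure, ParticleSite, SimulationRegion, WaterModel, WaterMolecule

__all__ = [
    "KB",
    "COULOMB_CONSTANT",
    "EnergyParams",
    "switching_factor",
    "pair_energy",
    "restraint_energy",
    "water_host_energy",
    "water_water_energy",
    "total_energy",
]

#: Boltzmann constant, kcal mol^-1 K^-1
KB = 0.0019872041
#: Coulomb prefactor, kcal A mol^-1 e^-2
COULOMB_CONSTANT = 332.0637

# site-site separations below this (A) are treated as hard overlaps (+inf)
_OVERLAP_GUARD = 0.05


@dataclass(frozen=True)
class EnergyParams:
    """Global nonbonded parameters."""

    cutoff: float = 10.0
    switch_width: float = 0.5
    coulomb_constant: float = COULOMB_CONSTANT
    temperature: float = 298.0

    def __post_init__(self):
        if not (0 < self.switch_width < self.cutoff):
            raise ValueError("require 0 < switch_width < cutoff")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kT(self) -> float:
        return KB * self.temperature

    @property
    def beta(self) -> float:
        return 1.0 / self.kT


def switching_factor(r, params: EnergyParams):
    """Energy-switching factor in [0, 1]; scalar or array ``r``."""
    r = np.asarray(r, dtype=float)
    rc = params.cutoff
    ron = rc - params.switch_width
    rc2, ron2, r2 = rc * rc, ron * ron, r * r
    mid = (rc2 - r2) ** 2 * (rc2 + 2 * r2 - 3 * ron2) / (rc2 - ron2) ** 3
    out = np.where(r <= ron, 1.0, np.where(r >= rc, 0.0, mid))
    return float(out) if out.ndim == 0 else out


def _lj_energy(eps, sigma, r):
    """4 eps [(s/r)^12 - (s/r)^6]; r = 0 yields +inf."""
    with np.errstate(divide="ignore", over="ignore"):
        x = (sigma / r) ** 6
    return 4.0 * eps * (x * x - x)


def pair_energy(site_a: ParticleSite, site_b: ParticleSite, params: EnergyParams) -> float:
    """Switched LJ + Coulomb energy between two single sites."""
    r = float(np.linalg.norm(site_a.position - site_b.position))
    if r == 0.0:
        raise ValueError("coincident sites (r = 0) in a non-softcore potential")
    if r >= params.cutoff:
        return 0.0
    sigma = 0.5 * (site_a.lj_sigma + site_b.lj_sigma)
    eps = np.sqrt(site_a.lj_epsilon * site_b.lj_epsilon)
    e = _lj_energy(eps, sigma, r) if eps > 0 else 0.0
    e += params.coulomb_constant * site_a.charge * site_b.charge / r
    return float(e * switching_factor(r, params))


def restraint_energy(water, region: SimulationRegion) -> float:
    """Half-harmonic droplet restraint on the water's oxygen."""
    o = water.oxygen_position if isinstance(water, WaterMolecule) else np.asarray(water, float)
    d = float(np.linalg.norm(o - region.droplet_center))
    x = d - region.droplet_radius
    return 0.5 * region.restraint_k * x * x if x > 0 else 0.0


def water_host_energy(
    o_pos: np.ndarray,
    water_sites: np.ndarray,
    host: HostStructure,
    model: WaterModel,
    params: EnergyParams,
) -> float:
    """Interaction of one water (oxygen at ``o_pos``, lab-frame ``water_sites``)
    with every host site, with per-host-site molecular switching on the
    oxygen-site distance."""
    d = host.positions - o_pos
    r2 = np.einsum("ij,ij->i", d, d)
    mask = r2 < params.cutoff**2
    if not np.any(mask):
        return 0.0
    r = np.sqrt(r2[mask])
    sw = switching_factor(r, params)
    sigma = 0.5 * (model.oxygen_lj_sigma + host.lj_sigma[mask])
    eps = np.sqrt(model.oxygen_lj_epsilon * host.lj_epsilon[mask])
    lj = np.where(eps > 0, _lj_energy(eps, sigma, np.where(r > 0, r, np.nan)), 0.0)
    if np.any(r < _OVERLAP_GUARD):
        return np.inf
    # all water sites vs the in-range host sites
    dd = host.positions[mask][:, None, :] - water_sites[None, :, :]
    dist = np.sqrt(np.einsum("ijk,ijk->ij", dd, dd))
    if np.min(dist) < _OVERLAP_GUARD:
        return np.inf
    qq = host.charges[mask][:, None] * model.site_charges[None, :]
    coul = params.coulomb_constant * (qq / dist).sum(axis=1)
    return float(np.sum(sw * (lj + coul)))


def water_water_energy(
    o_pos: np.ndarray,
    water_sites: np.ndarray,
    other_oxygens: np.ndarray,
    other_sites: np.ndarray,
    model: WaterModel,
    params: EnergyParams,
) -> float:
    """Interaction of one water with ``n`` others (vectorised), molecular
    cutoff/switching on the oxygen-oxygen distance."""
    if len(other_oxygens) == 0:
        return 0.0
    d = other_oxygens - o_pos
    r2 = np.einsum("ij,ij->i", d, d)
    mask = r2 < params.cutoff**2
    if not np.any(mask):
        return 0.0
    r = np.sqrt(r2[mask])
    if np.any(r < _OVERLAP_GUARD):
        return np.inf
    sw = switching_factor(r, params)
    lj = _lj_energy(model.oxygen_lj_epsilon, model.oxygen_lj_sigma, r)
    dd = other_sites[mask][:, :, None, :] - water_sites[None, None, :, :]
    dist = np.sqrt(np.einsum("nijk,nijk->nij", dd, dd))
    if np.min(dist) < _OVERLAP_GUARD:
        return np.inf
    qq = np.outer(model.site_charges, model.site_charges)
    coul = params.coulomb_constant * (qq[None] / dist).sum(axis=(1, 2))
    return float(np.sum(sw * (lj + coul)))


def single_water_energy(
    i: int,
    oxygens: np.ndarray,
    sites: np.ndarray,
    host: HostStructure | None,
    model: WaterModel,
    params: EnergyParams,
    region: SimulationRegion,
) -> float:
    """Total interaction of water ``i`` with host, all other waters and the
    droplet restraint (the quantity entering insertion/deletion moves)."""
    others = np.delete(np.arange(len(oxygens)), i)
    e = 0.0
    if host is not None:
        e += water_host_energy(oxygens[i], sites[i], host, model, params)
        if not np.isfinite(e):
            return np.inf
    e += water_water_energy(oxygens[i], sites[i], oxygens[others], sites[others], model, params)
    if not np.isfinite(e):
        return np.inf
    return e + restraint_energy(oxygens[i], region)


def trial_water_energy(
    o_pos: np.ndarray,
    water_sites: np.ndarray,
    oxygens: np.ndarray,
    sites: np.ndarray,
    host: HostStructure | None,
    model: WaterModel,
    params: EnergyParams,
    region: SimulationRegion,
) -> float:
    """Interaction energy a trial water would have with the current system."""
    e = 0.0
    if host is not None:
        e = water_host_energy(o_pos, water_sites, host, model, params)
        if not np.isfinite(e):
            return np.inf
    if len(oxygens):
        e += water_water_energy(o_pos, water_sites, oxygens, sites, model, params)
        if not np.isfinite(e):
            return np.inf
    return e + restraint_energy(o_pos, region)


def total_energy(
    oxygens: np.ndarray,
    sites: np.ndarray,
    host: HostStructure | None,
    model: WaterModel,
    params: EnergyParams,
    region: SimulationRegion,
) -> float:
    """Full system energy: host-water + unique water-water pairs + restraints.

    The host's internal energy is a constant (rigid host) and is excluded.
    """
    n = len(oxygens)
    e = 0.0
    for i in range(n):
        if host is not None:
            e += water_host_energy(oxygens[i], sites[i], host, model, params)
        e += restraint_energy(oxygens[i], region)
        if i + 1 < n:
            e += water_water_energy(
                oxygens[i], sites[i], oxygens[i + 1 :], sites[i + 1 :], model, params
            )
        if not np.isfinite(e):
            return np.inf
    return float(e)
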