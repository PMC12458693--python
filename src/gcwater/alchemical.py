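"""Dual-topology alchemical transformations with softcore nonbonded scaling.

Both end-state ligands are present throughout; the environment couples to
ligand B with weight lambda and to ligand A with weight (1 - lambda), each
through softcore LJ/Coulomb forms that stay finite at zero separation for
partially decoupled sites:

    U_LJ  = 4 eps lam [ 1/(d(1-lam) + (r/sig)^6)^2 - 1/(d(1-lam) + (r/sig)^6) ]
    U_C   = C q_a q_b lam / sqrt(d_c (1-lam) + r^2)

with softcore parameters d (``delta``, LJ) and d_c (``delta_c``, Coulomb).
At lam = 1 both reduce to the plain switched potentials; at lam = 0 they
vanish identically.  Ligand A-B cross interactions are excluded; a zero-rest
harmonic "dummy bond" between the two centers of geometry keeps a decoupled
ligand from drifting, and rigid-body ligand moves translate/rotate both
copies identically.

Sampling is canonical (fixed water count) per lambda window with replica
exchange between adjacent windows; at every sample the reduced potential is
evaluated at all windows, giving the input matrix for the MBAR estimator.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .energy import (
    EnergyParams,
    restraint_energy,
    switching_factor,
    total_energy,
    trial_water_energy,
    single_water_energy,
)
from .estimators import mbar_free_energy
from .model import (
    HostStructure,
    ParticleSite,
    SimulationRegion,
    WaterModel,
    random_rotation,
    rotation_from_axis_angle,
)

__all__ = [
    "SoftcoreParams",
    "softcore_pair_energy",
    "DualTopologySystem",
    "AlchemicalConfig",
    "AlchemicalSchedule",
    "AlchemicalLeg",
    "dual_topology_energy",
    "run_alchemical_leg",
    "estimate_leg",
    "run_alchemical_repeats",
]


@dataclass(frozen=True)
class SoftcoreParams:
    """Softcore shape parameters (per transformation)."""

    delta: float = 0.2
    delta_c: float = 2.0

    def __post_init__(self):
        if self.delta < 0 or self.delta_c < 0:
            raise ValueError("softcore parameters must be >= 0")


def _site_arrays(sites: Sequence[ParticleSite]):
    pos = np.array([s.position for s in sites]).reshape(-1, 3)
    sig = np.array([s.lj_sigma for s in sites])
    eps = np.array([s.lj_epsilon for s in sites])
    q = np.array([s.charge for s in sites])
    return pos, sig, eps, q


def _softcore_group_energy(
    lig_pos, lig_sig, lig_eps, lig_q,
    env_pos, env_sig, env_eps, env_q,
    lam_scales, sc: SoftcoreParams, params: EnergyParams,
) -> np.ndarray:
    """Softcore interaction of a ligand site group with environment sites,
    for an array of coupling weights ``lam_scales``; returns one energy per
    weight.  Cutoff/switching act per site pair."""
    lam_scales = np.atleast_1d(np.asarray(lam_scales, dtype=float))
    out = np.zeros(len(lam_scales))
    if len(lig_pos) == 0 or len(env_pos) == 0:
        return out
    r = cdist(env_pos, lig_pos)
    mask = r < params.cutoff
    if not np.any(mask):
        return out
    r = r[mask]
    sw = switching_factor(r, params)
    sigma = 0.5 * (env_sig[:, None] + lig_sig[None, :])[mask]
    eps = np.sqrt(np.outer(env_eps, lig_eps))[mask]
    qq = np.outer(env_q, lig_q)[mask]
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        x6 = np.where(eps > 0, (r / np.where(sigma > 0, sigma, 1.0)) ** 6, np.inf)
    r2 = r * r
    for i, lam in enumerate(lam_scales):
        if lam == 0.0:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = sc.delta * (1.0 - lam) + x6
            inv = 1.0 / denom
            lj = 4.0 * eps * lam * (inv * inv - inv)
            coul = params.coulomb_constant * qq * lam / np.sqrt(sc.delta_c * (1.0 - lam) + r2)
        e = sw * (np.nan_to_num(lj, nan=np.inf, posinf=np.inf) + coul)
        out[i] = e.sum()
    return out


def softcore_pair_energy(
    site_a: ParticleSite,
    site_b: ParticleSite,
    lam_scale: float,
    sc: SoftcoreParams,
    params: EnergyParams,
) -> float:
    """Softcore LJ + Coulomb between two sites at coupling ``lam_scale``."""
    if not 0.0 <= lam_scale <= 1.0:
        raise ValueError("lam_scale must lie in [0, 1]")
    la_pos, la_sig, la_eps, la_q = _site_arrays([site_a])
    lb_pos, lb_sig, lb_eps, lb_q = _site_arrays([site_b])
    return float(
        _softcore_group_energy(
            la_pos, la_sig, la_eps, la_q, lb_pos, lb_sig, lb_eps, lb_q,
            [lam_scale], sc, params,
        )[0]
    )


@dataclass
class DualTopologySystem:
    """A dual-topology transformation in one environment.

    ``environment`` tags the leg: "waters-present", "waters-absent" or "bulk"
    (bulk legs have no host).  Ligand sites are given in their reference lab
    poses; the configuration tracks their current coordinates.
    """

    ligand_a: list
    ligand_b: list
    region: SimulationRegion
    host: Optional[HostStructure] = None
    softcore: SoftcoreParams = field(default_factory=SoftcoreParams)
    dummy_k: float = 10.0  # kcal/mol/A^2, zero-rest-length COG-COG bond
    environment: str = "waters-present"
    model: WaterModel = field(default_factory=WaterModel.tip4p)
    params: EnergyParams = field(default_factory=EnergyParams)

    def __post_init__(self):
        if self.environment not in ("waters-present", "waters-absent", "bulk"):
            raise ValueError(f"unknown environment tag {self.environment!r}")
        if self.environment == "bulk" and self.host is not None:
            raise ValueError("bulk legs must not carry a host")


@dataclass
class AlchemicalConfig:
    """Current coordinates of a dual-topology simulation."""

    lig_a_pos: np.ndarray
    lig_b_pos: np.ndarray
    water_oxygens: np.ndarray
    water_rotations: np.ndarray
    water_sites: np.ndarray

    @classmethod
    def initial(cls, system: DualTopologySystem, water_oxygens=None, water_rotations=None):
        la = np.array([s.position for s in system.ligand_a]).reshape(-1, 3)
        lb = np.array([s.position for s in system.ligand_b]).reshape(-1, 3)
        if water_oxygens is None:
            o = np.zeros((0, 3))
            r = np.zeros((0, 3, 3))
        else:
            o = np.atleast_2d(np.asarray(water_oxygens, dtype=float))
            if water_rotations is None:
                r = np.tile(np.eye(3), (len(o), 1, 1))
            else:
                r = np.asarray(water_rotations, dtype=float).reshape(len(o), 3, 3)
        sites = o[:, None, :] + np.einsum("sk,njk->nsj", system.model.site_offsets, r)
        return cls(la, lb, o, r, sites)


def _water_env_arrays(system: DualTopologySystem, config: AlchemicalConfig):
    """Flatten water sites into environment site arrays."""
    n = len(config.water_oxygens)
    s = system.model.n_sites
    pos = config.water_sites.reshape(n * s, 3) if n else np.zeros((0, 3))
    sig = np.tile(np.r_[system.model.oxygen_lj_sigma, np.zeros(s - 1)], n)
    eps = np.tile(np.r_[system.model.oxygen_lj_epsilon, np.zeros(s - 1)], n)
    q = np.tile(system.model.site_charges, n)
    return pos, sig, eps, q


def _env_arrays(system: DualTopologySystem, config: AlchemicalConfig):
    wpos, wsig, weps, wq = _water_env_arrays(system, config)
    if system.host is None:
        return wpos, wsig, weps, wq
    h = system.host
    return (
        np.vstack([h.positions, wpos]),
        np.r_[h.lj_sigma, wsig],
        np.r_[h.lj_epsilon, weps],
        np.r_[h.charges, wq],
    )


def ligand_environment_energy(
    system: DualTopologySystem, config: AlchemicalConfig, lam_values
) -> np.ndarray:
    """The lambda-dependent part of the energy, for an array of lambdas:
    env-B softcore at weight lam plus env-A softcore at weight (1 - lam)."""
    lam = np.atleast_1d(np.asarray(lam_values, dtype=float))
    env = _env_arrays(system, config)
    _, asig, aeps, aq = _site_arrays(system.ligand_a)
    _, bsig, beps, bq = _site_arrays(system.ligand_b)
    e_b = _softcore_group_energy(config.lig_b_pos, bsig, beps, bq, *env,
                                 lam, system.softcore, system.params)
    e_a = _softcore_group_energy(config.lig_a_pos, asig, aeps, aq, *env,
                                 1.0 - lam, system.softcore, system.params)
    return e_b + e_a


def _dummy_bond_energy(system: DualTopologySystem, config: AlchemicalConfig) -> float:
    if len(config.lig_a_pos) == 0 or len(config.lig_b_pos) == 0:
        return 0.0  # a null end state has no center of geometry to tether
    d = config.lig_a_pos.mean(axis=0) - config.lig_b_pos.mean(axis=0)
    return 0.5 * system.dummy_k * float(d @ d)


def _water_system_energy(system: DualTopologySystem, config: AlchemicalConfig) -> float:
    return total_energy(
        config.water_oxygens, config.water_sites, system.host,
        system.model, system.params, system.region,
    )


def dual_topology_energy(
    system: DualTopologySystem, config: AlchemicalConfig, lam: float
) -> float:
    """Total configuration energy at coupling ``lam`` (host internal and
    intra-ligand terms are rigid constants and excluded; A-B cross
    interactions are excluded by construction)."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    e = float(ligand_environment_energy(system, config, [lam])[0])
    e += _water_system_energy(system, config)
    e += _dummy_bond_energy(system, config)
    return e


@dataclass
class AlchemicalSchedule:
    """Canonical move mix and phase lengths for one lambda window."""

    n_equil: int = 1000
    n_production: int = 5000
    sampling_interval: int = 50
    p_ligand: float = 0.0  # probability of a coupled rigid-body ligand move
    p_jump: float = 0.2  # probability a water move is a box-uniform redraw
    max_translation: float = 0.35  # water, A
    max_rotation: float = np.pi  # water, rad
    lig_max_translation: float = 0.1
    lig_max_rotation: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.p_ligand <= 1.0:
            raise ValueError("p_ligand must lie in [0, 1]")
        if not 0.0 <= self.p_jump <= 1.0:
            raise ValueError("p_jump must lie in [0, 1]")
        if self.sampling_interval <= 0 or self.n_production % self.sampling_interval:
            raise ValueError("sampling_interval must divide n_production")

    def scaled(self, factor: float) -> "AlchemicalSchedule":
        return AlchemicalSchedule(
            n_equil=int(self.n_equil * factor),
            n_production=int(self.n_production * factor),
            sampling_interval=self.sampling_interval,
            p_ligand=self.p_ligand,
            p_jump=self.p_jump,
            max_translation=self.max_translation,
            max_rotation=self.max_rotation,
            lig_max_translation=self.lig_max_translation,
            lig_max_rotation=self.lig_max_rotation,
        )


@dataclass
class AlchemicalLeg:
    """Reduced-potential samples across a lambda ladder in one environment."""

    lambdas: np.ndarray  # (K,), covers 0 and 1
    u_kn: np.ndarray  # (K, N_total) reduced potentials, window-major samples
    n_k: np.ndarray  # (K,) samples per window
    environment: str
    dg: Optional[float] = None  # kcal/mol, filled by estimate_leg
    dg_err: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if abs(self.lambdas[0]) > 1e-12 or abs(self.lambdas[-1] - 1) > 1e-12:
            raise ValueError("lambda ladder must cover 0 and 1")


class _WindowState:
    def __init__(self, system, config, lam, rng):
        self.config = config
        self.lam = lam
        self.rng = rng
        # cache the lambda-dependent and water parts separately
        self.e_lig = float(ligand_environment_energy(system, config, [lam])[0])
        self.e_water = _water_system_energy(system, config)
        self.e_dummy = _dummy_bond_energy(system, config)

    @property
    def energy(self):
        return self.e_lig + self.e_water + self.e_dummy


def _single_water_total(system, config, i, lam):
    """Interaction of water i with everything, at coupling lam."""
    model, params = system.model, system.params
    e = single_water_energy(
        i, config.water_oxygens, config.water_sites, system.host, model, params, system.region
    )
    if not np.isfinite(e):
        return np.inf
    wsites = config.water_sites[i]
    wsig = np.r_[model.oxygen_lj_sigma, np.zeros(model.n_sites - 1)]
    weps = np.r_[model.oxygen_lj_epsilon, np.zeros(model.n_sites - 1)]
    wq = model.site_charges
    _, asig, aeps, aq = _site_arrays(system.ligand_a)
    _, bsig, beps, bq = _site_arrays(system.ligand_b)
    e += float(
        _softcore_group_energy(config.lig_b_pos, bsig, beps, bq, wsites, wsig, weps, wq,
                               [lam], system.softcore, params)[0]
        + _softcore_group_energy(config.lig_a_pos, asig, aeps, aq, wsites, wsig, weps, wq,
                                 [1 - lam], system.softcore, params)[0]
    )
    return e


def _attempt_water_move(system, ws: _WindowState, schedule) -> bool:
    config = ws.config
    n = len(config.water_oxygens)
    if n == 0:
        return False
    i = int(ws.rng.integers(n))
    old_o = config.water_oxygens[i].copy()
    old_R = config.water_rotations[i].copy()
    old_sites = config.water_sites[i].copy()
    if ws.rng.random() < schedule.p_jump:
        # box-uniform redraw with fresh orientation: a symmetric proposal
        # that hops basins a small step cannot connect ergodically
        r = system.region
        o = r.box_min + ws.rng.random(3) * (r.box_max - r.box_min)
        R = random_rotation(ws.rng)
    else:
        o = old_o + ws.rng.uniform(-schedule.max_translation, schedule.max_translation, 3)
        # network waters are region waters: keep the same configuration space
        # as the grand canonical legs by rejecting box-leaving proposals
        if not bool(system.region.contains(o[None])[0]):
            return False
        R = rotation_from_axis_angle(
            ws.rng.standard_normal(3),
            ws.rng.uniform(-schedule.max_rotation, schedule.max_rotation),
        ) @ old_R
    e_old = _single_water_total(system, config, i, ws.lam)
    config.water_oxygens[i] = o
    config.water_rotations[i] = R
    config.water_sites[i] = o + system.model.site_offsets @ R.T
    e_new = _single_water_total(system, config, i, ws.lam)
    du = e_new - e_old if np.isfinite(e_new) else np.inf
    beta = system.params.beta
    if du <= 0 or (np.isfinite(du) and ws.rng.random() < np.exp(-beta * du)):
        ws.e_water = _water_system_energy(system, config)
        ws.e_lig = float(ligand_environment_energy(system, config, [ws.lam])[0])
        return True
    config.water_oxygens[i] = old_o
    config.water_rotations[i] = old_R
    config.water_sites[i] = old_sites
    return False


def _attempt_ligand_move(system, ws: _WindowState, schedule) -> bool:
    """Coupled rigid-body move: identical translation and rotation (about each
    copy's own center of geometry) applied to both ligands."""
    config = ws.config
    t = ws.rng.uniform(-schedule.lig_max_translation, schedule.lig_max_translation, 3)
    R = rotation_from_axis_angle(
        ws.rng.standard_normal(3),
        ws.rng.uniform(-schedule.lig_max_rotation, schedule.lig_max_rotation),
    )
    old_a, old_b = config.lig_a_pos.copy(), config.lig_b_pos.copy()
    for arr in (config.lig_a_pos, config.lig_b_pos):
        cog = arr.mean(axis=0)
        arr[:] = (arr - cog) @ R.T + cog + t
    e_lig = float(ligand_environment_energy(system, config, [ws.lam])[0])
    e_dummy = _dummy_bond_energy(system, config)
    du = (e_lig + e_dummy) - (ws.e_lig + ws.e_dummy)
    beta = system.params.beta
    if du <= 0 or (np.isfinite(du) and ws.rng.random() < np.exp(-beta * du)):
        ws.e_lig, ws.e_dummy = e_lig, e_dummy
        return True
    config.lig_a_pos[:] = old_a
    config.lig_b_pos[:] = old_b
    return False


def run_alchemical_leg(
    system: DualTopologySystem,
    lambdas: Sequence[float],
    schedule: AlchemicalSchedule,
    seed: int,
    water_oxygens=None,
    water_rotations=None,
    exchange_interval: Optional[int] = None,
) -> AlchemicalLeg:
    """Sample every lambda window (with adjacent-window replica exchange) and
    record the reduced potential of each sample at all windows."""
    lambdas = np.asarray(sorted(float(x) for x in lambdas))
    if len(lambdas) < 2 or abs(lambdas[0]) > 1e-12 or abs(lambdas[-1] - 1) > 1e-12:
        raise ValueError("lambda ladder must have >= 2 windows covering 0 and 1")
    seqs = np.random.SeedSequence(seed).spawn(len(lambdas) + 1)
    base = AlchemicalConfig.initial(system, water_oxygens, water_rotations)
    windows = [
        _WindowState(system, copy.deepcopy(base), lam, np.random.default_rng(s))
        for lam, s in zip(lambdas, seqs[:-1])
    ]
    ex_rng = np.random.default_rng(seqs[-1])
    if exchange_interval is None:
        exchange_interval = max(1, schedule.sampling_interval * 5)
    beta = system.params.beta
    samples: list[list[np.ndarray]] = [[] for _ in windows]

    def do_moves(ws, n, collect, offset):
        has_waters = len(base.water_oxygens) > 0
        for m in range(n):
            if has_waters and (
                schedule.p_ligand == 0 or ws.rng.random() >= schedule.p_ligand
            ):
                _attempt_water_move(system, ws, schedule)
            elif schedule.p_ligand > 0:
                _attempt_ligand_move(system, ws, schedule)
            # with p_ligand = 0 and no waters the configuration is static
            if collect and (offset + m + 1) % schedule.sampling_interval == 0:
                e_lam = ligand_environment_energy(system, ws.config, lambdas)
                const = ws.e_water + ws.e_dummy
                samples[windows.index(ws)].append(beta * (e_lam + const))
        return offset + n

    def exchange(sweep):
        for i in range(sweep % 2, len(windows) - 1, 2):
            m, n = windows[i], windows[i + 1]
            # cross terms: only the lambda-dependent part differs
            emn = float(ligand_environment_energy(system, n.config, [m.lam])[0])
            enm = float(ligand_environment_energy(system, m.config, [n.lam])[0])
            log_acc = -beta * (emn + enm - m.e_lig - n.e_lig)
            if log_acc >= 0 or ex_rng.random() < np.exp(log_acc):
                m.config, n.config = n.config, m.config
                # window m now holds x_n, whose lambda-part at lam_m is emn
                m.e_lig, n.e_lig = emn, enm
                m.e_water, n.e_water = n.e_water, m.e_water
                m.e_dummy, n.e_dummy = n.e_dummy, m.e_dummy

    for phase_len, collect in ((schedule.n_equil, False), (schedule.n_production, True)):
        done, offs, sweep = 0, [0] * len(windows), 0
        while done < phase_len:
            c = min(exchange_interval, phase_len - done)
            for k, ws in enumerate(windows):
                offs[k] = do_moves(ws, c, collect, offs[k])
            done += c
            exchange(sweep)
            sweep += 1

    n_k = np.array([len(s) for s in samples])
    if n_k.sum() == 0:
        u_kn = np.zeros((len(lambdas), 0))
    else:
        u_kn = np.hstack([np.array(s).T for s in samples if len(s)])
    return AlchemicalLeg(
        lambdas=lambdas,
        u_kn=u_kn,
        n_k=n_k,
        environment=system.environment,
        metadata={"seed": seed, "schedule": schedule},
    )


def estimate_leg(leg: AlchemicalLeg, params: Optional[EnergyParams] = None) -> AlchemicalLeg:
    """Fill in the MBAR free-energy difference dG(lam=1) - dG(lam=0)."""
    params = params or EnergyParams()
    if leg.u_kn.shape[1] == 0:
        raise ValueError("leg carries no samples")
    dg, err = mbar_free_energy(leg.u_kn, leg.n_k, kT=params.kT)
    leg.dg, leg.dg_err = dg, err
    return leg


def run_alchemical_repeats(
    system: DualTopologySystem,
    lambdas: Sequence[float],
    schedule: AlchemicalSchedule,
    seeds: Sequence[int],
    water_oxygens=None,
    water_rotations=None,
) -> tuple[float, float, list[AlchemicalLeg]]:
    """Independent repeats; returns (mean dG, SD over repeats, legs)."""
    legs = [
        estimate_leg(
            run_alchemical_leg(system, lambdas, schedule, s, water_oxygens, water_rotations),
            system.params,
        )
        for s in seeds
    ]
    dgs = np.array([l.dg for l in legs])
    sd = float(dgs.std(ddof=1)) if len(dgs) > 1 else float(legs[0].dg_err)
    return float(dgs.mean()), sd, legs
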