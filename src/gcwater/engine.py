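"""Grand canonical Metropolis sampler for water with replica exchange in B.

The chemical potential is carried as the Adams B value, with insertion and
deletion acceptances

    P_ins = min(1, e^B / (N + 1) * e^(-beta dU))
    P_del = min(1, N e^(-B)     * e^(-beta dU))

where N counts waters whose oxygen lies in the GCMC box.  B absorbs the
thermal-wavelength and volume constants, so an ideal gas obeys <N> = e^B
exactly.  Displacement moves that would carry an oxygen across the box
boundary are rejected outright, keeping insertion/deletion the only
N-changing moves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .energy import EnergyParams, single_water_energy, total_energy, trial_water_energy
from .model import (
    HostStructure,
    SimulationRegion,
    WaterModel,
    random_rotation,
    rotation_from_axis_angle,
)

__all__ = [
    "MoveSchedule",
    "GCMCState",
    "GCMCTrajectory",
    "Insertion",
    "Deletion",
    "Displacement",
    "delta_energy_of_move",
    "attempt_insertion",
    "attempt_deletion",
    "attempt_displacement",
    "run_gcmc",
    "replica_exchange_sweep",
    "run_ladder",
]


@dataclass
class MoveSchedule:
    """Move mix and phase lengths.

    Production follows a two-phase equilibration: first only waters inside the
    GCMC region are sampled, then all waters.  ``sampling_interval`` must
    divide ``n_production``.
    """

    n_equil_region: int = 2000
    n_equil_all: int = 0
    n_production: int = 10000
    sampling_interval: int = 100
    p_insert: float = 0.35
    p_delete: float = 0.35
    p_displace_region: float = 0.20
    p_displace_bulk: float = 0.10
    max_translation: float = 0.35
    max_rotation: float = np.pi
    energy_check_interval: int = 0

    def __post_init__(self):
        probs = np.array(
            [self.p_insert, self.p_delete, self.p_displace_region, self.p_displace_bulk]
        )
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("move probabilities must be >= 0 and sum to 1")
        if self.n_production < 0 or self.n_equil_region < 0 or self.n_equil_all < 0:
            raise ValueError("phase lengths must be >= 0")
        if self.sampling_interval <= 0 or self.n_production % self.sampling_interval:
            raise ValueError("sampling_interval must divide n_production")

    def scaled(self, factor: float) -> "MoveSchedule":
        """Same schedule with all phase lengths multiplied by ``factor``."""
        return MoveSchedule(
            n_equil_region=int(self.n_equil_region * factor),
            n_equil_all=int(self.n_equil_all * factor),
            n_production=int(self.n_production * factor),
            sampling_interval=self.sampling_interval,
            p_insert=self.p_insert,
            p_delete=self.p_delete,
            p_displace_region=self.p_displace_region,
            p_displace_bulk=self.p_displace_bulk,
            max_translation=self.max_translation,
            max_rotation=self.max_rotation,
            energy_check_interval=self.energy_check_interval,
        )


class GCMCState:
    """A host plus a variable-size set of rigid waters at one B value."""

    def __init__(
        self,
        host: Optional[HostStructure],
        model: WaterModel,
        params: EnergyParams,
        region: SimulationRegion,
        B: float,
        rng: np.random.Generator | int,
    ):
        self.host = host
        self.model = model
        self.params = params
        self.region = region
        self.B = float(B)
        self.rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        s = model.n_sites
        self.oxygens = np.zeros((0, 3))
        self.rotations = np.zeros((0, 3, 3))
        self.sites = np.zeros((0, s, 3))
        self.in_region = np.zeros(0, dtype=bool)
        self.energy = 0.0
        self.counters: dict[str, list[int]] = {
            k: [0, 0] for k in ("insert", "delete", "displace_region", "displace_bulk")
        }
        self._max_translation = 0.35
        self._max_rotation = np.pi

    # -- bookkeeping ------------------------------------------------------
    @property
    def n_waters(self) -> int:
        return len(self.oxygens)

    @property
    def n_region(self) -> int:
        return int(self.in_region.sum())

    def add_water(self, o: np.ndarray, R: np.ndarray) -> None:
        s = o + self.model.site_offsets @ R.T
        self.oxygens = np.vstack([self.oxygens, o[None]])
        self.rotations = np.concatenate([self.rotations, R[None]])
        self.sites = np.concatenate([self.sites, s[None]])
        self.in_region = np.append(self.in_region, self.region.contains(o[None])[0])

    def remove_water(self, i: int) -> None:
        keep = np.arange(self.n_waters) != i
        self.oxygens = self.oxygens[keep]
        self.rotations = self.rotations[keep]
        self.sites = self.sites[keep]
        self.in_region = self.in_region[keep]

    def total_energy(self) -> float:
        """Brute-force recomputation of the full system energy."""
        return total_energy(
            self.oxygens, self.sites, self.host, self.model, self.params, self.region
        )

    def water_energy(self, i: int) -> float:
        return single_water_energy(
            i, self.oxygens, self.sites, self.host, self.model, self.params, self.region
        )

    def trial_energy(self, o: np.ndarray, sites: np.ndarray) -> float:
        return trial_water_energy(
            o, sites, self.oxygens, self.sites, self.host, self.model, self.params, self.region
        )

    def swap_configuration(self, other: "GCMCState") -> None:
        for attr in ("oxygens", "rotations", "sites", "in_region", "energy"):
            a, b = getattr(self, attr), getattr(other, attr)
            setattr(self, attr, b)
            setattr(other, attr, a)


# -- move objects (for explicit delta-energy evaluation) -------------------


@dataclass(frozen=True)
class Insertion:
    oxygen_position: np.ndarray
    orientation: np.ndarray


@dataclass(frozen=True)
class Deletion:
    index: int


@dataclass(frozen=True)
class Displacement:
    index: int
    oxygen_position: np.ndarray
    orientation: np.ndarray


def delta_energy_of_move(state: GCMCState, move) -> float:
    """dU = U_after - U_before for a proposed move, computed incrementally.

    Overlaps yield +inf (auto-reject), never an exception.
    """
    if isinstance(move, Insertion):
        sites = move.oxygen_position + state.model.site_offsets @ move.orientation.T
        return state.trial_energy(np.asarray(move.oxygen_position, float), sites)
    if isinstance(move, Deletion):
        return -state.water_energy(move.index)
    if isinstance(move, Displacement):
        e_old = state.water_energy(move.index)
        o = np.asarray(move.oxygen_position, float)
        sites = o + state.model.site_offsets @ move.orientation.T
        others = np.arange(state.n_waters) != move.index
        e_new = trial_water_energy(
            o,
            sites,
            state.oxygens[others],
            state.sites[others],
            state.host,
            state.model,
            state.params,
            state.region,
        )
        if not np.isfinite(e_new):
            return np.inf
        return e_new - e_old
    raise TypeError(f"unknown move type {type(move)!r}")


def _metropolis(state: GCMCState, log_acc: float) -> bool:
    if log_acc >= 0:
        return True
    if log_acc == -np.inf:
        return False
    return state.rng.random() < np.exp(log_acc)


def attempt_insertion(state: GCMCState) -> bool:
    """Trial water uniform in the GCMC box with uniform orientation."""
    c = state.counters["insert"]
    c[0] += 1
    r = state.region
    o = r.box_min + state.rng.random(3) * (r.box_max - r.box_min)
    R = random_rotation(state.rng)
    sites = o + state.model.site_offsets @ R.T
    du = state.trial_energy(o, sites)
    n = state.n_region
    log_acc = state.B - np.log(n + 1) - (state.params.beta * du if np.isfinite(du) else np.inf)
    if not _metropolis(state, log_acc):
        return False
    state.add_water(o, R)
    state.energy += du
    c[1] += 1
    return True


def attempt_deletion(state: GCMCState) -> bool:
    """Remove a uniformly chosen region water."""
    c = state.counters["delete"]
    c[0] += 1
    n = state.n_region
    if n == 0:
        return False
    idx = np.flatnonzero(state.in_region)
    i = int(state.rng.choice(idx))
    du = -state.water_energy(i)
    log_acc = np.log(n) - state.B - state.params.beta * du
    if not (du == -np.inf or _metropolis(state, log_acc)):
        return False
    state.remove_water(i)
    state.energy += du
    c[1] += 1
    return True


def attempt_displacement(state: GCMCState, region_waters: bool = True) -> bool:
    """Random rigid translation+rotation of one water; moves that would carry
    the oxygen across the GCMC box boundary are rejected outright."""
    key = "displace_region" if region_waters else "displace_bulk"
    c = state.counters[key]
    c[0] += 1
    pool = np.flatnonzero(state.in_region if region_waters else ~state.in_region)
    if len(pool) == 0:
        return False
    i = int(state.rng.choice(pool))
    sched_t, sched_r = state._max_translation, state._max_rotation
    o = state.oxygens[i] + state.rng.uniform(-sched_t, sched_t, 3)
    if bool(state.region.contains(o[None])[0]) != bool(state.in_region[i]):
        return False
    axis = state.rng.standard_normal(3)
    angle = state.rng.uniform(-sched_r, sched_r)
    R = rotation_from_axis_angle(axis, angle) @ state.rotations[i]
    du = delta_energy_of_move(state, Displacement(i, o, R))
    if not _metropolis(state, -state.params.beta * du if np.isfinite(du) else -np.inf):
        return False
    state.oxygens[i] = o
    state.rotations[i] = R
    state.sites[i] = o + state.model.site_offsets @ R.T
    state.energy += du
    c[1] += 1
    return True


@dataclass
class GCMCTrajectory:
    """Per-sample observables of one GCMC run at one B value."""

    B: float
    n: np.ndarray  # region water count per sample
    energy: np.ndarray  # running total energy per sample
    frames: list  # per-sample (n_i, 3) region oxygen coordinates
    counters: dict
    schedule: MoveSchedule
    metadata: dict = field(default_factory=dict)

    @property
    def mean_n(self) -> float:
        return float(self.n.mean()) if len(self.n) else 0.0

    @property
    def sem_n(self) -> float:
        if len(self.n) < 2:
            return 0.0
        return float(self.n.std(ddof=1) / np.sqrt(len(self.n)))


def _move_cumprobs(schedule: MoveSchedule, region_only: bool) -> np.ndarray:
    if region_only:
        probs = np.array([schedule.p_insert, schedule.p_delete, schedule.p_displace_region])
        probs = probs / probs.sum() if probs.sum() > 0 else np.array([1 / 3] * 3)
    else:
        probs = np.array(
            [
                schedule.p_insert,
                schedule.p_delete,
                schedule.p_displace_region,
                schedule.p_displace_bulk,
            ]
        )
    return np.cumsum(probs)


def _one_move(state: GCMCState, schedule: MoveSchedule, region_only: bool, cum=None) -> None:
    state._max_translation = schedule.max_translation
    state._max_rotation = schedule.max_rotation
    if cum is None:
        cum = _move_cumprobs(schedule, region_only)
    u = state.rng.random()
    if u < cum[0]:
        attempt_insertion(state)
    elif u < cum[1]:
        attempt_deletion(state)
    elif u < cum[2]:
        attempt_displacement(state, region_waters=True)
    else:
        attempt_displacement(state, region_waters=False)


class _Collector:
    def __init__(self):
        self.n = []
        self.energy = []
        self.frames = []
        self.max_drift = 0.0

    def sample(self, state: GCMCState):
        full = state.total_energy()
        drift = abs(full - state.energy)
        self.max_drift = max(self.max_drift, drift)
        state.energy = full  # refresh running total at sample points
        self.n.append(state.n_region)
        self.energy.append(full)
        self.frames.append(state.oxygens[state.in_region].copy())


def _run_moves(
    state: GCMCState,
    n_moves: int,
    schedule: MoveSchedule,
    region_only: bool,
    collector: Optional[_Collector] = None,
    move_offset: int = 0,
) -> int:
    """Run ``n_moves`` moves; sample into ``collector`` on the production
    clock (``move_offset`` counts production moves already done)."""
    check = schedule.energy_check_interval
    cum = _move_cumprobs(schedule, region_only)
    for m in range(n_moves):
        _one_move(state, schedule, region_only, cum)
        k = move_offset + m + 1
        if check and k % check == 0:
            full = state.total_energy()
            if abs(full - state.energy) > 1e-6:
                raise RuntimeError(
                    f"energy bookkeeping drift {abs(full - state.energy):.3e} kcal/mol"
                )
        if collector is not None and k % schedule.sampling_interval == 0:
            collector.sample(state)
        if not np.isfinite(state.energy):
            raise RuntimeError("non-finite energy after an accepted move")
    return move_offset + n_moves


def run_gcmc(state: GCMCState, schedule: MoveSchedule) -> GCMCTrajectory:
    """Two-phase equilibration followed by production sampling."""
    _run_moves(state, schedule.n_equil_region, schedule, region_only=True)
    _run_moves(state, schedule.n_equil_all, schedule, region_only=False)
    coll = _Collector()
    _run_moves(state, schedule.n_production, schedule, region_only=False, collector=coll)
    return GCMCTrajectory(
        B=state.B,
        n=np.array(coll.n, dtype=float),
        energy=np.array(coll.energy),
        frames=coll.frames,
        counters={k: tuple(v) for k, v in state.counters.items()},
        schedule=schedule,
        metadata={"max_energy_drift": coll.max_drift},
    )


def replica_exchange_sweep(
    states: Sequence[GCMCState], rng: np.random.Generator, parity: int = 0
) -> dict:
    """One sweep of adjacent-pair configuration swaps across the B ladder.

    With a shared potential, swapping configurations between B_m and B_n is
    accepted with min(1, exp[(B_m - B_n)(N_n - N_m)]).  Pairs alternate
    even/odd origin across sweeps via ``parity``.
    """
    bs = [s.B for s in states]
    if any(b2 <= b1 for b1, b2 in zip(bs, bs[1:])):
        raise ValueError("ladder B values must be strictly increasing")
    stats = {"attempted": 0, "accepted": 0}
    if len(states) < 2:
        return stats
    for i in range(parity % 2, len(states) - 1, 2):
        m, n = states[i], states[i + 1]
        log_acc = (m.B - n.B) * (n.n_region - m.n_region)
        stats["attempted"] += 1
        if log_acc >= 0 or rng.random() < np.exp(log_acc):
            m.swap_configuration(n)
            stats["accepted"] += 1
    return stats


def run_ladder(
    host: Optional[HostStructure],
    model: WaterModel,
    params: EnergyParams,
    region: SimulationRegion,
    b_values: Sequence[float],
    schedule: MoveSchedule,
    seed: int,
    exchange_interval: Optional[int] = None,
) -> list[GCMCTrajectory]:
    """Run a replica-exchange ladder of GCMC simulations, one per B value.

    Each replica gets an independent RNG stream derived from ``seed``; the
    exchange decisions use a further stream, so the whole ladder is
    reproducible bit-for-bit from the seed.
    """
    b_values = [float(b) for b in b_values]
    if any(b2 <= b1 for b1, b2 in zip(b_values, b_values[1:])):
        raise ValueError("b_values must be strictly increasing")
    seqs = np.random.SeedSequence(seed).spawn(len(b_values) + 1)
    states = [
        GCMCState(host, model, params, region, b, np.random.default_rng(s))
        for b, s in zip(b_values, seqs[:-1])
    ]
    ex_rng = np.random.default_rng(seqs[-1])
    if exchange_interval is None:
        exchange_interval = max(1, schedule.sampling_interval * 5)

    collectors = [_Collector() for _ in states]
    sweep = 0

    def chunked(n_moves: int, region_only: bool, production: bool, offsets: list[int]):
        nonlocal sweep
        done = 0
        while done < n_moves:
            c = min(exchange_interval, n_moves - done)
            for k, st in enumerate(states):
                offsets[k] = _run_moves(
                    st,
                    c,
                    schedule,
                    region_only,
                    collector=collectors[k] if production else None,
                    move_offset=offsets[k],
                )
            done += c
            replica_exchange_sweep(states, ex_rng, parity=sweep)
            sweep += 1

    offs = [0] * len(states)
    chunked(schedule.n_equil_region, True, False, offs)
    offs = [0] * len(states)
    chunked(schedule.n_equil_all, False, False, offs)
    offs = [0] * len(states)
    chunked(schedule.n_production, False, True, offs)

    return [
        GCMCTrajectory(
            B=st.B,
            n=np.array(c.n, dtype=float),
            energy=np.array(c.energy),
            frames=c.frames,
            counters={k: tuple(v) for k, v in st.counters.items()},
            schedule=schedule,
            metadata={"max_energy_drift": c.max_drift, "seed": seed},
        )
        for st, c in zip(states, collectors)
    ]
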