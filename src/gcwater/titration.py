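"""Titration curves and Grand Canonical Integration (GCI).

The grand potential of the GCMC region obeys d(beta Omega)/dB = -<N>, so the
free energy of assembling the water network is obtained by integrating the
titration curve <N>(B) from the empty limit upward ("the area underneath the
titration curve").  In the Adams bookkeeping used by the engine the grand
partition function is Xi(B) = sum_N e^{BN} Z_N / N! with dimensionless Z_N, and
the bulk chemical potential maps onto B_equil = beta mu'_hyd + ln(V_GCMC/V0).
Integrating exactly to B_equil, all reference terms cancel and

    dG_bind = -kT * integral_{B_0}^{B_equil} <N> dB,

the binding free energy of the network relative to the same number of waters
in bulk.  The general fixed-target form (network of exactly n waters,
integration stopping at the B* where <N> = n) is

    beta dG_bind(n) = -integral_{B_0}^{B*} <N> dB + n B* - n B_equil.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .energy import EnergyParams
from .engine import GCMCTrajectory
from .model import SimulationRegion

__all__ = [
    "TitrationCurve",
    "BulkWaterReference",
    "NetworkFreeEnergy",
    "occupancy_curve",
    "equilibrium_b",
    "grand_potential_change",
    "gci_network_binding_free_energy",
    "relative_network_stability",
]


@dataclass(frozen=True)
class BulkWaterReference:
    """Bulk-phase reference of the water model.

    ``mu_hyd`` is the excess hydration free energy (kcal/mol) and ``v0`` the
    bulk volume per molecule (A^3); defaults are the standard literature
    values for TIP4P at 298 K.
    """

    mu_hyd: float = -6.2
    v0: float = 30.0

    def __post_init__(self):
        if self.v0 <= 0:
            raise ValueError("bulk volume per molecule must be positive")


@dataclass
class TitrationCurve:
    """Mean occupancy vs B, with one row of occupancies per repeat."""

    b_values: np.ndarray  # (G,), strictly increasing
    occupancies: np.ndarray  # (R, G), per-repeat mean N at each B

    def __post_init__(self):
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.occupancies = np.atleast_2d(np.asarray(self.occupancies, dtype=float))
        if np.any(np.diff(self.b_values) <= 0):
            raise ValueError("B grid must be strictly increasing")
        if self.occupancies.shape[1] != len(self.b_values):
            raise ValueError("occupancy grid does not match B grid")
        if np.any(self.occupancies < 0):
            raise ValueError("occupancies must be >= 0")

    @property
    def n_repeats(self) -> int:
        return self.occupancies.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.occupancies.mean(axis=0)

    @property
    def sem(self) -> np.ndarray:
        """Standard error across repeat means (0 for a single repeat)."""
        r = self.n_repeats
        if r < 2:
            return np.zeros_like(self.b_values)
        return self.occupancies.std(axis=0, ddof=1) / np.sqrt(r)


def occupancy_curve(trajectories: Mapping[float, Sequence[GCMCTrajectory]]) -> TitrationCurve:
    """Assemble a titration curve from per-(B, repeat) trajectories.

    ``trajectories`` maps B -> list of repeats; every B must carry the same
    number of repeats.  The per-repeat mean is the time average of N over
    production samples.
    """
    if not trajectories:
        raise ValueError("no trajectories supplied")
    bs = np.array(sorted(trajectories), dtype=float)
    reps = {len(trajectories[b]) for b in trajectories}
    if len(reps) != 1:
        raise ValueError("every B value must have the same number of repeats")
    (n_rep,) = reps
    if n_rep == 0:
        raise ValueError("need at least one repeat per B value")
    occ = np.array([[trajectories[b][r].mean_n for b in bs] for r in range(n_rep)])
    return TitrationCurve(bs, occ)


def equilibrium_b(
    ref: BulkWaterReference, region: SimulationRegion, params: EnergyParams
) -> float:
    """B value at which the region is in equilibrium with bulk water:
    B_equil = beta mu'_hyd + ln(V_GCMC / V0)."""
    return ref.mu_hyd / params.kT + np.log(region.volume / ref.v0)


@dataclass
class NetworkFreeEnergy:
    """Binding free energy of the region's water network relative to bulk."""

    dg: float  # kcal/mol, pooled over repeats
    se: float  # kcal/mol, standard error over repeats
    n_equil: float  # mean occupancy at B_equil (continuous; round only to report)
    b_equil: float
    per_repeat: np.ndarray = field(default_factory=lambda: np.zeros(0))
    method: str = "trapezoid"

    def __post_init__(self):
        if self.se < 0:
            raise ValueError("standard error must be >= 0")


def _interp_occ(b_grid: np.ndarray, occ: np.ndarray, b: float) -> float:
    return float(np.interp(b, b_grid, occ))


def _integrate_to(b_grid: np.ndarray, occ: np.ndarray, b_end: float) -> float:
    """Trapezoid integral of the occupancy curve from the grid start to b_end."""
    inside = b_grid <= b_end
    bs = np.append(b_grid[inside], b_end)
    ns = np.append(occ[inside], _interp_occ(b_grid, occ, b_end))
    return float(np.trapezoid(ns, bs))


def grand_potential_change(
    curve: TitrationCurve, b_lo: float, b_hi: float, params: Optional[EnergyParams] = None
) -> float:
    """Grand-potential change Omega(b_hi) - Omega(b_lo) in kcal/mol:
    -kT * integral of the pooled <N>(B) between the two B values."""
    kT = (params or EnergyParams()).kT
    if not (curve.b_values[0] - 1e-9 <= b_lo < b_hi <= curve.b_values[-1] + 1e-9):
        raise ValueError("integration limits must lie inside the sampled B grid")
    b_lo = max(b_lo, float(curve.b_values[0]))
    b_hi = min(b_hi, float(curve.b_values[-1]))
    return -kT * (
        _integrate_to(curve.b_values, curve.mean, b_hi)
        - _integrate_to(curve.b_values, curve.mean, b_lo)
    )


def _logistic(b, n_max, b50, width):
    return n_max / (1.0 + np.exp(-(b - b50) / width))


def _fit_logistic(b_grid: np.ndarray, occ: np.ndarray):
    from scipy.optimize import curve_fit

    n_max = max(occ.max(), 1e-6)
    p0 = [n_max, float(b_grid[np.argmin(np.abs(occ - n_max / 2))]), 1.0]
    popt, _ = curve_fit(
        _logistic, b_grid, occ, p0=p0, maxfev=20000,
        bounds=([0, b_grid[0] - 20, 0.05], [10 * n_max + 1, b_grid[-1] + 20, 20]),
    )
    return popt


def gci_network_binding_free_energy(
    curve: TitrationCurve,
    b_equil: float,
    ref: BulkWaterReference,
    params: Optional[EnergyParams] = None,
    target_n: Optional[float] = None,
    method: str = "trapezoid",
    occ_zero_tol: float = 0.05,
    plateau_tol: float = 0.05,
) -> NetworkFreeEnergy:
    """Grand Canonical Integration of a titration curve.

    Computed independently for every repeat and pooled (mean +/- standard
    error).  With ``target_n`` unset the integral runs to ``b_equil`` and the
    result is the binding free energy of the equilibrium network; with
    ``target_n`` set, the integral stops at the B* where the (monotonised)
    repeat curve reaches ``target_n`` waters, giving the binding free energy
    of exactly that many waters -- the form needed for cycle network legs.

    ``method``: "trapezoid" (default) integrates the simulated grid directly;
    "logistic" integrates a fitted monotone logistic (useful for sparse
    ladders) and is flagged in the result.
    """
    params = params or EnergyParams()
    kT = params.kT
    bs = curve.b_values
    if b_equil > bs[-1] + 1e-12 and target_n is None:
        raise ValueError("curve must extend at least to B_equil; extend the ladder upward")

    per = []
    n_at_equil = []
    for r in range(curve.n_repeats):
        occ = curve.occupancies[r]
        if occ[0] > occ_zero_tol:
            raise ValueError(
                f"occupancy {occ[0]:.3f} at the lowest B is not ~0; "
                "extend the ladder to lower B values"
            )
        if method == "logistic":
            n_max, b50, width = _fit_logistic(bs, occ)
            grid = np.linspace(bs[0], max(bs[-1], b_equil), 2001)
            occ_use = _logistic(grid, n_max, b50, width)
            bs_use = grid
        elif method == "trapezoid":
            bs_use, occ_use = bs, occ
        else:
            raise ValueError(f"unknown integration method {method!r}")

        if target_n is None:
            area = _integrate_to(bs_use, occ_use, b_equil)
            beta_dg = -area  # endpoint terms cancel exactly at B_equil
            n_at_equil.append(_interp_occ(bs_use, occ_use, b_equil))
        else:
            # B* where the (monotonised) curve reaches target_n; a plateau
            # slightly below the integer (finite-T fluctuations) is accepted
            # because -int <N> dB + n B* is stationary along the plateau
            mono = np.maximum.accumulate(occ_use)
            if target_n > mono[-1] + plateau_tol:
                raise ValueError(
                    f"curve never reaches target occupancy {target_n}; extend the ladder"
                )
            t_eff = min(float(target_n), float(mono[-1]))
            idx = int(np.searchsorted(mono, t_eff))
            if idx == 0:
                b_star = float(bs_use[0])
            elif mono[idx] > mono[idx - 1]:
                frac = (t_eff - mono[idx - 1]) / (mono[idx] - mono[idx - 1])
                b_star = float(bs_use[idx - 1] + frac * (bs_use[idx] - bs_use[idx - 1]))
            else:
                b_star = float(bs_use[idx])
            area = _integrate_to(bs_use, occ_use, b_star)
            beta_dg = -area + target_n * b_star - target_n * b_equil
            n_at_equil.append(float(target_n))
        per.append(kT * beta_dg)

    per = np.array(per)
    se = float(per.std(ddof=1) / np.sqrt(len(per))) if len(per) > 1 else 0.0
    return NetworkFreeEnergy(
        dg=float(per.mean()),
        se=se,
        n_equil=float(np.mean(n_at_equil)),
        b_equil=float(b_equil),
        per_repeat=per,
        method=method,
    )


def relative_network_stability(a: NetworkFreeEnergy, b: NetworkFreeEnergy):
    """ddG = dG_b - dG_a with root-sum-square error.

    Positive values mean the network in system b is destabilised relative to
    system a (less negative binding free energy).
    """
    if abs(a.b_equil - b.b_equil) > 1e-9:
        raise ValueError("network free energies computed at different B_equil")
    return b.dg - a.dg, float(np.hypot(a.se, b.se))
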