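"""Softcore potentials, dual-topology energies, window sampling and the
MBAR/BAR estimators."""

import numpy as np
import pytest

from gcwater.alchemical import (
    AlchemicalConfig,
    AlchemicalSchedule,
    DualTopologySystem,
    SoftcoreParams,
    dual_topology_energy,
    estimate_leg,
    run_alchemical_leg,
)
from gcwater.energy import KB, EnergyParams, pair_energy
from gcwater.estimators import bar_free_energy, mbar_free_energy, mbar_solve
from gcwater.model import HostStructure, ParticleSite, SimulationRegion

KT = KB * 298.0


def _pair(r, sigma=3.0, eps=0.15, qa=0.3, qb=-0.2):
    a = ParticleSite([0, 0, 0], lj_sigma=sigma, lj_epsilon=eps, charge=qa)
    b = ParticleSite([r, 0, 0], lj_sigma=sigma, lj_epsilon=eps, charge=qb)
    return a, b


class TestSoftcore:
    def test_full_coupling_reduces_to_plain_potential(self, params):
        from gcwater.alchemical import softcore_pair_energy

        sc = SoftcoreParams(delta=0.2, delta_c=2.0)
        for r in (2.5, 3.3, 5.0, 9.8):
            a, b = _pair(r)
            assert softcore_pair_energy(a, b, 1.0, sc, params) == pytest.approx(
                pair_energy(a, b, params), abs=1e-10
            )

    def test_zero_coupling_vanishes_even_at_contact(self, params):
        from gcwater.alchemical import softcore_pair_energy

        sc = SoftcoreParams()
        for r in (0.0, 0.5, 3.0):
            a, b = _pair(max(r, 0.0))
            assert softcore_pair_energy(a, b, 0.0, sc, params) == 0.0

    def test_half_coupling_finite_at_contact(self, params):
        from gcwater.alchemical import softcore_pair_energy

        sc = SoftcoreParams(delta=0.2, delta_c=2.0)
        a, b = _pair(0.0)
        got = softcore_pair_energy(a, b, 0.5, sc, params)
        # closed form with (r/sigma)^6 = 0 and r^2 = 0
        lam = 0.5
        lj = 4 * 0.15 * lam * (1 / (0.2 * lam) ** 2 - 1 / (0.2 * lam))
        coul = params.coulomb_constant * 0.3 * (-0.2) * lam / np.sqrt(2.0 * lam)
        assert np.isfinite(got)
        assert got == pytest.approx(lj + coul, rel=1e-10)

    def test_repulsive_core_monotone_in_coupling(self, params):
        from gcwater.alchemical import softcore_pair_energy

        sc = SoftcoreParams()
        a, b = _pair(2.0, qa=0.0, qb=0.0)  # r < sigma: repulsive core
        lams = np.linspace(0.0, 1.0, 21)
        es = [softcore_pair_energy(a, b, l, sc, params) for l in lams]
        assert all(e2 >= e1 - 1e-12 for e1, e2 in zip(es, es[1:]))


def _toy_system(environment="waters-absent", identical=False):
    params = EnergyParams()
    region = SimulationRegion([-2, -2, -2], [2, 2, 2], droplet_radius=12)
    host = HostStructure(
        [
            ParticleSite([0, 0, 3.2], lj_sigma=3.0, lj_epsilon=0.15, charge=0.25),
            ParticleSite([1.5, -1.0, -3.0], lj_sigma=3.0, lj_epsilon=0.15, charge=-0.25),
        ]
    )
    lig_a = [ParticleSite([0.0, 0.0, 0.0], lj_sigma=2.5, lj_epsilon=0.08, charge=0.12)]
    if identical:
        lig_b = [ParticleSite([0.0, 0.0, 0.0], lj_sigma=2.5, lj_epsilon=0.08, charge=0.12)]
    else:
        lig_b = [ParticleSite([0.4, 0.0, 0.0], lj_sigma=3.1, lj_epsilon=0.12, charge=-0.18)]
    return DualTopologySystem(
        ligand_a=lig_a, ligand_b=lig_b, region=region, host=host,
        environment=environment, params=params,
    )


class TestDualTopology:
    def test_endpoints_match_single_ligand_reference(self):
        """lambda = 0/1 recover the pure-A / pure-B environment energies."""
        system = _toy_system()
        config = AlchemicalConfig.initial(system)
        from gcwater.alchemical import ligand_environment_energy

        e0 = dual_topology_energy(system, config, 0.0)
        e1 = dual_topology_energy(system, config, 1.0)
        only_a = DualTopologySystem(
            ligand_a=system.ligand_a, ligand_b=[], region=system.region,
            host=system.host, environment=system.environment, params=system.params,
        )
        only_b = DualTopologySystem(
            ligand_a=[], ligand_b=system.ligand_b, region=system.region,
            host=system.host, environment=system.environment, params=system.params,
        )
        from gcwater.alchemical import _dummy_bond_energy

        dummy = _dummy_bond_energy(system, config)
        ca = AlchemicalConfig.initial(only_a)
        cb = AlchemicalConfig.initial(only_b)
        assert e0 == pytest.approx(
            float(ligand_environment_energy(only_a, ca, [0.0])[0]) + dummy, abs=1e-10
        )
        assert e1 == pytest.approx(
            float(ligand_environment_energy(only_b, cb, [1.0])[0]) + dummy, abs=1e-10
        )

    def test_identical_superposed_ligands_symmetric_profile(self):
        """With A = B superposed, the energy is symmetric under lam -> 1-lam
        and the endpoints coincide with the single-ligand value (the softcore
        forms are nonlinear in lam, so intermediate windows differ)."""
        system = _toy_system(identical=True)
        config = AlchemicalConfig.initial(system)
        e = {lam: dual_topology_energy(system, config, lam) for lam in (0.0, 0.25, 0.5, 0.75, 1.0)}
        assert e[0.0] == pytest.approx(e[1.0], abs=1e-10)
        assert e[0.25] == pytest.approx(e[0.75], abs=1e-10)

    def test_lambda_out_of_range(self):
        system = _toy_system()
        with pytest.raises(ValueError):
            dual_topology_energy(system, AlchemicalConfig.initial(system), 1.5)


class TestLegSampling:
    def test_zero_production_gives_empty_matrix(self):
        system = _toy_system()
        sched = AlchemicalSchedule(n_equil=50, n_production=0, sampling_interval=10)
        leg = run_alchemical_leg(system, np.linspace(0, 1, 4), sched, seed=1)
        assert leg.u_kn.shape == (4, 0)
        with pytest.raises(ValueError, match="no samples"):
            estimate_leg(leg)

    def test_dry_leg_is_static_energy_difference(self):
        """With no waters and a fixed ligand pair, MBAR reproduces the exact
        static endpoint energy difference."""
        system = _toy_system()
        sched = AlchemicalSchedule(n_equil=10, n_production=200, sampling_interval=20)
        leg = estimate_leg(run_alchemical_leg(system, np.linspace(0, 1, 8), sched, seed=2))
        config = AlchemicalConfig.initial(system)
        exact = dual_topology_energy(system, config, 1.0) - dual_topology_energy(
            system, config, 0.0
        )
        assert leg.dg == pytest.approx(exact, abs=1e-6)

    def test_wet_leg_antisymmetry(self):
        """Estimating B->A equals -(A->B) within statistical error."""
        fwd = _toy_system("waters-present")
        rev = DualTopologySystem(
            ligand_a=fwd.ligand_b, ligand_b=fwd.ligand_a, region=fwd.region,
            host=fwd.host, environment="waters-present", params=fwd.params,
        )
        sched = AlchemicalSchedule(n_equil=1000, n_production=8000, sampling_interval=40)
        lams = np.linspace(0, 1, 8)
        waters = np.array([[0.0, 0.0, 1.5]])
        lf = estimate_leg(run_alchemical_leg(fwd, lams, sched, 11, water_oxygens=waters))
        lr = estimate_leg(run_alchemical_leg(rev, lams, sched, 12, water_oxygens=waters))
        tol = 4 * np.hypot(lf.dg_err, lr.dg_err) + 0.05
        assert lf.dg == pytest.approx(-lr.dg, abs=tol)

    def test_same_seed_reproducible(self):
        system = _toy_system("waters-present")
        sched = AlchemicalSchedule(n_equil=100, n_production=500, sampling_interval=50)
        waters = np.array([[0.0, 0.0, 1.5]])
        l1 = run_alchemical_leg(system, np.linspace(0, 1, 4), sched, 5, water_oxygens=waters)
        l2 = run_alchemical_leg(system, np.linspace(0, 1, 4), sched, 5, water_oxygens=waters)
        assert np.array_equal(l1.u_kn, l2.u_kn)


class TestEstimators:
    def test_harmonic_wells_closed_form(self):
        """k vs 4k 1-D harmonic wells: dG = (kT/2) ln 4 ~ 0.410 kcal/mol."""
        k = 10.0
        rng = np.random.default_rng(7)
        n = 20000
        x = np.concatenate(
            [rng.normal(0, np.sqrt(KT / k), n), rng.normal(0, np.sqrt(KT / (4 * k)), n)]
        )
        u = np.vstack([0.5 * k * x**2 / KT, 0.5 * 4 * k * x**2 / KT])
        dg, err = mbar_free_energy(u, [n, n], kT=KT)
        assert dg == pytest.approx(KT / 2 * np.log(4), abs=0.05)
        assert 0 < err < 0.02

    def test_two_state_mbar_equals_bar(self):
        k = 10.0
        rng = np.random.default_rng(3)
        n = 5000
        x = np.concatenate(
            [rng.normal(0, np.sqrt(KT / k), n), rng.normal(0, np.sqrt(KT / (4 * k)), n)]
        )
        u = np.vstack([0.5 * k * x**2 / KT, 0.5 * 4 * k * x**2 / KT])
        dg_mbar, _ = mbar_free_energy(u, [n, n], kT=KT)
        dg_bar = bar_free_energy(u[1, :n] - u[0, :n], u[0, n:] - u[1, n:], kT=KT)
        assert abs(dg_mbar - dg_bar) <= 1e-6

    def test_identical_windows_zero(self):
        rng = np.random.default_rng(0)
        u_row = rng.normal(0, 1, 400)
        dg, _ = mbar_free_energy(np.vstack([u_row, u_row]), [200, 200], kT=KT)
        assert dg == pytest.approx(0.0, abs=1e-12)

    def test_discrete_enumeration_oracle(self):
        """MBAR matches the exact partition-function ratio of a 3-microstate
        system (brute-force enumeration)."""
        beta = 1.0 / KT
        E0 = np.array([0.0, 1.0, 3.0])
        E1 = np.array([2.0, 0.5, 1.0])
        exact = -KT * np.log(np.exp(-beta * E1).sum() / np.exp(-beta * E0).sum())
        rng = np.random.default_rng(5)
        m = 30000
        i0 = rng.choice(3, m, p=np.exp(-beta * E0) / np.exp(-beta * E0).sum())
        i1 = rng.choice(3, m, p=np.exp(-beta * E1) / np.exp(-beta * E1).sum())
        idx = np.concatenate([i0, i1])
        u = np.vstack([beta * E0[idx], beta * E1[idx]])
        dg, err = mbar_free_energy(u, [m, m], kT=KT)
        assert dg == pytest.approx(exact, abs=4 * err + 0.01)

    def test_poor_overlap_warns(self):
        rng = np.random.default_rng(1)
        n = 300
        # disjoint wells 40 sigma apart: essentially no phase-space overlap
        x = np.concatenate([rng.normal(0, 0.1, n), rng.normal(8.0, 0.1, n)])
        u = np.vstack([0.5 * (x / 0.1) ** 2, 0.5 * ((x - 8.0) / 0.1) ** 2])
        with pytest.warns(UserWarning, match="overlap"):
            mbar_free_energy(u, [n, n], kT=KT)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            mbar_solve(np.zeros((2, 10)), [4, 4])  # counts do not sum
        with pytest.raises(ValueError):
            bar_free_energy(np.array([]), np.array([1.0]))
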