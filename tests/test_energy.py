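"""Nonbonded energetics: LJ/Coulomb pair terms, switching, restraint, and
incremental-vs-brute-force bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcwater.energy import (
    EnergyParams,
    pair_energy,
    restraint_energy,
    switching_factor,
    total_energy,
)
from gcwater.engine import Deletion, Displacement, GCMCState, Insertion, delta_energy_of_move
from gcwater.model import (
    HostStructure,
    ParticleSite,
    SimulationRegion,
    WaterModel,
    WaterMolecule,
    random_rotation,
)


class TestPairEnergy:
    def test_lj_minimum(self, params):
        a = ParticleSite([0, 0, 0], lj_sigma=3.0, lj_epsilon=0.2)
        b = ParticleSite([2 ** (1 / 6) * 3.0, 0, 0], lj_sigma=3.0, lj_epsilon=0.2)
        assert pair_energy(a, b, params) == pytest.approx(-0.2, abs=1e-12)

    def test_coulomb_hand_value(self, params):
        # +0.52 e and -1.04 e at 3 A: 332.0637 * (-0.5408) / 3
        a = ParticleSite([0, 0, 0], charge=0.52)
        b = ParticleSite([3, 0, 0], charge=-1.04)
        expected = 332.0637 * 0.52 * (-1.04) / 3.0
        assert pair_energy(a, b, params) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(-59.86, abs=0.01)

    def test_beyond_cutoff_is_zero(self, params):
        a = ParticleSite([0, 0, 0], charge=1.0, lj_sigma=3.0, lj_epsilon=0.2)
        b = ParticleSite([10.5, 0, 0], charge=-1.0, lj_sigma=3.0, lj_epsilon=0.2)
        assert pair_energy(a, b, params) == 0.0

    def test_coincident_sites_error(self, params):
        a = ParticleSite([0, 0, 0], charge=1.0)
        with pytest.raises(ValueError, match="r = 0"):
            pair_energy(a, a, params)

    def test_symmetry(self, params):
        a = ParticleSite([0.3, 0.1, -0.2], lj_sigma=3.1, lj_epsilon=0.15, charge=0.4)
        b = ParticleSite([2.7, -1.0, 0.6], lj_sigma=2.8, lj_epsilon=0.05, charge=-0.2)
        assert pair_energy(a, b, params) == pytest.approx(pair_energy(b, a, params), abs=1e-14)


class TestSwitching:
    def test_plateau_and_cutoff(self, params):
        assert switching_factor(9.5, params) == 1.0
        assert switching_factor(10.0, params) == 0.0
        assert switching_factor(11.0, params) == 0.0
        assert switching_factor(2.0, params) == 1.0

    def test_midpoint_matches_polynomial(self, params):
        # CHARMM form evaluated by hand at r = 9.75, cutoff 10, width 0.5
        rc2, ron2, r2 = 100.0, 90.25, 9.75**2
        expected = (rc2 - r2) ** 2 * (rc2 + 2 * r2 - 3 * ron2) / (rc2 - ron2) ** 3
        got = switching_factor(9.75, params)
        assert got == pytest.approx(expected, rel=1e-12)
        assert 0.0 < got < 1.0

    @given(r=st.floats(0.1, 12.0, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_monotone_region(self, r):
        params = EnergyParams()
        s = switching_factor(r, params)
        assert 0.0 <= s <= 1.0
        if 9.5 <= r <= 10.0:
            assert switching_factor(r + 0.01, params) <= s + 1e-12


class TestRestraint:
    def test_inside_is_free(self):
        region = SimulationRegion([-1, -1, -1], [1, 1, 1], droplet_center=[0, 0, 0], droplet_radius=10)
        assert restraint_energy(WaterMolecule([0, 0, 5]), region) == 0.0

    @pytest.mark.parametrize("excess,expected", [(1.0, 0.75), (2.0, 3.0)])
    def test_half_harmonic_value(self, excess, expected):
        region = SimulationRegion([-1, -1, -1], [1, 1, 1], droplet_center=[0, 0, 0], droplet_radius=10)
        w = WaterMolecule([10 + excess, 0, 0])
        assert restraint_energy(w, region) == pytest.approx(expected)


def _random_state(n_waters, seed, host=None):
    model = WaterModel.tip4p()
    params = EnergyParams()
    region = SimulationRegion([-4, -4, -4], [4, 4, 4], droplet_radius=20)
    st_ = GCMCState(host, model, params, region, B=0.0, rng=seed)
    rng = np.random.default_rng(seed + 1)
    placed = 0
    while placed < n_waters:
        o = rng.uniform(-3.5, 3.5, 3)
        if placed and np.min(np.linalg.norm(st_.oxygens - o, axis=1)) < 2.4:
            continue
        st_.add_water(o, random_rotation(rng))
        placed += 1
    st_.energy = st_.total_energy()
    return st_, rng


class TestDeltaEnergy:
    def test_delete_only_water_in_empty_host(self):
        st_, _ = _random_state(1, 7)
        assert delta_energy_of_move(st_, Deletion(0)) == pytest.approx(-st_.energy, abs=1e-10)

    def test_insertion_far_from_everything(self):
        st_, _ = _random_state(0, 3)
        # inside the droplet but with no partners: only the (zero) restraint
        du = delta_energy_of_move(st_, Insertion(np.array([0.0, 0.0, 0.0]), np.eye(3)))
        assert du == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_incremental_matches_brute_force(self, seed):
        """dU of any move equals full before/after recomputation (<= 1e-8)."""
        host = HostStructure(
            [
                ParticleSite([0, 0, 2], lj_sigma=3.0, lj_epsilon=0.15, charge=0.3),
                ParticleSite([1, -1, -2], lj_sigma=2.8, lj_epsilon=0.1, charge=-0.3),
            ]
        )
        st_, rng = _random_state(4, 10 + seed, host=host)
        before = st_.total_energy()

        # displacement
        i = int(rng.integers(4))
        new_o = st_.oxygens[i] + rng.uniform(-0.3, 0.3, 3)
        new_R = random_rotation(rng)
        du = delta_energy_of_move(st_, Displacement(i, new_o, new_R))
        st2, _ = _random_state(4, 10 + seed, host=host)
        st2.oxygens[i] = new_o
        st2.rotations[i] = new_R
        st2.sites[i] = new_o + st2.model.site_offsets @ new_R.T
        assert du == pytest.approx(st2.total_energy() - before, abs=1e-8)

        # insertion
        o = rng.uniform(-3, 3, 3)
        R = random_rotation(rng)
        du = delta_energy_of_move(st_, Insertion(o, R))
        st3, _ = _random_state(4, 10 + seed, host=host)
        st3.add_water(o, R)
        assert du == pytest.approx(st3.total_energy() - before, abs=1e-8)

    def test_overlap_gives_infinite_not_exception(self):
        st_, _ = _random_state(1, 5)
        du = delta_energy_of_move(st_, Insertion(st_.oxygens[0].copy(), np.eye(3)))
        assert du == np.inf


class TestTotalEnergyInvariance:
    def test_rigid_motion_invariance(self, tip4p, params):
        """Energy is unchanged by translating the whole system."""
        host = HostStructure(
            [ParticleSite([0, 0, 0], lj_sigma=3.0, lj_epsilon=0.15, charge=0.4),
             ParticleSite([2, 1, 0], lj_sigma=3.0, lj_epsilon=0.15, charge=-0.4)]
        )
        region = SimulationRegion([-4, -4, -4], [4, 4, 4], droplet_radius=20)
        rng = np.random.default_rng(0)
        oxy = rng.uniform(-3, 3, (3, 3))
        rots = np.stack([random_rotation(rng) for _ in range(3)])
        sites = oxy[:, None, :] + np.einsum("sk,njk->nsj", tip4p.site_offsets, rots)
        e0 = total_energy(oxy, sites, host, tip4p, params, region)
        shift = np.array([5.0, -3.0, 2.0])
        e1 = total_energy(
            oxy + shift, sites + shift, host.translated(shift), tip4p, params,
            region.translated(shift),
        )
        assert e1 == pytest.approx(e0, abs=1e-8)
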