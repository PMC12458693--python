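"""Synthetic cage hosts, ligand series, planted fixtures and the grid
oracle's own invariants."""

import numpy as np
import pytest

from gcwater.energy import EnergyParams
from gcwater.model import WaterModel
from gcwater.synthetic import (
    LigandSpec,
    SyntheticSystemSpec,
    grid_grand_partition_oracle,
    make_cage_host,
    make_ligand_series,
    make_region,
    one_site_cage,
    planted_trajectory,
    site_well_depth,
    weak_site_cage,
)


class TestSpecValidation:
    def test_sites_too_close(self):
        with pytest.raises(ValueError, match="3 A apart"):
            SyntheticSystemSpec([[0, 0, 0], [2.0, 0, 0]], [-10, -10])

    def test_non_nested_series(self):
        with pytest.raises(ValueError, match="nested"):
            SyntheticSystemSpec(
                [[0, 0, 0], [5, 0, 0]], [-10, -10],
                ligand_series=[LigandSpec(blocked_sites=(0,)), LigandSpec(blocked_sites=(1,))],
            )

    def test_occlusion_of_missing_site(self):
        with pytest.raises(ValueError, match="nonexistent"):
            SyntheticSystemSpec([[0, 0, 0]], [-10], ligand_series=[LigandSpec(blocked_sites=(3,))])

    def test_contact_on_blocked_site(self):
        with pytest.raises(ValueError, match="surviving"):
            SyntheticSystemSpec(
                [[0, 0, 0], [5, 0, 0]], [-10, -10],
                ligand_series=[LigandSpec(blocked_sites=(0,), polar_contacts={0: 0.3})],
            )

    def test_positive_depth_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            SyntheticSystemSpec([[0, 0, 0]], [1.0])


class TestCageHost:
    def test_build_is_deterministic(self):
        h1 = make_cage_host(one_site_cage())
        h2 = make_cage_host(one_site_cage())
        assert np.array_equal(h1.positions, h2.positions)
        assert np.array_equal(h1.charges, h2.charges)

    def test_well_depth_near_target(self):
        spec = one_site_cage()
        host = make_cage_host(spec)
        depth, pos = site_well_depth(host, spec.site_positions[0])
        assert depth == pytest.approx(spec.well_depths[0], abs=0.5)
        assert np.linalg.norm(pos - spec.site_positions[0]) <= 0.5

    def test_crystal_waters_are_designed_positions(self):
        spec = weak_site_cage()
        host = make_cage_host(spec)
        assert np.allclose(host.crystal_water_oxygens, spec.site_positions)

    def test_depth_shallower_than_lj_cage_raises(self):
        # the bare LJ triad already binds more strongly than -0.05 kcal/mol
        with pytest.raises(ValueError, match="shallower"):
            make_cage_host(SyntheticSystemSpec([[0, 0, 0]], [-0.05]))


class TestLigandSeries:
    def _spec(self, qc=0.6):
        return SyntheticSystemSpec(
            [[0, 0, 0], [5.0, 0, 0]], [-13.0, -12.0],
            ligand_series=[
                LigandSpec(),
                LigandSpec(blocked_sites=(0,), polar_contacts={1: qc}),
            ],
        )

    def test_series_shapes(self):
        ligs = make_ligand_series(self._spec())
        assert len(ligs) == 2
        assert ligs[0] == []
        labels = [s.label for s in ligs[1]]
        assert any("occl" in l for l in labels)
        assert any("hb" in l for l in labels)

    def test_compound_is_neutral(self):
        for lig in make_ligand_series(self._spec()):
            assert abs(sum(s.charge for s in lig)) < 1e-12

    def test_polar_contact_strengthens_site(self):
        """Direct energy evaluation: the contact deepens the surviving site."""
        spec = self._spec()
        host = make_cage_host(spec)
        ligs = make_ligand_series(spec)
        bare, _ = site_well_depth(host, spec.site_positions[1])
        dressed, _ = site_well_depth(
            host.with_extra_sites(ligs[1]), spec.site_positions[1]
        )
        assert dressed < bare - 0.5

    def test_empty_series(self):
        assert make_ligand_series(SyntheticSystemSpec([[0, 0, 0]], [-10.0])) == []


class TestPlantedTrajectory:
    def test_full_occupancy_zero_jitter(self):
        sites = np.array([[1.0, 2.0, 3.0]])
        frames = planted_trajectory(sites, [1.0], jitter=0.0, n_frames=25, seed=0)
        assert len(frames) == 25
        assert all(np.allclose(f, sites) for f in frames)

    def test_binomial_occupancy_recovery(self):
        frames = planted_trajectory(np.zeros((1, 3)), [0.5], jitter=0.1, n_frames=10_000, seed=1)
        freq = np.mean([len(f) for f in frames])
        assert freq == pytest.approx(0.5, abs=0.015)

    def test_zero_frames(self):
        assert planted_trajectory(np.zeros((1, 3)), [1.0], 0.1, 0, 0) == []

    def test_deterministic(self):
        a = planted_trajectory(np.zeros((2, 3)) + [[0, 0, 0], [5, 0, 0]], [0.7, 0.4], 0.2, 50, 9)
        b = planted_trajectory(np.zeros((2, 3)) + [[0, 0, 0], [5, 0, 0]], [0.7, 0.4], 0.2, 50, 9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestOracle:
    def test_ideal_gas_mean_n(self, ideal_model):
        """No host: <N>(B) = e^B up to O(1/n_states) discretisation."""
        spec = weak_site_cage()
        region = make_region(spec)
        orc = grid_grand_partition_oracle(
            None, region, [-3.0, -2.0], max_n=2, model=ideal_model,
            spatial_step=0.5, n_orientations=32, z1_refine=1, z1_orientation_factor=1,
        )
        for b in (-3.0, -2.0):
            assert orc.mean_n_at(b) == pytest.approx(np.exp(b), rel=0.02)

    def test_max_n_zero(self, ideal_model):
        spec = weak_site_cage()
        orc = grid_grand_partition_oracle(
            None, make_region(spec), [0.0], max_n=0, model=ideal_model,
            spatial_step=0.5, n_orientations=32, z1_refine=1, z1_orientation_factor=1,
        )
        assert orc.mean_n_at(0.0) == 0.0
        assert orc.ln_xi_at(0.0) == 0.0

    def test_self_consistency_gci_identity(self):
        """-kT dln(Xi) between two B values equals the trapezoid integral of
        the oracle's own <N>(B) on a dense grid (the GCI identity)."""
        spec = weak_site_cage()
        host = make_cage_host(spec)
        orc = grid_grand_partition_oracle(host, make_region(spec), [-2.0], max_n=2,
                                          keep_window_kt=6.0)
        params = EnergyParams()
        b = np.linspace(-6.0, 0.0, 400)
        mean_n = np.array([orc.mean_n_at(x) for x in b])
        lhs = -params.kT * (orc.ln_xi_at(0.0) - orc.ln_xi_at(-6.0))
        rhs = -params.kT * np.trapezoid(mean_n, b)
        assert lhs == pytest.approx(rhs, abs=1e-4)

    def test_refinement_stability(self):
        """Refining the grid and densifying orientations moves the occupancy
        distribution by < 0.03 (the weak site is single-occupancy, so the
        single-particle level carries the whole distribution)."""
        spec = weak_site_cage()
        host = make_cage_host(spec)
        region = make_region(spec)
        coarse = grid_grand_partition_oracle(host, region, [-1.0], max_n=1)
        fine = grid_grand_partition_oracle(
            host, region, [-1.0], max_n=1, spatial_step=0.3, n_orientations=100,
            z1_refine=4, z1_orientation_factor=6,
        )
        p1 = coarse.occupancy_distribution(-1.0)
        p2 = fine.occupancy_distribution(-1.0)
        assert 0.5 * np.abs(p1 - p2).sum() < 0.03

    def test_enumeration_guard(self):
        spec = weak_site_cage()
        with pytest.raises(ValueError, match="guard"):
            grid_grand_partition_oracle(
                make_cage_host(spec), make_region(spec), [0.0], max_n=2,
                spatial_step=0.05,
            )
        with pytest.raises(ValueError, match="max_n"):
            grid_grand_partition_oracle(None, make_region(spec), [0.0], max_n=4)
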