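"""MM/GBSA engine: SASA, Born radii, GB energy, MM terms, binding, decomposition."""

from dataclasses import replace

import numpy as np
import pytest

import tileswitch as tw
from tileswitch._oracle import scalar_born_radii, scalar_total
from tileswitch.energy import (
    COULOMB_CONSTANT,
    BondedTopology,
    GBSettings,
    binding_energy,
    bonded_energy,
    born_radii,
    gb_polar_energy,
    mm_terms,
    sasa,
    total_energy,
)
from tileswitch.ensembles import AtomRecord, ConformerEnsemble
from tileswitch.geometry import random_rotation

from reference import lj_coulomb_double_loop

NO_SALT = GBSettings(salt_molar=0.0)


def _bead_ensemble(coords, charges=None, gb=3.0, eps=0.1, rmh=2.6):
    n = len(coords)
    charges = np.zeros(n) if charges is None else np.asarray(charges, float)
    atoms = tuple(
        AtomRecord(i, "CA", "C", i + 1, "ALA", "A", mass=100.0, charge=charges[i],
                   lj_epsilon=eps, lj_rmin_half=rmh, gb_radius=gb)
        for i in range(n)
    )
    return ConformerEnsemble(atoms, np.asarray(coords, float)[None, :, :])


class TestSasa:
    def test_isolated_atom_matches_sphere_area(self):
        areas = sasa(np.zeros((1, 3)), np.array([1.7]))
        exact = 4 * np.pi * 3.1**2
        assert abs(areas[0] - exact) / exact < 0.01

    def test_distant_atoms_keep_isolated_areas(self):
        coords = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        areas = sasa(coords, np.array([1.7, 2.0]))
        assert areas[0] == pytest.approx(4 * np.pi * 3.1**2, rel=0.01)
        assert areas[1] == pytest.approx(4 * np.pi * 3.4**2, rel=0.01)

    def test_atom_buried_inside_large_sphere_is_zero(self):
        coords = np.zeros((2, 3))
        areas = sasa(coords, np.array([0.5, 3.0]))
        assert areas[0] == 0.0

    def test_cross_check_against_biotite_shrake_rupley(self, rng):
        import biotite.structure as struc

        coords = rng.normal(size=(8, 3)) * 2.5
        radii = rng.uniform(1.4, 2.2, size=8)
        ours = sasa(coords, radii).sum()
        arr = struc.AtomArray(8)
        arr.coord = coords.astype(np.float32)
        arr.chain_id = np.array(["A"] * 8)
        arr.res_id = np.arange(1, 9)
        arr.res_name = np.array(["ALA"] * 8)
        arr.atom_name = np.array(["CA"] * 8)
        arr.element = np.array(["C"] * 8)
        theirs = struc.sasa(arr, probe_radius=1.4, point_number=960, vdw_radii=radii).sum()
        assert ours == pytest.approx(theirs, rel=0.02)

    def test_deterministic_given_point_count(self, rng):
        coords = rng.normal(size=(5, 3)) * 3
        radii = np.full(5, 1.8)
        assert np.array_equal(sasa(coords, radii), sasa(coords, radii))


class TestBornRadii:
    def test_isolated_atom_reduced_radius(self):
        b = born_radii(np.zeros((1, 3)), np.array([2.0]))
        assert b[0] == pytest.approx(2.0 - 0.09, abs=1e-12)

    def test_effective_radii_grow_as_atoms_approach(self):
        radii = np.array([1.5, 1.5])
        prev = None
        for d in (10.0, 6.0, 4.0, 3.0):
            b = born_radii(np.array([[0.0, 0, 0], [d, 0, 0]]), radii)
            if prev is not None:
                assert (b > prev).all()
            prev = b

    def test_toy_cluster_matches_scalar_transcription(self, rng):
        coords = rng.normal(size=(5, 3)) * 2.0
        radii = rng.uniform(1.2, 2.5, size=5)
        fast = born_radii(coords, radii)
        slow = scalar_born_radii([tuple(c) for c in coords], radii.tolist())
        assert np.abs(fast - np.array(slow)).max() < 1e-8


class TestGbPolarEnergy:
    def test_single_ion_analytic_born_formula(self):
        e = gb_polar_energy(np.zeros((1, 3)), np.array([1.0]), np.array([2.0]), NO_SALT)
        exact = -0.5 * (1 - 1 / 80) * COULOMB_CONSTANT / 2.0
        assert e == pytest.approx(exact, abs=0.01)

    def test_zero_charges_zero_energy(self, rng):
        coords = rng.normal(size=(6, 3)) * 4
        assert gb_polar_energy(coords, np.zeros(6), np.full(6, 1.8), NO_SALT) == 0.0

    def test_distant_pair_approaches_screened_coulomb(self):
        r = 200.0
        coords = np.array([[0.0, 0, 0], [r, 0, 0]])
        q = np.array([1.0, 1.0])
        b = np.array([2.0, 2.0])
        total = gb_polar_energy(coords, q, b, NO_SALT)
        self_terms = 2 * gb_polar_energy(np.zeros((1, 3)), q[:1], b[:1], NO_SALT)
        pair = total - self_terms
        expected = -(1 - 1 / 80) * COULOMB_CONSTANT / r
        assert pair == pytest.approx(expected, rel=1e-3)

    def test_magnitude_decreases_with_effective_radius(self):
        small = gb_polar_energy(np.zeros((1, 3)), np.array([1.0]), np.array([1.5]), NO_SALT)
        large = gb_polar_energy(np.zeros((1, 3)), np.array([1.0]), np.array([3.0]), NO_SALT)
        assert abs(large) < abs(small)

    def test_salt_deepens_single_ion_solvation(self):
        """Debye screening of the GB pair term makes solvation of a single ion
        more favorable at physiological salt than in pure water."""
        coords, q, b = np.zeros((1, 3)), np.array([1.0]), np.array([2.0])
        no_salt = gb_polar_energy(coords, q, b, NO_SALT)
        salty = gb_polar_energy(coords, q, b, GBSettings(salt_molar=0.15))
        assert abs(salty) > abs(no_salt)


class TestMmTerms:
    def test_lj_minimum_energy(self):
        coords = np.array([[0.0, 0, 0], [5.2, 0, 0]])  # rmin = 2.6 + 2.6
        ens = _bead_ensemble(coords)
        _, e_vdw, _ = mm_terms(coords, ens.lj_epsilon, ens.lj_rmin_half, ens.charges)
        assert e_vdw == pytest.approx(-0.1, abs=1e-12)

    def test_unit_charges_at_reference_distance(self):
        coords = np.array([[0.0, 0, 0], [3.320637, 0, 0]])
        _, _, e_ele = mm_terms(coords, np.zeros(2), np.zeros(2), np.array([1.0, 1.0]))
        assert e_ele == pytest.approx(100.0, abs=0.01)

    def test_matches_brute_force_double_loop(self, rng):
        coords = rng.normal(size=(7, 3)) * 6
        eps = rng.uniform(0.05, 0.3, 7)
        rmh = rng.uniform(1.5, 2.5, 7)
        q = rng.uniform(-1, 1, 7)
        _, e_vdw, e_ele = mm_terms(coords, eps, rmh, q)
        o_vdw, o_ele = lj_coulomb_double_loop(coords.tolist(), eps, rmh, q)
        assert e_vdw == pytest.approx(o_vdw, abs=1e-9)
        assert e_ele == pytest.approx(o_ele, abs=1e-9)

    def test_topology_exclusions_and_14_scaling(self):
        coords = np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0], [11.4, 0, 0]], float)
        q = np.array([0.5, -0.5, 0.5, -0.5])
        topo = BondedTopology(
            bonds=((0, 1, 10.0, 3.8), (1, 2, 10.0, 3.8), (2, 3, 10.0, 3.8)),
            angles=((0, 1, 2, 5.0, np.pi), (1, 2, 3, 5.0, np.pi)),
            dihedrals=((0, 1, 2, 3, 0.5, 1, 0.0),),
        )
        _, _, e_ele = mm_terms(coords, np.zeros(4), np.zeros(4), q, topology=topo)
        # only the 1-4 pair survives, scaled by 1/1.2
        expected = COULOMB_CONSTANT * 0.5 * -0.5 / 11.4 / 1.2
        assert e_ele == pytest.approx(expected, abs=1e-9)

    def test_bonded_energy_zero_at_equilibrium_geometry(self):
        coords = np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]], float)
        topo = BondedTopology(
            bonds=((0, 1, 10.0, 3.8), (1, 2, 10.0, 3.8)),
            angles=((0, 1, 2, 5.0, np.pi),),
        )
        assert bonded_energy(coords, topo) == pytest.approx(0.0, abs=1e-9)


class TestTotalEnergy:
    def test_zero_charge_zero_gamma_reduces_to_vdw(self, rng):
        coords = rng.normal(size=(5, 3)) * 5
        ens = _bead_ensemble(coords)
        settings = GBSettings(surface_tension=0.0, salt_molar=0.0)
        bd = total_energy(ens, 0, settings)
        assert bd.e_pol == 0 and bd.e_npol == 0 and bd.e_bon == 0
        assert bd.g_total == pytest.approx(bd.e_vdw)

    def test_isolated_ion_combines_born_and_surface_terms(self):
        ens = _bead_ensemble(np.zeros((1, 3)), charges=[1.0], gb=2.0)
        settings = GBSettings(salt_molar=0.0)
        bd = total_energy(ens, 0, settings)
        born = -0.5 * (1 - 1 / 80) * COULOMB_CONSTANT / (2.0 - 0.09)
        surface = 0.0072 * 4 * np.pi * (2.0 + 1.4) ** 2
        assert bd.e_pol == pytest.approx(born, abs=0.01)
        assert bd.e_npol == pytest.approx(surface, rel=0.01)

    def test_components_sum_to_total_for_random_systems(self, rng):
        for _ in range(3):
            coords = rng.normal(size=(6, 3)) * 5
            ens = _bead_ensemble(coords, charges=rng.uniform(-1, 1, 6))
            bd = total_energy(ens, 0)
            assert bd.g_total == pytest.approx(
                bd.e_bon + bd.e_vdw + bd.e_ele + bd.e_pol + bd.e_npol, abs=1e-6
            )

    def test_matches_scalar_transcription(self, toy):
        ens, _ = toy
        bd = total_energy(ens, 0)
        slow = scalar_total(ens.frames[0], ens.lj_epsilon, ens.lj_rmin_half,
                            ens.charges, ens.gb_radius)
        assert bd.g_total == pytest.approx(slow, abs=1e-9)

    def test_rigid_motion_invariance(self, toy, rng):
        ens, _ = toy
        rot = random_rotation(rng)
        moved = ConformerEnsemble(
            ens.atoms, (ens.frames @ rot.T) + np.array([5.0, -3.0, 9.0])
        )
        a = total_energy(ens, 0)
        b = total_energy(moved, 0)
        for field in ("e_vdw", "e_ele", "e_pol"):
            assert getattr(a, field) == pytest.approx(getattr(b, field), abs=1e-6)
        # the fixed Shrake-Rupley point set makes SASA orientation-dependent
        # at the few-per-mille level; only translation invariance is exact
        assert a.e_npol == pytest.approx(b.e_npol, rel=0.02)
        shifted = ConformerEnsemble(ens.atoms, ens.frames + np.array([7.0, 1.0, -2.0]))
        c = total_energy(shifted, 0)
        assert a.e_npol == pytest.approx(c.e_npol, abs=1e-9)


class TestBindingEnergy:
    def _sel(self, chain):
        return tw.Selection(chains=frozenset(chain))

    def test_noninteracting_distant_parts_bind_zero(self):
        coords = np.array([[0.0, 0, 0], [3.8, 0, 0], [500.0, 0, 0], [503.8, 0, 0]])
        atoms = tuple(
            AtomRecord(i, "CA", "C", i + 1, "ALA", "AB"[i // 2], mass=1.0, charge=0.0,
                       lj_epsilon=0.0, lj_rmin_half=2.6, gb_radius=3.0)
            for i in range(4)
        )
        ens = ConformerEnsemble(atoms, coords[None])
        res = binding_energy(ens, self._sel("A"), self._sel("B"),
                             GBSettings(surface_tension=0.0), n_frames=None)
        assert abs(res.delta_g_mean) < 1e-6

    def test_matches_stored_brute_force_oracle(self, toy):
        ens, oracle = toy
        res = binding_energy(ens, self._sel("A"), self._sel("B"), n_frames=None)
        assert res.delta_g_mean == pytest.approx(oracle["delta_g_mean"], abs=1e-6)
        assert res.delta_g_sd == pytest.approx(oracle["delta_g_sd"], abs=1e-6)
        assert np.abs(res.per_frame - oracle["per_frame"]).max() < 1e-6

    def test_frame_duplication_preserves_mean_and_sd(self, toy):
        ens, _ = toy
        doubled = ConformerEnsemble(ens.atoms, np.concatenate([ens.frames, ens.frames]))
        a = binding_energy(ens, self._sel("A"), self._sel("B"), n_frames=None)
        b = binding_energy(doubled, self._sel("A"), self._sel("B"), n_frames=None)
        assert a.delta_g_mean == pytest.approx(b.delta_g_mean, abs=1e-9)
        assert a.delta_g_sd == pytest.approx(b.delta_g_sd, abs=1e-9)

    def test_overlapping_selections_rejected(self, toy):
        ens, _ = toy
        with pytest.raises(ValueError, match="overlap"):
            binding_energy(ens, tw.Selection(), self._sel("B"))


class TestDecomposition:
    def _result(self, toy):
        ens, _ = toy
        return ens, binding_energy(
            ens, tw.Selection(chains=frozenset("A")), tw.Selection(chains=frozenset("B")),
            n_frames=None,
        )

    def test_per_residue_sum_conserves_total(self, toy):
        _, res = self._result(toy)
        total = sum(v[0] for v in res.per_residue.values())
        assert total == pytest.approx(res.delta_g_mean, abs=0.05)

    def test_matches_oracle_per_residue(self, toy):
        ens, res = self._result(toy)
        _, oracle = toy
        for key, (mean, sd) in res.per_residue.items():
            o_mean, o_sd = oracle["per_residue"][key]
            assert mean == pytest.approx(o_mean, abs=1e-6)
            assert sd == pytest.approx(o_sd, abs=1e-6)

    def test_planted_charge_pairs_reach_report_threshold(self, toy):
        _, res = self._result(toy)
        report = res.filtered_report(threshold=-2.0)
        reported = set(zip(report["chain"], report["residue_id"]))
        assert ("A", 1) in reported  # facing K...E pair across the interface
        assert ("B", 101) in reported

    def test_zeroed_residue_contributes_nothing(self, toy):
        ens, _ = toy
        atoms = tuple(
            replace(a, charge=0.0, lj_epsilon=0.0) if a.residue_id == 2 else a
            for a in ens.atoms
        )
        dead = ConformerEnsemble(atoms, ens.frames)
        res = binding_energy(
            dead, tw.Selection(chains=frozenset("A")), tw.Selection(chains=frozenset("B")),
            GBSettings(surface_tension=0.0), n_frames=None,
        )
        mean, sd = res.per_residue[("A", 2, "ALA")]
        assert abs(mean) < 1e-9 and sd < 1e-9
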