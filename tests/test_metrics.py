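"""R_g geometry, distributions, comparison statistics, switch rule, landscapes."""

import warnings

import numpy as np
import pytest

import tileswitch as tw
from tileswitch.geometry import random_rotation
from tileswitch.metrics import RgSeries, rg_histogram, spread_stats, switch_statistic

from reference import ecdf_ks, histogram_counts, rg_direct


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        assert tw.radius_of_gyration(np.zeros((1, 3)), np.array([12.0])) == 0.0

    def test_two_unit_masses_two_angstroms_apart(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert tw.radius_of_gyration(coords, np.ones(2)) == pytest.approx(1.0)

    def test_unit_square(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        rg = tw.radius_of_gyration(coords, np.ones(4))
        assert rg == pytest.approx(0.70711, abs=1e-5)

    def test_matches_direct_formula_with_masses(self, rng):
        coords = rng.normal(size=(20, 3)) * 5
        masses = rng.uniform(50, 200, size=20)
        assert tw.radius_of_gyration(coords, masses) == pytest.approx(
            rg_direct(coords.tolist(), masses.tolist()), abs=1e-12
        )

    def test_rigid_motion_invariance(self, rng):
        coords = rng.normal(size=(30, 3)) * 8
        masses = rng.uniform(50, 200, size=30)
        rot = random_rotation(rng)
        moved = coords @ rot.T + np.array([11.0, -4.0, 7.0])
        assert abs(
            tw.radius_of_gyration(coords, masses) - tw.radius_of_gyration(moved, masses)
        ) < 1e-9

    def test_linear_under_uniform_scaling(self, rng):
        coords = rng.normal(size=(15, 3))
        masses = np.ones(15)
        rg1 = tw.radius_of_gyration(coords, masses)
        rg3 = tw.radius_of_gyration(3.0 * coords, masses)
        assert rg3 == pytest.approx(3.0 * rg1, rel=1e-12)


class TestRgSeries:
    def test_constant_conformation_gives_constant_series(self, compact_ens):
        frames = np.repeat(compact_ens.frames[:1], 5, axis=0)
        ens = tw.ConformerEnsemble(compact_ens.atoms, frames)
        series = tw.rg_series(ens)
        assert np.ptp(series.values) == 0

    def test_two_state_ensemble_is_bimodal_per_labels(self):
        spec = tw.MixtureSpec(0.5, tw.compact_model(), tw.extended_model(), 200, seed=77)
        ens, labels = tw.mixture_ensemble(spec)
        series = tw.rg_series(ens)
        compact_mean = series.values[labels == "compact"].mean()
        extended_mean = series.values[labels == "extended"].mean()
        assert compact_mean < 14 < extended_mean

    def test_rotated_frame_same_value(self, compact_ens, rng):
        rot = random_rotation(rng)
        frames = compact_ens.frames.copy()
        frames[0] = frames[0] @ rot.T
        ens = tw.ConformerEnsemble(compact_ens.atoms, frames)
        a = tw.rg_series(compact_ens).values[0]
        b = tw.rg_series(ens).values[0]
        assert a == pytest.approx(b, abs=1e-9)


class TestRgHistogram:
    def test_identical_values_single_occupied_bin(self):
        dist = rg_histogram(RgSeries(np.full(50, 12.3)))
        assert np.count_nonzero(dist.frequencies) == 1
        assert dist.frequencies.max() == pytest.approx(1.0)

    def test_matches_direct_counting(self, rng):
        values = rng.uniform(2, 38, size=300)
        dist = rg_histogram(RgSeries(values), bin_width=2.0)
        counts = histogram_counts(values.tolist(), dist.bin_edges.tolist())
        assert np.allclose(dist.frequencies, np.array(counts) / 300)

    def test_total_mass_conserved_under_refinement(self, rng):
        values = rng.uniform(0, 40, size=500)
        for width in (4.0, 1.0, 0.25):
            dist = rg_histogram(RgSeries(values), bin_width=width)
            assert dist.frequencies.sum() == pytest.approx(1.0, abs=1e-9)

    def test_nonpositive_bin_width_rejected(self):
        with pytest.raises(ValueError):
            rg_histogram(RgSeries(np.array([1.0, 2.0])), bin_width=0.0, range_=None)


class TestKsStatistic:
    def test_identical_series_zero(self, rng):
        v = rng.normal(10, 2, size=100)
        assert tw.ks_statistic(RgSeries(v), RgSeries(v.copy())) == 0.0

    def test_disjoint_supports_one(self, rng):
        a = RgSeries(rng.uniform(1, 5, 80))
        b = RgSeries(rng.uniform(20, 30, 80))
        assert tw.ks_statistic(a, b) == pytest.approx(1.0)

    def test_matches_brute_force_ecdf_sweep(self, rng):
        a = RgSeries(np.abs(rng.normal(12, 3, 150)))
        b = RgSeries(np.abs(rng.normal(14, 5, 120)))
        expected = ecdf_ks(a.values.tolist(), b.values.tolist())
        assert tw.ks_statistic(a, b) == pytest.approx(expected, abs=1e-12)
        assert tw.ks_statistic(b, a) == pytest.approx(expected, abs=1e-12)

    def test_triangle_like_bound(self, rng):
        a = RgSeries(rng.normal(10, 2, 60))
        b = RgSeries(rng.normal(12, 2, 60))
        c = RgSeries(rng.normal(15, 2, 60))
        assert tw.ks_statistic(a, c) <= tw.ks_statistic(a, b) + tw.ks_statistic(b, c) + 1e-12


class TestSpreadStats:
    def test_constant_series(self):
        stats = spread_stats(RgSeries(np.full(30, 9.0)))
        assert stats["sd"] == 0 and stats["iqr"] == 0 and stats["tail_fraction"] == 0

    def test_gaussian_sample_recovers_parameters(self, rng):
        n = 4000
        stats = spread_stats(RgSeries(np.abs(rng.normal(20, 2, size=n))))
        assert abs(stats["mean"] - 20) < 3 * 2 / np.sqrt(n)
        assert abs(stats["sd"] - 2) < 3 * 2 / np.sqrt(2 * n)

    def test_duplication_leaves_statistics_unchanged(self, rng):
        v = rng.uniform(5, 30, size=101)
        s1 = spread_stats(RgSeries(v))
        s2 = spread_stats(RgSeries(np.concatenate([v, v])))
        assert s2["mean"] == pytest.approx(s1["mean"])
        assert s2["sd"] == pytest.approx(s1["sd"])
        assert s2["tail_fraction"] == pytest.approx(s1["tail_fraction"])
        # percentile-based widths use linear interpolation; duplication shifts
        # plotting positions by O(1/n)
        assert s2["iqr"] == pytest.approx(s1["iqr"], rel=0.02)
        assert s2["p5_p95_width"] == pytest.approx(s1["p5_p95_width"], rel=0.02)


class TestSwitchStatistic:
    def test_identical_ensembles_score_zero(self, rng):
        v = RgSeries(rng.uniform(5, 30, 200))
        score = switch_statistic(v, RgSeries(v.values.copy()))
        assert score.mean_shift == 0
        assert score.spread_reduction == 0
        assert score.tail_depletion == 0
        assert score.ks_d == 0
        assert not score.flagged

    def test_planted_compaction_is_flagged(self):
        spec = tw.MixtureSpec(0.5, tw.compact_model(), tw.extended_model(), 150, seed=41)
        broad, _ = tw.mixture_ensemble(spec)
        compact = tw.sample_chain(tw.compact_model(), 150, seed=42)
        score = switch_statistic(tw.rg_series(broad), tw.rg_series(compact))
        assert score.flagged
        assert score.tail_depletion > 0.25
        assert score.mean_shift > 0

    def test_exchanged_arguments_negate_mean_shift(self, rng):
        a = RgSeries(rng.normal(15, 4, 100))
        b = RgSeries(rng.normal(11, 1, 100))
        fwd = switch_statistic(a, b)
        rev = switch_statistic(b, a)
        assert fwd.mean_shift == pytest.approx(-rev.mean_shift)

    def test_degenerate_reference_reported_not_flagged(self):
        ref = RgSeries(np.full(50, 10.0))
        pert = RgSeries(np.linspace(8, 12, 50))
        score = switch_statistic(ref, pert)
        assert score.degenerate_reference
        assert score.spread_reduction == 0
        assert not score.flagged


class TestLandscape:
    def test_two_point_normalization(self):
        lscape = tw.landscape(RgSeries(np.array([10.0, 20.0])), np.array([-100.0, -50.0]))
        assert np.allclose(lscape.energy_norm, [0.0, 1.0])

    def test_affine_energy_invariance(self, rng):
        series = RgSeries(rng.uniform(5, 30, 50))
        energies = rng.normal(-500, 30, 50)
        base = tw.landscape(series, energies)
        shifted = tw.landscape(series, 3.0 * energies + 42.0)
        assert np.allclose(base.energy_norm, shifted.energy_norm)

    def test_joint_vs_separate_normalization_hand_check(self):
        """Four points, two per condition: pooled min-max is (-10, 2) so the
        reference pair maps to (0, 1/2) jointly but (0, 1) separately."""
        ref = RgSeries(np.array([10.0, 12.0]))
        pert = RgSeries(np.array([8.0, 9.0]))
        ref_e = np.array([-10.0, -4.0])
        pert_e = np.array([-6.0, 2.0])
        joint_ref, joint_pert = tw.paired_landscapes(ref, ref_e, pert, pert_e, "joint")
        assert np.allclose(joint_ref.energy_norm, [0.0, 0.5])
        assert np.allclose(joint_pert.energy_norm, [1.0 / 3.0, 1.0])
        sep_ref, sep_pert = tw.paired_landscapes(ref, ref_e, pert, pert_e, "separate")
        assert np.allclose(sep_ref.energy_norm, [0.0, 1.0])
        assert np.allclose(sep_pert.energy_norm, [0.0, 1.0])

    def test_flat_energies_warn_and_zero(self):
        with pytest.warns(UserWarning, match="identical"):
            lscape = tw.landscape(RgSeries(np.array([10.0, 11.0])), np.array([5.0, 5.0]))
        assert np.allclose(lscape.energy_norm, 0.0)
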