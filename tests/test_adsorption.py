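"""Vapor-exposed area, adsorption scores, sequence mining, kinetics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from surfads.adsorption import (adsorption_score, aads_timeseries,
                                cumulative_hydrophobic_sasa, delta_sasa,
                                hydrophobicity_area_stats,
                                mine_adsorbing_sequences,
                                normalized_sequence_area,
                                sequence_hydrophobicity,
                                species_composition, surface_free_energy,
                                time_average, vapor_exposed_area,
                                AdsorbingSequence)
from surfads.core import Frame, Trajectory, load_default_scale
from surfads.interface import InterfacePair
from surfads.sasa import compute_sasa
from surfads import synthetic as syn


def _plane(z_upper, z_lower=-1000.0):
    return InterfacePair(z_lower=z_lower, z_upper=z_upper,
                         bulk_density=33.0, method="test")


class TestVaporExposedArea:
    def test_half_exposed_sphere(self):
        system, oracle = syn.make_sphere_system(0.17, 0.0, 5.0, 0.2)
        result = vapor_exposed_area(system, _plane(5.0), 0.2, 960)
        assert oracle == pytest.approx(2 * math.pi * 0.37 ** 2)
        assert result.total == pytest.approx(oracle, rel=0.01)

    def test_deep_submersion_gives_zero(self):
        system, oracle = syn.make_sphere_system(0.17, -0.5, 5.0, 0.2)
        result = vapor_exposed_area(system, _plane(5.0), 0.2, 960)
        assert oracle == 0.0
        assert result.total == 0.0

    def test_spherical_cap_closed_form(self):
        system, oracle = syn.make_sphere_system(0.17, 0.1, 5.0, 0.2)
        result = vapor_exposed_area(system, _plane(5.0), 0.2, 960)
        assert oracle == pytest.approx(2 * math.pi * 0.37 * 0.47)
        assert result.total == pytest.approx(oracle, rel=0.01)

    def test_z_scan_is_monotone(self):
        offsets = np.linspace(-0.6, 0.6, 25)
        totals = []
        for off in offsets:
            system, _ = syn.make_sphere_system(0.17, float(off), 5.0, 0.2)
            totals.append(vapor_exposed_area(system, _plane(5.0),
                                             0.2, 960).total)
        diffs = np.diff(totals)
        assert np.all(diffs >= 0)

    def test_partition_and_bound(self, mixed_peptide):
        pep = mixed_peptide.translated([0, 0, 5.0])
        result = vapor_exposed_area(pep, _plane(5.0), 0.2, 960)
        assert result.per_residue.sum() == pytest.approx(result.total,
                                                         abs=1e-6)
        assert result.per_atom.sum() == pytest.approx(result.total,
                                                      abs=1e-6)
        assert result.total <= result.sasa.total_area + 1e-9
        assert np.all(result.per_residue
                      <= result.sasa.per_residue_area + 1e-9)

    def test_lower_interface_also_counts_as_vapor(self):
        system, _ = syn.make_sphere_system(0.17, 0.0, 5.0, 0.2)
        # sphere sits on the LOWER plane of a slab above it
        pair = InterfacePair(z_lower=5.0, z_upper=20.0, bulk_density=33.0)
        result = vapor_exposed_area(system, pair, 0.2, 960)
        assert result.total == pytest.approx(2 * math.pi * 0.37 ** 2,
                                             rel=0.01)


class TestAadsTimeseries:
    def test_static_frames_give_constant_series(self, ala_leu_ala):
        pep = ala_leu_ala.translated([0, 0, 5.0])
        frames = [Frame(0.1 * k, pep.positions) for k in range(5)]
        traj = Trajectory(pep, frames)
        series, total = aads_timeseries(traj, _plane(5.0), 0.2, 960)
        single = vapor_exposed_area(pep, _plane(5.0), 0.2, 960)
        assert np.allclose(total, single.total)
        for s, expected in zip(series, single.per_residue):
            assert np.allclose(s.aads, expected)

    def test_submerged_trajectory_is_all_zero(self, ala_leu_ala):
        sched = syn.make_protrusion_schedule(6, "submerged", z_min=-2.0)
        traj, oracle, pair = syn.make_adsorption_trajectory(
            ala_leu_ala, sched)
        _, total = aads_timeseries(traj, pair, 0.2, 960)
        assert np.all(oracle == 0)
        assert np.all(total == 0)

    def test_planted_protrusion_matches_oracle(self, mixed_peptide):
        sched = syn.make_protrusion_schedule(12, "mixed", seed=4)
        traj, oracle, pair = syn.make_adsorption_trajectory(
            mixed_peptide, sched)
        _, total = aads_timeseries(traj, pair, 0.2, 960)
        floor = 3 * 4 * math.pi * (mixed_peptide.radii.max() + 0.2)**2 / 960
        assert np.all(np.abs(total - oracle)
                      <= np.maximum(0.05 * oracle, floor))

    def test_interface_count_mismatch_rejected(self, ala_leu_ala):
        frames = [Frame(0.1 * k, ala_leu_ala.positions) for k in range(3)]
        traj = Trajectory(ala_leu_ala, frames)
        with pytest.raises(ValueError, match="interface"):
            aads_timeseries(traj, [_plane(5.0)] * 2, 0.2, 960)


class TestTimeAverage:
    def test_constant_series(self):
        assert time_average(np.full(10, 3.3), 0.75) == pytest.approx(3.3)

    def test_trailing_half(self):
        assert time_average(np.array([0.0, 0, 4, 4]), 0.5) == 4.0

    def test_linear_ramp_matches_direct_mean(self):
        ramp = np.linspace(0, 10, 200)
        assert time_average(ramp, 0.75) == pytest.approx(ramp[50:].mean())

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            time_average(np.ones(5), 0.0)


class TestDeltaSasa:
    def test_identical_inputs_zero_and_antisymmetry(self, mixed_peptide):
        a = compute_sasa(mixed_peptide, 0.14, 960)
        assert np.all(delta_sasa(a, a) == 0)
        rot = syn.make_toy_peptide("ALA LEU VAL GLY PHE SER",
                                   geometry="helixlike")
        b = compute_sasa(rot, 0.14, 960)
        assert np.array_equal(delta_sasa(a, b), -delta_sasa(b, a))

    def test_direct_subtraction(self, mixed_peptide):
        helix = syn.make_toy_peptide("ALA LEU VAL GLY PHE SER",
                                     geometry="helixlike")
        a = compute_sasa(mixed_peptide, 0.14, 960)
        b = compute_sasa(helix, 0.14, 960)
        assert np.array_equal(delta_sasa(a, b),
                              b.per_residue_area - a.per_residue_area)

    def test_mismatched_tables_rejected(self, mixed_peptide, ala_leu_ala):
        a = compute_sasa(mixed_peptide, 0.14, 960)
        b = compute_sasa(ala_leu_ala, 0.14, 960)
        with pytest.raises(ValueError, match="residue tables"):
            delta_sasa(a, b)


class TestAdsorptionScore:
    def test_all_contributing(self):
        table = adsorption_score(np.full((9, 1), 0.6))
        assert table["score_nm2"][0] == pytest.approx(0.6)
        assert table["n_contributing"][0] == 9

    def test_none_contributing(self):
        table = adsorption_score(np.full((9, 1), 0.4))
        assert table["score_nm2"][0] == 0.0
        assert table["n_contributing"][0] == 0

    def test_mixed_conventions(self):
        values = np.array([[0.8, 0.6, 0.4, 0, 0, 0, 0, 0, 0]]).T
        default = adsorption_score(values)
        assert default["score_nm2"][0] == pytest.approx(0.7)
        alt = adsorption_score(values, denominator="total")
        assert alt["score_nm2"][0] == pytest.approx(1.4 / 9)
        assert alt.attrs["denominator"] == "total"

    def test_exact_cutoff_does_not_contribute(self):
        table = adsorption_score(np.array([[0.5], [0.5]]))
        assert table["score_nm2"][0] == 0.0


class TestSequenceMining:
    def test_simple_runs(self):
        pep = syn.make_toy_peptide("ALA ALA ALA ALA ALA ALA")
        areas = [0, 0.2, 0.3, 0, 0.15, 0.15]
        seqs, singles = mine_adsorbing_sequences(areas, pep, 0.1)
        assert [(s.start, s.end) for s in seqs] == [(1, 2), (4, 5)]
        assert singles == []

    def test_all_below_threshold(self):
        pep = syn.make_toy_peptide("AAAA")
        seqs, singles = mine_adsorbing_sequences([0.05] * 4, pep, 0.1)
        assert seqs == [] and singles == []

    def test_singletons_reported_separately(self):
        pep = syn.make_toy_peptide("AAAAA")
        seqs, singles = mine_adsorbing_sequences(
            [0.5, 0, 0.5, 0.5, 0], pep, 0.1)
        assert [(s.start, s.end) for s in seqs] == [(2, 3)]
        assert [(s.start, s.end) for s in singles] == [(0, 0)]

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.booleans(), min_size=2, max_size=60))
    def test_planted_runs_recovered(self, pattern):
        pep = syn.make_toy_peptide("A" * len(pattern))
        areas = [0.3 if p else 0.02 for p in pattern]
        seqs, singles = mine_adsorbing_sequences(areas, pep, 0.1)
        # reconstruct membership and compare with the planted pattern
        member = np.zeros(len(pattern), dtype=bool)
        for s in seqs + singles:
            member[s.start:s.end + 1] = True
            assert all(a > 0.1 for a in s.mean_aads)
        assert member.tolist() == pattern
        # maximality: adjacent residues of any run are below threshold
        for s in seqs + singles:
            if s.start > 0:
                assert not pattern[s.start - 1]
            if s.end < len(pattern) - 1:
                assert not pattern[s.end + 1]


class TestSequenceStatistics:
    def _seq(self, names, areas):
        return AdsorbingSequence(chain_id="A", start=0, end=len(names) - 1,
                                 residue_names=names, mean_aads=areas,
                                 threshold=0.1)

    def test_normalized_area_is_per_residue_mean(self):
        assert normalized_sequence_area(
            self._seq(["ALA"] * 3, [0.6, 0.2, 0.4])) == pytest.approx(0.4)

    def test_normalized_area_linearity(self):
        seq = self._seq(["ALA"] * 3, [0.6, 0.2, 0.4])
        doubled = self._seq(["ALA"] * 3, [1.2, 0.4, 0.8])
        assert normalized_sequence_area(doubled) == pytest.approx(
            2 * normalized_sequence_area(seq))

    def test_hydrophobicity_sums_members(self):
        scale = load_default_scale()
        seq = self._seq(["GLY", "VAL", "PRO"], [0.2, 0.2, 0.2])
        expected = scale["VAL"] + scale["PRO"]
        assert sequence_hydrophobicity(seq) == pytest.approx(expected)
        # glycine adds exactly zero under the shifted scale
        no_gly = self._seq(["VAL", "PRO"], [0.2, 0.2])
        assert sequence_hydrophobicity(no_gly) == pytest.approx(expected)

    def test_all_glycine_is_zero(self):
        assert sequence_hydrophobicity(
            self._seq(["GLY"] * 4, [0.2] * 4)) == 0.0


class TestHydrophobicityAreaStats:
    def test_exact_linear_limit(self):
        names = ["LEU", "VAL", "PHE", "TRP", "ILE", "MET"] * 4
        scale = load_default_scale()
        areas = [0.3 + 0.5 * scale[n] for n in names]
        stats = hydrophobicity_area_stats(names, areas, floor=0.0)
        assert stats.pearson_r == pytest.approx(1.0)
        assert stats.slope == pytest.approx(0.5)

    def test_constant_groups_have_zero_sd(self):
        names = ["LEU", "LEU", "VAL", "VAL"]
        stats = hydrophobicity_area_stats(names, [0.4, 0.4, 0.2, 0.2],
                                          floor=0.0)
        assert np.allclose(stats.group_sd, 0.0)

    def test_planted_slope_recovery(self):
        rng = np.random.default_rng(13)
        scale = load_default_scale()
        names = list(rng.choice(
            ["LEU", "VAL", "PHE", "TRP", "ILE", "ALA", "PRO"], size=100))
        rh = np.array([scale[n] for n in names])
        areas = 0.3 + 0.05 * rh + rng.normal(0, 0.02, size=100)
        stats = hydrophobicity_area_stats(names, areas, floor=0.0)
        assert abs(stats.slope - 0.05) < 3 * stats.slope_stderr

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            hydrophobicity_area_stats(["LEU"], [0.5], floor=0.1)


class TestSpeciesComposition:
    def test_hand_worked_percentages(self):
        pep = syn.make_toy_peptide("LEU LEU LEU VAL GLY")
        pct, frac = species_composition([0.6, 0.7, 0.8, 0.9, 0.1], pep,
                                        cutoff=0.5,
                                        restrict_to_hydrophobic=True)
        assert pct == {"LEU": pytest.approx(75.0), "VAL": pytest.approx(25.0)}
        assert frac == 1.0

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(7)
        seq = list(rng.choice(["LEU", "VAL", "PRO", "SER", "ARG"], size=40))
        pep = syn.make_toy_peptide(seq)
        areas = rng.uniform(0, 1.2, size=40)
        if not np.any(areas > 0.5):
            areas[0] = 0.6
        pct, _ = species_composition(areas, pep, cutoff=0.5)
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-9)

    def test_empty_restricted_set_errors(self):
        pep = syn.make_toy_peptide("GLY GLY SER")
        with pytest.raises(ValueError):
            species_composition([0.6, 0.6, 0.6], pep, cutoff=0.5,
                                restrict_to_hydrophobic=True)

    def test_planted_composition_recovered(self):
        seq = ["LEU"] * 4 + ["VAL"] * 2 + ["PRO"] * 1 + ["SER"] * 3
        pep = syn.make_toy_peptide(seq)
        areas = [0.8] * 10
        pct, frac = species_composition(areas, pep, cutoff=0.5)
        assert pct["LEU"] == pytest.approx(40.0)
        assert pct["VAL"] == pytest.approx(20.0)
        assert pct["PRO"] == pytest.approx(10.0)
        assert pct["SER"] == pytest.approx(30.0)
        assert frac == pytest.approx(0.7)


class TestCumulativeHydrophobicSasa:
    def test_constant_structure_gives_static_sum(self, ala_leu_ala):
        frames = [Frame(0.1 * k, ala_leu_ala.positions) for k in range(12)]
        traj = Trajectory(ala_leu_ala, frames)
        times, smoothed = cumulative_hydrophobic_sasa(
            traj, [0, 1, 2], running_window=10)
        static = compute_sasa(ala_leu_ala, 0.14, 960).per_residue_area.sum()
        assert len(smoothed) == 3
        assert np.allclose(smoothed, static)

    def test_window_one_is_identity(self, ala_leu_ala):
        frames = [Frame(0.1 * k, ala_leu_ala.positions + [0, 0, 0.01 * k])
                  for k in range(4)]
        traj = Trajectory(ala_leu_ala, frames)
        _, smoothed = cumulative_hydrophobic_sasa(traj, [1],
                                                  running_window=1)
        direct = [compute_sasa(traj.system_at(k), 0.14,
                               960).per_residue_area[1] for k in range(4)]
        assert np.allclose(smoothed, direct)

    def test_progressive_extension_is_nondecreasing(self):
        pep = syn.make_toy_peptide("ALA LEU ALA")
        cb = 3  # LEU side-chain bead
        frames = []
        for k in range(8):
            pos = pep.positions.copy()
            pos[cb, 1] += 0.05 * k   # pull the side chain outward
            frames.append(Frame(0.1 * k, pos))
        traj = Trajectory(pep, frames)
        _, smoothed = cumulative_hydrophobic_sasa(traj, [1],
                                                  running_window=3)
        assert np.all(np.diff(smoothed) >= -1e-9)

    def test_window_longer_than_series_rejected(self, ala_leu_ala):
        frames = [Frame(0.1 * k, ala_leu_ala.positions) for k in range(3)]
        traj = Trajectory(ala_leu_ala, frames)
        with pytest.raises(ValueError, match="window"):
            cumulative_hydrophobic_sasa(traj, [0], running_window=10)


class TestSurfaceFreeEnergy:
    def test_zero_area_zero_energy(self):
        assert surface_free_energy(0.0).joules == 0.0

    def test_unit_conversion(self):
        fe = surface_free_energy(1.0, gamma_mN_per_m=62.0,
                                 temperature_K=300.0)
        assert fe.joules == pytest.approx(62e-21)
        assert fe.kBT == pytest.approx(14.97, abs=0.01)

    def test_linearity(self):
        base = surface_free_energy(1.0, 62.0).kBT
        assert surface_free_energy(2.0, 62.0).kBT == pytest.approx(2 * base)
        assert surface_free_energy(1.0, 124.0).kBT == pytest.approx(2 * base)
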