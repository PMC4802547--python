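"""Contact maps, the 10-zone directory, window and replicate averaging."""

import numpy as np
import pytest

from memsurf import (
    ContactMap,
    assign_domains,
    average_maps,
    contact_map,
    zone_directory,
    zone_stats,
)
from memsurf.model import Atom, DomainPartition, System

from conftest import brute_force_min_image


def _residue_cloud(rng, n_res, atoms_per_res=3, box_side=30.0):
    atoms = []
    serial = 1
    for r in range(1, n_res + 1):
        centre = rng.uniform(0, box_side, 3)
        for _ in range(atoms_per_res):
            atoms.append(Atom(serial, "C", "C", r, "GLY", "A",
                              centre + rng.normal(0, 1.0, 3), 1, "protein"))
            serial += 1
    return System(atoms, box=(box_side, box_side, box_side))


class TestContactMap:
    def test_two_single_atom_residues(self):
        atoms = [
            Atom(1, "CA", "C", 1, "GLY", "A", np.zeros(3), 1, "protein"),
            Atom(2, "CA", "C", 2, "GLY", "A", np.array([0, 0, 5.0]), 1, "protein"),
        ]
        m = contact_map(System(atoms))
        assert m.matrix[0, 1] == pytest.approx(0.5)  # nm
        assert m.matrix[1, 0] == pytest.approx(0.5)

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(0)
        m = contact_map(_residue_cloud(rng, 8))
        np.testing.assert_allclose(m.matrix, m.matrix.T)
        np.testing.assert_allclose(np.diag(m.matrix), 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        frame = _residue_cloud(rng, 10)
        m = contact_map(frame)
        box = frame.box
        coords = {}
        for a in frame.atoms:
            coords.setdefault(a.residue_index, []).append(a.position)
        for i in range(10):
            for j in range(i + 1, 10):
                expected = brute_force_min_image(
                    np.array(coords[i + 1]), np.array(coords[j + 1]), box).min()
                assert m.matrix[i, j] * 10.0 == pytest.approx(expected, abs=1e-9)

    def test_hydrogens_excluded_by_default(self):
        atoms = [
            Atom(1, "CA", "C", 1, "GLY", "A", np.zeros(3), 1, "protein"),
            Atom(2, "CA", "C", 2, "GLY", "A", np.array([0, 0, 6.0]), 1, "protein"),
            Atom(3, "H", "H", 2, "GLY", "A", np.array([0, 0, 3.0]), 1, "protein"),
        ]
        system = System(atoms)
        assert contact_map(system).matrix[0, 1] == pytest.approx(0.6)
        assert contact_map(system, heavy_only=False).matrix[0, 1] == pytest.approx(0.3)

    def test_needs_two_residues(self):
        atoms = [Atom(1, "CA", "C", 1, "GLY", "A", np.zeros(3), 1, "protein")]
        with pytest.raises(ValueError):
            contact_map(System(atoms))


class TestZoneDirectory:
    def test_ten_zones(self, d42):
        directory = zone_directory(assign_domains(d42, 17))
        assert len(directory.zones) == 10

    def test_pair_assignments(self, d42):
        directory = zone_directory(assign_domains(d42, 17))
        assert directory.zones[directory.zone_of(1, 1)] == frozenset({"N_A"})
        assert directory.zones[directory.zone_of(5, 60)] == frozenset({"N_A", "C_B"})
        assert directory.zones[directory.zone_of(20, 70)] == frozenset({"C_A", "C_B"})
        assert 1 <= directory.zone_of(5, 60) <= 10

    def test_zone_layout_within_then_across(self, d42):
        directory = zone_directory(assign_domains(d42, 17))
        for zid in (1, 2, 3):
            assert all("_A" in m for m in directory.zones[zid])
        for zid in (4, 5, 6):
            assert all("_B" in m for m in directory.zones[zid])
        for zid in (7, 8, 9, 10):
            chains = {m.split("_")[1] for m in directory.zones[zid]}
            assert chains == {"A", "B"}

    def test_every_pair_maps_to_exactly_one_zone(self, d42):
        part = assign_domains(d42, 17)
        directory = zone_directory(part)
        residues = part.residues
        count = 0
        for i, ri in enumerate(residues):
            for rj in residues[i + 1:]:
                directory.zone_of(ri, rj)  # raises if unmapped
                count += 1
        assert count == 84 * 83 // 2  # strict i<j convention, diagonal excluded

    def test_two_chains_required(self):
        part = DomainPartition(2, {"A": {"N": [1, 2], "C": [3, 4]}})
        with pytest.raises(ValueError):
            zone_directory(part)


def _const_map(value, n=4):
    m = np.full((n, n), float(value))
    np.fill_diagonal(m, 0.0)
    return ContactMap(list(range(1, n + 1)), m)


class TestAveraging:
    def test_single_frame_identity(self):
        m = _const_map(2.0)
        avg = average_maps({"rep1": [(0.0, m)]}, window_ns=50.0)
        np.testing.assert_allclose(avg.matrix, m.matrix)

    def test_two_constant_replicates(self):
        avg = average_maps({"r1": [(0.0, _const_map(1.0))],
                            "r2": [(0.0, _const_map(3.0))]}, window_ns=50.0)
        np.testing.assert_allclose(avg.matrix, _const_map(2.0).matrix)

    def test_two_stage_equals_flat_mean_for_equal_frame_counts(self):
        rng = np.random.default_rng(8)
        reps = {}
        all_mats = []
        for r in range(3):
            maps = []
            for k in range(5):
                mat = rng.uniform(0.1, 5.0, (4, 4))
                mat = (mat + mat.T) / 2
                np.fill_diagonal(mat, 0.0)
                maps.append((60.0 + k, ContactMap(list(range(1, 5)), mat)))
                all_mats.append(mat)
            reps[f"rep{r}"] = maps
        avg = average_maps(reps, window_ns=4.0)
        np.testing.assert_allclose(avg.matrix, np.mean(all_mats, axis=0))

    def test_window_selects_trailing_frames(self):
        maps = [(0.0, _const_map(10.0)), (60.0, _const_map(1.0)),
                (100.0, _const_map(3.0))]
        avg = average_maps({"rep1": maps}, window_ns=50.0)
        np.testing.assert_allclose(avg.matrix, _const_map(2.0).matrix)

    def test_short_replicate_error_names_it(self):
        maps = [(0.0, _const_map(1.0)), (10.0, _const_map(2.0))]
        with pytest.raises(ValueError, match="repX"):
            average_maps({"repX": maps}, window_ns=50.0)

    def test_output_stays_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(9)
        mat = rng.uniform(0.1, 2.0, (5, 5))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0.0)
        avg = average_maps({"r": [(0.0, ContactMap(list(range(1, 6)), mat))]},
                           window_ns=50.0)
        np.testing.assert_allclose(avg.matrix, avg.matrix.T)
        np.testing.assert_allclose(np.diag(avg.matrix), 0.0)


class TestZoneStats:
    def _directory(self):
        # two residues per domain so within-domain zones have an i<j pair
        part = DomainPartition(2, {
            "A": {"N": [1, 2], "C": [3, 4]},
            "B": {"N": [5, 6], "C": [7, 8]},
        })
        return zone_directory(part)

    def test_identical_replicates_have_zero_sem(self):
        directory = self._directory()
        reps = {f"r{k}": [(0.0, _const_map(2.0, 8))] for k in range(4)}
        stats = zone_stats(reps, directory, window_ns=50.0)
        assert stats.n_replicates == 4
        assert len(stats.means) == 10
        for z in stats.sems:
            assert stats.sems[z] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_sem(self):
        directory = self._directory()
        reps = {"r1": [(0.0, _const_map(1.0, 8))], "r2": [(0.0, _const_map(2.0, 8))]}
        stats = zone_stats(reps, directory, window_ns=50.0)
        cross = [z for z, m in directory.zones.items() if len(m) == 2][0]
        assert stats.means[cross] == pytest.approx(1.5)
        assert stats.sems[cross] == pytest.approx(0.5)

    def test_single_replicate_sem_is_not_available(self):
        stats = zone_stats({"r1": [(0.0, _const_map(1.0, 8))]}, self._directory(),
                           window_ns=50.0)
        assert all(np.isnan(s) for s in stats.sems.values())
        # but means equal that replicate's zone means exactly
        cross = [z for z, m in self._directory().zones.items() if len(m) == 2][0]
        assert stats.means[cross] == pytest.approx(1.0)

    def test_within_domain_zones_exclude_diagonal(self, d42):
        # a map with zeros on the diagonal and 2 nm elsewhere: within-domain
        # means must not be deflated by the diagonal zeros
        part = assign_domains(d42, 17)
        directory = zone_directory(part)
        n = 84
        mat = np.full((n, n), 2.0)
        np.fill_diagonal(mat, 0.0)
        cmap = ContactMap(list(range(1, n + 1)), mat)
        stats = zone_stats({"r": [(0.0, cmap)]}, directory, window_ns=50.0)
        for z in stats.means:
            assert stats.means[z] == pytest.approx(2.0)
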