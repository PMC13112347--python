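"""Interface statistics, segment selection, RMSD, extension intervals,
MSA frequencies."""

import numpy as np
import pytest

import zernipep as zp
from zernipep.analysis import ContactProfile, SegmentSelection
from zernipep.errors import EmptyInputError, NoSegmentError
from zernipep.fixtures import ContactSchedule, make_synthetic_trajectory


def two_ca_frame(distance):
    a = zp.ResidueRecord("A", 1, "ALA", [zp.AtomRecord("CA", "C", (0.0, 0.0, 0.0))])
    b = zp.ResidueRecord("B", 1, "ALA", [zp.AtomRecord("CA", "C", (distance, 0.0, 0.0))])
    return zp.ChainStructure({"A": [a], "B": [b]})


class TestInterfaceResidues:
    def test_just_inside_cutoff(self):
        sa, sb = zp.interface_residues(two_ca_frame(7.9), "A", "B", 8.0)
        assert sa == {1} and sb == {1}

    def test_exactly_at_cutoff_excluded(self):
        sa, sb = zp.interface_residues(two_ca_frame(8.0), "A", "B", 8.0)
        assert sa == set() and sb == set()

    def test_matches_brute_force_scan(self, toy_dimer):
        sa, sb = zp.interface_residues(toy_dimer, "A", "B", 8.0)
        brute_a, brute_b = set(), set()
        for ra in toy_dimer.residues("A"):
            for rb in toy_dimer.residues("B"):
                if np.linalg.norm(ra.ca.position - rb.ca.position) < 8.0:
                    brute_a.add(ra.seq_index)
                    brute_b.add(rb.seq_index)
        assert sa == brute_a and sb == brute_b


class TestContactOccurrence:
    def test_half_time_contact(self, toy_dimer):
        sched = ContactSchedule(np.full(8, 0.5), n_frames=100, seed=0)
        traj = make_synthetic_trajectory(toy_dimer, sched)
        prof = zp.contact_occurrence(traj, "A", "B")
        np.testing.assert_allclose(prof.occurrence, 0.5)

    def test_never_in_contact(self, toy_dimer):
        occ = np.zeros(8)
        traj = make_synthetic_trajectory(toy_dimer, ContactSchedule(occ, 10, 0))
        prof = zp.contact_occurrence(traj, "A", "B")
        assert np.all(prof.occurrence == 0.0)

    def test_recovers_prescribed_occupancies(self, toy_dimer, contact_schedule):
        traj = make_synthetic_trajectory(toy_dimer, contact_schedule)
        prof = zp.contact_occurrence(traj, "A", "B")
        np.testing.assert_allclose(prof.occurrence, contact_schedule.occupancies)

    def test_matches_brute_force_recount(self, toy_dimer):
        rng_occ = np.array([0.2, 0.8, 0.4, 0.6, 1.0, 0.0, 0.3, 0.7])
        traj = make_synthetic_trajectory(
            toy_dimer, ContactSchedule(rng_occ, n_frames=20, seed=5)
        )
        prof = zp.contact_occurrence(traj, "A", "B")
        ids = prof.residue_ids
        counts = dict.fromkeys(ids, 0)
        for frame in traj:
            for ra in frame.residues("A"):
                if any(
                    np.linalg.norm(ra.ca.position - rb.ca.position) < 8.0
                    for rb in frame.residues("B")
                ):
                    counts[ra.seq_index] += 1
        expected = np.array([counts[i] / 20 for i in ids])
        np.testing.assert_allclose(prof.occurrence, expected)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(EmptyInputError):
            zp.contact_occurrence(zp.Trajectory([]), "A", "B")


class TestSelectSegment:
    def _profile(self, occ):
        occ = np.asarray(occ, float)
        return ContactProfile(list(range(1, len(occ) + 1)), occ, 100)

    def test_enumeration_example(self):
        seg = zp.select_peptide_segment(self._profile([0.1, 0.3, 0.4, 0.5, 0.2]))
        assert (seg.start, seg.end, seg.length) == (2, 4, 3)

    def test_whole_chain_above_threshold(self):
        seg = zp.select_peptide_segment(self._profile([0.9] * 7))
        assert (seg.start, seg.end) == (1, 7)

    def test_tie_broken_by_mean_occurrence(self):
        seg = zp.select_peptide_segment(
            self._profile([0.5, 0.5, 0.1, 0.7, 0.7])
        )
        assert (seg.start, seg.end) == (4, 5)

    def test_no_residue_above_threshold(self):
        with pytest.raises(NoSegmentError):
            zp.select_peptide_segment(self._profile([0.1, 0.2, 0.05]))

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            occ = rng.random(12)
            prof = self._profile(occ)
            # brute force: every contiguous all-above run
            best = None
            for i in range(12):
                for j in range(i, 12):
                    if np.all(occ[i : j + 1] > 0.25):
                        cand = (j - i + 1, occ[i : j + 1].mean(), -(i + 1))
                        if best is None or cand > best:
                            best = cand
                            expected = (i + 1, j + 1)
            if best is None:
                with pytest.raises(NoSegmentError):
                    zp.select_peptide_segment(prof)
            else:
                seg = zp.select_peptide_segment(prof)
                assert (seg.start, seg.end) == expected

    def test_planted_block_recovered(self, toy_dimer, contact_schedule):
        traj = make_synthetic_trajectory(toy_dimer, contact_schedule)
        prof = zp.contact_occurrence(traj, "A", "B")
        seg = zp.select_peptide_segment(prof, 0.25)
        assert (seg.start, seg.end) == (3, 6)


class TestVdwFractions:
    def _matrix(self, values):
        values = np.asarray(values, float)
        rows = [("A", i + 1) for i in range(values.shape[0])]
        cols = [("B", j + 1) for j in range(values.shape[1])]
        return zp.EnergyMatrix(rows, cols, values)

    def test_arithmetic_example(self):
        m = self._matrix([[-4.0, -2.5], [-2.0, -1.5]])
        seg = SegmentSelection(1, 1, np.array([1.0]))
        assert zp.segment_vdw_fraction(m, seg) == pytest.approx(0.65)

    def test_full_segment_is_one(self):
        m = self._matrix(np.full((3, 2), -1.0))
        seg = SegmentSelection(1, 3, np.ones(3))
        assert zp.segment_vdw_fraction(m, seg) == pytest.approx(1.0)

    def test_complement_partition(self):
        rng = np.random.default_rng(0)
        m = self._matrix(rng.normal(size=(6, 4)))
        seg = SegmentSelection(2, 4, np.ones(3))
        comp_rows = [1, 5, 6]
        comp = sum(
            m.values[m.row_index(i)].sum() for i in comp_rows
        ) / m.values.sum()
        assert zp.segment_vdw_fraction(m, seg) + comp == pytest.approx(1.0)

    def test_per_residue_shares_sum_to_one(self):
        rng = np.random.default_rng(1)
        m = self._matrix(rng.normal(size=(5, 3)))
        shares = [zp.per_residue_vdw_share(m, i + 1) for i in range(5)]
        assert sum(shares) == pytest.approx(1.0)

    def test_single_nonzero_row(self):
        vals = np.zeros((3, 2))
        vals[1] = [-1.0, -2.0]
        m = self._matrix(vals)
        assert zp.per_residue_vdw_share(m, 2) == pytest.approx(1.0)

    def test_matches_brute_force_row_mask(self):
        rng = np.random.default_rng(2)
        m = self._matrix(rng.normal(size=(8, 5)))
        seg = SegmentSelection(3, 6, np.ones(4))
        brute = m.values[2:6].sum() / m.values.sum()
        assert zp.segment_vdw_fraction(m, seg) == pytest.approx(brute, rel=1e-12)


class TestRmsd:
    def test_identical_frames(self, toy_dimer):
        assert zp.rmsd(toy_dimer, toy_dimer) == 0.0

    def test_uniform_translation(self, toy_dimer):
        d = np.array([3.0, -4.0, 12.0])  # |d| = 13
        assert zp.rmsd(toy_dimer.translated(d), toy_dimer) == pytest.approx(
            13.0, abs=1e-9
        )

    def test_single_displaced_atom(self, toy_dimer):
        moved = toy_dimer.copy()
        moved.atoms()[0].position = moved.atoms()[0].position + np.array([2.0, 0, 0])
        n = toy_dimer.n_atoms
        assert zp.rmsd(moved, toy_dimer) == pytest.approx(2.0 / np.sqrt(n), abs=1e-9)

    def test_superpose_never_worse(self, toy_dimer):
        rng = np.random.default_rng(4)
        moved = toy_dimer.copy()
        for a in moved.atoms():
            a.position = a.position + rng.normal(0, 0.5, 3)
        ang = 0.3
        R = np.array([
            [np.cos(ang), -np.sin(ang), 0],
            [np.sin(ang), np.cos(ang), 0],
            [0, 0, 1],
        ])
        moved = moved.rotated(R).translated((1.0, 2.0, 3.0))
        assert zp.rmsd(moved, toy_dimer, superpose=True) <= zp.rmsd(
            moved, toy_dimer, superpose=False
        )

    def test_superposed_rigid_copy_is_zero(self, toy_dimer):
        ang = 0.9
        R = np.array([
            [1, 0, 0],
            [0, np.cos(ang), -np.sin(ang)],
            [0, np.sin(ang), np.cos(ang)],
        ])
        moved = toy_dimer.rotated(R).translated((5.0, -2.0, 0.5))
        assert zp.rmsd(moved, toy_dimer, superpose=True) < 1e-9

    def test_selection_filters_atoms(self, toy_dimer):
        moved = toy_dimer.copy()
        for res in moved.residues():
            cb = res.atom("CB")
            if cb is not None:
                cb.position = cb.position + np.array([0, 0, 5.0])
        only_ca = lambda res, a: a.name == "CA"
        assert zp.rmsd(moved, toy_dimer, selection=only_ca) == pytest.approx(0.0)


class TestEdgeToEdge:
    def _collinear(self, n=16, spacing=3.8):
        residues = [
            zp.ResidueRecord("A", i + 1, "ALA",
                             [zp.AtomRecord("CA", "C", (spacing * i, 0.0, 0.0))])
            for i in range(n)
        ]
        return zp.ChainStructure({"A": residues})

    def test_collinear_sixteen(self):
        frame = self._collinear()
        seg = SegmentSelection(1, 16, np.ones(16))
        assert zp.edge_to_edge(frame, seg) == pytest.approx(57.0)

    def test_hairpin(self):
        frame = self._collinear(4)
        frame.residues("A")[3].atoms[0].position = np.array([5.0, 0.0, 0.0])
        seg = SegmentSelection(1, 4, np.ones(4))
        assert zp.edge_to_edge(frame, seg) == pytest.approx(5.0)

    def test_rigid_motion_invariance(self):
        frame = self._collinear(8)
        seg = SegmentSelection(1, 8, np.ones(8))
        ang = 1.1
        R = np.array([
            [np.cos(ang), 0, np.sin(ang)],
            [0, 1, 0],
            [-np.sin(ang), 0, np.cos(ang)],
        ])
        moved = frame.rotated(R).translated((10.0, 20.0, 30.0))
        assert zp.edge_to_edge(moved, seg) == pytest.approx(
            zp.edge_to_edge(frame, seg), rel=1e-12
        )


class TestExtensionInterval:
    def test_hand_computed_series(self):
        iv = zp.extension_interval([1, 1, 1, 3, 3, 3], k_sigma=1.0)
        assert iv.mean == pytest.approx(2.0)
        assert iv.sd == pytest.approx(1.0)
        assert (iv.low, iv.high) == (1.0, 3.0)
        assert iv.occupancy == 1.0

    def test_gaussian_two_sigma_coverage(self):
        rng = np.random.default_rng(6)
        d = rng.normal(10.0, 2.0, 100_000)
        iv = zp.extension_interval(d, k_sigma=2.0)
        assert iv.occupancy == pytest.approx(0.9545, abs=0.01)

    def test_k_zero_degenerate(self):
        iv = zp.extension_interval([1.0, 2.0, 2.0, 3.0], k_sigma=0.0)
        assert iv.occupancy == pytest.approx(0.5)  # the two exact-mean frames

    def test_external_interval_occupancy(self):
        iv = zp.extension_interval([1, 2, 3, 4, 5, 6], interval=(2.5, 4.5))
        assert iv.occupancy == pytest.approx(2 / 6)


class TestMsaFrequencies:
    MSA = (
        ">ref\nAC-GT\n"
        ">s2\nAC-GT\n"
        ">s3\nTCAG-\n"
        ">s4\n-CAGT\n"
    )

    def test_conserved_column(self):
        freqs = zp.msa_position_frequencies(self.MSA, [2], "ref")
        assert freqs[2] == {"C": pytest.approx(1.0)}

    def test_gap_excluded_from_denominator(self):
        freqs = zp.msa_position_frequencies(self.MSA, [1], "ref")
        assert freqs[1]["A"] == pytest.approx(2 / 3)
        assert freqs[1]["T"] == pytest.approx(1 / 3)

    def test_columns_sum_to_one(self):
        freqs = zp.msa_position_frequencies(self.MSA, [1, 2, 3, 4], "ref")
        for col in freqs.values():
            assert sum(col.values()) == pytest.approx(1.0)

    def test_gap_aware_position_mapping(self):
        # reference position 3 is 'G', which sits in alignment column 4
        freqs = zp.msa_position_frequencies(self.MSA, [3], "ref")
        assert set(freqs[3]) == {"G"}

    def test_position_out_of_range(self):
        with pytest.raises(IndexError):
            zp.msa_position_frequencies(self.MSA, [5], "ref")
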