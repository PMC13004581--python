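"""Contacts, occupancy, entry events, RMSD/RMSF, H-bonds, SASA, planarity."""

import numpy as np
import pytest

from anionscout.binding_dynamics import (
    ContactFingerprint,
    cavity_occupancy,
    chromophore_planarity,
    contact_fingerprint,
    detect_entry_events,
    hydrogen_bonds,
    rmsd,
    rmsf,
    sasa,
    superpose,
)
from anionscout.traj_io import Frame, Topology, Trajectory

from conftest import brute_min_image_distance, random_trajectory


def make_traj(rows, coords_per_frame, box=None):
    top = Topology.from_rows(rows)
    frames = [Frame(coords=np.asarray(c, dtype=float), box=box)
              for c in coords_per_frame]
    return Trajectory(topology=top, frames=frames)


class TestContacts:
    def test_touching_residue_included_distant_excluded(self):
        rows = [(1, "CL", "Cl", "CLA", 99, "A"),
                (2, "CB", "C", "TYR", 64, "A"),
                (3, "CB", "C", "LYS", 168, "A")]
        traj = make_traj(rows, [[[0, 0, 0], [0, 0, 0], [0, 0, 10]]])
        fp = contact_fingerprint(traj, [0], [1, 2], cutoff=4.0)
        assert fp.frames[0] == frozenset({64})

    def test_far_anion_yields_empty_sets(self):
        rows = [(1, "CL", "Cl", "CLA", 99, "A"), (2, "CB", "C", "TYR", 64, "A")]
        traj = make_traj(rows, [[[0, 0, 0], [0, 0, 30]]])
        assert contact_fingerprint(traj, [0], [1]).frames[0] == frozenset()

    def test_empty_anion_selection_rejected(self, rng):
        traj = random_trajectory(rng, n_atoms=10)
        with pytest.raises(ValueError):
            contact_fingerprint(traj, [], "all")

    def test_matches_brute_force_with_periodic_box(self, rng):
        box = (20.0, 25.0, 18.0)
        for _ in range(30):
            n = int(rng.integers(10, 50))
            traj = random_trajectory(rng, n_atoms=n, n_frames=2, box=box)
            anion = [0]
            prot = list(range(1, n))
            fp = contact_fingerprint(traj, anion, prot, cutoff=6.0)
            for fr, got in zip(traj.frames, fp.frames):
                expected = set()
                for j in prot:
                    d = brute_min_image_distance(fr.coords[0], fr.coords[j], box)
                    if d <= 6.0:
                        expected.add(traj.topology.resids[j])
                assert got == frozenset(expected)


class TestOccupancy:
    def _fp(self, bound_pattern, cavity=(1, 2, 3)):
        frames = [frozenset(cavity) if b else frozenset() for b in bound_pattern]
        return ContactFingerprint(cutoff=4.0, frames=frames)

    def test_always_bound_is_one_full_segment(self):
        occ = cavity_occupancy(self._fp([1] * 6), {1, 2, 3}, min_residues=3)
        assert occ.segments == [(0, 6)]

    def test_short_gap_merges(self):
        occ = cavity_occupancy(self._fp([1, 1, 0, 0, 1, 1]), {1, 2, 3},
                               min_residues=3, gap_tolerance=2)
        assert occ.segments == [(0, 6)]
        assert occ.n_bound_frames == 4

    def test_gap_beyond_tolerance_splits(self):
        occ = cavity_occupancy(self._fp([1, 0, 0, 0, 1]), {1, 2, 3},
                               min_residues=3, gap_tolerance=2)
        assert occ.segments == [(0, 1), (4, 5)]

    def test_zero_tolerance_segments_are_maximal_runs(self, rng):
        for _ in range(50):
            pattern = rng.random(30) < 0.4
            occ = cavity_occupancy(self._fp(pattern), {1, 2, 3},
                                   min_residues=3, gap_tolerance=0)
            covered = occ.in_segment()
            assert np.array_equal(covered, pattern)
            for (a, b), (c, d) in zip(occ.segments, occ.segments[1:]):
                assert b < c

    def test_min_residues_threshold(self):
        frames = [frozenset({1, 2}), frozenset({1, 2, 3})]
        fp = ContactFingerprint(cutoff=4.0, frames=frames)
        occ = cavity_occupancy(fp, {1, 2, 3}, min_residues=3, gap_tolerance=0)
        assert occ.bound.tolist() == [False, True]
        with pytest.raises(ValueError):
            cavity_occupancy(fp, {1, 2, 3}, min_residues=4)


class TestEntryEvents:
    def _traj(self, dists):
        rows = [(1, "C1", "C", "CRO", 1, "A"), (2, "CL", "Cl", "CLA", 99, "A")]
        coords = [[[0, 0, 0], [d, 0, 0]] for d in dists]
        return make_traj(rows, coords)

    def test_anion_staying_in_bulk_gives_no_event(self):
        traj = self._traj([20.0] * 30)
        assert detect_entry_events(traj, [1], [0], min_persistence=5) == []

    def test_anion_starting_inside_without_bulk_history_gives_no_event(self):
        traj = self._traj([4.0] * 30)
        assert detect_entry_events(traj, [1], [0], min_persistence=5) == []

    def test_scripted_crossing_detected_at_the_planted_frame(self):
        dists = [20.0] * 12 + [5.0] * 15 + [20.0] * 3
        traj = self._traj(dists)
        events = detect_entry_events(traj, [1], [0], min_persistence=10)
        assert len(events) == 1
        assert events[0].frame == 12
        assert events[0].persistence == 15
        assert events[0].gate_residues is None

    def test_short_visit_ignored_and_hysteresis_enforced(self):
        # enters twice but never returns to bulk in between: one event
        dists = [20.0] * 5 + [5.0] * 12 + [10.0] * 3 + [5.0] * 12
        traj = self._traj(dists)
        events = detect_entry_events(traj, [1], [0], min_persistence=10)
        assert [e.frame for e in events] == [5]

    def test_gate_pair_is_nearest_candidate(self):
        rows = [(1, "C1", "C", "CRO", 1, "A"),
                (2, "CL", "Cl", "CLA", 99, "A"),
                (3, "CB", "C", "PHE", 208, "A"),
                (4, "CB", "O", "SER", 146, "A"),
                (5, "CB", "C", "GLY", 300, "A"),
                (6, "CB", "C", "GLY", 301, "A")]
        near = [[6, 0, 0], [6, 1, 0]]
        far = [[-30, 0, 0], [-30, 1, 0]]
        coords = [[[0, 0, 0], [d, 0, 0]] + near + far
                  for d in [20.0] * 5 + [5.0] * 15]
        traj = make_traj(rows, coords)
        events = detect_entry_events(traj, [1], [0], min_persistence=10,
                                     gate_candidates=[(208, 146), (300, 301)])
        assert events[0].gate_residues == (208, 146)

    def test_threshold_ordering_enforced(self):
        traj = self._traj([20.0] * 5)
        with pytest.raises(ValueError):
            detect_entry_events(traj, [1], [0], r_inside=16.0, r_bulk=15.0)


class TestRMSD:
    def test_identical_frames_zero(self, rng):
        x = rng.normal(size=(10, 3))
        assert rmsd(x, x) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_recovered_by_superposition(self, rng):
        x = rng.normal(size=(12, 3))
        theta = np.radians(37.0)
        Rz = np.array([[np.cos(theta), -np.sin(theta), 0],
                       [np.sin(theta), np.cos(theta), 0],
                       [0, 0, 1.0]])
        moved = x @ Rz.T + np.array([1.0, -2.0, 3.0])
        assert rmsd(moved, x, superpose_first=True) == pytest.approx(0.0, abs=1e-6)
        assert rmsd(moved, x, superpose_first=False) > 1.0

    def test_three_four_five_translation_without_fitting(self, rng):
        x = rng.normal(size=(7, 3))
        assert rmsd(x + np.array([3.0, 4.0, 0.0]), x,
                    superpose_first=False) == pytest.approx(5.0, abs=1e-12)

    def test_symmetry_and_nonnegativity(self, rng):
        a = rng.normal(size=(9, 3))
        b = rng.normal(size=(9, 3))
        ab = rmsd(a, b)
        assert ab == pytest.approx(rmsd(b, a), abs=1e-9)
        assert ab >= 0

    def test_cardinality_and_collinearity_errors(self, rng):
        with pytest.raises(ValueError):
            rmsd(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))
        line = np.outer(np.arange(5.0), np.array([1.0, 0, 0]))
        with pytest.raises(ValueError):
            superpose(line, line + 1.0)


class TestRMSF:
    def test_static_trajectory_is_zero(self, rng):
        x = rng.normal(size=(8, 3)) * 5
        rows = [(i + 1, "CA", "C", "GLY", i + 1, "A") for i in range(8)]
        traj = make_traj(rows, [x, x, x])
        assert np.allclose(rmsf(traj), 0.0, atol=1e-9)

    def test_single_oscillating_atom_closed_form(self, rng):
        n_static = 20
        static = rng.normal(scale=4.0, size=(n_static, 3))
        # oscillator at the static centroid: no torque, so the superposition
        # only absorbs the d/n centroid shift and the closed form is exact
        base = np.vstack([static, static.mean(axis=0)])
        d = 0.7
        n = n_static + 1
        frames = []
        for s in (+1, -1, +1, -1):
            c = base.copy()
            c[n_static, 0] += s * d
            frames.append(c)
        rows = [(i + 1, "CA", "C", "GLY", i + 1, "A") for i in range(n)]
        traj = make_traj(rows, frames)
        vals = rmsf(traj)
        assert vals[n_static] == pytest.approx(d * (1 - 1 / n), abs=1e-9)
        assert np.allclose(vals[:n_static], d / n, atol=1e-9)

    def test_matches_brute_force_formula(self, rng):
        from scipy.spatial.transform import Rotation

        base = rng.normal(size=(10, 3)) * 4
        frames = [base + rng.normal(scale=0.3, size=base.shape) for _ in range(6)]
        rows = [(i + 1, "CA", "C", "GLY", i + 1, "A") for i in range(10)]
        traj = make_traj(rows, frames)
        got = rmsf(traj)

        ref = frames[0]
        aligned = []
        for f in frames:
            rot, _ = Rotation.align_vectors(ref - ref.mean(0), f - f.mean(0))
            aligned.append(rot.apply(f - f.mean(0)) + ref.mean(0))
        aligned = np.array(aligned)
        mean = aligned.mean(axis=0)
        expected = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))
        assert np.allclose(got, expected, atol=1e-8)

    def test_single_frame_rejected(self, rng):
        traj = random_trajectory(rng, n_atoms=5, n_frames=1)
        with pytest.raises(ValueError):
            rmsf(traj)


class TestHydrogenBonds:
    def _traj(self, acceptor_x, h_x=0.96):
        rows = [(1, "OG", "O", "SER", 1, "A"),
                (2, "HG", "H", "SER", 1, "A"),
                (3, "OD1", "O", "ASP", 2, "A")]
        coords = [[[0, 0, 0], [h_x, 0, 0], [acceptor_x, 0, 0]]]
        return make_traj(rows, coords)

    def test_collinear_short_contact_present(self):
        occ = hydrogen_bonds(self._traj(2.8), [(0, 1)], [2])
        assert occ[(0, 1, 2)] == 1.0

    def test_long_contact_absent(self):
        occ = hydrogen_bonds(self._traj(4.0), [(0, 1)], [2])
        assert occ[(0, 1, 2)] == 0.0

    def test_bent_geometry_fails_angle_criterion(self):
        rows = [(1, "OG", "O", "SER", 1, "A"),
                (2, "HG", "H", "SER", 1, "A"),
                (3, "OD1", "O", "ASP", 2, "A")]
        # acceptor on the far side of the donor: D-H...A angle ~ 0°
        traj = make_traj(rows, [[[0, 0, 0], [0.96, 0, 0], [-2.0, 0, 0]]])
        occ = hydrogen_bonds(traj, [(0, 1)], [2])
        assert occ[(0, 1, 2)] == 0.0

    def test_unbonded_donor_pair_skipped_with_warning(self):
        traj = self._traj(2.8, h_x=2.0)
        with pytest.warns(UserWarning, match="skipped"):
            occ = hydrogen_bonds(traj, [(0, 1)], [2])
        assert occ == {}

    def test_matches_brute_force_occupancies(self, rng):
        for _ in range(20):
            n = 12
            rows = []
            for i in range(n):
                el = "O" if i % 3 == 0 else ("H" if i % 3 == 1 else "N")
                rows.append((i + 1, el, el, "GLY", i + 1, "A"))
            frames = []
            base = rng.uniform(0, 8, size=(n, 3))
            for _ in range(4):
                f = base.copy()
                # keep each donor H near its heavy atom
                for d in range(0, n, 3):
                    f[d + 1] = f[d] + rng.normal(scale=0.3, size=3)
                    f[d + 1] = f[d] + 0.96 * (f[d + 1] - f[d]) / np.linalg.norm(f[d + 1] - f[d])
                frames.append(f + rng.normal(scale=0.2, size=f.shape))
            traj = make_traj(rows, frames)
            donors = [(d, d + 1) for d in range(0, n, 3)]
            acceptors = [a for a in range(2, n, 3)]
            import warnings as _w
            with _w.catch_warnings():
                # jitter occasionally stretches a D-H pair past the bonding
                # check; those pairs are (correctly) dropped
                _w.simplefilter("ignore", UserWarning)
                got = hydrogen_bonds(traj, donors, acceptors)
            for (d, h, a), occ in got.items():
                hits = 0
                for fr in traj.frames:
                    da = np.linalg.norm(fr.coords[d] - fr.coords[a])
                    v1 = fr.coords[d] - fr.coords[h]
                    v2 = fr.coords[a] - fr.coords[h]
                    ang = np.degrees(np.arccos(np.clip(
                        v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2), -1, 1)))
                    if da <= 3.5 and ang >= 120.0:
                        hits += 1
                assert occ == pytest.approx(hits / traj.n_frames)


class TestSASA:
    def test_isolated_sphere_closed_form(self):
        area = sasa(np.zeros((1, 3)), ["S"], radii_map={"S": 1.9})
        assert area[0] == pytest.approx(4 * np.pi * 3.3 ** 2, rel=1e-12)

    def test_two_distant_atoms_keep_full_area(self):
        coords = np.array([[0, 0, 0], [100.0, 0, 0]])
        areas = sasa(coords, ["C", "O"])
        assert areas[0] == pytest.approx(4 * np.pi * (1.70 + 1.4) ** 2, rel=1e-12)
        assert areas[1] == pytest.approx(4 * np.pi * (1.52 + 1.4) ** 2, rel=1e-12)

    def test_engulfed_atom_has_zero_area(self):
        coords = np.zeros((2, 3))
        areas = sasa(coords, ["H", "C"], radii_map={"H": 0.1, "C": 5.0})
        assert areas[0] == 0.0

    def test_missing_radius_names_element(self):
        with pytest.raises(ValueError, match="SE"):
            sasa(np.zeros((1, 3)), ["Se"], radii_map={"C": 1.7})

    def test_burial_monotone_as_neighbor_approaches(self):
        base = np.array([[0.0, 0, 0], [8.0, 0, 0]])
        prev = np.inf
        for x in (8.0, 6.0, 4.0, 3.0):
            base[1, 0] = x
            a = sasa(base, ["C", "C"])[0]
            assert a <= prev + 1e-9
            prev = a


class TestPlanarity:
    def _traj(self, coords):
        rows = [(i + 1, f"C{i+1}", "C", "CRO", 1, "A") for i in range(len(coords))]
        return make_traj(rows, [coords])

    def test_coplanar_atoms_zero(self):
        sq = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        assert chromophore_planarity(self._traj(sq), [0, 1, 2, 3])[0] == pytest.approx(0.0, abs=1e-12)

    def test_lifted_corner_matches_brute_force_plane_fit(self, rng):
        pts = np.array([[0, 0, 0], [2, 0, 0], [2, 2, 0], [0, 2, 0], [1, 1, 0.8]])
        got = chromophore_planarity(self._traj(pts), list(range(5)))[0]
        centered = pts - pts.mean(axis=0)
        _, _, Vt = np.linalg.svd(centered)
        expected = np.sqrt(np.mean((centered @ Vt[-1]) ** 2))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_rigid_rotation(self, rng):
        pts = rng.normal(size=(6, 3))
        theta = 0.9
        R = np.array([[np.cos(theta), 0, np.sin(theta)],
                      [0, 1, 0],
                      [-np.sin(theta), 0, np.cos(theta)]])
        a = chromophore_planarity(self._traj(pts), list(range(6)))[0]
        b = chromophore_planarity(self._traj(pts @ R.T + 3.0), list(range(6)))[0]
        assert a == pytest.approx(b, abs=1e-9)

    def test_too_few_atoms_rejected(self):
        tri = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            chromophore_planarity(self._traj(tri), [0, 1, 2])
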