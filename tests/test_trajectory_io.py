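"""Ensemble I/O, outcome classification and subset selection."""

import numpy as np
import pytest

from entropath.trajectory_io import (Outcome, Trajectory, TrajectoryEnsemble,
                                     bond_length_series, classify_outcome,
                                     read_ensemble, read_ensemble_hdf5,
                                     read_xyz_frames, select_subsets,
                                     write_ensemble, write_ensemble_hdf5)

BONDS = {1: (1, 2), 2: (0, 1), 3: (0, 2)}
TSS = {1: 1.6, 2: 2.5, 3: 2.5}


def synthetic_trajectory(d2_series, d3_series, d1_series=None, outcome=None):
    """Three atoms embedded so all three bond-length series are realized
    exactly (atom 2 trilaterated from atoms 0 and 1)."""
    f = len(d2_series)
    d1 = d1_series if d1_series is not None else [1.6] * f
    coords = np.zeros((f, 3, 3))
    for t in range(f):
        a, b, c = d2_series[t], d3_series[t], d1[t]
        coords[t, 1] = (a, 0.0, 0.0)
        x = (a * a + b * b - c * c) / (2 * a)
        coords[t, 2] = (x, np.sqrt(max(b * b - x * x, 0.0)), 0.0)
    traj = Trajectory(coordinates=coords, velocities=None,
                      energies=np.zeros(f),
                      times=np.arange(f, dtype=float),
                      atom_labels=["C", "C", "C"], outcome=outcome)
    return traj


class TestClassifyOutcome:
    def test_bond2_first_crossing_labels_adduct_42(self):
        traj = synthetic_trajectory([2.3, 2.0, 1.65], [2.6, 2.5, 2.4])
        assert classify_outcome(traj, BONDS, TSS) == Outcome.ADDUCT_42

    def test_constant_bonds_are_unresolved(self):
        traj = synthetic_trajectory([2.5] * 10, [2.5] * 10)
        assert classify_outcome(traj, BONDS, TSS) == Outcome.UNRESOLVED

    def test_labels_match_brute_force_scan(self, rng):
        """50 random-walk trajectories: the label equals a frame-by-frame
        brute-force search for the first decisive event."""
        for _ in range(50):
            f = 40
            d2 = 2.5 + np.cumsum(rng.normal(0, 0.12, f))
            d3 = 2.5 + np.cumsum(rng.normal(0, 0.12, f))
            d1 = 1.6 + np.cumsum(rng.normal(0, 0.08, f))
            coords = np.zeros((f, 3, 3))
            # explicit embedding: atom0 at origin, atom1 on x, atom2 placed
            # to satisfy both d3 (to atom0) and d1 (to atom1) when possible
            for t in range(f):
                coords[t, 1] = (d2[t], 0, 0)
                a, b, c = d2[t], d3[t], d1[t]
                x = (a * a + b * b - c * c) / (2 * a)
                y2 = max(b * b - x * x, 0.0)
                coords[t, 2] = (x, np.sqrt(y2), 0)
            traj = Trajectory(coordinates=coords, velocities=None,
                              energies=np.zeros(f),
                              times=np.arange(f, dtype=float),
                              atom_labels=["C"] * 3)
            # brute force oracle
            expected = Outcome.UNRESOLVED
            d1s = bond_length_series(traj, BONDS[1])
            d2s = bond_length_series(traj, BONDS[2])
            d3s = bond_length_series(traj, BONDS[3])
            for t in range(f):
                if d2s[t] < 1.7:
                    expected = Outcome.ADDUCT_42
                    break
                if d3s[t] < 1.7:
                    expected = Outcome.ADDUCT_64
                    break
                if d1s[t] > TSS[1] + 0.5 and d2s[t] > 1.7 and d3s[t] > 1.7:
                    expected = Outcome.RECROSS
                    break
            assert classify_outcome(traj, BONDS, TSS) == expected

    def test_invariant_to_post_termination_frames(self):
        d2 = [2.3, 2.0, 1.65, 3.5, 0.9]
        d3 = [2.6, 2.5, 2.4, 2.4, 1.2]
        short = synthetic_trajectory(d2[:3], d3[:3])
        long = synthetic_trajectory(d2, d3)
        assert classify_outcome(short, BONDS, TSS) \
            == classify_outcome(long, BONDS, TSS)


class TestSelectSubsets:
    def _ensemble(self, n_a, n_b):
        trajs = []
        for k in range(n_a):
            trajs.append(synthetic_trajectory([2.0, 1.6], [2.4, 2.4],
                                              outcome=Outcome.ADDUCT_42))
        for k in range(n_b):
            trajs.append(synthetic_trajectory([2.4, 2.4], [2.0, 1.6],
                                              outcome=Outcome.ADDUCT_64))
        return TrajectoryEnsemble(trajs, BONDS, TSS)

    def test_subset_sizes_are_exact(self):
        ens = self._ensemble(737, 196)   # scaled-down imbalanced classes
        subs = select_subsets(ens, n_per_outcome=102, seed=4)
        assert {len(v) for v in subs.values()} == {102}

    def test_subsets_have_no_label_leakage(self):
        ens = self._ensemble(120, 110)
        subs = select_subsets(ens, n_per_outcome=50, seed=4)
        for outcome, trajs in subs.items():
            assert all(t.outcome == outcome for t in trajs)

    def test_full_class_returned_when_n_equals_size(self):
        ens = self._ensemble(10, 15)
        subs = select_subsets(ens, n_per_outcome=10, seed=0)
        assert len(subs[Outcome.ADDUCT_42]) == 10

    def test_deterministic_under_seed(self):
        ens = self._ensemble(60, 60)
        a = select_subsets(ens, n_per_outcome=20, seed=7)
        b = select_subsets(ens, n_per_outcome=20, seed=7)
        for oc in a:
            assert [id(t) for t in a[oc]] == [id(t) for t in b[oc]]

    def test_too_small_class_reports_count(self):
        ens = self._ensemble(5, 200)
        with pytest.raises(ValueError, match="only 5"):
            select_subsets(ens, n_per_outcome=102, seed=0)


class TestRoundTrip:
    def test_xyz_sidecar_round_trip_is_bit_identical(self, small_ensemble,
                                                     tmp_path):
        sub = TrajectoryEnsemble(small_ensemble.trajectories[:3],
                                 small_ensemble.bond_definitions,
                                 small_ensemble.tss_bond_lengths,
                                 meta=small_ensemble.meta)
        write_ensemble(sub, tmp_path)
        back = read_ensemble(tmp_path)
        for ta, tb in zip(sub.trajectories, back.trajectories):
            assert np.array_equal(ta.coordinates, tb.coordinates)
            assert np.array_equal(ta.velocities, tb.velocities)
            assert np.array_equal(ta.energies, tb.energies)
            assert ta.outcome == tb.outcome

    def test_hdf5_round_trip(self, small_ensemble, tmp_path):
        path = tmp_path / "ens.h5"
        write_ensemble_hdf5(small_ensemble, path)
        back = read_ensemble_hdf5(path)
        assert len(back) == len(small_ensemble)
        ta = small_ensemble.trajectories[5]
        tb = back.trajectories[5]
        assert np.array_equal(ta.coordinates, tb.coordinates)
        assert np.array_equal(ta.energies, tb.energies)

    def test_bond_series_matches_direct_recomputation(self, small_ensemble):
        for traj in small_ensemble.trajectories[:10]:
            series = bond_length_series(traj, (0, 1))
            direct = np.sqrt(((traj.coordinates[:, 0]
                               - traj.coordinates[:, 1]) ** 2).sum(axis=1))
            assert np.array_equal(series, direct)

    def test_missing_atom_reports_frame(self, tmp_path):
        content = "3\nframe=0 time_fs=0.0\nC 0 0 0\nC 1 0 0\nC 0 1 0\n" \
                  "3\nframe=1 time_fs=1.0\nC 0 0 0\nC 1 0 0\n"
        bad = tmp_path / "bad.xyz"
        bad.write_text(content)
        with pytest.raises(ValueError, match="frame 1"):
            read_xyz_frames(bad)

    def test_mdanalysis_reads_written_xyz(self, small_ensemble, tmp_path):
        """The written multi-frame XYZ is readable by an independent
        trajectory library to its parsing precision."""
        mda = pytest.importorskip("MDAnalysis")
        sub = TrajectoryEnsemble(small_ensemble.trajectories[:1],
                                 small_ensemble.bond_definitions,
                                 small_ensemble.tss_bond_lengths)
        write_ensemble(sub, tmp_path)
        u = mda.Universe(str(tmp_path / "traj_00000.xyz"))
        ref = sub.trajectories[0]
        assert len(u.trajectory) == ref.n_frames
        u.trajectory[0]
        assert np.allclose(u.atoms.positions,
                           ref.coordinates[0], atol=1e-3)
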