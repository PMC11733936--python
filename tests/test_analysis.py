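"""Trajectory post-processing: superposition, RMSD, unbinding detection,
censored medians and temperature scans."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from modbind.analysis import (
    CENSOR_AT_TMAX,
    DROP_CENSORED,
    LOWER_BOUND,
    RELIABLE,
    ReplicaSetResult,
    RmsdSeries,
    Trajectory,
    UnbindingEvent,
    detect_unbinding,
    ligand_rmsd_series,
    median_unbinding_time,
    superpose_to_first_frame,
    temperature_scan,
)
from modbind.errors import InvalidInputError
from modbind.toy import ScriptedTrajectorySpec, make_scripted_trajectory


def _static_traj(structure, n_frames=5):
    frames = np.repeat(structure.xyz[None], n_frames, axis=0)
    return Trajectory(structure, frames, np.arange(n_frames) * 10.0)


class TestSuperposition:
    def test_identity_frames_unchanged(self, toy_structure):
        traj = _static_traj(toy_structure)
        out = superpose_to_first_frame(traj)
        np.testing.assert_allclose(out.frames, traj.frames, atol=1e-9)

    def test_removes_rigid_rotation(self, toy_structure):
        rot = Rotation.from_euler("y", 90, degrees=True)
        frames = np.stack([toy_structure.xyz, rot.apply(toy_structure.xyz) + 3.0])
        traj = Trajectory(toy_structure, frames, np.array([0.0, 10.0]))
        out = superpose_to_first_frame(traj)
        prot = toy_structure.protein_indices
        rmsd = np.sqrt(np.mean(np.sum((out.frames[1, prot] - out.frames[0, prot]) ** 2, axis=1)))
        assert rmsd < 1e-6

    def test_ligand_displacement_survives_protein_fit(self, toy_structure):
        spec = ScriptedTrajectorySpec(
            n_frames=4, departure_frame=2, displacement_A=8.0,
            rotation_deg_per_frame=25.0,
        )
        traj = make_scripted_trajectory(spec, toy_structure)
        series = ligand_rmsd_series(superpose_to_first_frame(traj))
        assert series.values_A[2] == pytest.approx(8.0, abs=1e-8)

    def test_degenerate_selection_rejected(self, toy_structure):
        traj = _static_traj(toy_structure)
        with pytest.raises(InvalidInputError):
            superpose_to_first_frame(traj, selection=[0, 1])


class TestLigandRmsd:
    def test_reference_frame_is_zero(self, toy_structure):
        series = ligand_rmsd_series(_static_traj(toy_structure))
        assert series.values_A[0] == pytest.approx(0.0, abs=1e-6)

    def test_uniform_translation_gives_pythagorean_rmsd(self, toy_structure):
        frames = np.repeat(toy_structure.xyz[None], 2, axis=0)
        frames[1, toy_structure.ligand_selection] += np.array([3.0, 4.0, 0.0])
        traj = Trajectory(toy_structure, frames, np.array([0.0, 10.0]))
        series = ligand_rmsd_series(traj)
        assert series.values_A[1] == pytest.approx(5.0, rel=1e-12)


class TestDetectUnbinding:
    def test_all_bound_is_censored(self):
        series = RmsdSeries(np.arange(10) * 10.0, np.full(10, 1.0))
        event = detect_unbinding(series, cutoff_A=5.0, persistence=1)
        assert event.censored and event.t_max_ps == 90.0

    def test_crossing_time_reported_in_time_units(self, toy_structure):
        spec = ScriptedTrajectorySpec(n_frames=120, departure_frame=100)
        series = ligand_rmsd_series(
            superpose_to_first_frame(make_scripted_trajectory(spec, toy_structure))
        )
        assert detect_unbinding(series, 5.0, persistence=1).unbind_time_ps == 1000.0

    def test_single_frame_excursion_ignored_with_persistence(self, toy_structure):
        spec = ScriptedTrajectorySpec(
            n_frames=120, departure_frame=100, recrossing_frames=(50,)
        )
        series = ligand_rmsd_series(
            superpose_to_first_frame(make_scripted_trajectory(spec, toy_structure))
        )
        assert detect_unbinding(series, 5.0, persistence=1).unbind_time_ps == 500.0
        assert detect_unbinding(series, 5.0, persistence=5).unbind_time_ps == 1000.0

    def test_trailing_run_shorter_than_persistence_is_censored(self):
        values = np.array([0.0, 1.0, 1.0, 6.0, 6.0])
        series = RmsdSeries(np.arange(5) * 10.0, values)
        assert detect_unbinding(series, 5.0, persistence=3).censored
        assert detect_unbinding(series, 5.0, persistence=2).unbind_time_ps == 30.0

    def test_interval_refinement_leaves_time_unchanged(self, toy_structure):
        """Detected unbinding is a time, not a frame index."""
        coarse = ScriptedTrajectorySpec(n_frames=120, frame_interval_ps=10.0, departure_frame=100)
        fine = ScriptedTrajectorySpec(n_frames=240, frame_interval_ps=5.0, departure_frame=200)
        times = []
        for spec in (coarse, fine):
            series = ligand_rmsd_series(
                superpose_to_first_frame(make_scripted_trajectory(spec, toy_structure))
            )
            times.append(detect_unbinding(series, 5.0, persistence=1).unbind_time_ps)
        assert times[0] == times[1] == 1000.0


def _events(times, t_max):
    return [
        UnbindingEvent(i, t, t_max) for i, t in enumerate(times)
    ]


class TestMedianUnbindingTime:
    def test_textbook_median_odd_and_even(self):
        res = ReplicaSetResult("lig", 900.0, _events([1000.0, 2000.0, 3000.0], 5000.0))
        assert median_unbinding_time(res) == (2000.0, RELIABLE)
        res4 = ReplicaSetResult("lig", 900.0, _events([1000.0, 2000.0, 3000.0, 4000.0], 5000.0))
        assert median_unbinding_time(res4)[0] == 2500.0

    def test_censored_enters_at_tmax(self):
        res = ReplicaSetResult("lig", 900.0, _events([1000.0, 2000.0, None], 5000.0))
        tau, quality = median_unbinding_time(res)
        assert (tau, quality) == (2000.0, RELIABLE)

    def test_majority_censored_is_lower_bound(self):
        res = ReplicaSetResult("lig", 900.0, _events([1000.0, None, None, None], 5000.0))
        tau, quality = median_unbinding_time(res)
        assert quality == LOWER_BOUND
        assert tau == 5000.0

    def test_exactly_half_unbound_is_lower_bound(self):
        res = ReplicaSetResult("lig", 900.0, _events([1000.0, None], 5000.0))
        assert median_unbinding_time(res)[1] == LOWER_BOUND

    def test_drop_policy(self):
        res = ReplicaSetResult("lig", 900.0, _events([1000.0, 3000.0, None], 5000.0))
        assert median_unbinding_time(res, DROP_CENSORED)[0] == 2000.0
        all_censored = ReplicaSetResult("lig", 900.0, _events([None, None], 5000.0))
        with pytest.raises(InvalidInputError):
            median_unbinding_time(all_censored, DROP_CENSORED)

    def test_empty_event_list_rejected(self):
        with pytest.raises(InvalidInputError):
            median_unbinding_time(ReplicaSetResult("lig", 900.0, []))

    @given(
        times=st.lists(
            st.one_of(st.none(), st.floats(1.0, 999.0)), min_size=1, max_size=12
        ),
        idx=st.integers(0, 11),
    )
    def test_censoring_never_decreases_median(self, times, idx):
        idx = idx % len(times)
        base = ReplicaSetResult("lig", 900.0, _events(times, 1000.0))
        censored_times = list(times)
        censored_times[idx] = None
        more = ReplicaSetResult("lig", 900.0, _events(censored_times, 1000.0))
        assert median_unbinding_time(more)[0] >= median_unbinding_time(base)[0]


class TestTemperatureScan:
    def _res(self, tau_ps_list, t_max=4000.0):
        times = [t if t is not None and t <= t_max else None for t in tau_ps_list]
        return ReplicaSetResult("ref", 0.0, _events(times, t_max))

    def test_lowest_qualifying_temperature_wins(self):
        by_T = {
            600.0: [self._res([None, None, 3000.0])],
            800.0: [self._res([1000.0, 2000.0, 3000.0])],
            1000.0: [self._res([100.0, 200.0, 300.0])],
        }
        scan = temperature_scan(by_T, target_window_ns=(0.0, 4.0))
        assert scan.recommended_K == 800.0 and not scan.no_solution

    def test_only_hottest_unbinds_everything(self):
        by_T = {
            600.0: [self._res([None, None, None])],
            1000.0: [self._res([500.0, 1500.0, 2500.0])],
        }
        assert temperature_scan(by_T).recommended_K == 1000.0

    def test_no_solution_flagged_with_table(self):
        by_T = {
            600.0: [self._res([None, None, None])],
            800.0: [self._res([None, None, None])],
        }
        scan = temperature_scan(by_T)
        assert scan.no_solution and scan.recommended_K is None
        assert len(scan.table) == 2
        assert not scan

    def test_requires_two_temperatures(self):
        with pytest.raises(InvalidInputError):
            temperature_scan({600.0: [self._res([100.0])]})
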