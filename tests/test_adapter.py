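"""Restraint selection, simulation-spec validation, replica planning and the
toy backend's fulfilment of the MD contract."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from modbind.adapter import (
    ReplicaRun,
    ToyBackend,
    build_simulation_spec,
    plan_replicas,
    select_restrained_atoms,
)
from modbind.analysis import analyze_replica_trajectories
from modbind.errors import ConfigValidationError, InvalidInputError
from modbind.model import KoffModel
from modbind.structure import StructureModel
from modbind.toy import ToyPotential


def _three_residue_structure(distances=(3.0, 5.9, 10.0)):
    """Single-atom ligand at the origin; one backbone residue per distance."""
    names, elements, resids, resnames, chains, records, coords = [], [], [], [], [], [], []
    for i, d in enumerate(distances):
        for j, name in enumerate(("N", "CA", "C", "O")):
            names.append(name)
            elements.append(name[0])
            resids.append(i + 1)
            resnames.append("GLY")
            chains.append("A")
            records.append("ATOM")
            # CA sits exactly at the stated distance; the rest slightly beyond
            coords.append([d + (0.0 if name == "CA" else 0.5 + 0.1 * j), 0.0, 0.0])
    names.append("C1")
    elements.append("C")
    resids.append(len(distances) + 1)
    resnames.append("LIG")
    chains.append("A")
    records.append("HETATM")
    coords.append([0.0, 0.0, 0.0])
    n = len(names)
    return StructureModel(
        serials=np.arange(1, n + 1),
        names=np.array(names),
        elements=np.array(elements),
        resids=np.array(resids),
        resnames=np.array(resnames),
        chains=np.array(chains),
        record_types=np.array(records),
        xyz=np.array(coords),
        ligand_selection=np.array([n - 1]),
        protein_backbone=np.arange(n - 1),
    )


class TestRestraintSelection:
    def test_residue_at_5p9_escapes_restraints_at_cutoff_6(self):
        s = _three_residue_structure()
        restrained = select_restrained_atoms(s, cutoff_A=6.0)
        freed_resids = set(s.resids[np.setdiff1d(s.protein_backbone, restrained)])
        assert freed_resids == {1, 2}
        assert set(s.resids[restrained]) == {3}

    def test_far_ligand_restrains_entire_backbone(self):
        s = _three_residue_structure(distances=(20.0, 30.0, 40.0))
        restrained = select_restrained_atoms(s, cutoff_A=6.0)
        np.testing.assert_array_equal(np.sort(restrained), s.protein_backbone)

    def test_zero_cutoff_restrains_entire_backbone(self):
        s = _three_residue_structure()
        restrained = select_restrained_atoms(s, cutoff_A=0.0)
        np.testing.assert_array_equal(np.sort(restrained), s.protein_backbone)

    def test_invariant_under_rigid_motion(self, toy_structure):
        before = select_restrained_atoms(toy_structure, 6.0)
        rot = Rotation.from_euler("xyz", [30, -45, 60], degrees=True)
        moved = toy_structure.with_coordinates(rot.apply(toy_structure.xyz) + 12.3)
        after = select_restrained_atoms(moved, 6.0)
        np.testing.assert_array_equal(before, after)

    def test_empty_ligand_selection_rejected(self, toy_structure):
        bare = toy_structure.with_coordinates(toy_structure.xyz)
        bare.ligand_selection = np.array([], dtype=int)
        with pytest.raises(InvalidInputError):
            select_restrained_atoms(bare, 6.0)


class TestSimulationSpec:
    def test_minimal_config_fills_protocol_defaults(self, toy_structure):
        spec = build_simulation_spec(
            {"temperature_K": 900.0, "total_time_ns": 1.0}, toy_structure
        )
        assert spec.temperature_K == 900.0
        assert spec.time_step_fs == 2.0
        assert spec.ensemble == "NVT"
        assert spec.restraints.sigma_A == 3.0
        assert spec.n_replicas == 32
        assert spec.n_frames == 101

    def test_explicit_replica_count_honored(self, toy_structure):
        spec = build_simulation_spec(
            {"temperature_K": 900.0, "total_time_ns": 1.0, "n_replicas": 8}, toy_structure
        )
        assert spec.n_replicas == 8

    def test_validation_error_lists_offending_keys(self, toy_structure):
        with pytest.raises(ConfigValidationError, match="temperature_K"):
            build_simulation_spec(
                {"temperature_K": -1.0, "total_time_ns": 1.0}, toy_structure
            )
        with pytest.raises(ConfigValidationError, match="time_step_fs"):
            build_simulation_spec(
                {"temperature_K": 900.0, "total_time_ns": 1.0, "time_step_fs": 0},
                toy_structure,
            )
        with pytest.raises(ConfigValidationError, match="integer frame count"):
            build_simulation_spec(
                {"temperature_K": 900.0, "total_time_ns": 1.0, "frame_interval_ps": 7.0},
                toy_structure,
            )

    def test_boltzmann_consistent_force_constant(self, toy_structure):
        spec = build_simulation_spec(
            {"temperature_K": 900.0, "total_time_ns": 1.0}, toy_structure
        )
        # k_B * 300 K / (3 A)^2 in kcal/mol/A^2
        assert spec.restraints.force_constant_kcal_mol_A2 == pytest.approx(
            1.987e-3 * 300.0 / 9.0, rel=1e-12
        )


class TestReplicaPlan:
    def test_seeds_are_base_plus_index(self, toy_structure):
        spec = build_simulation_spec(
            {"temperature_K": 900.0, "total_time_ns": 1.0, "n_replicas": 32,
             "base_seed": 77}, toy_structure
        )
        plan = plan_replicas(spec)
        assert len(plan) == 32
        assert [r.seed for r in plan] == [77 + i for i in range(32)]
        assert len({r.seed for r in plan}) == 32

    def test_plan_is_deterministic(self, toy_structure):
        spec = build_simulation_spec(
            {"temperature_K": 900.0, "total_time_ns": 1.0, "n_replicas": 4}, toy_structure
        )
        assert plan_replicas(spec) == plan_replicas(spec)

    def test_single_replica_uses_base_seed(self, toy_structure):
        spec = build_simulation_spec(
            {"temperature_K": 900.0, "total_time_ns": 1.0, "n_replicas": 1,
             "base_seed": 5}, toy_structure
        )
        assert plan_replicas(spec) == [ReplicaRun(0, 5, spec)]


class TestToyBackendContract:
    def test_trajectory_has_declared_frame_count_and_interval(self, toy_structure):
        spec = build_simulation_spec(
            {"temperature_K": 900.0, "total_time_ns": 0.5, "n_replicas": 2,
             "frame_interval_ps": 10.0}, toy_structure
        )
        backend = ToyBackend(toy_structure, ToyPotential(barrier_height=5.0), spec)
        traj = backend.run(plan_replicas(spec)[0])
        assert traj.n_frames == spec.n_frames == 51
        assert np.allclose(np.diff(traj.times_ps), 10.0)

    def test_plan_simulate_analyze_end_to_end(self, toy_structure):
        """Full integration: plan -> toy backend -> analysis -> k_off estimate."""
        spec = build_simulation_spec(
            {"temperature_K": 900.0, "total_time_ns": 1.0, "n_replicas": 6,
             "base_seed": 3}, toy_structure
        )
        backend = ToyBackend(toy_structure, ToyPotential(barrier_height=5.0), spec)
        trajs = [backend.run(r) for r in plan_replicas(spec)]
        result = analyze_replica_trajectories(trajs, "lig", 900.0, persistence=2)
        assert result.n_replicas == 6
        # detected times agree with the backend's own first-passage times
        # up to frame quantisation (one frame interval)
        for rep, event in zip(plan_replicas(spec), result.events):
            t_ps = backend.escape_time_ps(rep)
            if event.censored:
                assert t_ps is None or t_ps > spec.total_time_ns * 1000.0
            else:
                assert 0 <= event.unbind_time_ps - t_ps <= spec.frame_interval_ps
        from modbind.reweight import ReweightingParams

        res = KoffModel(result, ReweightingParams(900.0, 300.0)).fit(
            allow_lower_bound=True, n_boot=0
        )
        assert np.isfinite(res.log10_koff_ref)
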